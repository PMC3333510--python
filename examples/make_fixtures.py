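"""Write a complete synthetic study to disk, then run the CLI on it.

Produces reference.fa, bracket-dialect read files, the cross-reference
snapshot and the truth table under ./fixture_demo/, reproducibly for a
given seed.  The equivalent shell commands are printed at the end.
"""

from uasis import FixtureSpec
from uasis.fixtures import generate_fixture_set

spec = FixtureSpec(
    genome_length=20_000,
    n_snps=50,
    read_lengths=(35, 76),
    substitution_error_rate=0.01,
    seed=7,
)
paths = generate_fixture_set(spec, "fixture_demo")
for kind, path in paths.items():
    print(f"{kind:12} {path}")

# only about half the planted variants carry snapshot identifiers
# (the rest exercise "none" reporting); pick one that does
first_rs = next(
    line.split("\t")[3]
    for line in open(paths["xref"])
    if not line.startswith(("#", "chrom"))
)
print("\nnow try, for example:")
print(f"  uasis align {paths['reads_L76']} --reference {paths['reference']} "
      f"--xref {paths['xref']}")
print(f"  uasis map {first_rs} --xref {paths['xref']}")
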