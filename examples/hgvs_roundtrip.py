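"""Translate between accession-based (HGVS genomic) and universal names.

One SNP has as many legal accession-based names as there are contigs
covering it; the universal name is unique.  The accession map supplies
each contig's placement on the genome.
"""

from uasis import (
    AccessionEntry,
    AccessionMap,
    hgvs_to_uasis,
    parse_hgvs_g,
    uasis_to_hgvs,
)
from uasis.errors import UnsupportedHgvsError

amap = AccessionMap([
    AccessionEntry("NT_021937", 19, chromosome="1", genome_start=3917856,
                   strand="+", length=10_000_000),
    AccessionEntry("NT_other", 3, chromosome="1", genome_start=11000000,
                   strand="+", length=2_000_000),
])

h = parse_hgvs_g("NT_021937.19:g.7871183G>A")
u = hgvs_to_uasis(h, amap, build=19)
print(f"{h} -> {u}")
# the accession offset places contig position 7871183 at genome locus
# 3917856 + 7871183 - 1 = 11789038 on chromosome 1

names = uasis_to_hgvs(u, amap)
print(f"{u} -> {len(names)} accession-based names:")
for n in names:
    print("  ", n)
# the reverse direction is one-to-many: every covering accession
# yields a legal name, which is exactly why the universal form exists

try:
    parse_hgvs_g("NM_001286.2:c.87+45G>A")
except UnsupportedHgvsError as e:
    print("coding-coordinate names are recognized but not translated:", e)
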