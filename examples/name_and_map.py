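"""Generate a universal SNP name from pivot features and map it back.

Builds a tiny in-memory cross-reference snapshot, names a variant from
its genome coordinates, and resolves existing database names against
the snapshot.
"""

from uasis import (
    VariantDescriptor,
    XrefRecord,
    XrefStore,
    displaced_reference_position,
    format_uasis,
    map_name,
    parse_uasis,
    validate_descriptor,
)

# --- name generation: pivot features -> universal name ---------------
descriptor = VariantDescriptor(
    build=19, chromosome="1", locus=11789038,
    variant_class="substitution", alleles=["G", "A"],
)
name = validate_descriptor(descriptor)
print("universal name:", format_uasis(name))
# the name alone pins the variant: build 19, chr 1, 1-based position
# 11789038, alleles G (reference) and A

# --- indel convention -------------------------------------------------
ins = parse_uasis("HG19.1:1234:insT")
print("insertion at", ins.locus, "displaces the old base to",
      displaced_reference_position(ins))

# --- name mapping: any known identifier -> every namespace -----------
store = XrefStore([
    XrefRecord("1", 11789038, "G/A", rs_id="rs3737965",
               jsnp_id="IMS-JST083663", hapmap_id="rs3737965",
               gwas_id="HGVM2256489"),
])
for query in ["rs3737965", "IMS-JST083663", "Chr1:11,789,038 G/A", "bogus"]:
    report = map_name(store, query)
    if report.status != "OK":
        print(f"{query!r:30} -> None   (unresolvable input name)")
    else:
        print(f"{query!r:30} -> {report.uasis}  rs={report.rs} "
              f"jsnp={report.jsnp} gwas={report.gwas}")
# per-database "none" marks a database with no record; a whole-line
# "None" marks an input name that could not be resolved at all
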