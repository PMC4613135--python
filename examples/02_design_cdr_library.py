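"""Design a full non-combinatorial CDR library.

Estimates profiles for all nine regions from synthetic natural repertoires
at realistic sizes, then simulates PTM-filtered repertoires at the standard
per-region totals (7,836 for CDR-H3, 1,000-1,500 elsewhere) and prints a
Total/Unique design table.
"""

import cdrforge as cf
from cdrforge.regions import CdrRegion

germlines = cf.sanitize_germline(cf.germline_fixture())
scaffolds = cf.scaffold_fixture()

bundle = cf.ProfileBundle()
for region in CdrRegion:
    if region is CdrRegion.H3:
        continue
    rep = cf.generate_natural_repertoire(
        cf.make_repertoire_spec(region, germlines, seed=1), germlines)
    bundle.shm[region] = cf.build_shm_profile(rep, germlines)
    if region.is_light_cdr3:
        bundle.l3_tails[region] = cf.build_l3_tail_profile(rep)
bundle.h3 = cf.build_h3_profile(cf.generate_h3_repertoire(cf.make_h3_truth(seed=1),
                                                          8846, seed=2))

config = cf.DesignConfig(seed=1)  # standard totals, PTM policy, pool capacity
designs = cf.design_library(config, bundle, scaffolds)

print("designed CDR repertoires (Total = drawn, Unique = distinct sequences):")
print("region  total  unique")
for region, rep in designs.items():
    print(f"  {region.label:4s} {rep.total:6d} {rep.unique_count:7d}")

table = cf.ptm_statistics({r: d.sequences for r, d in designs.items()})
print(f"\nmax Total-PTM % across regions after filtering: {table.loc['Total'].max():.2f}")
print("(every designed sequence was rejected-and-redrawn until motif-free,")
print(" so the designed library carries no liability motifs by construction)")
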