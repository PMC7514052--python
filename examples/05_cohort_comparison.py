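"""Healthy vs dystrophic cohort: who loses which foci, and where.

Simulates 4 animals per genotype (4 fields each), runs the full
pipeline, and compares per-animal means with two-tailed Mann-Whitney U
tests — mature (small sarcoplasmic) foci collapse in dystrophic muscle
while nascent (large nuclear) foci persist.
"""

from fociq import (AnimalConfig, CohortConfig, FieldGeometry,
                   compare_cohorts, correlate, example_scene, run_pipeline)

geometry = FieldGeometry(width_px=694, height_px=520)
animals = tuple(
    AnimalConfig(f"{g}{i + 1}", g, example_scene(g, geometry=geometry),
                 n_fields=4)
    for g in ("wt", "mdx") for i in range(4))
result = run_pipeline(CohortConfig(animals, seed=11))
table = result.table
table["small_sarc"] = (table.small_5p_sarcoplasmic
                       + table.small_3p_sarcoplasmic)

for metric in ("small_sarc", "large_5p_total", "small_5p_nuclear", "nuclei"):
    res = compare_cohorts(table, metric)
    flag = "*" if res["significant"] else "n.s."
    print(f"{metric:>18}: wt {res['group_means']['wt']:7.1f}  "
          f"mdx {res['group_means']['mdx']:7.1f}  "
          f"p={res['pvalue']:.3f} {flag}")

r_wt, _ = correlate(table[table.genotype == "wt"],
                    "small_5p_total", "small_3p_total")
r_mdx, _ = correlate(table[table.genotype == "mdx"],
                     "small_5p_total", "small_3p_total")
print(f"per-image 5' vs 3' Pearson r: wt {r_wt:.2f}, mdx {r_mdx:.2f}")
print("Only the mature (sarcoplasmic) transcript pool is lost in "
      "dystrophic muscle; nascent transcription continues, and the tight "
      "5'/3' coupling of healthy fields breaks down.")
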