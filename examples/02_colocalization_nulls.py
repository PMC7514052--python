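"""Measure 5'<->3' pairing against rotation and random null models.

Mature transcripts carry both probe regions, so their 5' and 3' foci sit
within ~1 um of each other in the sarcoplasm. Rotating one channel 90
degrees, or replacing it with uniform random points, destroys this
pairing while preserving density.
"""

import numpy as np

from fociq import (FieldGeometry, compartment_counts, example_scene,
                   generate_field, nearest_neighbor_distances,
                   pairing_summary, random_null, rotation_null,
                   segment_nuclei)

geometry = FieldGeometry(width_px=694, height_px=520)
field = generate_field(example_scene("wt", geometry=geometry, seed=2))
mask = segment_nuclei(field.images["dapi"])
summary = compartment_counts({"5p": field.images["5p"],
                              "3p": field.images["3p"]}, mask, geometry)

src = [f.centroid_um for f in summary.foci[("5p", "sarcoplasmic")]
       if f.size_class == "small"]
tgt = [f.centroid_um for f in summary.foci[("3p", "sarcoplasmic")]
       if f.size_class == "small"]
observed = {
    "5p_to_3p": nearest_neighbor_distances(src, tgt, "5p_to_3p"),
    "3p_to_5p": nearest_neighbor_distances(tgt, src, "3p_to_5p"),
}
nulls = {
    "rotation": nearest_neighbor_distances(src, rotation_null(tgt, geometry)),
    "random": random_null(len(src), len(tgt), geometry, n_fields=1000,
                          seed=7),
}
table = pairing_summary(observed, nulls)
print(table.round(4).to_string(index=False))
obs1 = table.query("model == 'observed' and threshold_um == 1.0")
print(f"\n{100 * float(obs1.fraction_within.iloc[0]):.0f}% of sarcoplasmic "
      "foci pair within 1 um — an order of magnitude above both nulls, the "
      "signature of intact mature transcripts carrying both probe regions.")
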