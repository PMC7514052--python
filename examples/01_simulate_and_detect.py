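"""Simulate a healthy-muscle field and count probe foci by size class.

Generates one synthetic 347x260 um field with ground truth, segments the
nuclear stain, detects 5' and 3' probe foci, and prints counts split
into small (single-transcript, 0.5-10 um^2) and large (nascent-
transcription, 10-100 um^2) classes per compartment.
"""

from fociq import (FieldGeometry, compartment_counts, example_scene,
                   generate_field, segment_nuclei)

geometry = FieldGeometry(width_px=694, height_px=520)
scene = example_scene("wt", geometry=geometry, seed=1)
field = generate_field(scene)

mask = segment_nuclei(field.images["dapi"], algorithm="huang")
summary = compartment_counts({"5p": field.images["5p"],
                              "3p": field.images["3p"]},
                             mask, geometry)

planted = field.truth.kind.value_counts()
print(f"planted: {planted.get('nucleus', 0)} nuclei, "
      f"{planted.get('small_focus', 0)} small foci, "
      f"{planted.get('large_focus', 0)} large foci")
print(f"segmented nuclei: {summary.nuclei_count}")
print(summary.counts.drop(index="rejected", level="size_class"))
print(f"fraction of nuclei with a large 5' focus: "
      f"{summary.fraction_expressing_nuclei:.2f}")
print("Large 5' foci mark nuclei engaged in concerted nascent "
      "transcription; in healthy muscle they are exclusively nuclear and "
      "mark ~20-30% of nuclei.")
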