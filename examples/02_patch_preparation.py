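"""Two-step cropping-selection of a slide into an ordered patch sequence.

Tiles the slide on a non-overlapping grid, filters patches below 20%
tissue, and orders the survivors top-right to bottom-left — the sequence
the LSTM consumes.
"""

from histofusion.patch_prep import (compute_tissue_fractions, crop_patches,
                                    order_patches, select_patches)
from histofusion.synthetic import SyntheticCohortConfig, generate_cohort

cohort = generate_cohort(SyntheticCohortConfig(n_patients=3, seed=2))
slide = cohort.slides[0]

patches = crop_patches(slide.image, patch_size=64, stride=64)
patches = compute_tissue_fractions(patches)
kept = select_patches(patches, min_fraction=0.2)
seq = order_patches(kept, patient_id=slide.patient_id)

print(f"slide {slide.patient_id}: {len(patches)} grid cells, "
      f"{len(kept)} kept by the 20% tissue rule")
print("sequence order (row, col, tissue fraction):")
for p in seq.patches:
    print(f"  ({p.grid_row}, {p.grid_col})  tissue={p.tissue_fraction:.2f}")
print("the blank background row is rejected; within a row the order runs "
      "right to left")
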