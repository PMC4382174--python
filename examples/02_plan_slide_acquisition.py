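"""Plan microscope acquisition positions from a low-resolution slide scan.

Builds a synthetic 300 dpi slide scan with 8 mounted wings, segments the
wing regions, locates each wing's origin (hinge) and axis, trims the hinge
neighbourhood, partitions the blade with k-means, and maps the resulting
positions into microscope stage coordinates.
"""

import numpy as np

from wingspot import (
    RegionFilterRanges, SlideImage, StageTransform, filter_regions,
    generate_slide_image, locate_origin_and_axis, partition_acquisitions,
    segment_wings, to_stage_coords, trim_region,
)

img, outlines = generate_slide_image(8, seed=11)
slide = SlideImage(img)  # 300 dpi -> 84.7 um/px

regions = segment_wings(slide, threshold_fraction=0.15)
kept, discarded = filter_regions(regions, RegionFilterRanges())
print(f"{len(regions)} candidate regions, {len(kept)} kept "
      f"({len(discarded)} discarded by aspect/area/position limits)")

ref_area = float(np.median([r.area_px for r in kept]))
transform = StageTransform(center_xy=(img.shape[1] / 2, img.shape[0] / 2),
                           theta_rad=0.0, ratio=0.32 / slide.pixel_pitch_um)

total = 0
for w, region in enumerate(kept):
    region = locate_origin_and_axis(region, slide)
    trimmed = trim_region(region, min_distance_um=400.0,
                          pixel_pitch_um=slide.pixel_pitch_um)
    positions = partition_acquisitions(trimmed, max_fields=6,
                                       reference_area_px=ref_area, seed=0)
    total += len(positions)
    stage = to_stage_coords(positions[0], transform)
    print(f"wing {w}: origin {region.origin_xy}, {len(positions)} fields, "
          f"first field at stage ({stage[0]:.1f}, {stage[1]:.1f})")
print(f"{total} acquisition positions planned "
      f"(number of fields scales with wing area, at most 6 per wing)")
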