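#!/usr/bin/env python
"""Render one example of every scene geometry and export raster + truth.

Writes a small gallery under scratch/scenes/ — a patterned colony, a
multi-colony field with a merged pair, a transwell sheet, a secretor
colony, a ZO-1 z-stack and a shrinking-reporter time-lapse — each as
TIFF with its ground-truth CSV/JSON, so the synthetic inputs the later
analyses consume can be inspected directly.
"""

from pathlib import Path

import numpy as np
import tifffile

from gastruloid_quant import scenarios as sc
from gastruloid_quant.scenes import (SceneSpec, SecretorSpec, TimeSceneSpec,
                                     ZSceneSpec, generate_colony_image,
                                     generate_multicolony_field,
                                     generate_timelapse,
                                     generate_transwell_field,
                                     generate_zstack, save_scene)

OUT = Path(__file__).resolve().parents[1] / "scratch" / "scenes"
SEED = 0


def main() -> None:
    colony, truth = generate_colony_image(sc.three_ring_spec(SEED, 167.0))
    save_scene(OUT / "three_ring_colony", colony.raster, truth,
               colony.channel_names)
    print(f"three-ring colony: {len(truth.nuclei)} nuclei, "
          f"channels {colony.channel_names}")

    spec = SceneSpec(colony_radius=100.0, density=3700.0, seed=SEED)
    field, ftruth = generate_multicolony_field(
        spec, [(400.0, 400.0), (900.0, 400.0)], include_merged=True)
    save_scene(OUT / "field_with_merged_pair", field.raster, ftruth,
               field.channel_names)
    print(f"field: {len(ftruth.colony_centers)} colonies, "
          f"merged pair {ftruth.merged_pair}")

    img, ttruth = generate_transwell_field(
        sc.transwell_spec(SEED), n_positive=140, response_channel="SMAD23")
    save_scene(OUT / "transwell_sheet", img.raster, ttruth,
               img.channel_names)
    print(f"transwell sheet: {len(ttruth.nuclei)} nuclei, 140 positive")

    secretors = SecretorSpec(n_secretors=3, cluster_radius=10.0,
                             suppression_radius=200.0, channel="NOG")
    simg, struth = generate_transwell_field(
        SceneSpec(colony_radius=250.0, n_nuclei=700, seed=SEED),
        response_channel="pSMAD1", secretors=secretors, layout="disc")
    save_scene(OUT / "secretor_colony", simg.raster, struth,
               simg.channel_names)
    print(f"secretor colony: {len(struth.secretor_ids)} secretors")

    zspec = ZSceneSpec(z_planes=25, z_step=1.0, lateral_size=100.0,
                       base_height=10.0, undulation_amplitude=2.0,
                       channel_offsets={"ACVR2B": (5.0, 1.0),
                                        "DAPI": (6.0, 1.0)},
                       gap_patches=((20.0, 20.0, 40.0, 40.0),))
    stack, names, ztruth = generate_zstack(zspec, SceneSpec(n_nuclei=1,
                                                            seed=SEED))
    (OUT / "zstack").mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(OUT / "zstack" / "stack.ome.tif", stack,
                     metadata={"axes": "CZYX", "channels": names})
    np.save(OUT / "zstack" / "apical_surface_truth.npy",
            ztruth.apical_surface)
    print(f"z-stack: {stack.shape} ({names})")

    ts = TimeSceneSpec(n_frames=12, frame_interval=30.0,
                       radius_schedule=tuple(np.linspace(250.0, 100.0, 12)))
    frames, fnames, ttr = generate_timelapse(
        ts, SceneSpec(colony_radius=250.0, density=3700.0, seed=SEED))
    (OUT / "timelapse").mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(OUT / "timelapse" / "series.ome.tif", frames,
                     metadata={"axes": "TCYX", "channels": fnames})
    print(f"time-lapse: {frames.shape}, radius "
          f"{ttr.radius_schedule[0]:.0f}->{ttr.radius_schedule[-1]:.0f} um")


if __name__ == "__main__":
    main()
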