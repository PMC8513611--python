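#!/usr/bin/env python
"""Receptor localization relative to the ZO-1 apical surface.

Builds z-stacks emulating polarized versus mispolarized receptor
placement — a basolateral receptor (+5 µm), an apically shifted one
(−2 µm), and DNA (+6 µm) — interpolates the apical surface from the ZO-1
channel (including across a junction gap patch), and tabulates the signed
distance-to-apical distributions per condition under results/polarity/.
"""

from pathlib import Path

from gastruloid_quant.polarity import (compare_polarity, distance_to_apical,
                                       interpolate_apical_surface)
from gastruloid_quant.scenes import SceneSpec, ZSceneSpec, generate_zstack

OUT = Path(__file__).resolve().parents[1] / "results" / "polarity"
SEED = 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    zspec = ZSceneSpec(
        z_planes=25, z_step=1.0, lateral_size=100.0, base_height=10.0,
        undulation_amplitude=2.0, undulation_wavelength=50.0,
        channel_offsets={"ACVR2B_polarized": (5.0, 1.0),
                         "ACVR2B_mispolarized": (1.0, 2.5),
                         "DAPI": (6.0, 1.0)},
        gap_patches=((20.0, 20.0, 40.0, 40.0),))
    stack, names, truth = generate_zstack(zspec, SceneSpec(n_nuclei=1,
                                                           seed=SEED))
    surf = interpolate_apical_surface(stack[names.index("ZO1")],
                                      zspec.z_step)
    print(f"apical surface: {surf.valid.mean():.1%} of positions valid "
          "(gap patch interpolated)")

    dists = {ch: distance_to_apical(stack[names.index(ch)], surf)
             for ch in names if ch != "ZO1"}
    table = compare_polarity(dists)
    table.to_csv(OUT / "distance_to_apical.csv", index=False)
    print(table.to_string(index=False))
    print("positive medians = basal placement; the mispolarized receptor's "
          "median sits closer to the apical plane")


if __name__ == "__main__":
    main()
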