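#!/usr/bin/env python
"""VCD under three model assumptions at several incidence angles.

Grid of panels (angle x thickness) comparing the Beer-Lambert baseline, the
copolarized-only transfer-matrix solution (interference without helicity
coupling) and the full 4x4 solution.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from vcdtmm import (
    beer_lambert_vcd,
    copolarized_vcd,
    helicity_transmittances,
    ideal_absorber,
    single_layer_stack,
    stack_jones,
    vcd_from_transmittances,
)

THICKNESSES_UM = (1.0, 10.0, 25.0)
ANGLES_DEG = (0.0, 50.0, 80.0)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("scratch/vcd_model_comparison.png"))
    parser.add_argument("--step", type=float, default=1.0, help="grid step, cm^-1")
    args = parser.parse_args()

    nu = np.arange(200.0, 4500.0 + 0.5 * args.step, args.step)
    mat = ideal_absorber()

    fig, axes = plt.subplots(
        len(ANGLES_DEG), len(THICKNESSES_UM), figsize=(12, 8), sharex=True
    )
    for i, theta in enumerate(ANGLES_DEG):
        for j, d_um in enumerate(THICKNESSES_UM):
            stack = single_layer_stack(mat, d_um)
            t = stack_jones(stack, nu, theta)
            full = vcd_from_transmittances(*helicity_transmittances(t))
            ax = axes[i, j]
            ax.plot(nu, beer_lambert_vcd(mat, d_um, nu, theta), color="tab:orange",
                    lw=0.8, label="Beer-Lambert")
            ax.plot(nu, copolarized_vcd(t), color="gold", lw=0.8, label="copolarized")
            ax.plot(nu, full, "b--", lw=0.8, label="full 4x4")
            ax.set_title(f"d = {d_um:g} um, theta = {theta:g} deg", fontsize=9)
    axes[0, 0].legend(frameon=False, fontsize=8)
    for ax in axes[-1]:
        ax.set_xlabel("wavenumber (cm$^{-1}$)")
    for row in axes:
        row[0].set_ylabel("VCD")
    fig.tight_layout()
    args.out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(args.out, dpi=150)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
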