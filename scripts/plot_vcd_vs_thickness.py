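#!/usr/bin/env python
"""Helicity-resolved absorbances and VCD of the chiral ideal absorber.

Three thicknesses at normal incidence; VCD amplitude scales linearly with
optical path, with negative lobes at the absorption bands.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from vcdtmm import compute_spectrum, ideal_absorber, single_layer_stack

THICKNESSES_UM = (1.0, 25.0, 50.0)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("scratch/vcd_vs_thickness.png"))
    parser.add_argument("--step", type=float, default=1.0, help="grid step, cm^-1")
    args = parser.parse_args()

    nu = np.arange(200.0, 4500.0 + 0.5 * args.step, args.step)
    mat = ideal_absorber()

    fig, axes = plt.subplots(len(THICKNESSES_UM), 2, figsize=(10, 8), sharex=True)
    for row, d_um in zip(axes, THICKNESSES_UM):
        spec = compute_spectrum(single_layer_stack(mat, d_um), nu, 0.0)
        row[0].plot(nu, spec.A_plus, lw=0.7, label="$A_+$")
        row[0].plot(nu, spec.A_minus, lw=0.7, ls="--", label="$A_-$")
        row[0].set_ylabel(f"A (d = {d_um:g} um)")
        row[1].plot(nu, spec.vcd, lw=0.7, color="tab:purple")
        row[1].set_ylabel("VCD")
        row[1].axhline(0.0, color="0.8", lw=0.5)
    axes[0, 0].legend(frameon=False)
    for ax in axes[-1]:
        ax.set_xlabel("wavenumber (cm$^{-1}$)")
    fig.tight_layout()
    args.out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(args.out, dpi=150)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
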