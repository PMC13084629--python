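#!/usr/bin/env python
"""Absorbance of the achiral ideal absorber: full TMM vs Beer-Lambert.

Six panels for film thicknesses 1-50 um at normal incidence; thin films show
interference fringes, thick films converge to the Beer-Lambert baseline.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from vcdtmm import (
    beer_lambert_absorbance,
    compute_spectrum,
    ideal_absorber,
    single_layer_stack,
)
from vcdtmm.materials import sqrt_im_nonneg

THICKNESSES_UM = (1.0, 5.0, 10.0, 20.0, 30.0, 50.0)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("scratch/absorbance_vs_thickness.png"))
    parser.add_argument("--step", type=float, default=1.0, help="grid step, cm^-1")
    args = parser.parse_args()

    nu = np.arange(200.0, 4500.0 + 0.5 * args.step, args.step)
    mat = ideal_absorber(kappa_0=0.0)
    eps, mu, _ = mat.evaluate(nu)
    n_imag = sqrt_im_nonneg(eps * mu).imag

    fig, axes = plt.subplots(3, 2, figsize=(9, 9), sharex=True)
    for ax, d_um in zip(axes.ravel(), THICKNESSES_UM):
        spec = compute_spectrum(single_layer_stack(mat, d_um), nu, 0.0)
        ax.plot(nu, spec.A_plus, lw=0.8, label="TMM")
        ax.plot(nu, beer_lambert_absorbance(n_imag, d_um, nu), "r--", lw=0.8, label="Beer-Lambert")
        ax.set_title(f"d = {d_um:g} um")
        ax.set_ylabel("A")
    for ax in axes[-1]:
        ax.set_xlabel("wavenumber (cm$^{-1}$)")
    axes[0, 0].legend(frameon=False)
    fig.tight_layout()
    args.out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(args.out, dpi=150)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
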