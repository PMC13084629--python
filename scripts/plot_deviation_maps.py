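#!/usr/bin/env python
"""Angular-spectral maps of the Beer-Lambert baseline and artifact deviations.

For each thickness: log10|VCD_BL|, the interference deviation and the
coupling deviation over (theta, wavenumber).
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from vcdtmm import deviation_maps, ideal_absorber, single_layer_stack

THICKNESSES_UM = (1.0, 10.0, 25.0)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("scratch/deviation_maps.png"))
    parser.add_argument("--step", type=float, default=5.0, help="grid step, cm^-1")
    parser.add_argument("--n-theta", type=int, default=17)
    args = parser.parse_args()

    nu = np.arange(200.0, 4500.0 + 0.5 * args.step, args.step)
    thetas = np.linspace(0.0, 80.0, args.n_theta)
    mat = ideal_absorber()

    fig, axes = plt.subplots(3, len(THICKNESSES_UM), figsize=(12, 9), sharex=True, sharey=True)
    extent = [nu[0], nu[-1], thetas[0], thetas[-1]]
    for j, d_um in enumerate(THICKNESSES_UM):
        amap = deviation_maps(single_layer_stack(mat, d_um), thetas, nu)
        rows = (
            (np.log10(np.abs(amap.vcd_bl)), "log10 |VCD$_{BL}$|"),
            (amap.dev_itf, "interference deviation"),
            (amap.dev_cpl, "coupling deviation"),
        )
        for i, (data, label) in enumerate(rows):
            ax = axes[i, j]
            im = ax.imshow(data, origin="lower", aspect="auto", extent=extent)
            fig.colorbar(im, ax=ax, shrink=0.8)
            if i == 0:
                ax.set_title(f"d = {d_um:g} um")
            if j == 0:
                ax.set_ylabel(f"{label}\ntheta (deg)")
    for ax in axes[-1]:
        ax.set_xlabel("wavenumber (cm$^{-1}$)")
    fig.tight_layout()
    args.out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(args.out, dpi=150)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
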