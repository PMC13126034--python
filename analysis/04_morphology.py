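#!/usr/bin/env python
"""Morphology vs input strength: cable length regressions and density map.

Writes synthetic SWC skeletons for every DN, re-reads them, joins cable length
with total axo-axonic input strength, and fits the linear and quadratic
regressions plus a 2-D kernel density estimate of the scatter.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from axoaxonic.connectome import load_table, scrub
from axoaxonic.morphology import cable_length, fit_strength_vs_length, kde2d, read_swc
from axoaxonic.netstats import input_summary
from axoaxonic.synth import generate_skeletons


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--data", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--out", type=Path, default=Path("results/morphology"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    table, _ = scrub(load_table(args.data / "neurons.csv", args.data / "connections.csv"))
    swc_dir = args.out / "skeletons"
    truth = generate_skeletons(table, swc_dir, seed=args.seed)
    print(f"wrote {len(truth)} SWC skeletons")

    strengths = dict(
        zip(*(input_summary(table).per_dn[c] for c in ("neuron_id", "total_strength")))
    )
    points = []
    for nid in truth:
        if nid in strengths:
            points.append((cable_length(read_swc(swc_dir / f"{nid}.swc")), strengths[nid]))

    lin = fit_strength_vs_length(points, "linear")
    quad = fit_strength_vs_length(points, "quadratic")
    print(f"linear fit:    R² = {lin.r_squared:.3f} (Pearson r = {lin.pearson_r:.3f}, "
          f"p = {lin.pearson_p:.2e}, n = {lin.n_points})")
    print(f"quadratic fit: R² = {quad.r_squared:.3f}")

    xx, yy, dens = kde2d(points, grid_size=80)
    cell = (xx[0, 1] - xx[0, 0]) * (yy[1, 0] - yy[0, 0])
    print(f"KDE grid integral: {dens.sum() * cell:.3f}")

    payload = {
        "n_points": len(points),
        "linear": {"coefficients": lin.coefficients, "r_squared": lin.r_squared,
                   "pearson_r": lin.pearson_r, "pearson_p": lin.pearson_p},
        "quadratic": {"coefficients": quad.coefficients, "r_squared": quad.r_squared},
        "kde_integral": float(dens.sum() * cell),
    }
    (args.out / "morphology.json").write_text(json.dumps(payload, indent=2))
    np.savetxt(args.out / "length_vs_strength.csv",
               np.array(points), delimiter=",", header="cable_length_um,total_strength",
               comments="")


if __name__ == "__main__":
    main()
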