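"""SWC skeletons, cable length, and strength-vs-morphology regressions.

Cable length is the sum over non-root nodes of the Euclidean distance to the
parent node — the standard skeleton convention, ignoring radii.  Regressions of
total input strength against cable length use ordinary least squares with an
intercept (linear or quadratic), and the scatter can be summarised with a 2-D
Gaussian kernel density estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = [
    "Skeleton",
    "RegressionResult",
    "SWCFormatError",
    "read_swc",
    "write_swc",
    "cable_length",
    "fit_strength_vs_length",
    "kde2d",
]


class SWCFormatError(ValueError):
    """File is not a valid single-rooted SWC tree."""


@dataclass
class Skeleton:
    """An SWC tree: node ids, coordinates (µm), radii, and parent links."""

    node_ids: np.ndarray     # (n,) int
    xyz: np.ndarray          # (n, 3) float
    radius: np.ndarray       # (n,) float
    parent: np.ndarray       # (n,) int; -1 for the root, else a node id
    neuron_id: int | None = None

    def __post_init__(self) -> None:
        roots = np.flatnonzero(self.parent == -1)
        if len(roots) != 1:
            raise SWCFormatError(f"expected exactly one root, found {len(roots)}")
        if not np.all(np.isfinite(self.xyz)):
            raise SWCFormatError("non-finite coordinates")
        index = {int(i): k for k, i in enumerate(self.node_ids)}
        if len(index) != len(self.node_ids):
            raise SWCFormatError("duplicate node ids")
        # parents must resolve, and following them must terminate at the root
        for k, p in enumerate(self.parent):
            if p == -1:
                continue
            if int(p) not in index:
                raise SWCFormatError(f"node {self.node_ids[k]} has dangling parent {p}")
        # cycle check by chasing parents with a step budget
        n = len(self.node_ids)
        for k in range(n):
            steps, cur = 0, k
            while self.parent[cur] != -1:
                cur = index[int(self.parent[cur])]
                steps += 1
                if steps > n:
                    raise SWCFormatError("cycle in parent links")


def read_swc(path: str | Path, neuron_id: int | None = None) -> Skeleton:
    """Parse a 7-column SWC file ('#' comments allowed) into a validated tree."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise SWCFormatError(f"{path}: expected 7 columns, got {len(parts)}: {line!r}")
        rows.append(parts)
    if not rows:
        raise SWCFormatError(f"{path}: no data rows")
    arr = np.array(rows)
    try:
        node_ids = arr[:, 0].astype(int)
        xyz = arr[:, 2:5].astype(float)
        radius = arr[:, 5].astype(float)
        parent = arr[:, 6].astype(int)
    except ValueError as exc:
        raise SWCFormatError(f"{path}: non-numeric field") from exc
    if neuron_id is None:
        stem = Path(path).stem
        neuron_id = int(stem) if stem.isdigit() else None
    return Skeleton(node_ids, xyz, radius, parent, neuron_id)


def write_swc(skeleton: Skeleton, path: str | Path) -> None:
    lines = []
    for i, nid in enumerate(skeleton.node_ids):
        x, y, z = skeleton.xyz[i]
        lines.append(
            f"{nid} 0 {x:.6f} {y:.6f} {z:.6f} {skeleton.radius[i]:.4f} {skeleton.parent[i]}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def cable_length(skeleton: Skeleton) -> float:
    """Total cable length: Σ over non-root nodes of distance to parent (µm)."""
    index = {int(i): k for k, i in enumerate(skeleton.node_ids)}
    total = 0.0
    for k, p in enumerate(skeleton.parent):
        if p == -1:
            continue
        total += float(np.linalg.norm(skeleton.xyz[k] - skeleton.xyz[index[int(p)]]))
    return total


@dataclass
class RegressionResult:
    model: str  # "linear" | "quadratic"
    coefficients: list[float]  # highest degree first (numpy.polyfit order)
    r_squared: float
    n_points: int
    pearson_r: float | None = None
    pearson_p: float | None = None


def fit_strength_vs_length(points, model: str = "linear") -> RegressionResult:
    """Least-squares fit (with intercept) of strength against cable length.

    ``points`` is a sequence of (length, strength) pairs.  The linear model also
    reports Pearson r with a two-sided p-value.
    """
    pts = np.asarray(list(points), dtype=float)
    degree = {"linear": 1, "quadratic": 2}.get(model)
    if degree is None:
        raise ValueError(f"unknown model {model!r}")
    if len(pts) < degree + 2:
        raise ValueError(f"need at least {degree + 2} points for a {model} fit")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: fit undefined")
    coeff = np.polyfit(x, y, degree)
    yhat = np.polyval(coeff, x)
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    pr = pp = None
    if model == "linear":
        r, p = stats.pearsonr(x, y)
        pr, pp = float(r), float(p)
    return RegressionResult(model, [float(c) for c in coeff], r2, len(pts), pr, pp)


def kde2d(points, bandwidth: float | str = "scott", grid_size: int = 100, pad: float = 0.25):
    """Gaussian KDE of 2-D scatter on a regular grid.

    Returns ``(xx, yy, density)``; the density numerically integrates to ≈ 1
    over the (padded) grid.  ``bandwidth`` follows scipy's ``gaussian_kde``
    (Scott's rule by default); zero or negative bandwidths are rejected.
    """
    pts = np.asarray(list(points), dtype=float)
    if len(pts) < 2:
        raise ValueError("need at least 2 points")
    if isinstance(bandwidth, (int, float)) and bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    kde = stats.gaussian_kde(pts.T, bw_method=bandwidth)
    x, y = pts[:, 0], pts[:, 1]
    dx = np.ptp(x) or 1.0
    dy = np.ptp(y) or 1.0
    xs = np.linspace(x.min() - pad * dx, x.max() + pad * dx, grid_size)
    ys = np.linspace(y.min() - pad * dy, y.max() + pad * dy, grid_size)
    xx, yy = np.meshgrid(xs, ys)
    density = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(xx.shape)
    return xx, yy, density
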