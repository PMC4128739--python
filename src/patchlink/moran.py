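"""Global Moran's I on block-aggregated rasters.

The landscape is aggregated to square blocks (default 100 m) holding the
fraction of usable habitat; clumping is then scored with global Moran's I
under binary rook (or queen) contiguity weights, not row-standardized.
Expectation under no autocorrelation is -1/(n-1); the variance comes from the
standard closed forms for either the normality or the randomization
(permutation-moment) null, with a two-sided normal p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grids import GridLandscape, LandscapeError

__all__ = [
    "MoranResult",
    "ConstantFieldError",
    "aggregate_to_blocks",
    "global_morans_i",
    "moran_permutation_p",
]


class ConstantFieldError(ValueError):
    """Moran's I is undefined for a constant field."""


@dataclass
class MoranResult:
    I: float
    expected_I: float
    variance_I: float
    z_score: float
    p_value: float
    n_units: int
    weights_spec: str

    def to_dict(self) -> dict:
        return {
            "I": self.I,
            "expected_I": self.expected_I,
            "variance_I": self.variance_I,
            "z_score": self.z_score,
            "p_value": self.p_value,
            "n_units": self.n_units,
            "weights_spec": self.weights_spec,
        }


def aggregate_to_blocks(
    landscape: GridLandscape,
    block_size_m: float = 100.0,
    usable_codes: tuple[int, ...] | None = None,
) -> np.ndarray:
    """Fraction of usable cells per square block; partial edge blocks dropped.

    ``usable_codes`` defaults to every non-zero functional class.
    """
    if block_size_m < landscape.cell_size_m:
        raise LandscapeError("block_size_m must be >= cell_size_m")
    b = int(round(block_size_m / landscape.cell_size_m))
    if usable_codes is None:
        if landscape.level != "functional":
            raise LandscapeError("usable_codes required for structural landscapes")
        usable = landscape.class_grid != 0
    else:
        usable = np.isin(landscape.class_grid, usable_codes)
    rows = (landscape.n_rows // b) * b
    cols = (landscape.n_cols // b) * b
    if rows == 0 or cols == 0:
        raise LandscapeError("landscape smaller than one block")
    trimmed = usable[:rows, :cols].astype(float)
    return trimmed.reshape(rows // b, b, cols // b, b).mean(axis=(1, 3))


def _pair_sum(z: np.ndarray, weights: str) -> float:
    """sum_{i<j} w_ij z_i z_j for binary contiguity on a grid (unordered)."""
    s = float((z[:, 1:] * z[:, :-1]).sum() + (z[1:, :] * z[:-1, :]).sum())
    if weights == "queen":
        s += float((z[1:, 1:] * z[:-1, :-1]).sum() + (z[1:, :-1] * z[:-1, 1:]).sum())
    return s


def _degree_grid(shape: tuple[int, int], weights: str) -> np.ndarray:
    deg = np.zeros(shape)
    deg[:, 1:] += 1
    deg[:, :-1] += 1
    deg[1:, :] += 1
    deg[:-1, :] += 1
    if weights == "queen":
        deg[1:, 1:] += 1
        deg[:-1, :-1] += 1
        deg[1:, :-1] += 1
        deg[:-1, 1:] += 1
    return deg


def global_morans_i(
    values: np.ndarray,
    weights: str = "rook",
    null: str = "randomization",
) -> MoranResult:
    """Global Moran's I of a 2-D field under binary contiguity weights.

    ``null`` selects the variance: ``"randomization"`` (permutation moments,
    default) or ``"normality"``.
    """
    if weights not in ("rook", "queen"):
        raise ValueError(f"unknown weights {weights!r}")
    if null not in ("randomization", "normality"):
        raise ValueError(f"unknown null {null!r}")
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValueError("values must be a 2-D block grid")
    n = x.size
    if n < 9:
        raise ValueError("need at least 9 blocks")
    z = x - x.mean()
    m2 = float((z**2).sum())
    if m2 == 0.0:
        raise ConstantFieldError("constant field: Moran's I undefined")

    deg = _degree_grid(x.shape, weights)
    W = float(deg.sum())  # sum of all (ordered) weights
    S1 = 2.0 * W
    S2 = float(4.0 * (deg**2).sum())
    num = 2.0 * _pair_sum(z, weights)  # ordered-pair sum

    I = (n / W) * num / m2
    E = -1.0 / (n - 1)
    if null == "normality":
        V = (n**2 * S1 - n * S2 + 3 * W**2) / (W**2 * (n**2 - 1)) - E**2
    else:
        b2 = n * float((z**4).sum()) / m2**2
        V = (
            n * ((n**2 - 3 * n + 3) * S1 - n * S2 + 3 * W**2)
            - b2 * ((n**2 - n) * S1 - 2 * n * S2 + 6 * W**2)
        ) / ((n - 1) * (n - 2) * (n - 3) * W**2) - E**2
    zscore = (I - E) / np.sqrt(V)
    p = float(2.0 * stats.norm.sf(abs(zscore)))
    return MoranResult(
        I=float(I),
        expected_I=float(E),
        variance_I=float(V),
        z_score=float(zscore),
        p_value=min(1.0, max(p, np.finfo(float).tiny)),
        n_units=int(n),
        weights_spec=f"binary {weights} contiguity, not row-standardized",
    )


def moran_permutation_p(
    values: np.ndarray,
    weights: str = "rook",
    n_perm: int = 999,
    seed: int | None = None,
) -> float:
    """Two-sided Monte-Carlo permutation p for Moran's I (value shuffling)."""
    x = np.asarray(values, dtype=float)
    obs = global_morans_i(x, weights=weights).I
    E = -1.0 / (x.size - 1)
    rng = np.random.default_rng(seed)
    flat = x.ravel().copy()
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(flat)
        I = global_morans_i(flat.reshape(x.shape), weights=weights).I
        if abs(I - E) >= abs(obs - E) - 1e-15:
            hits += 1
    return (1 + hits) / (n_perm + 1)
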