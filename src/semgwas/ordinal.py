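"""Threshold models for ordinal variables and polychoric/polyserial correlation.

Ordinal observations are viewed as a hidden standard-normal variable cut at
thresholds: category k is observed iff the hidden value lies in
(t_{k-1}, t_k]. Thresholds are estimated from marginal category proportions
(t_k is the standard-normal quantile of the cumulative proportion), and the
latent correlation is then maximized with the thresholds held fixed
(two-step estimation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

_CLIP = 8.5       # beyond this |z| the normal CDF is 1 within double precision
_RHO_MAX = 0.999

CONTINUOUS = "continuous"
ORDINAL = "ordinal"


class DegenerateTableError(ValueError):
    """Contingency table concentrates in a single row/column; correlation undefined."""


@dataclass
class ThresholdSet:
    """Finite interior cutpoints and category proportions of one ordinal variable."""

    cutpoints: np.ndarray        # n-1 strictly increasing finite values
    proportions: np.ndarray      # n positive values summing to 1

    def __post_init__(self):
        self.cutpoints = np.asarray(self.cutpoints, dtype=float)
        self.proportions = np.asarray(self.proportions, dtype=float)

    @property
    def n_categories(self) -> int:
        return self.proportions.size

    def bounds(self, k: int) -> tuple[float, float]:
        """Open/closed interval (t_{k-1}, t_k] of category k (0-based)."""
        lo = -np.inf if k == 0 else self.cutpoints[k - 1]
        hi = np.inf if k == self.n_categories - 1 else self.cutpoints[k]
        return lo, hi

    def padded(self) -> np.ndarray:
        return np.concatenate([[-np.inf], self.cutpoints, [np.inf]])


def estimate_thresholds(category_counts) -> ThresholdSet:
    counts = np.asarray(list(category_counts), dtype=float)
    if counts.size < 2:
        raise ValueError("need at least 2 categories")
    if (counts < 1).any():
        raise ValueError(
            "empty ordinal category; merge categories before threshold estimation")
    f = counts / counts.sum()
    cut = stats.norm.ppf(np.cumsum(f)[:-1])
    return ThresholdSet(cutpoints=cut, proportions=f)


@dataclass
class CorrEstimate:
    rho: float
    converged: bool
    boundary: bool = False

    def __float__(self) -> float:
        return float(self.rho)


_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(64)


def _bvn_cdf(h: np.ndarray, k: np.ndarray, rho: float) -> np.ndarray:
    """P(X <= h, Y <= k) for a standard bivariate normal with correlation rho.

    Uses the tetrachoric integral Phi(h)Phi(k) +
    (2*pi)^-1 * int_0^{asin rho} exp(-(h^2 + k^2 - 2 h k sin t) / (2 cos^2 t)) dt
    on fixed Gauss-Legendre nodes; vectorized over (h, k), much faster than the
    generic multivariate normal CDF and accurate to ~1e-10 for |rho| <= 0.999.
    """
    from scipy.special import ndtr

    h = np.clip(np.asarray(h, float), -_CLIP, _CLIP)
    k = np.clip(np.asarray(k, float), -_CLIP, _CLIP)
    h, k = np.broadcast_arrays(h, k)
    base = ndtr(h) * ndtr(k)
    if abs(rho) < 1e-14:
        return base
    asr = np.arcsin(float(np.clip(rho, -1.0, 1.0)))
    theta = asr * (_GL_NODES + 1.0) / 2.0
    sn = np.sin(theta)
    cos2 = np.cos(theta) ** 2
    hh = h[..., None]
    kk = k[..., None]
    expo = -(hh * hh + kk * kk - 2.0 * hh * kk * sn) / (2.0 * cos2)
    integral = np.exp(expo) @ _GL_WEIGHTS * asr / (4.0 * np.pi)
    return np.clip(base + integral, 0.0, 1.0)


def _cell_probs(rho: float, row_cut: np.ndarray, col_cut: np.ndarray) -> np.ndarray:
    """Rectangle probabilities of the bivariate normal over the threshold grid."""
    a = np.concatenate([[-_CLIP], row_cut, [_CLIP]])
    b = np.concatenate([[-_CLIP], col_cut, [_CLIP]])
    aa, bb = np.meshgrid(a, b, indexing="ij")
    F = _bvn_cdf(aa.ravel(), bb.ravel(), rho).reshape(aa.shape)
    p = F[1:, 1:] - F[:-1, 1:] - F[1:, :-1] + F[:-1, :-1]
    return np.clip(p, 1e-300, None)


def polychoric(contingency_table) -> CorrEstimate:
    """Two-step polychoric correlation from a category x category count table."""
    table = np.asarray(contingency_table, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise DegenerateTableError("need a table with >= 2 categories on each margin")
    row_tot, col_tot = table.sum(axis=1), table.sum(axis=0)
    if (row_tot == 0).any() or (col_tot == 0).any() or (table.sum() == table.max()):
        raise DegenerateTableError("contingency table is degenerate")
    if (table == 0).any():
        table = table + 0.5      # continuity correction keeps the boundary finite
        row_tot, col_tot = table.sum(axis=1), table.sum(axis=0)
    row_cut = estimate_thresholds(row_tot).cutpoints
    col_cut = estimate_thresholds(col_tot).cutpoints

    def nll(rho: float) -> float:
        return -float((table * np.log(_cell_probs(rho, row_cut, col_cut))).sum())

    res = optimize.minimize_scalar(nll, bounds=(-_RHO_MAX, _RHO_MAX),
                                   method="bounded", options={"xatol": 1e-6})
    rho = float(res.x)
    boundary = abs(rho) >= _RHO_MAX - 1e-4
    return CorrEstimate(rho=np.clip(rho, -_RHO_MAX, _RHO_MAX),
                        converged=bool(res.success), boundary=boundary)


def polyserial(continuous_values, ordinal_values) -> CorrEstimate:
    """Two-step polyserial correlation between a continuous and an ordinal variable."""
    x = np.asarray(continuous_values, dtype=float)
    codes = np.asarray(ordinal_values)
    ok = np.isfinite(x) & (~pd.isna(codes))
    x, codes = x[ok], codes[ok]
    if x.std() == 0:
        raise ValueError("continuous variable has zero variance")
    z = (x - x.mean()) / x.std()
    cats, idx = np.unique(codes, return_inverse=True)
    if cats.size < 2:
        raise DegenerateTableError("ordinal variable has a single category")
    thr = estimate_thresholds(np.bincount(idx))
    pad = thr.padded()
    lo, hi = pad[idx], pad[idx + 1]

    from scipy.special import ndtr

    def nll(rho: float) -> float:
        s = np.sqrt(1.0 - rho * rho)
        p = ndtr((np.clip(hi, -_CLIP, _CLIP) - rho * z) / s) \
            - ndtr((np.clip(lo, -_CLIP, _CLIP) - rho * z) / s)
        return -float(np.log(np.clip(p, 1e-300, None)).sum())

    res = optimize.minimize_scalar(nll, bounds=(-_RHO_MAX, _RHO_MAX),
                                   method="bounded", options={"xatol": 1e-6})
    rho = float(res.x)
    return CorrEstimate(rho=rho, converged=bool(res.success),
                        boundary=abs(rho) >= _RHO_MAX - 1e-4)


@dataclass
class HybridMatrix:
    """Mixed Pearson/polyserial/polychoric correlation matrix with a PSD repair."""

    names: list[str]
    matrix: np.ndarray
    psd_matrix: np.ndarray
    flags: dict = field(default_factory=dict)

    @property
    def repair_norm(self) -> float:
        return float(np.linalg.norm(self.psd_matrix - self.matrix))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.names, columns=self.names)


def hybrid_matrix(data, variable_kinds) -> HybridMatrix:
    """Correlation matrix mixing variable kinds.

    Pearson for continuous pairs, polyserial for mixed pairs, polychoric for
    ordinal pairs; pairwise-complete observations; unit diagonal. ``data`` is a
    DataFrame or (n, p) array; ``variable_kinds`` maps/lists 'continuous' or
    'ordinal' per column.
    """
    if isinstance(data, pd.DataFrame):
        names = [str(c) for c in data.columns]
        values = data.to_numpy(dtype=float)
    else:
        values = np.asarray(data, dtype=float)
        names = [f"v{i}" for i in range(values.shape[1])]
    if isinstance(variable_kinds, dict):
        kinds = [variable_kinds[n] for n in names]
    else:
        kinds = list(variable_kinds)
    if len(kinds) != values.shape[1]:
        raise ValueError("one kind per column required")
    p = values.shape[1]
    R = np.eye(p)
    flags: dict = {}
    for i in range(p):
        for j in range(i + 1, p):
            ok = np.isfinite(values[:, i]) & np.isfinite(values[:, j])
            xi, xj = values[ok, i], values[ok, j]
            ki, kj = kinds[i], kinds[j]
            try:
                if ki == CONTINUOUS and kj == CONTINUOUS:
                    r = float(np.corrcoef(xi, xj)[0, 1])
                elif ki == ORDINAL and kj == ORDINAL:
                    tab = pd.crosstab(xi, xj).to_numpy()
                    r = polychoric(tab).rho
                elif ki == CONTINUOUS:
                    r = polyserial(xi, xj).rho
                else:
                    r = polyserial(xj, xi).rho
            except (DegenerateTableError, ValueError) as exc:
                flags[(names[i], names[j])] = str(exc)
                r = np.nan
            R[i, j] = R[j, i] = r
    if np.isnan(R).any():
        raise ValueError(f"unestimable correlation entries: {sorted(flags)}")
    from .model import nearest_psd

    psd = nearest_psd(R)
    np.fill_diagonal(psd, 1.0)
    return HybridMatrix(names=names, matrix=R, psd_matrix=psd, flags=flags)
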