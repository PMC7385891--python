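"""Core SEM parameter containers, implied covariance, Wishart likelihood and ML fitting.

The model couples a structural part (relations among latent factors, plus
factor-level SNP effects) with a measurement part (factor loadings on traits,
plus trait-level SNP effects):

    eta = B eta + Pi g + eps,   eps ~ N(0, diag(theta_eps))
    p   = Lambda eta + K y + delta,   delta ~ N(0, diag(theta_delta))

where ``g`` and ``y`` are SNP predictors on the latent-normal scale.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import optimize, stats


class StructuralSingularityError(ValueError):
    """(I - B) is singular; the structural system has no reduced form."""


class DefinitenessError(ValueError):
    """A covariance matrix that must be positive definite is not."""


def is_acyclic(b_mask: np.ndarray) -> bool:
    """True iff the directed graph with edge j->i for b_mask[i, j] has no cycle."""
    b_mask = np.asarray(b_mask)
    if b_mask.ndim != 2 or b_mask.shape[0] != b_mask.shape[1]:
        raise ValueError("b_mask must be square")
    g = nx.DiGraph()
    g.add_nodes_from(range(b_mask.shape[0]))
    rows, cols = np.nonzero(b_mask)
    g.add_edges_from(zip(cols.tolist(), rows.tolist()))
    return nx.is_directed_acyclic_graph(g)


def nearest_psd(a: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Eigenvalue-clipped positive semi-definite repair of a symmetric matrix."""
    a = (a + a.T) / 2.0
    w, v = np.linalg.eigh(a)
    if w.min() >= eps:
        return a
    w = np.clip(w, eps, None)
    return (v * w) @ v.T


@dataclass
class ModelSpec:
    """Masks and values for all parameter matrices of the SEM.

    ``*_free`` boolean arrays mark estimable cells; non-free nonzero cells are
    held fixed at their stored value. Error variances are stored as diagonals.
    """

    latent_names: list[str]
    trait_names: list[str]
    snp_factor_names: list[str] = field(default_factory=list)
    snp_trait_names: list[str] = field(default_factory=list)
    trait_kinds: dict[str, str] = field(default_factory=dict)

    B: np.ndarray = None
    B_free: np.ndarray = None
    Lambda: np.ndarray = None
    Lambda_free: np.ndarray = None
    Pi: np.ndarray = None
    Pi_free: np.ndarray = None
    K: np.ndarray = None
    K_free: np.ndarray = None
    theta_eps: np.ndarray = None
    theta_eps_free: np.ndarray = None
    theta_delta: np.ndarray = None
    theta_delta_free: np.ndarray = None

    def __post_init__(self):
        nl, nt = len(self.latent_names), len(self.trait_names)
        ng, ny = len(self.snp_factor_names), len(self.snp_trait_names)
        defaults = {
            "B": ((nl, nl), 0.0), "Lambda": ((nt, nl), 0.0),
            "Pi": ((nl, ng), 0.0), "K": ((nt, ny), 0.0),
            "theta_eps": ((nl,), 1.0), "theta_delta": ((nt,), 1.0),
        }
        for name, (shape, fill) in defaults.items():
            if getattr(self, name) is None:
                setattr(self, name, np.full(shape, fill))
            else:
                setattr(self, name, np.asarray(getattr(self, name), dtype=float).reshape(shape))
            if getattr(self, name + "_free") is None:
                setattr(self, name + "_free", np.zeros(shape, dtype=bool))
            else:
                setattr(self, name + "_free",
                        np.asarray(getattr(self, name + "_free"), dtype=bool).reshape(shape))

    # -- bookkeeping -------------------------------------------------------

    MATRICES = ("B", "Lambda", "Pi", "K", "theta_eps", "theta_delta")

    @property
    def n_latent(self) -> int:
        return len(self.latent_names)

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    def validate(self) -> None:
        if not is_acyclic(self.B != 0):
            raise ValueError("B defines a cyclic structural graph")
        for mat, free in ((self.Pi, self.Pi_free), (self.K, self.K_free)):
            if free.size and (free.sum(axis=0) > 1).any():
                raise ValueError("each SNP column may have at most one free cell")
        if (self.theta_eps <= 0).any() or (self.theta_delta <= 0).any():
            raise ValueError("error variances must be strictly positive")

    def copy(self) -> "ModelSpec":
        return ModelSpec(
            latent_names=list(self.latent_names), trait_names=list(self.trait_names),
            snp_factor_names=list(self.snp_factor_names),
            snp_trait_names=list(self.snp_trait_names),
            trait_kinds=dict(self.trait_kinds),
            **{m: getattr(self, m).copy() for m in self.MATRICES},
            **{m + "_free": getattr(self, m + "_free").copy() for m in self.MATRICES},
        )

    def free_param_names(self) -> list[str]:
        names = []
        labels = {
            "B": (self.latent_names, self.latent_names),
            "Lambda": (self.trait_names, self.latent_names),
            "Pi": (self.latent_names, self.snp_factor_names),
            "K": (self.trait_names, self.snp_trait_names),
        }
        for m in self.MATRICES:
            free = getattr(self, m + "_free")
            if free.ndim == 1:
                row_names = self.latent_names if m == "theta_eps" else self.trait_names
                names += [f"{m}[{row_names[i]}]" for i in np.nonzero(free)[0]]
            else:
                rn, cn = labels[m]
                names += [f"{m}[{rn[i]},{cn[j]}]" for i, j in zip(*np.nonzero(free))]
        return names

    @property
    def n_free(self) -> int:
        return sum(int(getattr(self, m + "_free").sum()) for m in self.MATRICES)

    def pack_free(self) -> np.ndarray:
        return np.concatenate(
            [getattr(self, m)[getattr(self, m + "_free")] for m in self.MATRICES]
        ) if self.n_free else np.empty(0)

    def set_free(self, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        k = 0
        for m in self.MATRICES:
            free = getattr(self, m + "_free")
            cnt = int(free.sum())
            getattr(self, m)[free] = values[k:k + cnt]
            k += cnt
        if k != values.size:
            raise ValueError("wrong number of free-parameter values")

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "latent_names": self.latent_names, "trait_names": self.trait_names,
            "snp_factor_names": self.snp_factor_names,
            "snp_trait_names": self.snp_trait_names,
            "trait_kinds": self.trait_kinds,
        }
        for m in self.MATRICES:
            vals, free = getattr(self, m), getattr(self, m + "_free")
            cells = np.nonzero((vals != 0) | free)
            if vals.ndim == 1:
                doc[m] = [[int(i), float(vals[i]), bool(free[i])] for i in cells[0]]
            else:
                doc[m] = [[int(i), int(j), float(vals[i, j]), bool(free[i, j])]
                          for i, j in zip(*cells)]
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        doc = json.loads(text)
        spec = cls(latent_names=doc["latent_names"], trait_names=doc["trait_names"],
                   snp_factor_names=doc.get("snp_factor_names", []),
                   snp_trait_names=doc.get("snp_trait_names", []),
                   trait_kinds=doc.get("trait_kinds", {}))
        for m in cls.MATRICES:
            vals, free = getattr(spec, m), getattr(spec, m + "_free")
            if vals.ndim == 1:
                vals[:] = 0.0
            for cell in doc.get(m, []):
                if vals.ndim == 1:
                    i, v, f = cell
                    vals[i], free[i] = v, f
                else:
                    i, j, v, f = cell
                    vals[i, j], free[i, j] = v, f
        return spec


@dataclass
class ExogenousCov:
    """Covariance among exogenous observed SNP variables (g then y), latent-normal scale."""

    names: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.names),) * 2:
            raise ValueError("exogenous covariance shape does not match names")

    def aligned_to(self, model: ModelSpec) -> "ExogenousCov":
        want = list(model.snp_factor_names) + list(model.snp_trait_names)
        idx = [self.names.index(n) for n in want]
        return ExogenousCov(want, self.matrix[np.ix_(idx, idx)])


def _reduced_form(model: ModelSpec) -> np.ndarray:
    imb = np.eye(model.n_latent) - model.B
    try:
        return np.linalg.inv(imb)
    except np.linalg.LinAlgError as exc:
        raise StructuralSingularityError("(I - B) is singular") from exc


def implied_covariance(model: ModelSpec, exo: ExogenousCov) -> np.ndarray:
    """Model-implied covariance over (traits, factor-SNPs, trait-SNPs).

    Standard reduced-form algebra: with A = (I - B)^-1,
    Cov(eta) = A (Pi S_gg Pi' + Theta_eps) A' and the trait block follows from
    the measurement equation; exogenous blocks pass through unchanged.
    """
    ng, ny = len(model.snp_factor_names), len(model.snp_trait_names)
    if exo.matrix.shape[0] != ng + ny:
        raise ValueError("exogenous covariance does not match model SNP count")
    S = exo.matrix
    S_gg, S_gy, S_yy = S[:ng, :ng], S[:ng, ng:], S[ng:, ng:]
    A = _reduced_form(model)
    L, K, Pi = model.Lambda, model.K, model.Pi
    APi = A @ Pi
    cov_eta = APi @ S_gg @ APi.T + A @ np.diag(model.theta_eps) @ A.T
    cov_eta_y = APi @ S_gy                                     # (nl, ny)
    cov_p = (L @ cov_eta @ L.T + L @ cov_eta_y @ K.T
             + K @ cov_eta_y.T @ L.T + K @ S_yy @ K.T + np.diag(model.theta_delta))
    cov_pg = L @ APi @ S_gg + K @ S_gy.T                       # (nt, ng)
    cov_py = L @ cov_eta_y + K @ S_yy                          # (nt, ny)
    top = np.hstack([cov_p, cov_pg, cov_py])
    bottom = np.hstack([np.vstack([cov_pg.T, cov_py.T]), S])
    full = np.vstack([top, bottom])
    return (full + full.T) / 2.0


def implied_trait_covariance(model: ModelSpec, exo: ExogenousCov) -> np.ndarray:
    nt = model.n_traits
    return implied_covariance(model, exo)[:nt, :nt]


def wishart_loglik(S: np.ndarray, Sigma: np.ndarray, n: int) -> float:
    """Log-density of the sample covariance S under the model.

    Convention: (n-1) S follows a Wishart with n-1 degrees of freedom and
    scale Sigma, so that E[S] = Sigma. The value is the Wishart log-pdf
    evaluated at (n-1) S.
    """
    S, Sigma = np.asarray(S, float), np.asarray(Sigma, float)
    d = S.shape[0]
    if Sigma.shape != S.shape:
        raise ValueError("S and Sigma must have the same shape")
    if n <= d:
        raise ValueError("need n > dimension for a proper Wishart density")
    try:
        np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError as exc:
        raise DefinitenessError("implied covariance is not positive definite") from exc
    return float(stats.wishart.logpdf((n - 1) * S, df=n - 1, scale=Sigma))


def _objective(model: ModelSpec, S: np.ndarray, n: int, exo: ExogenousCov):
    nt = model.n_traits

    def fun(theta: np.ndarray) -> float:
        model.set_free(theta)
        if (model.theta_eps <= 0).any() or (model.theta_delta <= 0).any():
            return np.inf
        try:
            Sigma = implied_covariance(model, exo)
            return -wishart_loglik(S, Sigma, n)
        except (DefinitenessError, StructuralSingularityError):
            return np.inf

    return fun


def _variance_bounds(model: ModelSpec) -> list[tuple]:
    bounds = []
    for m in ModelSpec.MATRICES:
        cnt = int(getattr(model, m + "_free").sum())
        lo = 1e-6 if m.startswith("theta") else -np.inf
        bounds += [(lo, np.inf)] * cnt
    return bounds


def _numerical_hessian(fun, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    k = x.size
    hess = np.empty((k, k))
    f0 = fun(x)
    steps = h * np.maximum(1.0, np.abs(x))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = steps[i]
            ej = np.zeros(k); ej[j] = steps[j]
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    if not np.isfinite(hess).all():
        hess[~np.isfinite(hess)] = 0.0
    return hess


@dataclass
class FitResult:
    model: ModelSpec
    estimates: np.ndarray
    param_names: list[str]
    loglik: float
    info_matrix: np.ndarray
    converged: bool
    n_iter: int


def default_start(model: ModelSpec) -> np.ndarray:
    """Deterministic start: free loadings 1 (keeping any stored sign), free
    B/Pi/K 0.05, free variances 0.5. Stored nonzero coefficient values (e.g.
    sign hints from factor analysis) take precedence over the fill value."""
    fills = {"B": 0.05, "Lambda": 1.0, "Pi": 0.05, "K": 0.05}
    start = []
    for m in ModelSpec.MATRICES:
        free = getattr(model, m + "_free")
        if m.startswith("theta"):
            start += [0.5] * int(free.sum())
        else:
            vals = getattr(model, m)[free]
            fill = fills[m]
            start += [v if v != 0 else fill for v in vals]
    return np.asarray(start)


def fit_ml(model: ModelSpec, S: np.ndarray, n: int,
           exo: ExogenousCov | None = None,
           start: np.ndarray | None = None,
           compute_info: bool = True,
           gtol: float = 1e-6, max_iter: int = 500) -> FitResult:
    """Maximize the Wishart log-likelihood over the free cells of ``model``.

    ``S`` is the full sample covariance over (traits, factor-SNPs, trait-SNPs).
    If ``exo`` is omitted, the exogenous block is taken from ``S`` itself.
    """
    model = model.copy()
    nt = model.n_traits
    d = S.shape[0]
    if model.n_free > d * (d + 1) // 2:
        raise ValueError("more free parameters than distinct covariance entries")
    if exo is None:
        exo = ExogenousCov(
            list(model.snp_factor_names) + list(model.snp_trait_names),
            nearest_psd(S[nt:, nt:]) if d > nt else np.empty((0, 0)),
        )
    fun = _objective(model, S, n, exo)
    x0 = default_start(model) if start is None else np.asarray(start, float)
    if x0.size == 0:
        model.set_free(x0)
        ll = -fun(x0)
        return FitResult(model, x0, [], ll, np.empty((0, 0)), True, 0)
    res = optimize.minimize(fun, x0, method="L-BFGS-B",
                            bounds=_variance_bounds(model),
                            options={"gtol": gtol, "maxiter": max_iter})
    model.set_free(res.x)
    info = _numerical_hessian(fun, res.x) if compute_info else np.empty((0, 0))
    if not res.success:
        warnings.warn(f"ML optimizer did not converge: {res.message}")
    return FitResult(model, res.x.copy(), model.free_param_names(),
                     -float(res.fun), info, bool(res.success), int(res.nit))


def param_significance(estimates: np.ndarray, info_matrix: np.ndarray) -> np.ndarray:
    """Two-sided Wald z-test p-values from estimates and observed information."""
    estimates = np.asarray(estimates, float)
    try:
        cov = np.linalg.inv(info_matrix)
        var = np.diag(cov)
        if (var <= 0).any():
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn("information matrix not invertible; reporting p=1")
        return np.ones_like(estimates)
    se = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, estimates / se, 0.0)
    return 2.0 * stats.norm.sf(np.abs(z))
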