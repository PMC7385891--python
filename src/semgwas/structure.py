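"""Automatic model construction: factor count, trait attribution, and the
greedy acyclic search over factor-factor edges."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import FactorAnalysis

from .model import FitResult, ModelSpec, fit_ml, is_acyclic, param_significance

LOADING_CUTOFF = 0.5
MIN_TRAITS_PER_FACTOR = 2


class NoMeasurementStructureError(ValueError):
    """No factor retained: the traits carry no usable shared structure."""


def parallel_analysis(trait_data, n_sim: int = 500, quantile: float = 0.95,
                      seed: int = 0) -> int:
    """Number of correlation-matrix eigenvalues exceeding the permutation null.

    The null is built by independently permuting each trait column ``n_sim``
    times; an eigenvalue counts if it exceeds the per-rank ``quantile`` of the
    null eigenvalues.
    """
    X = np.asarray(trait_data, dtype=float)
    n, p = X.shape
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    if n < p:
        import warnings

        warnings.warn("fewer samples than traits; correlation matrix is rank-deficient")
    obs = np.linalg.eigvalsh(np.corrcoef(X, rowvar=False))[::-1]
    rng = np.random.default_rng(seed)
    null = np.empty((n_sim, p))
    Xp = X.copy()
    for s in range(n_sim):
        for j in range(p):
            rng.shuffle(Xp[:, j])
        null[s] = np.linalg.eigvalsh(np.corrcoef(Xp, rowvar=False))[::-1]
    thresh = np.quantile(null, quantile, axis=0)
    keep = obs > thresh
    # count the leading run: a sub-threshold eigenvalue ends the retained set
    k = 0
    for flag in keep:
        if not flag:
            break
        k += 1
    return k


@dataclass
class FactorAttribution:
    """Trait-to-factor assignment produced by the loading rule."""

    assignments: dict[str, list[str]]          # factor -> attributed traits
    loadings: pd.DataFrame                     # traits x factors, rotated
    retained_traits: list[str]
    dropped_traits: list[str]
    n_factors_initial: int = 0


def _factor_loadings(X: np.ndarray, n_factors: int, seed: int = 0) -> np.ndarray:
    fa = FactorAnalysis(n_components=n_factors, rotation="varimax",
                        random_state=seed)
    fa.fit(X)
    return fa.components_.T      # (traits, factors); standardized input -> loadings


def build_measurement(trait_data, trait_kinds: dict[str, str] | None = None,
                      n_sim: int = 500, quantile: float = 0.95,
                      seed: int = 0,
                      n_factors: int | None = None) -> tuple[ModelSpec, FactorAttribution]:
    """Factor analysis with parallel-analysis factor count and the 0.5 rule.

    A trait is attributed to the factor with its largest absolute loading,
    provided that loading exceeds 0.5. Factors with fewer than two attributed
    traits and unattributed traits are dropped. The returned ModelSpec has the
    loading mask populated, with the first attributed trait of each factor
    fixed at loading 1 for identification.
    """
    if isinstance(trait_data, pd.DataFrame):
        names = [str(c) for c in trait_data.columns]
        X = trait_data.to_numpy(dtype=float)
    else:
        X = np.asarray(trait_data, dtype=float)
        names = [f"T{i + 1}" for i in range(X.shape[1])]
    std = X.std(axis=0, ddof=1)
    if (std == 0).any():
        raise ValueError("constant trait column")
    Xs = (X - X.mean(axis=0)) / std

    if n_factors is None:
        n_factors = parallel_analysis(Xs, n_sim=n_sim, quantile=quantile, seed=seed)
    if n_factors == 0:
        raise NoMeasurementStructureError("parallel analysis retained zero factors")
    L = _factor_loadings(Xs, n_factors, seed=seed)

    best = np.abs(L).argmax(axis=1)
    attributed = np.abs(L[np.arange(len(names)), best]) > LOADING_CUTOFF
    assignments: dict[int, list[int]] = {j: [] for j in range(n_factors)}
    for t in range(len(names)):
        if attributed[t]:
            assignments[best[t]].append(t)
    kept_factors = [j for j in range(n_factors)
                    if len(assignments[j]) >= MIN_TRAITS_PER_FACTOR]
    if not kept_factors:
        raise NoMeasurementStructureError("no factor retained >= 2 traits")
    kept_traits = sorted(t for j in kept_factors for t in assignments[j])
    dropped = [names[t] for t in range(len(names)) if t not in kept_traits]

    latent_names = [f"F{i + 1}" for i in range(len(kept_factors))]
    trait_names = [names[t] for t in kept_traits]
    kinds = {t: (trait_kinds or {}).get(t, "continuous") for t in trait_names}
    spec = ModelSpec(latent_names=latent_names, trait_names=trait_names,
                     trait_kinds=kinds)
    spec.theta_delta_free[:] = True
    spec.theta_eps_free[:] = True
    for new_j, j in enumerate(kept_factors):
        anchor_sign = np.sign(L[assignments[j][0], j]) or 1.0
        for rank, t in enumerate(assignments[j]):
            row = kept_traits.index(t)
            if rank == 0:
                spec.Lambda[row, new_j] = 1.0      # anchor loading
            else:
                # start sign relative to the anchor's factor-analysis sign
                spec.Lambda_free[row, new_j] = True
                spec.Lambda[row, new_j] = (np.sign(L[t, j]) or 1.0) * anchor_sign
    attribution = FactorAttribution(
        assignments={latent_names[nj]: [names[t] for t in assignments[j]]
                     for nj, j in enumerate(kept_factors)},
        loadings=pd.DataFrame(L, index=names,
                              columns=[f"F{i + 1}" for i in range(n_factors)]),
        retained_traits=trait_names, dropped_traits=dropped,
        n_factors_initial=n_factors)
    return spec, attribution


@dataclass
class StructuralSearchResult:
    model: ModelSpec
    fit: FitResult
    edges: list[tuple[str, str]]
    loglik_trace: list[float]


def _lambda_b_pvalues(fit: FitResult) -> np.ndarray:
    pvals = param_significance(fit.estimates, fit.info_matrix)
    idx = [i for i, nm in enumerate(fit.param_names)
           if nm.startswith("Lambda[") or nm.startswith("B[")]
    return pvals[idx]


def build_structural(model: ModelSpec, S: np.ndarray, n: int,
                     alpha: float = 0.05, tol: float = 1e-4,
                     max_edges: int | None = None,
                     tie_tol: float = 1e-3) -> StructuralSearchResult:
    """Greedy forward search over directed factor-factor edges.

    At each iteration every admissible edge (both directions of every factor
    pair, cycles excluded) is fitted by ML; an edge is a candidate only if all
    free loading and structural coefficients stay significant at ``alpha``.
    The candidate with the highest log-likelihood is added; the search stops
    when the best gain drops to ``tol`` or below.

    Gaussian DAGs in the same Markov-equivalence class fit identically, so a
    later candidate replaces the incumbent only when it improves the
    log-likelihood by more than ``tie_tol``; ties resolve to the first edge in
    (source, target) factor-index order, making the search deterministic.
    """
    model = model.copy()
    nl = model.n_latent
    if S.shape[0] != model.n_traits:
        raise ValueError("S must cover exactly the model's retained traits")
    base_fit = fit_ml(model, S, n)
    model = base_fit.model
    trace = [base_fit.loglik]
    edges: list[tuple[str, str]] = []
    current_fit = base_fit
    limit = max_edges if max_edges is not None else nl * (nl - 1)
    while len(edges) < limit:
        best = None
        for src in range(nl):
            for dst in range(nl):
                if src == dst or model.B_free[dst, src]:
                    continue
                mask = (model.B != 0) | model.B_free
                mask[dst, src] = True
                if not is_acyclic(mask):
                    continue
                cand = model.copy()
                cand.B_free[dst, src] = True
                cand.B[dst, src] = 0.05
                fit = fit_ml(cand, S, n, start=cand.pack_free())
                if (_lambda_b_pvalues(fit) >= alpha).any():
                    continue
                if best is None or fit.loglik > best[0] + tie_tol:
                    best = (fit.loglik, (src, dst), fit)
        if best is None or best[0] - trace[-1] <= tol:
            break
        _, (src, dst), fit = best
        model = fit.model
        current_fit = fit
        edges.append((model.latent_names[src], model.latent_names[dst]))
        trace.append(fit.loglik)
    return StructuralSearchResult(model=model, fit=current_fit,
                                  edges=edges, loglik_trace=trace)


def attribution_table(attr: FactorAttribution) -> pd.DataFrame:
    rows = [(f, t, float(attr.loadings.loc[t].abs().max()))
            for f, traits in attr.assignments.items() for t in traits]
    return pd.DataFrame(rows, columns=["factor", "trait", "loading"])
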