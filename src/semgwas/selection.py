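"""Greedy Wishart-density SNP selection into the factor (Pi) and trait (K) blocks.

With the measurement and structural coefficients held fixed, candidate SNPs
are tried one at a time as the sole new free coefficient, fitted by ML over
the full observed covariance, scored by the Wishart log-density of the
phenotype-only covariance block, and the best one is frozen into the model at
its ML estimate. Variables are visited breadth-first along the structural DAG
(latent factors first, then traits).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import DatasetBundle, ORDINAL
from .model import ExogenousCov, ModelSpec, fit_ml, implied_covariance, is_acyclic, wishart_loglik
from .ordinal import HybridMatrix, hybrid_matrix


@dataclass
class StopConfig:
    """Stopping and redundancy control for per-variable SNP selection."""

    max_snps: int = 15
    min_gain: float = 2.0          # log-density units; ~AIC penalty for 1 df
    redundancy_r: float = 0.9      # drop candidates this code-correlated to a pick
    rescore: bool = True           # re-rank remaining candidates after each add


@dataclass
class SelectionRecord:
    iteration: int
    target: str
    snp: str
    coefficient: float
    log_density: float
    gain: float


@dataclass
class SnpScoreTable:
    """Per-candidate ML coefficient and phenotype-block Wishart log-density."""

    table: pd.DataFrame            # columns: snp, coefficient, log_density, rank

    def top(self) -> pd.Series:
        return self.table.iloc[0]


def traversal_order(model: ModelSpec) -> list[tuple[str, str]]:
    """Latents in BFS order over the structural DAG (name tie-break within a
    level), followed by traits in declared order."""
    mask = (model.B != 0) | model.B_free
    if not is_acyclic(mask):
        raise ValueError("structural graph has a cycle")
    nl = model.n_latent
    parents = [set(np.nonzero(mask[j])[0]) for j in range(nl)]
    visited: list[int] = []
    remaining = set(range(nl))
    while remaining:
        frontier = sorted((j for j in remaining if parents[j] <= set(visited)),
                          key=lambda j: model.latent_names[j])
        if not frontier:
            raise ValueError("structural graph has a cycle")
        visited.extend(frontier)
        remaining -= set(frontier)
    return ([("latent", model.latent_names[j]) for j in visited]
            + [("trait", t) for t in model.trait_names])


def fix_structure(model: ModelSpec) -> ModelSpec:
    """Freeze measurement and structural coefficients at their current values."""
    model = model.copy()
    model.Lambda_free[:] = False
    model.B_free[:] = False
    return model


def _append_snp(model: ModelSpec, snp_name: str, block: str,
                target_idx: int, value: float, free: bool) -> ModelSpec:
    m = model.copy()
    if block == "g":
        m.snp_factor_names = m.snp_factor_names + [snp_name]
        col_val = np.zeros((m.n_latent, 1))
        col_free = np.zeros((m.n_latent, 1), dtype=bool)
        col_val[target_idx, 0], col_free[target_idx, 0] = value, free
        m.Pi = np.hstack([m.Pi, col_val])
        m.Pi_free = np.hstack([m.Pi_free, col_free])
    elif block == "y":
        m.snp_trait_names = m.snp_trait_names + [snp_name]
        col_val = np.zeros((m.n_traits, 1))
        col_free = np.zeros((m.n_traits, 1), dtype=bool)
        col_val[target_idx, 0], col_free[target_idx, 0] = value, free
        m.K = np.hstack([m.K, col_val])
        m.K_free = np.hstack([m.K_free, col_free])
    else:
        raise ValueError(block)
    return m


def _submatrix(H: HybridMatrix, names: list[str]) -> np.ndarray:
    idx = [H.names.index(n) for n in names]
    return H.psd_matrix[np.ix_(idx, idx)]


def _observed_names(model: ModelSpec) -> list[str]:
    return (list(model.trait_names) + list(model.snp_factor_names)
            + list(model.snp_trait_names))


def _pheno_density(model: ModelSpec, H: HybridMatrix, n: int) -> float:
    nt = model.n_traits
    S = _submatrix(H, _observed_names(model))
    exo = ExogenousCov(list(model.snp_factor_names) + list(model.snp_trait_names),
                       S[nt:, nt:])
    Sigma = implied_covariance(model, exo)
    return wishart_loglik(S[:nt, :nt], Sigma[:nt, :nt], n)


def _refit_variances(model: ModelSpec, H: HybridMatrix, n: int) -> ModelSpec:
    S = _submatrix(H, _observed_names(model))
    fit = fit_ml(model, S, n, start=model.pack_free(), compute_info=False)
    return fit.model


def score_snp(model: ModelSpec, H: HybridMatrix, snp_name: str,
              target_kind: str, target_idx: int, n: int
              ) -> tuple[float, float, ModelSpec]:
    """Fit a candidate SNP as the sole new free parameter; return its ML
    coefficient, the phenotype-block Wishart log-density, and the fitted model.

    Error variances are held at the current model's values during the fit, so
    a candidate with genuine cross-covariance to the traits shifts the
    phenotype-block density away from the no-candidate optimum in proportion
    to its effect; null candidates leave it untouched. Ranking and the
    stopping rule use the magnitude of that shift.
    """
    block = "g" if target_kind == "latent" else "y"
    frozen = model.copy()
    frozen.theta_eps_free[:] = False
    frozen.theta_delta_free[:] = False
    cand = _append_snp(frozen, snp_name, block, target_idx, 0.05, free=True)
    S = _submatrix(H, _observed_names(cand))
    try:
        fit = fit_ml(cand, S, n, start=cand.pack_free(), compute_info=False)
        density = _pheno_density(fit.model, H, n)
    except (np.linalg.LinAlgError, ValueError):
        return 0.0, np.nan, cand
    mat = fit.model.Pi if block == "g" else fit.model.K
    coef = float(mat[target_idx, -1])
    return coef, density, fit.model


def score_table(model: ModelSpec, H: HybridMatrix, n: int, target_kind: str,
                target_idx: int, candidates: list[str],
                baseline: float) -> SnpScoreTable:
    rows = []
    for s in candidates:
        coef, density, _ = score_snp(model, H, s, target_kind, target_idx, n)
        impact = abs(baseline - density) if np.isfinite(density) else -np.inf
        rows.append({"snp": s, "coefficient": coef, "log_density": density,
                     "impact": impact})
    tab = pd.DataFrame(rows).sort_values("impact", ascending=False,
                                         kind="stable").reset_index(drop=True)
    tab["rank"] = np.arange(1, len(tab) + 1)
    return SnpScoreTable(table=tab)


def select_snps_for_variable(model: ModelSpec, H: HybridMatrix, n: int,
                             target_kind: str, target_name: str,
                             candidates: list[str],
                             code_corr: pd.DataFrame,
                             stop_cfg: StopConfig | None = None,
                             ) -> tuple[ModelSpec, list[SelectionRecord], list[str]]:
    """Greedy selection loop for one latent factor or trait.

    Returns the updated model (chosen SNP coefficients frozen at their ML
    estimates), a per-addition log, and the surviving candidate pool.
    """
    stop_cfg = stop_cfg or StopConfig()
    pool = list(candidates)
    records: list[SelectionRecord] = []
    if stop_cfg.max_snps <= 0 or not pool:
        return model, records, pool
    if target_kind == "latent":
        target_idx = model.latent_names.index(target_name)
    else:
        target_idx = model.trait_names.index(target_name)
    model = _refit_variances(model, H, n)
    current = _pheno_density(model, H, n)
    ranking: list[str] | None = None
    for it in range(stop_cfg.max_snps):
        if not pool:
            break
        if stop_cfg.rescore or ranking is None:
            tab = score_table(model, H, n, target_kind, target_idx, pool, current)
            ranking = tab.table["snp"].tolist()
            impacts = dict(zip(tab.table["snp"], tab.table["impact"]))
            coefs = dict(zip(tab.table["snp"], tab.table["coefficient"]))
        top = next(s for s in ranking if s in pool)
        if not stop_cfg.rescore:
            coef, density, _ = score_snp(model, H, top, target_kind, target_idx, n)
            impact = abs(current - density) if np.isfinite(density) else -np.inf
        else:
            impact, coef = impacts[top], coefs[top]
        if not np.isfinite(impact) or impact < stop_cfg.min_gain:
            break
        block = "g" if target_kind == "latent" else "y"
        model = _append_snp(model, top, block, target_idx, coef, free=False)
        model = _refit_variances(model, H, n)
        current = _pheno_density(model, H, n)
        records.append(SelectionRecord(iteration=it, target=target_name, snp=top,
                                       coefficient=coef, log_density=current,
                                       gain=impact))
        pool.remove(top)
        if top in code_corr.columns:
            r = code_corr[top].abs()
            pool = [s for s in pool
                    if s not in r.index or r[s] <= stop_cfg.redundancy_r]
        if ranking is not None:
            ranking = [s for s in ranking if s in pool]
    return model, records, pool


def build_full_model(model: ModelSpec, dataset: DatasetBundle,
                     stop_cfg: StopConfig | None = None,
                     extended: bool = False,
                     hybrid: HybridMatrix | None = None,
                     ) -> tuple[ModelSpec, list[SelectionRecord]]:
    """Attach SNPs to every latent factor (Pi), then optionally to every trait
    (K), visiting variables in structural-DAG breadth-first order.

    ``model`` must have its measurement (and, for connected models, structural)
    part built; its Lambda and B coefficients are frozen here. ``extended``
    selects the trait pass. SNPs already fixed in Pi are excluded from trait
    candidacy (one variable per SNP).
    """
    stop_cfg = stop_cfg or StopConfig()
    model = fix_structure(model)
    if hybrid is None:
        hybrid = dataset_hybrid(dataset, model)
    n = len(dataset.samples)
    code_corr = dataset.genotypes.corr()
    records: list[SelectionRecord] = []
    pool = [s for s in dataset.snp_names]
    order = traversal_order(model)
    for kind, name in order:
        if kind == "trait" and not extended:
            continue
        model, recs, pool = select_snps_for_variable(
            model, hybrid, n, kind, name, pool, code_corr, stop_cfg)
        records.extend(recs)
    return model, records


def dataset_hybrid(dataset: DatasetBundle, model: ModelSpec) -> HybridMatrix:
    """Hybrid correlation matrix over the model's traits plus all SNPs.

    SNP codes are treated as ordinal variables throughout.
    """
    traits = dataset.phenotypes[model.trait_names]
    combined = pd.concat([traits, dataset.genotypes], axis=1)
    kinds = [model.trait_kinds.get(t, "continuous") for t in model.trait_names]
    kinds += [ORDINAL] * len(dataset.snp_names)
    return hybrid_matrix(combined, kinds)


def selection_log(records: list[SelectionRecord],
                  snp_info: pd.DataFrame | None = None) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"iteration": r.iteration, "target": r.target, "snp": r.snp,
               "coefficient": r.coefficient, "log_density": r.log_density,
               "gain": r.gain}
        if snp_info is not None and r.snp in snp_info.index:
            row["chrom"] = snp_info.loc[r.snp, "chrom"]
            row["pos"] = snp_info.loc[r.snp, "pos"]
        rows.append(row)
    return pd.DataFrame(rows)
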