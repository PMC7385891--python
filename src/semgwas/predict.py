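"""Trait prediction from genotypes, k-fold cross-validation, prediction
metrics, sliding-window congruence and the peak-vs-hit permutation test."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import DatasetBundle, ORDINAL
from .gibbs import GibbsConfig, estimates_to_model, posterior_summary, run_chains
from .model import ModelSpec
from .ordinal import ThresholdSet, estimate_thresholds, hybrid_matrix
from .selection import StopConfig, build_full_model
from .structure import build_measurement, build_structural

MODEL_TYPES = ("zero-base", "connected-base", "zero-extended", "connected-extended")


def truncated_mean(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Mean of a standard normal truncated to (lo, hi]."""
    num = stats.norm.pdf(lo) - stats.norm.pdf(hi)
    den = stats.norm.cdf(hi) - stats.norm.cdf(lo)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / den
    return np.where(den > 0, out, 0.0)


def snp_codes_to_latent(codes: pd.DataFrame,
                        thresholds: dict[str, ThresholdSet]) -> pd.DataFrame:
    """Map genotype codes to the conditional mean of the underlying normal.

    Missing codes map to 0 (the latent-scale mean).
    """
    out = pd.DataFrame(0.0, index=codes.index, columns=codes.columns)
    for snp in codes.columns:
        thr = thresholds[snp]
        pad = thr.padded()
        col = codes[snp].to_numpy(dtype=float)
        vals = np.zeros(col.size)
        cats = np.sort(np.unique(col[np.isfinite(col)]))
        for k, cat in enumerate(cats[:thr.n_categories]):
            sel = col == cat
            vals[sel] = truncated_mean(pad[k], pad[k + 1])
        out[snp] = vals
    return out


def predict_phenotypes(model: ModelSpec, test_genotypes: pd.DataFrame,
                       snp_thresholds: dict[str, ThresholdSet]) -> pd.DataFrame:
    """Conditional-mean trait predictions from SNP codes.

    eta_hat = (I - B)^-1 Pi g_tilde; p_hat = Lambda eta_hat + K y_tilde.
    """
    needed = list(model.snp_factor_names) + list(model.snp_trait_names)
    missing = [s for s in needed if s not in test_genotypes.columns]
    if missing:
        raise KeyError(f"model SNPs absent from test genotypes: {missing}")
    latent = snp_codes_to_latent(test_genotypes[needed], {
        s: snp_thresholds[s] for s in needed})
    ng = len(model.snp_factor_names)
    g = latent.iloc[:, :ng].to_numpy()
    y = latent.iloc[:, ng:].to_numpy()
    A = np.linalg.inv(np.eye(model.n_latent) - model.B)
    eta_hat = g @ (A @ model.Pi).T
    p_hat = eta_hat @ model.Lambda.T + y @ model.K.T
    return pd.DataFrame(p_hat, index=test_genotypes.index,
                        columns=model.trait_names)


@dataclass
class Metrics:
    r: float
    r2: float
    nrmse: float
    valid: bool = True


def prediction_metrics(observed, predicted) -> Metrics:
    """Pearson r, its square (the reported coefficient of determination), and
    RMSE normalized by the observed standard deviation."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    ok = np.isfinite(obs) & np.isfinite(pred)
    obs, pred = obs[ok], pred[ok]
    if obs.size < 3:
        raise ValueError("need at least 3 observation pairs")
    if obs.std() == 0:
        warnings.warn("zero-variance observed vector; metrics undefined")
        return Metrics(np.nan, np.nan, np.nan, valid=False)
    if pred.std() == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(obs, pred)[0, 1])
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    return Metrics(r=r, r2=r * r, nrmse=rmse / float(obs.std()))


@dataclass
class CVResult:
    per_trait: pd.DataFrame                      # r, r2, nrmse per trait
    pooled: dict[str, tuple[np.ndarray, np.ndarray]]
    fold_summaries: list[dict]
    k: int
    seed: int
    model_type: str

    def to_table(self) -> pd.DataFrame:
        return self.per_trait.reset_index(names="trait")


def _fold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(perm[i::k]) for i in range(k)]


def fit_pipeline(train: DatasetBundle, model_type: str,
                 stop_cfg: StopConfig | None = None,
                 gibbs_cfg: GibbsConfig | None = None,
                 n_factors: int | None = None,
                 pa_sims: int = 200, seed: int = 0):
    """Full automatic construction + Bayesian fit on one training set.

    Returns (posterior-mean model, SNP thresholds, selection records).
    """
    if model_type not in MODEL_TYPES:
        raise ValueError(f"model_type must be one of {MODEL_TYPES}")
    connected = model_type.startswith("connected")
    extended = model_type.endswith("extended")
    kinds = train.trait_kinds()
    spec, attribution = build_measurement(train.phenotypes, trait_kinds=kinds,
                                          n_sim=pa_sims, seed=seed,
                                          n_factors=n_factors)
    n = len(train.samples)
    if connected:
        traits = train.phenotypes[spec.trait_names]
        kind_list = [kinds[t] for t in spec.trait_names]
        if any(k == ORDINAL for k in kind_list):
            S_traits = hybrid_matrix(traits, kind_list).psd_matrix
        else:
            std = (traits - traits.mean()) / traits.std(ddof=1)
            S_traits = np.corrcoef(std.to_numpy(), rowvar=False)
        search = build_structural(spec, S_traits, n)
        spec = search.model
    model, records = build_full_model(spec, train, stop_cfg=stop_cfg,
                                      extended=extended)
    samples = run_chains(model, train, config=gibbs_cfg, seed=seed)
    fitted = estimates_to_model(model, posterior_summary(samples))
    thresholds = {}
    for snp in train.snp_names:
        col = train.genotypes[snp].to_numpy(dtype=float)
        cats = np.sort(np.unique(col[np.isfinite(col)]))
        counts = [(col == c).sum() for c in cats]
        if len(counts) >= 2:
            thresholds[snp] = estimate_thresholds(counts)
        else:
            thresholds[snp] = ThresholdSet(cutpoints=np.empty(0),
                                           proportions=np.ones(1))
    return fitted, thresholds, records


def cross_validate(dataset: DatasetBundle, k: int = 20,
                   model_type: str = "connected-base", seed: int = 0,
                   stop_cfg: StopConfig | None = None,
                   gibbs_cfg: GibbsConfig | None = None,
                   n_factors: int | None = None,
                   pa_sims: int = 200) -> CVResult:
    """Seeded k-fold cross-validation of the full pipeline.

    Each fold's model (measurement, structural, SNP selection, Gibbs) is built
    on the training split alone -- thresholds included -- and predictions for
    the held-out split are pooled across folds before computing metrics.
    """
    n = len(dataset.samples)
    folds = _fold_indices(n, k, seed)
    pooled_obs: dict[str, list] = {}
    pooled_pred: dict[str, list] = {}
    fold_summaries = []
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        train = dataset.subset_samples(train_idx)
        test = dataset.subset_samples(test_idx)
        try:
            fitted, thresholds, records = fit_pipeline(
                train, model_type, stop_cfg=stop_cfg, gibbs_cfg=gibbs_cfg,
                n_factors=n_factors, pa_sims=pa_sims, seed=seed + f)
        except ValueError as exc:
            warnings.warn(f"fold {f} skipped: {exc}")
            fold_summaries.append({"fold": f, "skipped": str(exc)})
            continue
        preds = predict_phenotypes(fitted, test.genotypes, thresholds)
        for t in fitted.trait_names:
            pooled_obs.setdefault(t, []).extend(
                test.phenotypes[t].to_numpy(dtype=float))
            pooled_pred.setdefault(t, []).extend(preds[t].to_numpy())
        fold_summaries.append({
            "fold": f,
            "n_pi_snps": len(fitted.snp_factor_names),
            "n_k_snps": len(fitted.snp_trait_names),
            "n_traits": fitted.n_traits,
            "n_factors": fitted.n_latent,
        })
    rows = {}
    pooled = {}
    for t in pooled_obs:
        obs = np.asarray(pooled_obs[t])
        pred = np.asarray(pooled_pred[t])
        pooled[t] = (obs, pred)
        m = prediction_metrics(obs, pred)
        rows[t] = {"r": m.r, "r2": m.r2, "nrmse": m.nrmse}
    per_trait = pd.DataFrame(rows).T if rows else pd.DataFrame(
        columns=["r", "r2", "nrmse"])
    return CVResult(per_trait=per_trait, pooled=pooled,
                    fold_summaries=fold_summaries, k=k, seed=seed,
                    model_type=model_type)


# -- positional congruence ---------------------------------------------------

def _window_starts(length: int, window: int, step: int) -> np.ndarray:
    # grid at nonnegative multiples of step; a window exists iff it starts
    # inside the chromosome
    return np.arange(0, max(int(length), 1), step)


def window_congruence(snp_positions: pd.DataFrame,
                      chrom_lengths: dict, window: int = 500_000,
                      step: int = 100_000) -> pd.DataFrame:
    """Per-window count of models having at least one SNP inside.

    ``snp_positions`` columns: model, chrom, pos (optionally subset; counts are
    then per subset). Windows are 0-based half-open [start, start + window)
    with starts at multiples of ``step``.
    """
    df = snp_positions.copy()
    if "subset" not in df.columns:
        df["subset"] = "all"
    for chrom, grp in df.groupby("chrom"):
        if chrom not in chrom_lengths:
            raise KeyError(f"unknown chromosome {chrom}")
        if (grp["pos"] >= chrom_lengths[chrom]).any() or (grp["pos"] < 0).any():
            raise ValueError(f"positions beyond chromosome {chrom} length")
    subsets = sorted(df["subset"].unique()) if len(df) else ["all"]
    records = []
    for chrom, length in chrom_lengths.items():
        starts = _window_starts(length, window, step)
        for subset in subsets:
            cgrp = df[(df["subset"] == subset) & (df["chrom"] == chrom)]
            for start in starts:
                end = start + window
                inside = cgrp[(cgrp["pos"] >= start) & (cgrp["pos"] < end)]
                records.append({"chrom": chrom, "start": int(start),
                                "end": int(end), "subset": subset,
                                "model_count": int(inside["model"].nunique())})
    return pd.DataFrame(records)


def peak_hit_permutation(peak_windows: pd.DataFrame, hit_positions: pd.DataFrame,
                         chrom_lengths: dict, n_perm: int = 1000,
                         seed: int = 0) -> float:
    """Permutation p-value for overlap between peak windows and hit positions.

    Observed statistic: number of hits inside any peak window. Null: hits are
    circularly shifted per chromosome by a uniform offset; p-value
    (1 + #{null >= observed}) / (1 + n_perm).
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse p-value")
    if len(peak_windows) == 0:
        return 1.0

    def count_hits(hits: pd.DataFrame) -> int:
        total = 0
        for chrom, grp in hits.groupby("chrom"):
            peaks = peak_windows[peak_windows["chrom"] == chrom]
            if len(peaks) == 0:
                continue
            pos = grp["pos"].to_numpy()
            inside = np.zeros(pos.size, dtype=bool)
            for _, w in peaks.iterrows():
                inside |= (pos >= w["start"]) & (pos < w["end"])
            total += int(inside.sum())
        return total

    observed = count_hits(hit_positions)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        shifted = []
        for chrom, grp in hit_positions.groupby("chrom"):
            length = int(chrom_lengths[chrom])
            offset = int(rng.integers(0, length))
            g = grp.copy()
            g["pos"] = (g["pos"] + offset) % length
            shifted.append(g)
        if count_hits(pd.concat(shifted)) >= observed:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)
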