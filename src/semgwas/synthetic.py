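"""Generative twin of the SEM: synthetic models and datasets with known truth.

Every downstream stage (implied covariance, ML fitting, structure learning,
SNP selection, Gibbs sampling, cross-validation) is testable against the truth
stored in a :class:`TrueModel`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CONTINUOUS, ORDINAL, DatasetBundle, VariableMeta
from .model import ModelSpec, is_acyclic
from .ordinal import ThresholdSet, estimate_thresholds


def discretize(continuous_values, thresholds, start: int = 1) -> np.ndarray:
    """Ordinal codes from threshold intervals: code k iff value in (t_{k-1}, t_k].

    Values exactly at a cutpoint take the lower interval (right-closed).
    Codes run from ``start`` to ``start + n_categories - 1``.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size and (np.diff(thresholds) <= 0).any():
        raise ValueError("thresholds must be strictly increasing")
    values = np.asarray(continuous_values, dtype=float)
    codes = np.searchsorted(thresholds, values, side="left") + start
    return codes


def hwe_proportions(alt_freq: float) -> np.ndarray:
    q = float(alt_freq)
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])


@dataclass
class TrueModel:
    """A fully valued ModelSpec plus everything needed to simulate from it."""

    spec: ModelSpec
    allele_freqs: np.ndarray                 # alt-allele frequency per SNP (g then y)
    snp_thresholds: list[ThresholdSet]
    trait_thresholds: dict[str, ThresholdSet] = field(default_factory=dict)
    chrom: np.ndarray = None                 # per SNP
    pos: np.ndarray = None

    @property
    def snp_names(self) -> list[str]:
        return list(self.spec.snp_factor_names) + list(self.spec.snp_trait_names)

    def latent_variances(self) -> np.ndarray:
        """Var(eta) under the generative equations (unit-variance SNP scale)."""
        spec = self.spec
        A = np.linalg.inv(np.eye(spec.n_latent) - spec.B)
        ng = len(spec.snp_factor_names)
        S_gg = np.eye(ng)
        cov = A @ (spec.Pi @ S_gg @ spec.Pi.T + np.diag(spec.theta_eps)) @ A.T
        return np.diag(cov)

    def code_prediction_ceiling(self) -> np.ndarray:
        """Per-trait upper bound on prediction r given observed genotype codes:
        sqrt(Var(E[p | codes]) / Var(p)).

        Compared with the latent-scale ceiling this includes the attenuation
        from observing each SNP only through its discretized code.
        """
        from scipy import stats as _st

        spec = self.spec
        A = np.linalg.inv(np.eye(spec.n_latent) - spec.B)
        W = np.hstack([spec.Lambda @ A @ spec.Pi, spec.K])   # (nt, n_snps)
        info = np.empty(len(self.snp_names))
        for s, thr in enumerate(self.snp_thresholds):
            pad = thr.padded()
            var_mean = 0.0
            for k in range(thr.n_categories):
                lo, hi = pad[k], pad[k + 1]
                f = thr.proportions[k]
                m = (_st.norm.pdf(lo) - _st.norm.pdf(hi)) / max(f, 1e-12)
                var_mean += f * m ** 2
            info[s] = var_mean                   # Var(E[g|code]) of a unit normal
        genetic = (W ** 2) @ info
        cov_eta = A @ (spec.Pi @ spec.Pi.T + np.diag(spec.theta_eps)) @ A.T
        total = np.diag(spec.Lambda @ cov_eta @ spec.Lambda.T) \
            + (spec.K ** 2).sum(axis=1) + spec.theta_delta
        return np.sqrt(genetic / total)

    def snp_explained_trait_variance(self) -> np.ndarray:
        """Per-trait variance explained by SNPs (latent-normal scale), for
        prediction ceilings: Var(Lambda A Pi g + K y) / Var(p)."""
        spec = self.spec
        A = np.linalg.inv(np.eye(spec.n_latent) - spec.B)
        LAP = spec.Lambda @ A @ spec.Pi
        genetic = (LAP ** 2).sum(axis=1) + (spec.K ** 2).sum(axis=1)
        cov_eta = A @ (spec.Pi @ spec.Pi.T + np.diag(spec.theta_eps)) @ A.T
        total = np.diag(spec.Lambda @ cov_eta @ spec.Lambda.T) \
            + (spec.K ** 2).sum(axis=1) + spec.theta_delta
        return genetic / total


def _as_list(value, n: int) -> list:
    if np.isscalar(value):
        return [value] * n
    value = list(value)
    if len(value) != n:
        raise ValueError("length mismatch")
    return value


def _draw_effect(rng, effect_sizes) -> float:
    if np.isscalar(effect_sizes):
        mag = float(effect_sizes)
    else:
        lo, hi = effect_sizes
        mag = float(rng.uniform(lo, hi))
    return mag


def make_true_model(n_factors: int,
                    traits_per_factor,
                    snps_per_factor=2,
                    snps_per_trait=0,
                    b_edges=(),
                    effect_sizes=(0.3, 0.5),
                    seed: int = 0,
                    ordinal_traits: dict[int, int] | None = None,
                    maf_range=(0.1, 0.5),
                    loading_range=(0.6, 0.9),
                    snps_per_chromosome: int = 50,
                    position_step: int = 50_000,
                    anchor: bool = False) -> TrueModel:
    """Build a fully valued generative model.

    ``b_edges`` is a sequence of (source_factor, target_factor, coefficient)
    index triples and must be acyclic. ``effect_sizes`` is a scalar or (lo, hi)
    range for SNP coefficient magnitudes. ``ordinal_traits`` maps trait index
    to its number of (balanced) categories; unlisted traits are continuous.
    """
    rng = np.random.default_rng(seed)
    traits_per_factor = _as_list(traits_per_factor, n_factors)
    n_traits = int(sum(traits_per_factor))
    snps_per_factor = _as_list(snps_per_factor, n_factors)
    snps_per_trait = _as_list(snps_per_trait, n_traits)

    latent_names = [f"F{i + 1}" for i in range(n_factors)]
    trait_names = [f"T{i + 1:02d}" for i in range(n_traits)]
    g_names = [f"gsnp{i + 1:03d}" for i in range(int(sum(snps_per_factor)))]
    y_names = [f"ysnp{i + 1:03d}" for i in range(int(sum(snps_per_trait)))]

    B = np.zeros((n_factors, n_factors))
    for src, dst, coef in b_edges:
        B[dst, src] = coef
    if not is_acyclic(B != 0):
        raise ValueError("b_edges must form an acyclic graph")

    Lambda = np.zeros((n_traits, n_factors))
    t0 = 0
    for j, block in enumerate(traits_per_factor):
        for t in range(t0, t0 + block):
            Lambda[t, j] = rng.uniform(*loading_range) * rng.choice([-1.0, 1.0])
        t0 += block

    Pi = np.zeros((n_factors, len(g_names)))
    col = 0
    for j, cnt in enumerate(snps_per_factor):
        for _ in range(cnt):
            Pi[j, col] = _draw_effect(rng, effect_sizes) * rng.choice([-1.0, 1.0])
            col += 1
    K = np.zeros((n_traits, len(y_names)))
    col = 0
    for t, cnt in enumerate(snps_per_trait):
        for _ in range(cnt):
            K[t, col] = _draw_effect(rng, effect_sizes) * rng.choice([-1.0, 1.0])
            col += 1

    # scale error variances so latent factors and traits come out near unit
    # variance (loadings then read as correlations, matching the 0.5 rule)
    theta_eps = np.empty(n_factors)
    order = _topological_order(B)
    var_eta = np.zeros(n_factors)
    for j in order:
        genetic = float((Pi[j] ** 2).sum())
        inherited = float((B[j] ** 2) @ var_eta)
        theta_eps[j] = max(0.05, 1.0 - genetic - inherited)
        var_eta[j] = genetic + inherited + theta_eps[j]
    theta_delta = np.empty(n_traits)
    for t in range(n_traits):
        explained = float((Lambda[t] ** 2) @ var_eta) + float((K[t] ** 2).sum())
        theta_delta[t] = max(0.05, 1.0 - explained)

    if anchor:
        # rescale each factor so its first attributed trait loads exactly 1
        # (the estimation-side identification convention); eta_j -> a_j eta_j
        t0 = 0
        scale = np.ones(n_factors)
        for j, block in enumerate(traits_per_factor):
            scale[j] = Lambda[t0, j]
            t0 += block
        Lambda = Lambda / scale
        Pi = Pi * scale[:, None]
        theta_eps = theta_eps * scale ** 2
        B = B * scale[:, None] / scale[None, :]
        var_eta = var_eta * scale ** 2

    trait_kinds = {}
    trait_thresholds = {}
    ordinal_traits = ordinal_traits or {}
    for idx, name in enumerate(trait_names):
        if idx in ordinal_traits:
            ncat = int(ordinal_traits[idx])
            trait_kinds[name] = ORDINAL
            trait_thresholds[name] = estimate_thresholds([1] * ncat)
        else:
            trait_kinds[name] = CONTINUOUS

    spec = ModelSpec(latent_names=latent_names, trait_names=trait_names,
                     snp_factor_names=g_names, snp_trait_names=y_names,
                     trait_kinds=trait_kinds,
                     B=B, Lambda=Lambda, Pi=Pi, K=K,
                     theta_eps=theta_eps, theta_delta=theta_delta)
    spec.validate()

    n_snps = len(g_names) + len(y_names)
    freqs = rng.uniform(*maf_range, size=n_snps)
    snp_thr = [estimate_thresholds(np.maximum(hwe_proportions(q) * 1000, 1))
               for q in freqs]
    chrom = np.array([i // snps_per_chromosome + 1 for i in range(n_snps)])
    pos = np.array([(i % snps_per_chromosome + 1) * position_step
                    for i in range(n_snps)])
    return TrueModel(spec=spec, allele_freqs=freqs, snp_thresholds=snp_thr,
                     trait_thresholds=trait_thresholds, chrom=chrom, pos=pos)


def _topological_order(B: np.ndarray) -> list[int]:
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(range(B.shape[0]))
    rows, cols = np.nonzero(B)
    g.add_edges_from(zip(cols.tolist(), rows.tolist()))
    return list(nx.topological_sort(g))


def simulate_dataset(true_model: TrueModel, n_samples: int, seed: int = 0,
                     missing_rate: float = 0.0,
                     return_latent: bool = False):
    """Draw a dataset from the generative equations.

    SNP latent values are standard normal and discretized at Hardy-Weinberg
    thresholds (loci independent); eta = (I-B)^-1 (Pi g + eps); continuous
    traits from the measurement equation, ordinal traits discretized.
    """
    if n_samples < 2:
        raise ValueError("need n_samples >= 2")
    rng = np.random.default_rng(seed)
    spec = true_model.spec
    ng = len(spec.snp_factor_names)
    n_snps = len(true_model.snp_names)

    g_tilde = rng.standard_normal((n_samples, n_snps))
    codes = np.empty_like(g_tilde)
    for s in range(n_snps):
        codes[:, s] = discretize(g_tilde[:, s],
                                 true_model.snp_thresholds[s].cutpoints, start=0)

    eps = rng.standard_normal((n_samples, spec.n_latent)) * np.sqrt(spec.theta_eps)
    A = np.linalg.inv(np.eye(spec.n_latent) - spec.B)
    eta = (g_tilde[:, :ng] @ spec.Pi.T + eps) @ A.T
    delta = rng.standard_normal((n_samples, spec.n_traits)) * np.sqrt(spec.theta_delta)
    p_latent = eta @ spec.Lambda.T + g_tilde[:, ng:] @ spec.K.T + delta

    phen = p_latent.copy()
    trait_meta = {}
    for idx, name in enumerate(spec.trait_names):
        kind = spec.trait_kinds.get(name, CONTINUOUS)
        if kind == ORDINAL:
            thr = true_model.trait_thresholds[name]
            phen[:, idx] = discretize(p_latent[:, idx], thr.cutpoints, start=1)
            trait_meta[name] = VariableMeta(name=name, kind=ORDINAL,
                                            categories=list(range(1, thr.n_categories + 1)))
        else:
            trait_meta[name] = VariableMeta(name=name, kind=CONTINUOUS)

    if missing_rate > 0:
        mask = rng.random(codes.shape) < missing_rate
        codes[mask] = np.nan

    samples = [f"s{i + 1:04d}" for i in range(n_samples)]
    genotypes = pd.DataFrame(codes, index=samples, columns=true_model.snp_names)
    snp_info = pd.DataFrame({
        "chrom": true_model.chrom, "pos": true_model.pos,
        "ref": "A", "alt": "G",
    }, index=true_model.snp_names)
    phenotypes = pd.DataFrame(phen, index=samples, columns=spec.trait_names)
    bundle = DatasetBundle(genotypes=genotypes, snp_info=snp_info,
                           phenotypes=phenotypes, trait_meta=trait_meta)
    if return_latent:
        return bundle, {"eta": eta, "snp_latent": g_tilde, "trait_latent": p_latent}
    return bundle
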