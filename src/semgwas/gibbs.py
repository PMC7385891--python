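"""Gibbs sampler for all SEM parameters with data augmentation for ordinal
variables, plus convergence diagnostics.

Each sweep follows a six-step scan:

1. augmented latent values for ordinal traits and all SNPs from truncated
   standard normals within their observed category intervals (independent of
   the current parameters);
2. latent factors eta from their exact multivariate-normal full conditional;
3. factor error variances theta_eps from conjugate inverse-gamma updates;
4. rows of the [B, Pi] block from conjugate multivariate-normal regressions;
5. trait error variances theta_delta from inverse-gamma updates;
6. rows of the [Lambda, K] block from conjugate normal regressions.

Coefficient priors are normal, centered at the construction-time values;
variance priors are inverse-gamma. Identification anchor loadings (fixed at 1)
are never sampled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .data import DatasetBundle, ORDINAL
from .model import ModelSpec
from .ordinal import ThresholdSet, estimate_thresholds


@dataclass
class GibbsConfig:
    n_chains: int = 5
    length: int = 2000
    burn_in: int = 500
    coef_prior_sd: float = 1.0
    ig_shape: float = 2.0      # alpha_0
    ig_rate: float = 1.0       # beta_0
    init_coef_sd: float = 0.1
    store_latent: bool = False


# -- elementary draws --------------------------------------------------------

def draw_augmented(lo: np.ndarray, hi: np.ndarray, rng: np.random.Generator
                   ) -> np.ndarray:
    """Inverse-CDF truncated standard-normal draws inside (lo, hi] elementwise."""
    a, b = ndtr(lo), ndtr(hi)
    u = rng.random(lo.shape)
    return ndtri(np.clip(a + u * (b - a), 1e-15, 1 - 1e-15))


def draw_variances(ssr: np.ndarray, n_eff: int, shape0: float, rate0: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Conjugate inverse-gamma draws: IG(shape0 + n/2, rate0 + SSR/2)."""
    shape = shape0 + n_eff / 2.0
    rate = rate0 + np.asarray(ssr, float) / 2.0
    return rate / rng.gamma(shape, 1.0, size=rate.shape)


def draw_coefficient_row(X: np.ndarray, r: np.ndarray, sigma2: float,
                         prior_mean: np.ndarray, prior_sd: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Draw the free coefficients of one row regression r ~ X beta + N(0, sigma2).

    Conjugate multivariate-normal full conditional with independent
    N(prior_mean, prior_sd^2) priors per coefficient.
    """
    k = X.shape[1]
    prec = X.T @ X / sigma2 + np.eye(k) / prior_sd ** 2
    rhs = X.T @ r / sigma2 + prior_mean / prior_sd ** 2
    try:
        chol = np.linalg.cholesky(prec)
    except np.linalg.LinAlgError:
        prec = prec + np.eye(k) * 1e-8
        chol = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, rhs)
    z = rng.standard_normal(k)
    return mean + np.linalg.solve(chol.T, z)


def draw_eta(p_resid: np.ndarray, g_tilde: np.ndarray, model: ModelSpec,
             rng: np.random.Generator, jitter_log: list | None = None
             ) -> np.ndarray:
    """Exact multivariate-normal full conditional of the latent factors.

    ``p_resid`` is p - K y (n, nt); ``g_tilde`` the factor-SNP latents (n, ng).
    Prior from the structural equation: eta ~ N(A Pi g, A Theta_eps A');
    likelihood p_resid = Lambda eta + delta.
    """
    nl = model.n_latent
    A = np.linalg.inv(np.eye(nl) - model.B)
    m0 = g_tilde @ (A @ model.Pi).T                     # (n, nl)
    S0 = A @ np.diag(model.theta_eps) @ A.T
    S0_inv = np.linalg.inv(S0)
    LD = model.Lambda.T / model.theta_delta             # (nl, nt)
    prec = S0_inv + LD @ model.Lambda
    try:
        chol = np.linalg.cholesky(prec)
    except np.linalg.LinAlgError:
        prec = prec + np.eye(nl) * 1e-8
        chol = np.linalg.cholesky(prec)
        if jitter_log is not None:
            jitter_log.append(1e-8)
    rhs = m0 @ S0_inv.T + p_resid @ LD.T                # (n, nl)
    means = np.linalg.solve(prec, rhs.T).T
    z = rng.standard_normal(means.shape)
    return means + np.linalg.solve(chol.T, z.T).T


# -- sampled-parameter bookkeeping ------------------------------------------

def sampled_masks(model: ModelSpec) -> dict[str, np.ndarray]:
    """Cells whose posterior is sampled: every nonzero/free coefficient except
    the identification anchors (Lambda cells fixed at exactly 1), plus all
    error variances."""
    masks = {}
    for m in ("B", "Lambda", "Pi", "K"):
        vals, free = getattr(model, m), getattr(model, m + "_free")
        mask = (vals != 0) | free
        if m == "Lambda":
            mask &= ~((vals == 1.0) & ~free)
        masks[m] = mask
    masks["theta_eps"] = np.ones(model.n_latent, dtype=bool)
    masks["theta_delta"] = np.ones(model.n_traits, dtype=bool)
    return masks


def sampled_param_names(model: ModelSpec) -> list[str]:
    masks = sampled_masks(model)
    labels = {
        "B": (model.latent_names, model.latent_names),
        "Lambda": (model.trait_names, model.latent_names),
        "Pi": (model.latent_names, model.snp_factor_names),
        "K": (model.trait_names, model.snp_trait_names),
    }
    names = []
    for m in ("B", "Lambda", "Pi", "K"):
        rn, cn = labels[m]
        names += [f"{m}[{rn[i]},{cn[j]}]" for i, j in zip(*np.nonzero(masks[m]))]
    names += [f"theta_eps[{x}]" for x in model.latent_names]
    names += [f"theta_delta[{x}]" for x in model.trait_names]
    return names


def _extract(model: ModelSpec, masks: dict[str, np.ndarray]) -> np.ndarray:
    parts = [getattr(model, m)[masks[m]] for m in
             ("B", "Lambda", "Pi", "K", "theta_eps", "theta_delta")]
    return np.concatenate(parts) if parts else np.empty(0)


# -- data preparation --------------------------------------------------------

@dataclass
class GibbsData:
    """Observed arrays and truncation intervals for one dataset."""

    traits: np.ndarray                  # (n, nt); ordinal columns hold codes
    trait_is_ordinal: np.ndarray        # (nt,) bool
    trait_lo: np.ndarray                # (n, nt); -inf for continuous columns
    trait_hi: np.ndarray
    snp_lo: np.ndarray                  # (n, ng+ny)
    snp_hi: np.ndarray
    n: int


def _interval_bounds(codes: np.ndarray, thresholds: ThresholdSet,
                     categories: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pad = thresholds.padded()
    lo = np.full(codes.shape, -np.inf)
    hi = np.full(codes.shape, np.inf)
    for k, cat in enumerate(categories):
        sel = codes == cat
        lo[sel], hi[sel] = pad[k], pad[k + 1]
    return lo, hi       # missing codes keep (-inf, inf)


def prepare_gibbs_data(model: ModelSpec, dataset: DatasetBundle,
                       trait_thresholds: dict[str, ThresholdSet] | None = None,
                       snp_thresholds: dict[str, ThresholdSet] | None = None
                       ) -> GibbsData:
    """Assemble observed matrices and truncated-normal intervals.

    Thresholds default to empirical estimates from the supplied dataset; pass
    training-set thresholds explicitly to avoid leakage in cross-validation.
    """
    n = len(dataset.samples)
    nt = model.n_traits
    traits = dataset.phenotypes[model.trait_names].to_numpy(dtype=float)
    is_ord = np.array([model.trait_kinds.get(t, "continuous") == ORDINAL
                       for t in model.trait_names])
    t_lo = np.full((n, nt), -np.inf)
    t_hi = np.full((n, nt), np.inf)
    for j, name in enumerate(model.trait_names):
        if not is_ord[j]:
            continue
        col = traits[:, j]
        cats = np.unique(col[np.isfinite(col)])
        if trait_thresholds and name in trait_thresholds:
            thr = trait_thresholds[name]
        else:
            counts = [(col == c).sum() for c in cats]
            thr = estimate_thresholds(counts)
        t_lo[:, j], t_hi[:, j] = _interval_bounds(col, thr, cats)

    snp_names = list(model.snp_factor_names) + list(model.snp_trait_names)
    codes = dataset.genotypes[snp_names].to_numpy(dtype=float) if snp_names \
        else np.empty((n, 0))
    s_lo = np.full(codes.shape, -np.inf)
    s_hi = np.full(codes.shape, np.inf)
    for j, name in enumerate(snp_names):
        col = codes[:, j]
        cats = np.unique(col[np.isfinite(col)])
        if snp_thresholds and name in snp_thresholds:
            thr = snp_thresholds[name]
        else:
            counts = [(col == c).sum() for c in cats]
            thr = estimate_thresholds(counts)
        s_lo[:, j], s_hi[:, j] = _interval_bounds(col, thr, cats)
    return GibbsData(traits=traits, trait_is_ordinal=is_ord,
                     trait_lo=t_lo, trait_hi=t_hi,
                     snp_lo=s_lo, snp_hi=s_hi, n=n)


# -- the sampler -------------------------------------------------------------

@dataclass
class PosteriorSamples:
    param_names: list[str]
    chains: np.ndarray              # (n_chains, kept_iterations, n_params)
    burn_in: int
    length: int
    seeds: list[int]
    eta_chains: np.ndarray | None = None

    def pooled(self) -> np.ndarray:
        return self.chains.reshape(-1, self.chains.shape[-1])

    def to_frames(self) -> list[pd.DataFrame]:
        return [pd.DataFrame(c, columns=self.param_names) for c in self.chains]


def _row_regression_setup(model: ModelSpec, masks):
    """Precompute predictor layouts for the [B, Pi] and [Lambda, K] row draws."""
    struct_rows = []
    for j in range(model.n_latent):
        b_idx = np.nonzero(masks["B"][j])[0]
        pi_idx = np.nonzero(masks["Pi"][j])[0]
        fixed_b = np.nonzero((model.B[j] != 0) & ~masks["B"][j])[0]
        fixed_pi = np.nonzero((model.Pi[j] != 0) & ~masks["Pi"][j])[0]
        struct_rows.append((j, b_idx, pi_idx, fixed_b, fixed_pi))
    meas_rows = []
    for i in range(model.n_traits):
        l_idx = np.nonzero(masks["Lambda"][i])[0]
        k_idx = np.nonzero(masks["K"][i])[0]
        fixed_l = np.nonzero((model.Lambda[i] != 0) & ~masks["Lambda"][i])[0]
        fixed_k = np.nonzero((model.K[i] != 0) & ~masks["K"][i])[0]
        meas_rows.append((i, l_idx, k_idx, fixed_l, fixed_k))
    return struct_rows, meas_rows


def run_chains(model: ModelSpec, dataset: DatasetBundle,
               config: GibbsConfig | None = None, seed: int = 0,
               gibbs_data: GibbsData | None = None) -> PosteriorSamples:
    """Run independent Gibbs chains and collect post-burn-in draws."""
    config = config or GibbsConfig()
    if gibbs_data is None:
        gibbs_data = prepare_gibbs_data(model, dataset)
    masks = sampled_masks(model)
    names = sampled_param_names(model)
    prior = model.copy()     # construction-time values = prior means
    n = gibbs_data.n
    ng = len(model.snp_factor_names)
    n_params = len(names)
    kept = config.length - config.burn_in
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(config.n_chains)
    chains = np.empty((config.n_chains, kept, n_params))
    eta_store = (np.empty((config.n_chains, kept, n, model.n_latent))
                 if config.store_latent else None)
    struct_rows, meas_rows = _row_regression_setup(model, masks)
    prior_vec = {
        "B": prior.B, "Pi": prior.Pi, "Lambda": prior.Lambda, "K": prior.K,
    }
    is_ord = gibbs_data.trait_is_ordinal

    for c, cseed in enumerate(child_seeds):
        rng = np.random.default_rng(cseed)
        state = model.copy()
        # random initialization around the prior
        for m in ("B", "Lambda", "Pi", "K"):
            vals = getattr(state, m)
            vals[masks[m]] = prior_vec[m][masks[m]] \
                + rng.normal(0.0, config.init_coef_sd, int(masks[m].sum()))
        state.theta_eps[:] = draw_variances(
            np.zeros(model.n_latent), 0, config.ig_shape, config.ig_rate, rng)
        state.theta_delta[:] = draw_variances(
            np.zeros(model.n_traits), 0, config.ig_shape, config.ig_rate, rng)

        snp_latent = draw_augmented(gibbs_data.snp_lo, gibbs_data.snp_hi, rng)
        p_mat = gibbs_data.traits.copy()
        if is_ord.any():
            p_mat[:, is_ord] = draw_augmented(
                gibbs_data.trait_lo[:, is_ord], gibbs_data.trait_hi[:, is_ord], rng)
        eta = rng.standard_normal((n, model.n_latent))

        for it in range(config.length):
            # 1. augmented data, independent of current parameters
            snp_latent = draw_augmented(gibbs_data.snp_lo, gibbs_data.snp_hi, rng)
            if is_ord.any():
                p_mat[:, is_ord] = draw_augmented(
                    gibbs_data.trait_lo[:, is_ord],
                    gibbs_data.trait_hi[:, is_ord], rng)
            g_tilde = snp_latent[:, :ng]
            y_tilde = snp_latent[:, ng:]

            # 2. latent factors
            p_resid = p_mat - y_tilde @ state.K.T
            eta = draw_eta(p_resid, g_tilde, state, rng)

            # 3. factor error variances
            eps = eta @ (np.eye(model.n_latent) - state.B).T - g_tilde @ state.Pi.T
            state.theta_eps[:] = draw_variances(
                (eps ** 2).sum(axis=0), n, config.ig_shape, config.ig_rate, rng)

            # 4. [B, Pi] rows
            for j, b_idx, pi_idx, fb, fpi in struct_rows:
                k = b_idx.size + pi_idx.size
                if k == 0:
                    continue
                X = np.hstack([eta[:, b_idx], g_tilde[:, pi_idx]])
                offset = eta[:, fb] @ state.B[j, fb] + g_tilde[:, fpi] @ state.Pi[j, fpi]
                r = eta[:, j] - offset
                pm = np.concatenate([prior.B[j, b_idx], prior.Pi[j, pi_idx]])
                beta = draw_coefficient_row(X, r, state.theta_eps[j], pm,
                                            config.coef_prior_sd, rng)
                state.B[j, b_idx] = beta[:b_idx.size]
                state.Pi[j, pi_idx] = beta[b_idx.size:]

            # 5. trait error variances
            delta = p_mat - eta @ state.Lambda.T - y_tilde @ state.K.T
            state.theta_delta[:] = draw_variances(
                (delta ** 2).sum(axis=0), n, config.ig_shape, config.ig_rate, rng)

            # 6. [Lambda, K] rows
            for i, l_idx, k_idx, fl, fk in meas_rows:
                k = l_idx.size + k_idx.size
                if k == 0:
                    continue
                X = np.hstack([eta[:, l_idx], y_tilde[:, k_idx]])
                offset = eta[:, fl] @ state.Lambda[i, fl] + y_tilde[:, fk] @ state.K[i, fk]
                r = p_mat[:, i] - offset
                pm = np.concatenate([prior.Lambda[i, l_idx], prior.K[i, k_idx]])
                beta = draw_coefficient_row(X, r, state.theta_delta[i], pm,
                                            config.coef_prior_sd, rng)
                state.Lambda[i, l_idx] = beta[:l_idx.size]
                state.K[i, k_idx] = beta[l_idx.size:]

            if it >= config.burn_in:
                chains[c, it - config.burn_in] = _extract(state, masks)
                if eta_store is not None:
                    eta_store[c, it - config.burn_in] = eta

    return PosteriorSamples(param_names=names, chains=chains,
                            burn_in=config.burn_in, length=config.length,
                            seeds=[int(s.generate_state(1)[0]) for s in child_seeds],
                            eta_chains=eta_store)


# -- diagnostics -------------------------------------------------------------

def gelman_rubin(samples) -> np.ndarray:
    """Potential scale reduction factor per parameter from >= 2 equal-length chains."""
    chains = samples.chains if isinstance(samples, PosteriorSamples) else np.asarray(samples)
    if chains.ndim == 2:
        chains = chains[:, :, None]
    m, L, _ = chains.shape
    if m < 2:
        raise ValueError("Gelman-Rubin needs at least 2 chains")
    means = chains.mean(axis=1)                      # (m, P)
    W = chains.var(axis=1, ddof=1).mean(axis=0)      # (P,)
    B_over_n = means.var(axis=0, ddof=1)
    var_plus = (L - 1) / L * W + B_over_n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_plus / W)
    return np.where(W > 0, rhat, np.inf)


def _chain_autocorr(x: np.ndarray) -> np.ndarray:
    n = x.size
    xc = x - x.mean()
    f = np.fft.rfft(xc, 2 * n)
    acov = np.fft.irfft(f * np.conj(f))[:n] / n
    if acov[0] <= 0:
        return np.zeros(n)
    return acov / acov[0]


def effective_sample_size(samples) -> np.ndarray:
    """Autocorrelation-based ESS (Geyer initial monotone positive sequence),
    summed over chains. Constant chains report 0."""
    chains = samples.chains if isinstance(samples, PosteriorSamples) else np.asarray(samples)
    if chains.ndim == 1:
        chains = chains[None, :, None]
    elif chains.ndim == 2:
        chains = chains[:, :, None]
    m, L, P = chains.shape
    ess = np.empty(P)
    for p in range(P):
        total = 0.0
        for c in range(m):
            x = chains[c, :, p]
            if x.std() == 0:
                continue
            rho = _chain_autocorr(x)
            # Geyer: sum consecutive pairs while positive, enforce monotone decay
            pair_sums = []
            for t in range(1, L - 1, 2):
                s = rho[t] + rho[t + 1]
                if s <= 0:
                    break
                pair_sums.append(s)
            mono = np.minimum.accumulate(pair_sums) if pair_sums else []
            tau = 1.0 + 2.0 * float(np.sum(mono))
            total += L / max(tau, 1e-12)
        ess[p] = min(total, m * L)
    return ess


def posterior_summary(samples: PosteriorSamples) -> pd.DataFrame:
    """Pooled posterior mean, sd and 5%/95% quantiles per parameter."""
    pooled = samples.pooled()
    return pd.DataFrame({
        "mean": pooled.mean(axis=0),
        "sd": pooled.std(axis=0, ddof=1) if pooled.shape[0] > 1
        else np.zeros(pooled.shape[1]),
        "q05": np.quantile(pooled, 0.05, axis=0),
        "q95": np.quantile(pooled, 0.95, axis=0),
    }, index=samples.param_names)


def estimates_to_model(model: ModelSpec, summary: pd.DataFrame) -> ModelSpec:
    """Write posterior means back into a copy of the model."""
    out = model.copy()
    masks = sampled_masks(model)
    values = summary["mean"].to_numpy()
    k = 0
    for m in ("B", "Lambda", "Pi", "K", "theta_eps", "theta_delta"):
        mask = masks[m]
        cnt = int(mask.sum())
        getattr(out, m)[mask] = values[k:k + cnt]
        k += cnt
    return out


def diagnostics_report(samples: PosteriorSamples) -> pd.DataFrame:
    return pd.DataFrame({
        "rhat": gelman_rubin(samples),
        "ess": effective_sample_size(samples),
    }, index=samples.param_names)
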