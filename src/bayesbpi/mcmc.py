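"""Gibbs / Metropolis-Hastings samplers for Bayesian whole-genome regression.

The marker model is

    y = 1*mu + sum_j w_j g_j + e,        e ~ N(0, I sigma_e^2),

with g_j | sigma_gj^2 ~ N(0, sigma_gj^2).  The marker-variance prior is the
scaled inverse chi-squared x^-2(v, S) (a draw is S / chi2_v), with
v = 4.234 and S = 0.0429 by default; the residual variance carries the
non-informative x^-2(-2, 0) prior, so its full conditional is
x^-2(n - 2, e'e).

Three samplers share the sweep structure:

* BayesA — every marker variance is resampled each sweep from its conjugate
  full conditional x^-2(v + 1, S + g_j^2).
* BayesB — a point mass at sigma_gj^2 = 0 with prior probability pi is added.
  Because the conjugate update can never reach 0 once g_j != 0, variance and
  effect are updated jointly by a short Metropolis-Hastings run per locus:
  each cycle a uniform gate decides (with probability 1 - pi) whether a
  fresh variance is proposed from x^-2(v, S) or zero is proposed, and the
  proposal is accepted by the marginal-likelihood ratio with g_j integrated
  out.  pi is a single constant (0.95 by default).
* BayesB-pi — identical machinery, but pi is a per-marker vector, typically
  derived from single-marker ANOVA p-values (see :mod:`bayesbpi.anova`), so
  markers in strong marginal association are proposed into the model far
  more often than the genome-wide background.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

__all__ = [
    "PriorSpec",
    "ChainConfig",
    "SamplerState",
    "PosteriorSummary",
    "sample_marker_variance",
    "sample_residual_variance",
    "sample_overall_mean",
    "sample_marker_effect",
    "mh_update_locus",
    "run_mcmc",
    "predict_gebv",
    "effective_sample_size",
]

#: default marker-variance prior degrees of freedom and scale
V_MARKER_DEFAULT = 4.234
S_MARKER_DEFAULT = 0.0429


@dataclasses.dataclass
class PriorSpec:
    """Hyperparameters of the marker and residual variance priors.

    pi is the prior probability that a marker has no effect: a scalar for
    BayesB (default 0.95) or a length-m vector for BayesB-pi.
    """

    v_marker: float = V_MARKER_DEFAULT
    S_marker: float = S_MARKER_DEFAULT
    v_resid: float = -2.0
    S_resid: float = 0.0
    pi: float | np.ndarray = 0.95

    def __post_init__(self) -> None:
        if self.S_marker <= 0:
            raise ValueError("S_marker must be positive")
        pi = np.asarray(self.pi, dtype=float)
        if np.any(pi < 0) or np.any(pi > 1):
            raise ValueError("pi must lie in [0, 1]")

    def pi_vector(self, m: int) -> np.ndarray:
        pi = np.asarray(self.pi, dtype=float)
        if pi.ndim == 0:
            return np.full(m, float(pi))
        if pi.shape != (m,):
            raise ValueError(f"pi vector length {pi.shape} does not match m={m}")
        return pi


@dataclasses.dataclass
class ChainConfig:
    """MCMC run lengths.  Defaults: 10,000 sweeps, 2,000 burn-in, 100 inner
    Metropolis-Hastings cycles per locus per sweep."""

    n_iterations: int = 10_000
    burn_in: int = 2_000
    mh_cycles: int = 100
    seed: int = 0
    thinning: int = 1
    gate_mode: str = "propose_zero"  # or "skip": closed gate leaves the variance untouched

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iterations:
            raise ValueError("burn_in must be < n_iterations")
        if self.mh_cycles < 1:
            raise ValueError("mh_cycles must be >= 1")
        if self.gate_mode not in ("propose_zero", "skip"):
            raise ValueError("gate_mode must be 'propose_zero' or 'skip'")


@dataclasses.dataclass
class SamplerState:
    mu: float
    g: np.ndarray
    sigma2_g: np.ndarray
    sigma2_e: float
    e: np.ndarray


@dataclasses.dataclass
class PosteriorSummary:
    """Post-burn-in posterior means; inclusion_freq[j] is the fraction of
    retained sweeps in which marker j was in the model (sigma_gj^2 > 0)."""

    effect_means: np.ndarray
    inclusion_freq: np.ndarray
    mu_mean: float
    sigma2_e_mean: float
    n_samples: int
    marker_ids: list[str] | None = None
    seed: int | None = None
    method: str | None = None
    sigma2_e_trace: np.ndarray | None = None
    effect_trace: np.ndarray | None = None


def sample_marker_variance(
    g_j: float, n_j: int, prior: PriorSpec, rng: np.random.Generator
) -> float:
    """Conjugate draw from x^-2(v + n_j, S + g_j'g_j)."""
    df = prior.v_marker + n_j
    scale = prior.S_marker + g_j * g_j
    return scale / rng.chisquare(df)


def sample_residual_variance(e: np.ndarray, rng: np.random.Generator) -> float:
    """Draw sigma_e^2 from x^-2(n - 2, e'e)."""
    n = e.shape[0]
    if n <= 2:
        raise ValueError("need more than 2 observations for the residual update")
    ete = float(e @ e)
    return ete / rng.chisquare(n - 2)


def sample_overall_mean(
    y: np.ndarray, W: np.ndarray, g: np.ndarray, sigma2_e: float, rng: np.random.Generator
) -> float:
    """Draw mu from N((1'y - 1'Wg)/n, sigma_e^2 / n)."""
    n = y.shape[0]
    center = float(np.sum(y) - np.sum(W @ g)) / n
    if sigma2_e == 0:
        return center
    return rng.normal(center, math.sqrt(sigma2_e / n))


def sample_marker_effect(
    j: int, state: SamplerState, W: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> float:
    """Conjugate normal draw for g_j given its variance (must be > 0).

    The conditional is N(r / (c + lam), sigma_e^2 / (c + lam)) with
    c = w_j'w_j, lam = sigma_e^2 / sigma_gj^2 and r the inner product of w_j
    with the data adjusted for everything except locus j.  Updates the state
    residuals consistently.
    """
    if state.sigma2_g[j] <= 0:
        raise ValueError("sample_marker_effect called with sigma2_g[j] = 0")
    w = W[:, j]
    y_adj = state.e + w * state.g[j]
    c = float(w @ w)
    r = float(w @ y_adj)
    lam = state.sigma2_e / state.sigma2_g[j]
    mean = r / (c + lam)
    sd = math.sqrt(state.sigma2_e / (c + lam))
    g_new = rng.normal(mean, sd)
    state.e = y_adj - w * g_new
    state.g[j] = g_new
    return g_new


def _locus_loglik(sigma2: float, c: float, r: float, sigma2_e: float) -> float:
    """Log marginal likelihood of the locus-adjusted data under
    y_adj ~ N(0, sigma2 w w' + sigma_e^2 I), up to terms constant in sigma2
    (rank-one determinant and Sherman-Morrison identities)."""
    if sigma2 == 0.0:
        return 0.0
    t = sigma2 * c
    return -0.5 * math.log1p(t / sigma2_e) + 0.5 * sigma2 * r * r / (
        sigma2_e * (sigma2_e + t)
    )


def mh_update_locus(
    j: int,
    state: SamplerState,
    W: np.ndarray,
    prior: PriorSpec,
    mh_cycles: int,
    rng: np.random.Generator,
    pi_j: float | None = None,
    gate_mode: str = "propose_zero",
) -> tuple[float, float]:
    """Joint Metropolis-Hastings update of (sigma_gj^2, g_j) for one locus.

    Per cycle a uniform gate alpha is drawn: if alpha < 1 - pi_j a fresh
    variance is proposed from the slab x^-2(v, S), otherwise the spike
    (sigma2 = 0) is proposed (gate_mode='propose_zero'; with 'skip' the
    cycle leaves the variance untouched).  Because the proposal equals the
    mixture prior, the acceptance probability reduces to the marginal
    likelihood ratio with g_j integrated out.  After the cycles, g_j is
    redrawn from its conditional if the variance is positive, else set to 0.
    """
    if pi_j is None:
        pi_j = float(np.asarray(prior.pi).ravel()[0])
    w = W[:, j]
    y_adj = state.e + w * state.g[j]
    c = float(w @ w)
    r = float(w @ y_adj)
    s2e = state.sigma2_e

    sigma2 = float(state.sigma2_g[j])
    ll_old = _locus_loglik(sigma2, c, r, s2e)
    gate = rng.random(mh_cycles)
    slabs = prior.S_marker / rng.chisquare(prior.v_marker, mh_cycles)
    accept_u = rng.random(mh_cycles)
    open_thresh = 1.0 - pi_j
    for t in range(mh_cycles):
        if gate[t] < open_thresh:
            prop = slabs[t]
        elif gate_mode == "skip":
            continue
        else:
            prop = 0.0
        ll_new = _locus_loglik(prop, c, r, s2e)
        if ll_new >= ll_old or accept_u[t] < math.exp(ll_new - ll_old):
            sigma2 = prop
            ll_old = ll_new

    state.sigma2_g[j] = sigma2
    if sigma2 > 0:
        lam = s2e / sigma2
        mean = r / (c + lam)
        sd = math.sqrt(s2e / (c + lam))
        g_new = rng.normal(mean, sd)
    else:
        g_new = 0.0
    state.e = y_adj - w * g_new
    state.g[j] = g_new
    return sigma2, g_new


def run_mcmc(
    y: np.ndarray,
    W: np.ndarray,
    prior: PriorSpec | None = None,
    config: ChainConfig | None = None,
    method: str = "bayesBpi",
    marker_ids: list[str] | None = None,
    fix_sigma2_e: float | None = None,
    fix_sigma2_g: float | None = None,
    locus_keys: np.ndarray | None = None,
    store_trace: bool = False,
    return_state: bool = False,
) -> PosteriorSummary | tuple[PosteriorSummary, SamplerState]:
    """Run the full Gibbs/MH chain and average post-burn-in samples.

    Parameters
    ----------
    y : response vector (typically standardized).
    W : n x m genotype design, centered by twice the training allele
        frequencies (a raw 0/1/2 design is also valid; only the
        interpretation of mu changes).
    method : 'bayesA', 'bayesB' (scalar pi) or 'bayesBpi' (vector pi).
    fix_sigma2_e, fix_sigma2_g : hold a variance fixed instead of sampling
        it (used by the conjugate-posterior oracle tests).
    locus_keys : optional per-locus stream keys; when given, each locus draws
        from its own counter-based substream and loci are visited in key
        order, making the chain invariant to marker permutation (with keys
        permuted alongside).
    store_trace : keep the sigma_e^2 trace for convergence/ESS inspection.
    """
    prior = prior or PriorSpec()
    config = config or ChainConfig()
    y = np.asarray(y, dtype=float).ravel()
    if np.isnan(y).any():
        raise ValueError("response contains NaN")
    W = np.asfortranarray(W, dtype=float)
    n, m = W.shape
    if y.shape[0] != n:
        raise ValueError(f"y length {y.shape[0]} does not match W rows {n}")
    if method not in ("bayesA", "bayesB", "bayesBpi"):
        raise ValueError(f"unknown method {method!r}")
    pi_vec = None
    if method in ("bayesB", "bayesBpi"):
        pi_vec = prior.pi_vector(m)
        if method == "bayesBpi" and np.asarray(prior.pi).ndim == 0:
            raise ValueError("bayesBpi requires a per-marker pi vector")

    rng = np.random.default_rng(config.seed)
    wtw = np.einsum("ij,ij->j", W, W)
    if locus_keys is not None:
        locus_keys = np.asarray(locus_keys)
        if locus_keys.shape != (m,):
            raise ValueError("locus_keys length must equal m")
        order = np.argsort(locus_keys, kind="stable")
        locus_rngs = [
            np.random.default_rng(np.random.Philox(key=(config.seed << 20) + int(k)))
            for k in locus_keys
        ]
    else:
        order = np.arange(m)
        locus_rngs = None

    # Step 1: initialize with small positive numbers
    state = SamplerState(
        mu=float(np.mean(y)),
        g=np.full(m, 0.01),
        sigma2_g=np.full(m, prior.S_marker / max(prior.v_marker - 2.0, 0.1)),
        sigma2_e=fix_sigma2_e
        if fix_sigma2_e is not None
        else max(float(np.var(y)) / 2.0, 1e-8),
        e=np.empty(n),
    )
    if fix_sigma2_g is not None:
        state.sigma2_g[:] = fix_sigma2_g
    state.e = y - state.mu - W @ state.g

    eff_sum = np.zeros(m)
    incl_sum = np.zeros(m)
    mu_sum = 0.0
    s2e_sum = 0.0
    n_samples = 0
    trace = [] if store_trace else None
    g_trace = [] if store_trace else None

    for sweep in range(config.n_iterations):
        if method == "bayesA":
            # Step 2: conjugate marker-variance updates
            if fix_sigma2_g is None:
                state.sigma2_g = (prior.S_marker + state.g**2) / rng.chisquare(
                    prior.v_marker + 1.0, m
                )
        elif locus_rngs is not None or fix_sigma2_g is not None:
            for j in order:
                r_j = locus_rngs[j] if locus_rngs is not None else rng
                if fix_sigma2_g is not None:
                    sample_marker_effect(j, state, W, y, r_j)
                else:
                    mh_update_locus(
                        j,
                        state,
                        W,
                        prior,
                        config.mh_cycles,
                        r_j,
                        pi_j=float(pi_vec[j]),
                        gate_mode=config.gate_mode,
                    )
        else:
            _sweep_mh(state, W, wtw, prior, config, pi_vec, rng)
        # Step 3: residual variance
        if fix_sigma2_e is None:
            state.sigma2_e = sample_residual_variance(state.e, rng)
        # Step 4: overall mean (residuals shifted consistently)
        center = state.mu + float(np.mean(state.e))
        mu_new = (
            center
            if state.sigma2_e == 0
            else rng.normal(center, math.sqrt(state.sigma2_e / n))
        )
        state.e -= mu_new - state.mu
        state.mu = mu_new
        # Step 5: marker effects (BayesA; BayesB folds this into the MH pass)
        if method == "bayesA":
            for j in order:
                r_j = locus_rngs[j] if locus_rngs is not None else rng
                sample_marker_effect(j, state, W, y, r_j)

        if sweep >= config.burn_in and (sweep - config.burn_in) % config.thinning == 0:
            eff_sum += state.g
            incl_sum += state.sigma2_g > 0
            mu_sum += state.mu
            s2e_sum += state.sigma2_e
            n_samples += 1
            if trace is not None:
                trace.append(state.sigma2_e)
                g_trace.append(state.g.copy())

    summary = PosteriorSummary(
        effect_means=eff_sum / n_samples,
        inclusion_freq=incl_sum / n_samples,
        mu_mean=mu_sum / n_samples,
        sigma2_e_mean=s2e_sum / n_samples,
        n_samples=n_samples,
        marker_ids=marker_ids,
        seed=config.seed,
        method=method,
        sigma2_e_trace=np.asarray(trace) if trace is not None else None,
        effect_trace=np.asarray(g_trace) if g_trace is not None else None,
    )
    if return_state:
        return summary, state
    return summary


def _sweep_mh(
    state: SamplerState,
    W: np.ndarray,
    wtw: np.ndarray,
    prior: PriorSpec,
    config: ChainConfig,
    pi_vec: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """One BayesB/BayesB-pi sweep over all loci.

    Algorithmically identical to calling :func:`mh_update_locus` per locus
    (same proposals, same acceptance rule), but the uniform/chi-squared
    draws for the whole sweep are generated in one batch and residuals are
    only touched for loci whose effect actually changes, which is the
    common-case saving since most loci stay excluded under pi near 1.
    """
    m = W.shape[1]
    mh = config.mh_cycles
    gate = rng.random((m, mh))
    slabs = prior.S_marker / rng.chisquare(prior.v_marker, (m, mh))
    accept_u = rng.random((m, mh))
    normals = rng.standard_normal(m)
    skip_mode = config.gate_mode == "skip"
    s2e = state.sigma2_e
    g = state.g
    sigma2_g = state.sigma2_g
    e = state.e
    for j in range(m):
        c = wtw[j]
        g_old = g[j]
        if g_old != 0.0:
            y_adj = e + W[:, j] * g_old
        else:
            y_adj = e
        r = float(W[:, j] @ y_adj)
        sigma2 = sigma2_g[j]
        ll_old = _locus_loglik(sigma2, c, r, s2e)
        open_thresh = 1.0 - pi_vec[j]
        gj, aj, sj = gate[j], accept_u[j], slabs[j]
        for t in range(mh):
            if gj[t] < open_thresh:
                prop = sj[t]
            elif skip_mode:
                continue
            else:
                prop = 0.0
            ll_new = _locus_loglik(prop, c, r, s2e)
            if ll_new >= ll_old or aj[t] < math.exp(ll_new - ll_old):
                sigma2 = prop
                ll_old = ll_new
        sigma2_g[j] = sigma2
        if sigma2 > 0.0:
            lam = s2e / sigma2
            g_new = r / (c + lam) + math.sqrt(s2e / (c + lam)) * normals[j]
            state.e = e = y_adj - W[:, j] * g_new
        else:
            g_new = 0.0
            if g_old != 0.0:
                state.e = e = y_adj
        g[j] = g_new


def predict_gebv(
    summary: PosteriorSummary, W_new: np.ndarray, mu_included: bool = False
) -> np.ndarray:
    """GEBV = W_new @ posterior-mean effects (+ mu if requested).

    W_new must be centered with the training-set allele frequencies.
    """
    W_new = np.asarray(W_new, dtype=float)
    if W_new.shape[1] != summary.effect_means.shape[0]:
        raise ValueError(
            f"marker count mismatch: {W_new.shape[1]} columns vs "
            f"{summary.effect_means.shape[0]} effects"
        )
    gebv = W_new @ summary.effect_means
    if mu_included:
        gebv = gebv + summary.mu_mean
    return gebv


def effective_sample_size(x: np.ndarray) -> float:
    """Initial-positive-sequence ESS of a scalar MCMC trace."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1 :] / (np.arange(n, 0, -1) * np.var(x))
    s = 0.0
    for k in range(1, n // 2):
        pair = acf[2 * k - 1] + acf[2 * k] if 2 * k < n else acf[2 * k - 1]
        if pair < 0:
            break
        s += pair
    return float(n / (1.0 + 2.0 * s))
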