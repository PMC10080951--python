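"""Simulators and fitters for the perimetric psychophysical procedures.

The frequency-of-seeing (FOS) curve is the Gaussian-CDF psychometric
function with guess and lapse asymptotes,

    p_seen(x) = gamma + (1 - gamma - lambda) * Phi((mu - x) / sigma)

on the perimetric dB axis (higher dB = dimmer stimulus, so p_seen is
decreasing).  On top of it sit:

* ZEST -- a yes/no Bayesian staircase: uniform prior on [0, 50] dB,
  Gaussian-CDF likelihood (SD 1 dB, 3% guess/lapse), next stimulus =
  posterior mean rounded to integer dB, stop at posterior SD < 1.5 dB.
* QUEST+ -- joint (mu, sigma) Bayesian estimation choosing the stimulus
  that minimises expected posterior entropy, stopping at entropy <= 4.5
  (natural log) on the joint grid.
* MOCS -- seven constant levels placed at fixed FOS quantiles with
  instrument constraints (>= 1 dB apart, extremes >= 10 dB from the
  50% threshold, 1 dB grid).
* A hierarchical Bayesian FOS fit (per-location mu and sigma partially
  pooled; global lapse/guess) sampled with emcee.
* The log-linear slope-threshold relation between sigma and mu
  (multiplicative response noise) and a synthetic observer that turns
  model-predicted sensitivities into FOS parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, ndtr, ndtri
from scipy.stats import linregress

__all__ = [
    "PsychometricParams",
    "ZESTConfig",
    "QuestPlusConfig",
    "TrialRecord",
    "p_seen",
    "zest_run",
    "questplus_run",
    "mocs_design",
    "FOSFit",
    "fit_fos_hierarchical",
    "slope_threshold_regression",
    "filter_responses",
    "synthetic_observer",
    "SLOPE_THRESHOLD_INTERCEPT",
    "SLOPE_THRESHOLD_SLOPE",
]

#: default log-linear slope-threshold relation: log10 sigma = a + b * mu(dB)
#: (multiplicative-noise relation of the Henson type; shallower FOS
#: slopes at lower sensitivity)
SLOPE_THRESHOLD_INTERCEPT = 1.42
SLOPE_THRESHOLD_SLOPE = -0.035


@dataclass(frozen=True)
class PsychometricParams:
    """FOS parameters: 50% threshold mu (dB), spread sigma (dB), rates."""

    mu: float
    sigma: float
    lapse_rate: float = 0.0
    guess_rate: float = 0.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        for name in ("lapse_rate", "guess_rate"):
            v = getattr(self, name)
            if not 0 <= v < 0.5:
                raise ValueError(f"{name} must be in [0, 0.5), got {v}")


def p_seen(x, p: PsychometricParams):
    """Probability of seeing a stimulus of x dB."""
    x = np.asarray(x, float)
    out = p.guess_rate + (1.0 - p.guess_rate - p.lapse_rate) * ndtr((p.mu - x) / p.sigma)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# ZEST
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ZESTConfig:
    """ZEST strategy settings (instrument defaults)."""

    domain_min: float = 0.0
    domain_max: float = 50.0
    grid_step: float = 0.1
    likelihood_sd: float = 1.0
    likelihood_rate: float = 0.03  # guess and lapse of the assumed FOS
    stop_sd: float = 1.5
    max_trials: int = 200

    def grid(self) -> np.ndarray:
        n = int(round((self.domain_max - self.domain_min) / self.grid_step)) + 1
        return self.domain_min + self.grid_step * np.arange(n)


def _likelihood_seen(grid: np.ndarray, stim: float, cfg: ZESTConfig) -> np.ndarray:
    """P(seen | threshold = grid, stimulus = stim) under the ZEST likelihood."""
    r = cfg.likelihood_rate
    return r + (1.0 - 2.0 * r) * ndtr((grid - stim) / cfg.likelihood_sd)


def zest_run(
    observer: PsychometricParams,
    cfg: ZESTConfig = ZESTConfig(),
    seed: int = 0,
) -> tuple[float, int, list[tuple[float, bool]]]:
    """Simulate one ZEST thread against a synthetic observer.

    Returns (threshold estimate = final posterior mean, number of
    trials, trace of (stimulus dB, seen) pairs).  A thread that fails to
    terminate within ``max_trials`` returns the current mean (runaway
    flagged by the trial count).
    """
    rng = np.random.default_rng(seed)
    grid = cfg.grid()
    post = np.full(grid.shape, 1.0 / len(grid))
    trace: list[tuple[float, bool]] = []
    for _ in range(cfg.max_trials):
        mean = float(post @ grid)
        sd = float(np.sqrt(post @ (grid - mean) ** 2))
        if sd < cfg.stop_sd and trace:
            break
        stim = float(np.clip(round(mean), cfg.domain_min, cfg.domain_max))
        seen = bool(rng.random() < p_seen(stim, observer))
        like = _likelihood_seen(grid, stim, cfg)
        post = post * (like if seen else 1.0 - like)
        post /= post.sum()
        trace.append((stim, seen))
    return float(post @ grid), len(trace), trace


# ---------------------------------------------------------------------------
# QUEST+
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuestPlusConfig:
    """Two-parameter (mu, sigma) QUEST+ settings."""

    mu_seed: float = 25.0       # centre of the Gaussian mu prior
    mu_prior_sd: float = 4.0
    mu_halfspan: float = 5.0    # prior domain: seed +/- halfspan
    mu_step: float = 0.1
    sigma_min: float = 1.0
    sigma_max: float = 10.0
    sigma_step: float = 0.5
    rate: float = 0.03          # fixed guess/lapse of the assumed FOS
    stop_entropy: float = 4.5   # natural-log entropy on the joint grid
    max_trials: int = 200

    def mu_grid(self) -> np.ndarray:
        n = int(round(2 * self.mu_halfspan / self.mu_step)) + 1
        return self.mu_seed - self.mu_halfspan + self.mu_step * np.arange(n)

    def sigma_grid(self) -> np.ndarray:
        n = int(round((self.sigma_max - self.sigma_min) / self.sigma_step)) + 1
        return self.sigma_min + self.sigma_step * np.arange(n)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def questplus_run(
    observer: PsychometricParams,
    cfg: QuestPlusConfig,
    seed: int = 0,
    return_state: bool = False,
):
    """Simulate a QUEST+ thread; returns (mu_hat, sigma_hat, n_trials).

    With ``return_state=True`` the final joint-posterior entropy is
    appended to the return tuple.

    The candidate stimulus minimising the expected posterior entropy is
    chosen at each trial (integer-dB candidates spanning the mu domain
    plus three maximal sigmas each side).
    """
    rng = np.random.default_rng(seed)
    mu = cfg.mu_grid()
    sg = cfg.sigma_grid()
    prior_mu = np.exp(-0.5 * ((mu - cfg.mu_seed) / cfg.mu_prior_sd) ** 2)
    post = prior_mu[:, None] * np.ones(len(sg))[None, :]
    post /= post.sum()
    lo = np.floor(mu.min() - 3 * sg.max())
    hi = np.ceil(mu.max() + 3 * sg.max())
    candidates = np.arange(max(0.0, lo), min(50.0, hi) + 0.5)
    # P(seen | mu, sigma, x) for all grid points and candidates
    pgrid = cfg.rate + (1.0 - 2.0 * cfg.rate) * ndtr(
        (mu[:, None, None] - candidates[None, None, :]) / sg[None, :, None]
    )
    n_trials = 0
    for _ in range(cfg.max_trials):
        if _entropy(post.ravel()) <= cfg.stop_entropy and n_trials > 0:
            break
        # expected entropy after each candidate stimulus
        p_yes = np.einsum("ms,msc->c", post, pgrid)
        h_yes = np.empty(len(candidates))
        h_no = np.empty(len(candidates))
        for ci in range(len(candidates)):
            py = post * pgrid[:, :, ci]
            pn = post - py
            sy, sn = py.sum(), pn.sum()
            h_yes[ci] = _entropy((py / sy).ravel()) if sy > 0 else 0.0
            h_no[ci] = _entropy((pn / sn).ravel()) if sn > 0 else 0.0
        expected = p_yes * h_yes + (1.0 - p_yes) * h_no
        ci = int(np.argmin(expected))
        stim = float(candidates[ci])
        seen = bool(rng.random() < p_seen(stim, observer))
        post = post * (pgrid[:, :, ci] if seen else 1.0 - pgrid[:, :, ci])
        post /= post.sum()
        n_trials += 1
    mu_hat = float((post.sum(axis=1) * mu).sum())
    sigma_hat = float((post.sum(axis=0) * sg).sum())
    if return_state:
        return mu_hat, sigma_hat, n_trials, _entropy(post.ravel())
    return mu_hat, sigma_hat, n_trials


# ---------------------------------------------------------------------------
# MOCS
# ---------------------------------------------------------------------------

MOCS_QUANTILES = (0.0001, 0.1, 0.3, 0.5, 0.7, 0.9, 0.9999)
MOCS_REPEATS = 25


def mocs_design(mu_hat: float, sigma_hat: float) -> np.ndarray:
    """Seven MOCS levels (dB) for an estimated FOS curve.

    Levels sit at the configured FOS quantiles, then instrument
    constraints are enforced: the two extremes at least 10 dB from the
    threshold, all levels at least 1 dB apart (inner levels spread
    outward minimally), and finally rounding to the 1 dB grid preserving
    order.
    """
    if not 1.0 <= sigma_hat <= 10.0:
        raise ValueError(f"sigma_hat must be within the prior range [1, 10], got {sigma_hat}")
    z = ndtri(np.array(MOCS_QUANTILES))
    levels = mu_hat + sigma_hat * z
    # extremes: at least 10 dB above and below the 50% threshold
    levels[0] = min(levels[0], mu_hat - 10.0)
    levels[-1] = max(levels[-1], mu_hat + 10.0)
    # enforce >= 1 dB spacing, spreading inner levels outward from the centre
    mid = len(levels) // 2
    for i in range(mid + 1, len(levels) - 1):
        levels[i] = max(levels[i], levels[i - 1] + 1.0)
    for i in range(mid - 1, 0, -1):
        levels[i] = min(levels[i], levels[i + 1] - 1.0)
    levels[-1] = max(levels[-1], levels[-2] + 1.0)
    levels[0] = min(levels[0], levels[1] - 1.0)
    out = np.round(levels)
    # rounding must not collapse neighbours
    for i in range(mid + 1, len(out)):
        out[i] = max(out[i], out[i - 1] + 1.0)
    for i in range(mid - 1, -1, -1):
        out[i] = min(out[i], out[i + 1] - 1.0)
    return out


# ---------------------------------------------------------------------------
# trial records and response filtering
# ---------------------------------------------------------------------------

@dataclass
class TrialRecord:
    """One stimulus presentation."""

    location: tuple[float, float]
    size_label: str
    duration_ms: float
    stimulus_db: float
    seen: bool
    onset_ms: float | None = None
    response_ms: float | None = None  # time from onset; None if no response
    valid: bool = True


MIN_RESPONSE_LATENCY_MS = 180.0


def filter_responses(records, pause_windows=()) -> list:
    """Flag false responses: within a pause or < 180 ms after onset.

    ``pause_windows`` are (start_ms, end_ms) absolute intervals; a
    response falling inside any of them is invalid, as is any response
    earlier than 180 ms after stimulus onset.
    """
    out = []
    for rec in records:
        valid = True
        if rec.response_ms is not None:
            if rec.response_ms < MIN_RESPONSE_LATENCY_MS:
                valid = False
            if rec.onset_ms is not None:
                t_abs = rec.onset_ms + rec.response_ms
                for a, b in pause_windows:
                    if a <= t_abs <= b:
                        valid = False
                        break
        out.append(replace_valid(rec, valid))
    return out


def replace_valid(rec: TrialRecord, valid: bool) -> TrialRecord:
    return replace(rec, valid=valid)


# ---------------------------------------------------------------------------
# hierarchical FOS fitting
# ---------------------------------------------------------------------------

@dataclass
class FOSFit:
    """Posterior summaries of a (hierarchical) FOS fit."""

    mu_mean: np.ndarray
    mu_sd: np.ndarray
    mu_ci: np.ndarray      # (n_loc, 2): 2.5 / 97.5 percentiles
    sigma_mean: np.ndarray
    sigma_sd: np.ndarray
    sigma_ci: np.ndarray
    lapse_mean: float
    guess_mean: float
    hierarchical: bool
    n_locations: int
    chain: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


def _log_beta_1_19(v):
    # Beta(1, 19) log density up to a constant: 18 * log(1 - v)
    v = np.minimum(v, 1.0 - 1e-12)
    return 18.0 * np.log1p(-v)


def fit_fos_hierarchical(
    stimulus_db: np.ndarray,
    seen: np.ndarray,
    location_idx: np.ndarray,
    n_locations: int,
    hierarchical: bool = True,
    n_walkers: int = 40,
    n_steps: int = 1500,
    n_burn: int = 500,
    seed: int = 0,
) -> FOSFit:
    """Bayesian FOS fit with partial pooling across locations.

    Model: mu_loc ~ N(mu_pop, s_mu); log sigma_loc ~ N(log sigma_pop,
    s_sigma); lapse, guess ~ Beta(1, 19), shared across locations.
    Sampled with the emcee affine-invariant ensemble sampler.  With
    ``hierarchical=False`` the population layer is replaced by wide
    fixed priors, giving independent per-location fits on the same data
    (for shrinkage comparisons).

    Locations where every response is identical are fit anyway but are
    prior-dominated; a warning is emitted.
    """
    import warnings

    import emcee

    x = np.asarray(stimulus_db, float)
    y = np.asarray(seen, bool).astype(float)
    li = np.asarray(location_idx, int)
    if not (len(x) == len(y) == len(li)):
        raise ValueError("stimulus_db, seen and location_idx must align")
    for loc in range(n_locations):
        yy = y[li == loc]
        if len(yy) == 0:
            raise ValueError(f"no trials for location {loc}")
        if yy.min() == yy.max():
            warnings.warn(f"location {loc}: all responses identical; prior-dominated fit")

    L = n_locations
    # theta = [mu_pop, log_s_mu, log_sigma_pop, log_s_sigma,
    #          mu_loc (L), log_sigma_loc (L), logit_lapse, logit_guess]
    ndim = 4 + 2 * L + 2

    def unpack(th):
        mu_pop, log_s_mu, log_sig_pop, log_s_sig = th[:4]
        mu_loc = th[4:4 + L]
        log_sig_loc = th[4 + L:4 + 2 * L]
        lapse = 0.5 * expit(th[-2])
        guess = 0.5 * expit(th[-1])
        return mu_pop, np.exp(log_s_mu), log_sig_pop, np.exp(log_s_sig), \
            mu_loc, np.exp(log_sig_loc), lapse, guess

    def log_prob(th):
        mu_pop, s_mu, log_sig_pop, s_sig, mu_loc, sig_loc, lapse, guess = unpack(th)
        if np.any(sig_loc < 0.05) or np.any(sig_loc > 50):
            return -np.inf
        lp = 0.0
        if hierarchical:
            lp += -0.5 * ((mu_pop - 25.0) / 20.0) ** 2
            lp += -0.5 * (s_mu / 5.0) ** 2 + np.log(s_mu)      # HalfNormal(5), log-param jacobian
            lp += -0.5 * ((log_sig_pop - np.log(3.0)) / 1.0) ** 2
            lp += -0.5 * (s_sig / 1.0) ** 2 + np.log(s_sig)    # HalfNormal(1)
            lp += np.sum(-0.5 * ((mu_loc - mu_pop) / s_mu) ** 2 - np.log(s_mu))
            lp += np.sum(-0.5 * ((np.log(sig_loc) - log_sig_pop) / s_sig) ** 2 - np.log(s_sig))
        else:
            # wide independent priors; hyperparameters pinned by pseudo-priors
            lp += -0.5 * (mu_pop / 50.0) ** 2 - 0.5 * (np.log(s_mu)) ** 2
            lp += -0.5 * (log_sig_pop) ** 2 - 0.5 * (np.log(s_sig)) ** 2
            lp += np.sum(-0.5 * ((mu_loc - 25.0) / 20.0) ** 2)
            lp += np.sum(-0.5 * ((np.log(sig_loc) - np.log(3.0)) / 1.5) ** 2)
        lp += _log_beta_1_19(lapse / 0.5) + _log_beta_1_19(guess / 0.5)
        p = guess + (1.0 - guess - lapse) * ndtr((mu_loc[li] - x) / sig_loc[li])
        p = np.clip(p, 1e-9, 1.0 - 1e-9)
        lp += float(y @ np.log(p) + (1.0 - y) @ np.log1p(-p))
        return lp

    rng = np.random.default_rng(seed)
    # crude per-location starting values from the empirical FOS
    mu0 = np.empty(L)
    for loc in range(L):
        xx, yy = x[li == loc], y[li == loc]
        # levels straddling the transition get seen-rates near 0.5; the
        # seen-weighted mean of levels is a serviceable threshold start
        mu0[loc] = float(np.average(xx, weights=yy + 0.1)) if yy.any() else float(xx.mean())
    center = np.concatenate([
        [mu0.mean(), np.log(2.0), np.log(3.0), np.log(0.5)],
        mu0, np.full(L, np.log(3.0)), [-3.0, -3.0],
    ])
    p0 = center[None, :] + 0.1 * rng.standard_normal((n_walkers, ndim))
    sampler = emcee.EnsembleSampler(n_walkers, ndim, log_prob)
    # the ensemble moves draw from the sampler's own RandomState; seed it
    # so identical data + seed give identical posteriors
    sampler.random_state = np.random.RandomState(seed).get_state()
    sampler.run_mcmc(p0, n_steps, progress=False)
    chain = sampler.get_chain(discard=n_burn, flat=True)
    mu_s = chain[:, 4:4 + L]
    sig_s = np.exp(chain[:, 4 + L:4 + 2 * L])
    lapse_s = 0.5 * expit(chain[:, -2])
    guess_s = 0.5 * expit(chain[:, -1])
    return FOSFit(
        mu_mean=mu_s.mean(axis=0),
        mu_sd=mu_s.std(axis=0),
        mu_ci=np.percentile(mu_s, [2.5, 97.5], axis=0).T,
        sigma_mean=sig_s.mean(axis=0),
        sigma_sd=sig_s.std(axis=0),
        sigma_ci=np.percentile(sig_s, [2.5, 97.5], axis=0).T,
        lapse_mean=float(lapse_s.mean()),
        guess_mean=float(guess_s.mean()),
        hierarchical=hierarchical,
        n_locations=L,
        chain=chain,
    )


# ---------------------------------------------------------------------------
# slope-threshold relation and synthetic observers
# ---------------------------------------------------------------------------

def slope_threshold_regression(mus, sigmas):
    """OLS of log10(sigma) on mu (dB): returns (slope, intercept, p_value).

    A negative slope means shallower FOS curves (larger sigma) at lower
    sensitivity -- the signature of multiplicative response noise.
    """
    mus = np.asarray(mus, float)
    sigmas = np.asarray(sigmas, float)
    if len(mus) < 4:
        raise ValueError("need at least 4 (mu, sigma) points")
    if np.ptp(mus) == 0:
        raise ValueError("degenerate input: all thresholds identical")
    y = np.log10(sigmas)
    if np.ptp(y) == 0:
        # constant sigma: zero slope, no evidence against it
        return 0.0, float(y[0]), 1.0
    res = linregress(mus, y)
    return float(res.slope), float(res.intercept), float(res.pvalue)


def synthetic_observer(
    params,
    context,
    diameter: float,
    duration_ms: float,
    slope: float = SLOPE_THRESHOLD_SLOPE,
    intercept: float = SLOPE_THRESHOLD_INTERCEPT,
    lapse_rate: float = 0.01,
    guess_rate: float = 0.01,
    noise_sd_db: float = 0.0,
    seed: int = 0,
) -> PsychometricParams:
    """FOS parameters of a model-consistent synthetic observer.

    mu is the model-predicted sensitivity in dB (optionally perturbed by
    Gaussian test-retest noise); sigma follows the log-linear
    slope-threshold relation, clipped to the plausible [0.5, 10] dB
    range.
    """
    from .summation import predicted_dls

    area = np.pi * (diameter / 2.0) ** 2
    s = context.area_to_input(area)
    mu = 10.0 * predicted_dls(s, duration_ms, params)
    if noise_sd_db > 0:
        mu += np.random.default_rng(seed).normal(0.0, noise_sd_db)
    sigma = float(np.clip(10.0 ** (intercept + slope * mu), 0.5, 10.0))
    return PsychometricParams(mu=float(mu), sigma=sigma,
                              lapse_rate=lapse_rate, guess_rate=guess_rate)
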