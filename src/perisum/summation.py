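"""Spatiotemporal summation: the capacitor pooler and its fitting machinery.

The total spatial input S (sum of DoG-pooled, convergence-weighted RGC
responses at unit Weber contrast) is integrated over time by a single
leaky ("capacitor") stage whose time constant shrinks with the input::

    h(t) = (S / tau) * exp(-t * S / tau)        (unit area)
    r(t) = (f * h)(t),  f = unit step of duration T
    R    = [ integral r(t)^k dt ]^(1/k) * S^(1/k)

with k the summation exponent (4 here) and tau the integration
constant (input units x ms).  Everything depends on S and T only through
the normalised input  x = S*T/tau, and the closed form is

    R = (tau * g(x))^(1/k),
    g(x) = integral_0^x (1 - e^-u)^k du + (1 - e^-x)^k / k.

Predicted differential light sensitivity (DLS, dB/10) is
``log10(R) + Offset``.  Small/short stimuli give complete summation
(log-log slope 1 in both S and T: Ricco / Bloch); large/long stimuli
give partial summation with slope 1/k (Piper-like).  The critical point
(Ricco's area, critical duration) is where the slope crosses 0.5, at a
fixed normalised input x_c that solves

    x (1 - e^-x)^(k-1) = (k/2) g(x).

Fitting minimises the RMSE (in dB) over (log10 tau, Offset) by
Nelder-Mead with multiple starts, mirroring common practice for
summation-curve fits.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import comb

import numpy as np
from scipy import optimize
from scipy.integrate import quad
from scipy.signal import fftconvolve

__all__ = [
    "SpatiotemporalParams",
    "SummationResult",
    "CriticalPoint",
    "g_of_x",
    "pooled_response",
    "pooled_response_numeric",
    "predicted_dls",
    "critical_normalized_input",
    "critical_input",
    "critical_duration",
    "ricco_area",
    "summation_curve",
    "db_to_dls",
    "dls_to_db",
    "dls_to_weber",
    "weber_to_dls",
    "convert_sensitivity",
    "SpatiotemporalSummationModel",
    "SummationFitResults",
]

#: maximum stimulus luminance over the 10 cd/m^2 background: 3185/10
MAX_WEBER_CONTRAST = 318.5


# ---------------------------------------------------------------------------
# sensitivity unit conversions
# ---------------------------------------------------------------------------

def db_to_dls(db):
    """Perimetric dB (attenuation re 3,185 cd/m^2) -> DLS (dB/10)."""
    return np.asarray(db, float) / 10.0 if np.ndim(db) else float(db) / 10.0


def dls_to_db(dls):
    return np.asarray(dls, float) * 10.0 if np.ndim(dls) else float(dls) * 10.0


def dls_to_weber(dls):
    """DLS -> Weber contrast of the threshold stimulus."""
    return MAX_WEBER_CONTRAST * 10.0 ** (-np.asarray(dls, float))


def weber_to_dls(wc):
    wc = np.asarray(wc, float)
    if np.any(wc <= 0):
        raise ValueError("Weber contrast must be positive")
    return np.log10(MAX_WEBER_CONTRAST / wc)


def convert_sensitivity(value, frm: str, to: str):
    """Convert between 'db', 'dls' and 'weber' sensitivity scales."""
    frm, to = frm.lower(), to.lower()
    to_dls = {"db": db_to_dls, "dls": lambda v: np.asarray(v, float), "weber": weber_to_dls}
    from_dls = {"db": dls_to_db, "dls": lambda v: v, "weber": dls_to_weber}
    if frm not in to_dls or to not in from_dls:
        raise ValueError(f"unknown sensitivity scale: {frm!r} or {to!r}")
    out = from_dls[to](to_dls[frm](value))
    return out if np.ndim(out) else float(out)


# ---------------------------------------------------------------------------
# the pooler
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpatiotemporalParams:
    """Integration constant tau (input x ms), exponent k, log-DLS offset."""

    tau: float
    k: float = 4.0
    offset: float = 0.0

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.k < 1:
            raise ValueError("summation exponent k must be >= 1")


@dataclass(frozen=True)
class SummationResult:
    """Pooled response of one (S, T) condition."""

    S: float
    T: float
    x: float            # normalised input S*T/tau
    time_constant: float  # tau/S, ms
    R: float
    dls_pred: float


@dataclass(frozen=True)
class CriticalPoint:
    """Slope-0.5 transition: critical input / duration and Ricco's area."""

    x_c: float
    S_c: float
    T_c: float
    ricco_area: float | None = None


def g_of_x(x, k: float = 4.0):
    """g(x) = int_0^x (1-e^-u)^k du + (1-e^-x)^k / k.

    Closed form (binomial expansion) for integer k, adaptive quadrature
    otherwise.  Vectorised over x.
    """
    x = np.asarray(x, float)
    if np.any(x < 0):
        raise ValueError("x must be non-negative")
    if float(k).is_integer():
        ki = int(k)
        out = x.astype(float).copy()
        for j in range(1, ki + 1):
            out += comb(ki, j) * (-1.0) ** j * (1.0 - np.exp(-j * x)) / j
        out += (1.0 - np.exp(-x)) ** ki / ki
        # the binomial sum cancels catastrophically when x^k << 1;
        # switch to Gauss-Legendre quadrature of the smooth integrand there
        small = x < 0.05
        if np.any(small):
            xs = np.atleast_1d(x)[np.atleast_1d(small)]
            nodes, weights = np.polynomial.legendre.leggauss(24)
            u = 0.5 * xs[:, None] * (nodes[None, :] + 1.0)
            integ = ((-np.expm1(-u)) ** ki * weights[None, :]).sum(axis=1) * 0.5 * xs
            vals = integ + (-np.expm1(-xs)) ** ki / ki
            if out.ndim:
                out[small] = vals
            else:
                out = vals[0]
    else:
        def one(xx):
            v, _ = quad(lambda u: (1.0 - np.exp(-u)) ** k, 0.0, xx, limit=200)
            return v + (1.0 - np.exp(-xx)) ** k / k
        out = np.vectorize(one)(x)
    return out if out.ndim else float(out)


def pooled_response(S, T, params: SpatiotemporalParams) -> SummationResult:
    """Closed-form pooled response for input S held on for T ms."""
    S, T = float(S), float(T)
    if S <= 0 or T <= 0:
        raise ValueError("S and T must be positive")
    x = S * T / params.tau
    R = (params.tau * g_of_x(x, params.k)) ** (1.0 / params.k)
    return SummationResult(
        S=S, T=T, x=x, time_constant=params.tau / S, R=R,
        dls_pred=np.log10(R) + params.offset,
    )


def pooled_response_numeric(
    S: float, T: float, params: SpatiotemporalParams, n_per_scale: int = 800
) -> float:
    """Numerical-convolution route to R (oracle for the closed form).

    Samples the step f and the capacitor kernel h at midpoints of a grid
    resolving both T and the kernel time constant tau/S, convolves, and
    integrates r^k out to where the integrand is negligible.
    """
    if S <= 0 or T <= 0:
        raise ValueError("S and T must be positive")
    tc = params.tau / S
    dt = min(T, tc) / n_per_scale
    t_tail = 14.0 / params.k * tc  # r^k ~ exp(-k t/tc) after offset
    n = int(np.ceil((T + t_tail) / dt))
    t = (np.arange(n) + 0.5) * dt
    f = (t < T).astype(float)
    h = np.exp(-t / tc) / tc
    r = fftconvolve(f, h)[:n] * dt
    integral = float(np.sum(r ** params.k) * dt)
    return (integral ** (1.0 / params.k)) * S ** (1.0 / params.k)


def predicted_dls(S, T, params: SpatiotemporalParams):
    """Predicted DLS (dB/10) = log10 R + Offset; vectorised over S, T."""
    S = np.asarray(S, float)
    T = np.asarray(T, float)
    if np.any(S <= 0) or np.any(T <= 0):
        raise ValueError("S and T must be positive")
    x = S * T / params.tau
    R = (params.tau * g_of_x(x, params.k)) ** (1.0 / params.k)
    out = np.log10(R) + params.offset
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# critical point (Ricco / Bloch transition)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=32)
def critical_normalized_input(k: float = 4.0) -> float:
    """x_c solving x (1-e^-x)^(k-1) = (k/2) g(x); exists only for k > 2.

    The log-log slope of R against S (or T) is
    x g'(x) / (k g(x)) with g'(x) = (1-e^-x)^(k-1); it falls from 1 to
    1/k, so it crosses 0.5 only when 1/k < 0.5.
    """
    k = float(k)
    if k <= 2.0:
        raise ValueError(
            f"slope-0.5 criterion undefined for k <= 2 (asymptotic slope 1/k >= 0.5); got k={k}"
        )

    def phi(x):
        return x * (1.0 - np.exp(-x)) ** (k - 1.0) - (k / 2.0) * g_of_x(x, k)

    hi = 50.0
    while phi(hi) > 0:
        hi *= 4.0
        if hi > 1e6:
            raise ValueError(f"no slope-0.5 crossing found for k={k}")
    return float(optimize.brentq(phi, 0.1, hi, xtol=1e-9))


def summation_slope(x, k: float = 4.0):
    """d log10 R / d log10 S at fixed T (equals the slope in T at fixed S)."""
    x = np.asarray(x, float)
    out = x * (1.0 - np.exp(-x)) ** (k - 1.0) / (k * g_of_x(x, k))
    return out if out.ndim else float(out)


def critical_input(params: SpatiotemporalParams, T: float) -> CriticalPoint:
    """Critical total input S_c at duration T (slope-0.5 criterion)."""
    if T <= 0:
        raise ValueError("T must be positive")
    x_c = critical_normalized_input(params.k)
    S_c = x_c * params.tau / T
    return CriticalPoint(x_c=x_c, S_c=S_c, T_c=x_c * params.tau / S_c)


def critical_duration(params: SpatiotemporalParams, S: float) -> CriticalPoint:
    """Critical duration T_c (ms) for a fixed total input S."""
    if S <= 0:
        raise ValueError("S must be positive")
    x_c = critical_normalized_input(params.k)
    return CriticalPoint(x_c=x_c, S_c=S, T_c=x_c * params.tau / S)


def ricco_area(params: SpatiotemporalParams, T: float, context) -> float:
    """Ricco's area (deg^2) at duration T on the blur-free area<->input map.

    The critical input S_c is mapped back to a stimulus area with optics
    disabled, estimating the neural summation extent net of blur.
    """
    cp = critical_input(params, T)
    return float(context.input_to_area(cp.S_c, blur=False))


def ricco_area_loss_ratios(
    params: SpatiotemporalParams,
    T: float,
    context,
    loss_fraction: float,
    n_seeds: int = 100,
    seed: int = 0,
    average_curves: bool = True,
) -> np.ndarray:
    """Ricco-area inflation under diffuse random RGC loss.

    Each random thinning deletes every cell i.i.d. with probability
    ``loss_fraction``; the blur-free area->input curve is rebuilt from
    the survivors and Ricco's area re-read at the same critical input
    S_c.  With ``average_curves=True`` (default) the degraded response
    curves are first averaged over the ``n_seeds`` mosaics -- the
    noise-free readout, which approaches 1/(1 - loss_fraction) -- and a
    single ratio is returned.  With ``average_curves=False`` the
    per-mosaic ratios are returned instead; these carry the binomial
    noise of the handful of surviving cells at the critical area.
    """
    if not 0 <= loss_fraction < 1:
        raise ValueError("loss_fraction must be in [0, 1)")
    mosaic = context.mosaic()
    t = context._table(False)
    diameters = 2.0 * np.sqrt(10 ** t[:, 0] / np.pi)
    per_cell = np.array([context.per_cell_inputs(d, blur=False) for d in diameters])
    log_area = t[:, 0]
    s_intact = per_cell.sum(axis=1)
    s_c = critical_input(params, T).S_c
    if s_intact[-1] * (1 - loss_fraction) < 2 * s_c:
        raise ValueError(
            "area ladder does not bracket the degraded critical input; "
            "increase context.max_diameter"
        )

    def crossing(s_curve):
        # local window around the crossing, where the curve is populated
        # enough to be smooth and monotone
        sel = (s_curve > s_c / 5.0) & (s_curve < s_c * 5.0)
        if sel.sum() < 2:
            raise ValueError("area ladder too coarse around the critical input")
        return np.interp(np.log10(s_c), np.log10(s_curve[sel]), log_area[sel])

    base = crossing(s_intact)
    rng = np.random.default_rng(seed)
    curves = np.empty((n_seeds, len(s_intact)))
    for i in range(n_seeds):
        survive = rng.random(len(mosaic.positions)) >= loss_fraction
        curves[i] = per_cell[:, survive].sum(axis=1)
    if average_curves:
        return np.array([10 ** (crossing(curves.mean(axis=0)) - base)])
    return np.array([10 ** (crossing(c) - base) for c in curves])


def summation_curve(params: SpatiotemporalParams, context, T: float, areas) -> np.ndarray:
    """Predicted DLS along a ladder of stimulus areas at fixed duration.

    Returns an array of (area, dls_pred) rows.
    """
    areas = np.asarray(areas, float)
    s_vals = np.array([context.area_to_input(a) for a in areas])
    dls = predicted_dls(s_vals, np.full_like(s_vals, float(T)), params)
    return np.column_stack([areas, dls])


# ---------------------------------------------------------------------------
# model / results (fitting)
# ---------------------------------------------------------------------------

class SpatiotemporalSummationModel:
    """Fit the capacitor pooler to threshold data from one location.

    Parameters
    ----------
    db_obs : observed sensitivities in perimetric dB (10 x DLS).
    S : total spatial input of each stimulus (unit contrast).
    T : stimulus duration of each datum, ms.
    k : summation exponent, fixed during the fit (default 4).

    The free parameters are log10(tau) and the vertical Offset; the
    objective is the RMSE between observed and predicted dB.
    """

    def __init__(self, db_obs, S, T, k: float = 4.0):
        self.db_obs = np.asarray(db_obs, float)
        self.S = np.asarray(S, float)
        self.T = np.asarray(T, float)
        if not (len(self.db_obs) == len(self.S) == len(self.T)):
            raise ValueError("db_obs, S and T must have equal length")
        if len(self.db_obs) < 3:
            raise ValueError("need at least 3 data points")
        st = self.S * self.T
        if np.ptp(st) / st.mean() < 1e-9:
            raise ValueError("degenerate data: all stimuli have the same S*T product")
        self.k = float(k)
        self.context = None

    @classmethod
    def from_dataframe(cls, df, context, k: float = 4.0,
                       db_col: str = "db", diameter_col: str = "diameter_deg",
                       duration_col: str = "duration_ms"):
        """Build from a threshold table, deriving S from stimulus diameter.

        S is computed through the context's area->input mapping with the
        context's own optics setting (fits account for blur when the
        optical stage is enabled).
        """
        areas = np.pi * (np.asarray(df[diameter_col], float) / 2.0) ** 2
        s_vals = np.array([context.area_to_input(a) for a in areas])
        model = cls(df[db_col], s_vals, df[duration_col], k=k)
        model.context = context
        return model

    # objective ----------------------------------------------------------
    def _rmse(self, theta) -> float:
        log_tau, offset = theta
        params = SpatiotemporalParams(tau=10.0 ** log_tau, k=self.k, offset=offset)
        pred_db = 10.0 * predicted_dls(self.S, self.T, params)
        return float(np.sqrt(np.mean((pred_db - self.db_obs) ** 2)))

    def fit(self, starts=(2.0, 3.0, 4.0)) -> "SummationFitResults":
        """Multi-start Nelder-Mead on (log10 tau, Offset); deterministic."""
        best = None
        for lt0 in starts:
            # offset start: match the mean observed level at this tau
            p0 = SpatiotemporalParams(tau=10.0 ** lt0, k=self.k, offset=0.0)
            off0 = float(np.mean(self.db_obs / 10.0 - predicted_dls(self.S, self.T, p0)))
            res = optimize.minimize(
                self._rmse, x0=[lt0, off0], method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000},
            )
            if best is None or res.fun < best.fun:
                best = res
        log_tau, offset = best.x
        return SummationFitResults(self, tau=10.0 ** log_tau, offset=offset,
                                   rmse_db=best.fun, converged=bool(best.success))


class SummationFitResults:
    """Estimates, uncertainties and diagnostics of a summation fit."""

    def __init__(self, model: SpatiotemporalSummationModel, tau: float,
                 offset: float, rmse_db: float, converged: bool):
        self.model = model
        self.tau = tau
        self.offset = offset
        self.rmse_db = rmse_db
        self.converged = converged
        self.nobs = len(model.db_obs)
        self.df_resid = self.nobs - 2
        self._cov = None

    @property
    def params(self) -> dict:
        return {"tau": float(self.tau), "offset": float(self.offset)}

    @property
    def spatiotemporal_params(self) -> SpatiotemporalParams:
        return SpatiotemporalParams(tau=self.tau, k=self.model.k, offset=self.offset)

    # uncertainties ------------------------------------------------------
    def _jacobian(self) -> np.ndarray:
        """Numeric Jacobian of predicted dB wrt (log10 tau, offset)."""
        theta = np.array([np.log10(self.tau), self.offset])
        eps = np.array([1e-5, 1e-5])
        cols = []
        for i in range(2):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps[i]
            tm[i] -= eps[i]
            cols.append((self._pred_db(tp) - self._pred_db(tm)) / (2 * eps[i]))
        return np.column_stack(cols)

    def _pred_db(self, theta) -> np.ndarray:
        params = SpatiotemporalParams(tau=10.0 ** theta[0], k=self.model.k, offset=theta[1])
        return 10.0 * predicted_dls(self.model.S, self.model.T, params)

    @property
    def cov_params(self) -> np.ndarray:
        """Gauss-Newton covariance of (log10 tau, offset)."""
        if self._cov is None:
            J = self._jacobian()
            resid = self._pred_db([np.log10(self.tau), self.offset]) - self.model.db_obs
            s2 = float(resid @ resid) / max(self.df_resid, 1)
            self._cov = s2 * np.linalg.pinv(J.T @ J)
        return self._cov

    @property
    def bse(self) -> dict:
        se = np.sqrt(np.diag(self.cov_params))
        return {"log10_tau": se[0], "offset": se[1]}

    # derived quantities -------------------------------------------------
    def predict(self, S=None, T=None):
        """Predicted dB; defaults to the fitted sample."""
        S = self.model.S if S is None else S
        T = self.model.T if T is None else T
        return 10.0 * predicted_dls(S, T, self.spatiotemporal_params)

    @property
    def resid(self) -> np.ndarray:
        return self.model.db_obs - self.predict()

    def critical_input(self, T: float) -> CriticalPoint:
        return critical_input(self.spatiotemporal_params, T)

    def ricco_area(self, T: float, context=None) -> float:
        ctx = context if context is not None else self.model.context
        if ctx is None:
            raise ValueError("no retinal context attached; pass one explicitly")
        return ricco_area(self.spatiotemporal_params, T, ctx)

    def summary(self) -> str:
        se = self.bse
        lines = [
            "Spatiotemporal summation fit (capacitor pooler)",
            "=" * 55,
            f"{'n obs':<28}{self.nobs:>10d}",
            f"{'summation exponent k':<28}{self.model.k:>10.2f}  (fixed)",
            f"{'RMSE (dB)':<28}{self.rmse_db:>10.3f}",
            f"{'converged':<28}{str(self.converged):>10}",
            "-" * 55,
            f"{'parameter':<14}{'estimate':>12}{'std err':>12}",
            f"{'tau (x10^2)':<14}{self.tau / 100:>12.3f}{np.log(10) * self.tau * se['log10_tau'] / 100:>12.3f}",
            f"{'log10 tau':<14}{np.log10(self.tau):>12.4f}{se['log10_tau']:>12.4f}",
            f"{'Offset (dB/10)':<14}{self.offset:>12.4f}{se['offset']:>12.4f}",
            "=" * 55,
        ]
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Observed vs predicted sensitivity against log10 normalised input."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = self.model.S * self.model.T / self.tau
        order = np.argsort(x)
        ax.plot(np.log10(x[order]), self.predict()[order], "-", label="model")
        ax.plot(np.log10(x), self.model.db_obs, "o", ms=4, label="observed")
        ax.set_xlabel("log10 normalised input  x = S*T/tau")
        ax.set_ylabel("sensitivity (dB)")
        ax.legend()
        return ax
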