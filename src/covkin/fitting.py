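"""Regression stages of the covalent-inhibition pipeline.

Every stage is a small scikit-learn-style estimator (``fit`` /
``predict`` / ``get_params``; fitted attributes carry a trailing
underscore) so the stages compose with sklearn tooling, plus a thin
function wrapper returning a result dataclass:

* occupancy time course -> k_obs            (:class:`OnePhaseAssociation`)
* k_obs vs concentration -> (K_I, k_inact)  (:class:`SaturationKinetics`)
* HPLC AUC decay -> first-order rate        (:class:`LogLinearDecay`)
* fluorescence trace -> exchange rate       (:class:`SingleExponentialTrace`)
* dose-response -> IC50                     (:class:`FourParameterLogistic`)

All fits are unweighted least squares.  Non-convergence and degenerate
designs are carried as flags on the result, never silent NaNs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .kinetics import TwoStepParams

__all__ = [
    "InsufficientDataError",
    "OnePhaseAssociation",
    "SaturationKinetics",
    "LogLinearDecay",
    "SingleExponentialTrace",
    "FourParameterLogistic",
    "KobsEstimate",
    "TwoStepFit",
    "ReactivityResult",
    "DoseResponse",
    "fit_one_phase",
    "fit_kobs_vs_conc",
    "fit_log_linear_rate",
    "correct_gsh_rate",
    "fit_exponential_trace",
    "normalize_exchange_rates",
    "fit_ic50",
    "aggregate_replicates",
]

#: clamp window for slightly negative OLS slopes (h^-1)
NEGATIVE_RATE_CLAMP = 1e-3
#: GSH half-lives beyond the last sampled point are censored (h)
GSH_CENSOR_HORIZON_H = 72.0

MAX_NFEV = 10_000
FIT_XTOL = 1e-12


class InsufficientDataError(ValueError):
    """Raised when a fit is attempted with fewer points than parameters allow."""


def _column(X) -> np.ndarray:
    x = np.asarray(X, dtype=float)
    if x.ndim == 2 and x.shape[1] == 1:
        x = x[:, 0]
    if x.ndim != 1:
        raise ValueError(f"expected a 1-D array or single-column matrix, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input")
    return x


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KobsEstimate:
    """Pseudo-first-order labelling rate at one inhibitor concentration."""

    conc: float  # M
    k_obs: float  # s^-1
    k_obs_se: float  # s^-1
    plateau: float
    plateau_se: float
    n_points: int
    converged: bool = True
    degenerate: bool = False


@dataclass(frozen=True)
class TwoStepFit:
    """(K_I, k_inact) from the k_obs-concentration hyperbola."""

    K_I: float  # M
    k_inact: float  # s^-1
    K_I_se: float
    k_inact_se: float
    n_conc: int
    converged: bool = True
    poorly_determined: bool = False

    @property
    def params(self) -> TwoStepParams:
        return TwoStepParams(K_I=self.K_I, k_inact=self.k_inact)

    @property
    def efficiency(self) -> float:
        return self.k_inact / self.K_I


@dataclass(frozen=True)
class ReactivityResult:
    """GSH surrogate reactivity corrected for aqueous degradation.

    ``k_app = k_deg + k_GSH``; half-lives longer than the assay horizon
    (72 h) are censored and reported as a lower bound.
    """

    k_deg: float  # h^-1
    k_app: float  # h^-1
    k_gsh: float  # h^-1
    t_half_gsh: float  # h; = horizon when censored
    censored: bool = False

    @property
    def display(self) -> str:
        return f">{GSH_CENSOR_HORIZON_H:g}" if self.censored else f"{self.t_half_gsh:g}"


@dataclass(frozen=True)
class DoseResponse:
    """Four-parameter log-logistic dose-response fit."""

    concs: np.ndarray = field(repr=False)  # M
    responses: np.ndarray = field(repr=False)
    ic50: float  # M
    hill: float
    ic50_se: float
    top: float
    bottom: float
    converged: bool = True
    censored: str | None = None  # None, ">max" or "<min"


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class OnePhaseAssociation(RegressorMixin, BaseEstimator):
    """One-phase association fit of covalent occupancy vs time.

    Model: ``occupancy(t) = plateau * (1 - exp(-k_obs t))`` with
    ``plateau`` free in (0, 1] (incomplete labelling at saturation is
    common in MS occupancy data) and occupancy pinned to 0 at t = 0.

    Fitted attributes: ``k_obs_``, ``plateau_``, ``k_obs_se_``,
    ``plateau_se_``, ``converged_``, ``degenerate_``.
    """

    def __init__(self, min_points: int = 4):
        self.min_points = min_points

    def fit(self, X, y):
        t = _column(X)
        occ = np.asarray(y, dtype=float)
        if occ.shape != t.shape:
            raise ValueError("times and occupancy must have matching length")
        if len(np.unique(t)) < self.min_points:
            raise InsufficientDataError(
                f"one-phase fit needs >= {self.min_points} distinct time points"
            )
        if np.any((occ < 0) | (occ > 1)):
            raise ValueError("occupancy must lie in [0, 1]")

        self.n_points_ = t.size
        self.converged_ = True
        self.degenerate_ = False

        ymax = float(occ.max())
        if ymax <= 1e-12:  # null signal: no labelling observed
            self.k_obs_, self.plateau_ = 0.0, 0.0
            self.k_obs_se_ = self.plateau_se_ = np.nan
            self.degenerate_ = True
            return self

        p0_plateau = min(max(ymax, 1e-3), 1.0)
        # crude rate guess: time to half the apparent plateau
        above = t[(occ >= 0.5 * p0_plateau) & (t > 0)]
        t_half_guess = float(above.min()) if above.size else float(t[t > 0].min())
        p0_k = np.log(2.0) / max(t_half_guess, 1e-12)

        # nondimensionalise time so the rate parameter is O(1) and the
        # solver's relative tolerances are meaningful
        t_scale = float(t.max())

        def model(tt, k_scaled, plateau):
            return plateau * -np.expm1(-k_scaled * tt / t_scale)

        try:
            popt, pcov = optimize.curve_fit(
                model, t, occ,
                p0=[p0_k * t_scale, p0_plateau],
                bounds=([0.0, 1e-9], [np.inf, 1.0]),
                maxfev=MAX_NFEV, xtol=FIT_XTOL, ftol=FIT_XTOL, gtol=FIT_XTOL,
            )
        except RuntimeError:
            self.k_obs_, self.plateau_ = p0_k, p0_plateau
            self.k_obs_se_ = self.plateau_se_ = np.nan
            self.converged_ = False
            return self
        self.k_obs_, self.plateau_ = float(popt[0]) / t_scale, float(popt[1])
        ses = np.sqrt(np.diag(pcov))
        self.k_obs_se_, self.plateau_se_ = float(ses[0]) / t_scale, float(ses[1])
        # rate indistinguishable from zero at the sampled window
        if self.k_obs_ * t.max() < 1e-6:
            self.degenerate_ = True
        return self

    def predict(self, X):
        t = _column(X)
        return self.plateau_ * -np.expm1(-self.k_obs_ * t)


class SaturationKinetics(RegressorMixin, BaseEstimator):
    """Hyperbolic fit of k_obs vs inhibitor concentration.

    Model: ``k_obs = k_inact * c / (K_I + c)``; unweighted nonlinear
    least squares started from ``k_inact = max(k_obs)``,
    ``K_I = max(c)``.  A fitted K_I beyond ``ki_identifiability_factor``
    times the largest tested concentration means the design never left
    the linear (second-order) regime and K_I is flagged poorly
    determined.

    Fitted attributes: ``K_I_``, ``k_inact_``, ``K_I_se_``,
    ``k_inact_se_``, ``converged_``, ``poorly_determined_``.
    """

    def __init__(self, min_concs: int = 3, ki_identifiability_factor: float = 10.0):
        self.min_concs = min_concs
        self.ki_identifiability_factor = ki_identifiability_factor

    def fit(self, X, y):
        c = _column(X)
        k = np.asarray(y, dtype=float)
        if k.shape != c.shape:
            raise ValueError("concentration and k_obs must have matching length")
        if np.any(c <= 0) or np.any(k < 0):
            raise ValueError("concentrations must be > 0 and k_obs >= 0")
        if len(np.unique(c)) < self.min_concs:
            raise InsufficientDataError(
                f"k_obs-c fit needs >= {self.min_concs} distinct concentrations"
            )

        # fit in nondimensional units (c / c_max, k_obs / k_max) so both
        # parameters are O(1) for the bounded solver
        c_scale = float(c.max())
        k_scale = float(max(k.max(), 1e-300))

        def model(cc, k_inact_s, K_I_s):
            return k_inact_s * cc / (K_I_s + cc)

        p0 = [1.0, 1.0]  # k_inact = max(k_obs), K_I = max(c)
        self.converged_ = True
        try:
            popt, pcov = optimize.curve_fit(
                model, c / c_scale, k / k_scale, p0=p0,
                bounds=([0.0, 1e-12], [np.inf, np.inf]),
                maxfev=MAX_NFEV, xtol=FIT_XTOL, ftol=FIT_XTOL, gtol=FIT_XTOL,
            )
        except RuntimeError:
            popt, pcov = p0, np.full((2, 2), np.nan)
            self.converged_ = False
        self.k_inact_, self.K_I_ = float(popt[0]) * k_scale, float(popt[1]) * c_scale
        ses = np.sqrt(np.diag(pcov))
        self.k_inact_se_ = float(ses[0]) * k_scale
        self.K_I_se_ = float(ses[1]) * c_scale
        self.poorly_determined_ = bool(
            self.K_I_ > self.ki_identifiability_factor * c.max()
        )
        return self

    def predict(self, X):
        c = _column(X)
        return self.k_inact_ * c / (self.K_I_ + c)


class LogLinearDecay(RegressorMixin, BaseEstimator):
    """Pseudo-first-order decay rate from OLS on log signal.

    The decay rate is the negated slope of an ordinary least-squares
    regression of ln(AUC) on time.  Fitted attributes: ``rate_``,
    ``rate_se_``, ``intercept_``.
    """

    def __init__(self, min_points: int = 3):
        self.min_points = min_points

    def fit(self, X, y):
        t = _column(X)
        auc = np.asarray(y, dtype=float)
        if auc.shape != t.shape:
            raise ValueError("times and AUC must have matching length")
        if t.size < self.min_points:
            raise InsufficientDataError(f"log-linear fit needs >= {self.min_points} points")
        bad = np.flatnonzero(auc <= 0)
        if bad.size:
            raise ValueError(
                f"nonpositive AUC at sample index(es) {bad.tolist()} "
                f"(t = {t[bad].tolist()}); cannot take logarithm"
            )
        res = stats.linregress(t, np.log(auc))
        self.rate_ = -float(res.slope)
        self.rate_se_ = float(res.stderr)
        self.intercept_ = float(res.intercept)
        return self

    def predict(self, X):
        t = _column(X)
        return np.exp(self.intercept_ - self.rate_ * t)


class SingleExponentialTrace(RegressorMixin, BaseEstimator):
    """Single-exponential fit of a fluorescence trace.

    Model: ``F(t) = F_inf + (F_0 - F_inf) exp(-k t)`` with all three
    parameters free.  Fitted attributes: ``rate_``, ``rate_se_``,
    ``f0_``, ``finf_``, ``converged_``, ``degenerate_``.
    """

    def __init__(self, min_points: int = 5):
        self.min_points = min_points

    def fit(self, X, y):
        t = _column(X)
        f = np.asarray(y, dtype=float)
        if f.shape != t.shape:
            raise ValueError("times and fluorescence must have matching length")
        if t.size < self.min_points:
            raise InsufficientDataError(
                f"exponential trace fit needs >= {self.min_points} points"
            )
        self.converged_ = True
        self.degenerate_ = False
        amplitude = float(f.max() - f.min())
        span = float(t.max() - t.min())
        if amplitude <= 1e-12 * max(abs(f).max(), 1.0):  # flat trace
            self.rate_, self.f0_, self.finf_ = 0.0, float(f.mean()), float(f.mean())
            self.rate_se_ = np.nan
            self.degenerate_ = True
            return self

        t_scale = span  # nondimensional rate parameter is O(1)

        def model(tt, k_scaled, f0, finf):
            return finf + (f0 - finf) * np.exp(-k_scaled * tt / t_scale)

        p0 = [3.0, float(f[0]), float(f[-1])]
        try:
            popt, pcov = optimize.curve_fit(
                model, t, f, p0=p0, bounds=([0.0, -np.inf, -np.inf], np.inf),
                maxfev=MAX_NFEV, xtol=FIT_XTOL, ftol=FIT_XTOL, gtol=FIT_XTOL,
            )
        except RuntimeError:
            self.rate_, self.f0_, self.finf_ = p0[0] / t_scale, p0[1], p0[2]
            self.rate_se_ = np.nan
            self.converged_ = False
            return self
        self.rate_, self.f0_, self.finf_ = float(popt[0]) / t_scale, float(popt[1]), float(popt[2])
        self.rate_se_ = float(np.sqrt(pcov[0, 0])) / t_scale
        return self

    def predict(self, X):
        t = _column(X)
        return self.finf_ + (self.f0_ - self.finf_) * np.exp(-self.rate_ * t)


class FourParameterLogistic(RegressorMixin, BaseEstimator):
    """Four-parameter log-logistic dose-response fit (IC50 determination).

    Model: ``r(c) = bottom + (top - bottom) / (1 + (c / ic50)^hill)``
    so that ``hill > 0`` describes a response falling with dose and
    ``r(ic50)`` sits midway between top and bottom.  Top and bottom are
    constrained to [0, 1.2] times the observed dynamic range; an IC50
    fitted outside the tested concentration window is censored.

    Fitted attributes: ``ic50_``, ``hill_``, ``top_``, ``bottom_``,
    ``ic50_se_``, ``converged_``, ``censored_``.
    """

    def __init__(self, min_concs: int = 4, bound_factor: float = 1.2):
        self.min_concs = min_concs
        self.bound_factor = bound_factor

    def fit(self, X, y):
        c = _column(X)
        r = np.asarray(y, dtype=float)
        if r.shape != c.shape:
            raise ValueError("concentrations and responses must have matching length")
        if np.any(c <= 0):
            raise ValueError("concentrations must be > 0")
        if len(np.unique(c)) < self.min_concs:
            raise InsufficientDataError(
                f"IC50 fit needs >= {self.min_concs} distinct concentrations"
            )
        rmax = float(max(r.max(), 1e-9))
        hi = self.bound_factor * rmax

        def model(cc, log_ic50, hill, top, bottom):
            return bottom + (top - bottom) / (1.0 + (cc / np.exp(log_ic50)) ** hill)

        # midpoint guess: concentration where response crosses half range
        mid = 0.5 * (r.max() + r.min())
        order = np.argsort(c)
        below = c[order][r[order] <= mid]
        ic50_guess = float(below.min()) if below.size else float(np.median(c))
        p0 = [np.log(ic50_guess), 1.0, rmax, float(max(r.min(), 0.0))]
        lo_b = [np.log(c.min()) - 23.0, 0.05, 0.0, 0.0]
        hi_b = [np.log(c.max()) + 23.0, 20.0, hi, hi]
        self.converged_ = True
        try:
            popt, pcov = optimize.curve_fit(
                model, c, r, p0=p0, bounds=(lo_b, hi_b),
                maxfev=MAX_NFEV, xtol=FIT_XTOL, ftol=FIT_XTOL, gtol=FIT_XTOL,
            )
        except RuntimeError:
            popt, pcov = p0, np.full((4, 4), np.nan)
            self.converged_ = False
        log_ic50, self.hill_, self.top_, self.bottom_ = map(float, popt)
        self.ic50_ = float(np.exp(log_ic50))
        # delta-method SE on the natural scale
        self.ic50_se_ = float(self.ic50_ * np.sqrt(pcov[0, 0]))
        if self.ic50_ > c.max():
            self.censored_ = ">max"
        elif self.ic50_ < c.min():
            self.censored_ = "<min"
        else:
            self.censored_ = None
        return self

    def predict(self, X):
        c = _column(X)
        return self.bottom_ + (self.top_ - self.bottom_) / (
            1.0 + (c / self.ic50_) ** self.hill_
        )


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def fit_one_phase(times, occupancy, conc: float = np.nan) -> KobsEstimate:
    """Fit one occupancy time course; see :class:`OnePhaseAssociation`.

    ``conc`` only annotates the estimate for the downstream k_obs-c fit.
    """
    est = OnePhaseAssociation().fit(times, occupancy)
    return KobsEstimate(
        conc=conc,
        k_obs=est.k_obs_,
        k_obs_se=est.k_obs_se_,
        plateau=est.plateau_,
        plateau_se=est.plateau_se_,
        n_points=est.n_points_,
        converged=est.converged_,
        degenerate=est.degenerate_,
    )


def fit_kobs_vs_conc(estimates: list[KobsEstimate]) -> TwoStepFit:
    """Fit the k_obs-c hyperbola over per-concentration estimates."""
    conc = np.array([e.conc for e in estimates], dtype=float)
    kobs = np.array([e.k_obs for e in estimates], dtype=float)
    est = SaturationKinetics().fit(conc, kobs)
    return TwoStepFit(
        K_I=est.K_I_,
        k_inact=est.k_inact_,
        K_I_se=est.K_I_se_,
        k_inact_se=est.k_inact_se_,
        n_conc=len(np.unique(conc)),
        converged=est.converged_,
        poorly_determined=est.poorly_determined_,
    )


def fit_log_linear_rate(times, auc) -> float:
    """First-order decay rate (same units^-1 as ``times``) from log-OLS."""
    return LogLinearDecay().fit(times, auc).rate_


def correct_gsh_rate(k_app: float, k_deg: float) -> ReactivityResult:
    """Separate GSH reactivity from aqueous degradation.

    ``k_GSH = k_app - k_deg``; compounds whose corrected half-life
    exceeds the 72 h assay horizon are censored (reported "> 72 h").
    Small negative OLS slopes (down to -1e-3 h^-1) are clamped to zero.
    """
    for name, v in (("k_app", k_app), ("k_deg", k_deg)):
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite")
    clamped = []
    if -NEGATIVE_RATE_CLAMP <= k_app < 0:
        clamped.append("k_app")
        k_app = 0.0
    if -NEGATIVE_RATE_CLAMP <= k_deg < 0:
        clamped.append("k_deg")
        k_deg = 0.0
    if clamped:
        warnings.warn(
            f"small negative rate(s) clamped to 0: {', '.join(clamped)}",
            stacklevel=2,
        )
    if k_app < 0 or k_deg < 0:
        raise ValueError("rates must be >= 0 (beyond the small-slope clamp window)")

    threshold = np.log(2.0) / GSH_CENSOR_HORIZON_H
    k_gsh = k_app - k_deg
    if k_gsh <= threshold:
        # includes k_deg > k_app: no resolvable GSH reaction at this horizon
        return ReactivityResult(
            k_deg=k_deg, k_app=k_app, k_gsh=max(k_gsh, 0.0),
            t_half_gsh=GSH_CENSOR_HORIZON_H, censored=True,
        )
    return ReactivityResult(
        k_deg=k_deg, k_app=k_app, k_gsh=k_gsh,
        t_half_gsh=np.log(2.0) / k_gsh, censored=False,
    )


def fit_exponential_trace(times, fluorescence) -> float:
    """Exchange rate (s^-1) from a single-exponential fluorescence fit."""
    return SingleExponentialTrace().fit(times, fluorescence).rate_


def normalize_exchange_rates(
    rate_sample: float, rate_ras_sos: float, rate_ras_only: float
) -> float:
    """Normalise an exchange rate to the catalysed/uncatalysed window.

    1 = uninhibited (full SOS1-catalysed exchange), 0 = fully inhibited
    (intrinsic exchange only).
    """
    span = rate_ras_sos - rate_ras_only
    if span <= 0:
        raise ValueError(
            "zero or negative dynamic range: RAS-SOS1 rate must exceed RAS-only rate"
        )
    return (rate_sample - rate_ras_only) / span


def fit_ic50(concs, responses) -> DoseResponse:
    """Four-parameter log-logistic IC50 fit; see :class:`FourParameterLogistic`."""
    est = FourParameterLogistic().fit(concs, responses)
    return DoseResponse(
        concs=np.asarray(concs, dtype=float),
        responses=np.asarray(responses, dtype=float),
        ic50=est.ic50_,
        hill=est.hill_,
        ic50_se=est.ic50_se_,
        top=est.top_,
        bottom=est.bottom_,
        converged=est.converged_,
        censored=est.censored_,
    )


def aggregate_replicates(values) -> tuple[float, float | None]:
    """Mean and sample SD (n-1 denominator); SD is None when n = 1."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("cannot aggregate an empty replicate list")
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size > 1 else None
    return mean, sd
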