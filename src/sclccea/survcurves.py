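"""Parametric and flexible survival models for extrapolating reconstructed trial curves.

The model suite contains seven standard parametric families (exponential,
Weibull, Gompertz, log-normal, log-logistic, gamma, generalized gamma) and
flexible families used for survival extrapolation in health technology
assessment: fractional polynomials on the log hazard (FP1/FP2), restricted
cubic splines on the log hazard (RCS), Royston-Parmar spline models on the
log cumulative hazard / log cumulative odds / probit scales, and mixture cure
models S(t) = pi + (1 - pi) S_u(t).

All families share one right-censored log-likelihood
    l(theta) = sum_i [ d_i log f(t_i) + (1 - d_i) log S(t_i) ]
maximized by multi-start quasi-Newton, so AIC/BIC are comparable across the
whole suite.  Families whose cumulative hazard has no closed form (FP, RCS)
evaluate H(t) by trapezoidal integration on a refined log-spaced grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .km_ipd import PseudoIPD

__all__ = [
    "STANDARD_FAMILIES",
    "FLEXIBLE_FAMILIES",
    "ALL_FAMILIES",
    "SurvivalFit",
    "HRCurve",
    "CurveSet",
    "fit",
    "select",
    "survival_at",
    "apply_hr",
]

STANDARD_FAMILIES = (
    "exponential", "weibull", "gompertz", "lognormal", "loglogistic", "gamma", "gengamma",
)
FLEXIBLE_FAMILIES = ("fp1", "fp2", "rcs", "rp_hazard", "rp_odds", "rp_normal", "mcm")
ALL_FAMILIES = STANDARD_FAMILIES + FLEXIBLE_FAMILIES

_FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)
_TINY = 1e-300


# ---------------------------------------------------------------------------
# restricted cubic spline basis (natural cubic spline, linear beyond boundaries)

def _rcs_basis(x: np.ndarray, knots: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Royston-Parmar restricted cubic spline basis and its derivative.

    ``knots`` includes the two boundary knots; columns are [1, x, v_1..v_m]
    for the m internal knots.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    kmin, kmax = knots[0], knots[-1]
    cols = [np.ones_like(x), x]
    dcols = [np.zeros_like(x), np.ones_like(x)]
    for kj in knots[1:-1]:
        lam = (kmax - kj) / (kmax - kmin)
        u, umin, umax = (
            np.maximum(x - kj, 0.0), np.maximum(x - kmin, 0.0), np.maximum(x - kmax, 0.0))
        cols.append(u ** 3 - lam * umin ** 3 - (1 - lam) * umax ** 3)
        dcols.append(3 * (u ** 2 - lam * umin ** 2 - (1 - lam) * umax ** 2))
    return np.column_stack(cols), np.column_stack(dcols)


def _default_knots(t: np.ndarray, d: np.ndarray, n_internal: int) -> np.ndarray:
    """Boundary knots at min/max log uncensored event time, internal at quantiles."""
    ev = np.log(t[d == 1])
    if len(ev) < 2:
        raise ValueError("need >= 2 events to place spline knots")
    qs = np.linspace(0, 1, n_internal + 2)
    knots = np.quantile(ev, qs)
    # collapse of adjacent knots breaks the basis
    if len(np.unique(knots)) != len(knots):
        knots += np.linspace(0, 1e-6, len(knots))
    return knots


# ---------------------------------------------------------------------------
# family definitions

class _Family:
    """One survival family: unconstrained parameter vector theta -> likelihood pieces."""

    names: tuple[str, ...]

    def log_S(self, th: np.ndarray, t: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def log_f(self, th: np.ndarray, t: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def survival(self, th: np.ndarray, t: np.ndarray) -> np.ndarray:
        return np.exp(self.log_S(th, t))

    def inits(self, t: np.ndarray, d: np.ndarray) -> list[np.ndarray]:
        raise NotImplementedError

    def natural(self, th: np.ndarray) -> dict[str, float]:
        return dict(zip(self.names, np.asarray(th, dtype=float)))

    def loglik(self, th: np.ndarray, t: np.ndarray, d: np.ndarray) -> float:
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            lf = self.log_f(th, t)
            lS = self.log_S(th, t)
            ll = np.where(d == 1, lf, lS)
        if not np.all(np.isfinite(ll)):
            return -np.inf
        return float(ll.sum())


class _Exponential(_Family):
    names = ("rate",)

    def log_S(self, th, t):
        return -np.exp(th[0]) * t

    def log_f(self, th, t):
        return th[0] - np.exp(th[0]) * t

    def inits(self, t, d):
        crude = max(d.sum(), 0.5) / t.sum()
        return [np.array([np.log(crude)])]

    def natural(self, th):
        return {"rate": float(np.exp(th[0]))}


class _Weibull(_Family):
    names = ("shape", "scale")

    def log_S(self, th, t):
        shape, scale = np.exp(th)
        return -((np.maximum(t, _TINY) / scale) ** shape)

    def log_f(self, th, t):
        shape, scale = np.exp(th)
        tt = np.maximum(t, _TINY)
        return (np.log(shape / scale) + (shape - 1) * np.log(tt / scale)
                - (tt / scale) ** shape)

    def inits(self, t, d):
        crude = max(d.sum(), 0.5) / t.sum()
        base = np.array([0.0, -np.log(crude)])
        return [base, base + [np.log(1.5), 0.0], base + [np.log(0.7), 0.0]]

    def natural(self, th):
        return {"shape": float(np.exp(th[0])), "scale": float(np.exp(th[1]))}


class _Gompertz(_Family):
    names = ("rate", "shape")  # h(t) = rate * exp(shape * t)

    def log_S(self, th, t):
        a, b = np.exp(th[0]), th[1]
        if abs(b) < 1e-12:
            return -a * t
        return -(a / b) * np.expm1(b * t)

    def log_f(self, th, t):
        a, b = np.exp(th[0]), th[1]
        return th[0] + b * t + self.log_S(th, t)

    def inits(self, t, d):
        crude = max(d.sum(), 0.5) / t.sum()
        return [np.array([np.log(crude), s]) for s in (1e-4, -1e-4, 1.0 / max(t.max(), 1.0))]

    def natural(self, th):
        return {"rate": float(np.exp(th[0])), "shape": float(th[1])}


class _LogNormal(_Family):
    names = ("mu", "sigma")

    def log_S(self, th, t):
        mu, sig = th[0], np.exp(th[1])
        return stats.norm.logsf((np.log(np.maximum(t, _TINY)) - mu) / sig)

    def log_f(self, th, t):
        mu, sig = th[0], np.exp(th[1])
        tt = np.maximum(t, _TINY)
        z = (np.log(tt) - mu) / sig
        return stats.norm.logpdf(z) - np.log(sig * tt)

    def inits(self, t, d):
        lt = np.log(np.maximum(t, _TINY))
        return [np.array([lt.mean(), np.log(max(lt.std(), 0.2))])]

    def natural(self, th):
        return {"mu": float(th[0]), "sigma": float(np.exp(th[1]))}


class _LogLogistic(_Family):
    names = ("shape", "scale")

    def log_S(self, th, t):
        shape, scale = np.exp(th)
        return -np.log1p((np.maximum(t, _TINY) / scale) ** shape)

    def log_f(self, th, t):
        shape, scale = np.exp(th)
        tt = np.maximum(t, _TINY)
        lx = shape * np.log(tt / scale)
        return np.log(shape / tt) + lx - 2 * np.log1p(np.exp(np.minimum(lx, 500)))

    def inits(self, t, d):
        med = np.median(t[d == 1]) if d.sum() else np.median(t)
        return [np.array([0.3, np.log(max(med, 1.0))]), np.array([0.0, np.log(max(med, 1.0))])]

    def natural(self, th):
        return {"shape": float(np.exp(th[0])), "scale": float(np.exp(th[1]))}


class _Gamma(_Family):
    names = ("shape", "scale")

    def log_S(self, th, t):
        shape, scale = np.exp(th)
        return stats.gamma.logsf(t, shape, scale=scale)

    def log_f(self, th, t):
        shape, scale = np.exp(th)
        return stats.gamma.logpdf(np.maximum(t, _TINY), shape, scale=scale)

    def inits(self, t, d):
        m = t.mean()
        return [np.array([0.0, np.log(m)]), np.array([np.log(2.0), np.log(m / 2.0)])]

    def natural(self, th):
        return {"shape": float(np.exp(th[0])), "scale": float(np.exp(th[1]))}


class _GenGamma(_Family):
    # scipy parameterization: a (shape), c (power, != 0), scale
    names = ("a", "c", "scale")

    def log_S(self, th, t):
        a, c, scale = np.exp(th[0]), th[1], np.exp(th[2])
        if abs(c) < 1e-6:
            return np.full_like(t, -np.inf)
        return stats.gengamma.logsf(t, a, c, scale=scale)

    def log_f(self, th, t):
        a, c, scale = np.exp(th[0]), th[1], np.exp(th[2])
        if abs(c) < 1e-6:
            return np.full_like(t, -np.inf)
        return stats.gengamma.logpdf(np.maximum(t, _TINY), a, c, scale=scale)

    def inits(self, t, d):
        m = max(np.median(t[d == 1]) if d.sum() else np.median(t), 1.0)
        return [np.array([0.0, 1.0, np.log(m)]),
                np.array([np.log(2.0), 1.0, np.log(m / 2.0)]),
                np.array([0.0, 0.5, np.log(m)])]

    def natural(self, th):
        return {"a": float(np.exp(th[0])), "c": float(th[1]), "scale": float(np.exp(th[2]))}


class _RoystonParmar(_Family):
    """Spline s(x; gamma) in x = log t on a transformed survival scale.

    scale='hazard': log H(t) = s;  'odds': log[S^-1 - 1] = s;
    'normal': -Phi^-1(S) = s.  With no internal knots these reduce exactly to
    Weibull, log-logistic and log-normal respectively.
    """

    def __init__(self, scale: str, knots: np.ndarray):
        self.scale = scale
        self.knots = np.asarray(knots, dtype=float)
        self.names = tuple(f"gamma{i}" for i in range(len(self.knots)))

    def _s(self, th, t):
        x = np.log(np.maximum(t, _TINY))
        B, dB = _rcs_basis(x, self.knots)
        return B @ th, dB @ th, x

    def log_S(self, th, t):
        s, _, _ = self._s(th, t)
        if self.scale == "hazard":
            return -np.exp(np.minimum(s, 500))
        if self.scale == "odds":
            return -np.logaddexp(0.0, s)
        return stats.norm.logcdf(-s)

    def log_f(self, th, t):
        s, ds, x = self._s(th, t)
        if np.any(ds <= 0):
            return np.full_like(np.atleast_1d(s), -np.inf)
        if self.scale == "hazard":
            return s + np.log(ds) - x - np.exp(np.minimum(s, 500))
        if self.scale == "odds":
            return s + np.log(ds) - x - 2 * np.logaddexp(0.0, s)
        return stats.norm.logpdf(s) + np.log(ds) - x

    def inits(self, t, d):
        # regress the transformed KM estimate on the basis
        from lifelines import KaplanMeierFitter
        km = KaplanMeierFitter().fit(t, d)
        tt = np.asarray(km.survival_function_.index, dtype=float)
        ss = km.survival_function_.iloc[:, 0].to_numpy()
        keep = (tt > 0) & (ss > 1e-6) & (ss < 1 - 1e-6)
        tt, ss = tt[keep], ss[keep]
        if len(tt) < len(self.knots):
            return [np.zeros(len(self.knots))]
        if self.scale == "hazard":
            g = np.log(-np.log(ss))
        elif self.scale == "odds":
            g = np.log(1.0 / ss - 1.0)
        else:
            g = -stats.norm.ppf(ss)
        B, _ = _rcs_basis(np.log(tt), self.knots)
        coef, *_ = np.linalg.lstsq(B, g, rcond=None)
        if coef[1] <= 0:
            coef[1] = 0.5
        return [coef]


class _NumericHazard(_Family):
    """Log-hazard models without closed-form H(t): trapezoid cumulative hazard
    on a log-spaced grid refined with the observation times."""

    t_scale: float = 1.0

    def log_h(self, th, t):
        raise NotImplementedError

    def _cum_hazard(self, th, t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        tmax = max(t.max(), 1.0)
        eps = self.eps
        grid = np.unique(np.concatenate([
            np.geomspace(eps, tmax, 600), t[t > eps]]))
        with np.errstate(over="ignore"):
            h = np.exp(np.minimum(self.log_h(th, grid), 500))
        H = np.concatenate([[0.0], np.cumsum(np.diff(grid) * 0.5 * (h[1:] + h[:-1]))])
        # hazard treated as flat below the smallest grid point
        H = H + h[0] * eps
        out = np.interp(t, grid, H)
        out[t <= eps] = h[0] * np.maximum(t[t <= eps], 0.0)
        return out

    def log_S(self, th, t):
        return -self._cum_hazard(th, t)

    def log_f(self, th, t):
        return self.log_h(th, np.atleast_1d(np.asarray(t, float))) - self._cum_hazard(th, t)


class _FracPoly(_NumericHazard):
    """Fractional polynomial of degree 1 or 2 on the log hazard.

    log h(t) = b0 + sum_j b_j phi_j(t / t_scale) with phi from the standard
    power set; power 0 is log t and a repeated power multiplies by log t.
    """

    def __init__(self, powers: tuple[float, ...], t_scale: float, eps: float):
        self.powers = tuple(powers)
        self.t_scale = t_scale
        self.eps = eps
        self.names = ("beta0",) + tuple(f"beta{i+1}" for i in range(len(self.powers)))

    def _design(self, t):
        z = np.maximum(t, _TINY) / self.t_scale
        lz = np.log(z)
        cols = [np.ones_like(z)]
        prev_p = None
        for p in self.powers:
            base = lz if p == 0.0 else z ** p
            if prev_p is not None and p == prev_p:
                base = base * lz
            cols.append(base)
            prev_p = p
        return np.column_stack(cols)

    def log_h(self, th, t):
        return self._design(np.atleast_1d(np.asarray(t, float))) @ th

    def inits(self, t, d):
        crude = max(d.sum(), 0.5) / t.sum()
        th0 = np.zeros(len(self.powers) + 1)
        th0[0] = np.log(crude)
        return [th0]


class _RCSHazard(_NumericHazard):
    """Restricted cubic spline on the log hazard (distinct from the
    Royston-Parmar models, which put the spline on cumulative scales)."""

    def __init__(self, knots: np.ndarray, eps: float):
        self.knots = np.asarray(knots, dtype=float)
        self.eps = eps
        self.names = tuple(f"gamma{i}" for i in range(len(self.knots)))

    def log_h(self, th, t):
        B, _ = _rcs_basis(np.log(np.maximum(np.atleast_1d(np.asarray(t, float)), _TINY)),
                          self.knots)
        return B @ th

    def inits(self, t, d):
        crude = max(d.sum(), 0.5) / t.sum()
        th0 = np.zeros(len(self.knots))
        th0[0] = np.log(crude)
        return [th0]


class _MixtureCure(_Family):
    """S(t) = pi + (1 - pi) S_u(t); theta = [logit(pi), theta_uncured]."""

    def __init__(self, uncured: _Family):
        self.uncured = uncured
        self.names = ("cure_fraction",) + tuple(f"u_{n}" for n in uncured.names)

    @staticmethod
    def _pi(th):
        return 1.0 / (1.0 + np.exp(-th[0]))

    def log_S(self, th, t):
        pi = self._pi(th)
        Su = self.uncured.survival(th[1:], t)
        return np.log(pi + (1 - pi) * Su)

    def log_f(self, th, t):
        pi = self._pi(th)
        return np.log1p(-pi) + self.uncured.log_f(th[1:], t)

    def inits(self, t, d):
        from lifelines import KaplanMeierFitter
        km = KaplanMeierFitter().fit(t, d)
        plateau = float(km.survival_function_.iloc[-1, 0])
        pi0 = min(max(plateau, 0.01), 0.8)
        logit = math.log(pi0 / (1 - pi0))
        return [np.concatenate([[logit], u]) for u in self.uncured.inits(t, d)]

    def natural(self, th):
        out = {"cure_fraction": float(self._pi(th))}
        out.update({f"u_{k}": v for k, v in self.uncured.natural(th[1:]).items()})
        return out


_STANDARD = {
    "exponential": _Exponential,
    "weibull": _Weibull,
    "gompertz": _Gompertz,
    "lognormal": _LogNormal,
    "loglogistic": _LogLogistic,
    "gamma": _Gamma,
    "gengamma": _GenGamma,
}


# ---------------------------------------------------------------------------
# fitting

@dataclass
class SurvivalFit:
    """A fitted survival model exposing S(t) and information criteria."""

    family: str
    params: dict[str, float]
    loglik: float
    aic: float
    bic: float
    n: int
    knots_logtime: np.ndarray | None = None
    powers: tuple[float, ...] | None = None
    cure_fraction: float | None = None
    _model: _Family | None = None
    _theta: np.ndarray | None = None

    @property
    def k(self) -> int:
        return len(self.params)

    def survival(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("survival times must be >= 0")
        S = np.clip(self._model.survival(self._theta, np.atleast_1d(t)), 0.0, 1.0)
        S[np.atleast_1d(t) == 0.0] = 1.0
        return S if t.ndim else float(S[0])


def _maximize(model: _Family, t: np.ndarray, d: np.ndarray,
              n_jitter: int = 2) -> tuple[np.ndarray, float]:
    nll = lambda th: -model.loglik(th, t, d)
    best = None
    starts = list(model.inits(t, d))
    # deterministic jitter multi-start
    rng = np.random.default_rng(12345)
    starts += [s + rng.normal(0, 0.3, size=len(s)) for s in list(starts)
               for _ in range(n_jitter)]
    for th0 in starts:
        if not np.isfinite(nll(np.asarray(th0, float))):
            continue
        for method in ("Nelder-Mead", "BFGS"):
            try:
                res = optimize.minimize(
                    nll, th0, method=method,
                    options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10}
                    if method == "Nelder-Mead" else {"maxiter": 500, "gtol": 1e-8},
                )
            except Exception:
                continue
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                best = res
            th0 = res.x  # chain the methods
    if best is None:
        raise RuntimeError(f"{type(model).__name__}: optimizer failed from all starting values")
    return np.asarray(best.x, float), -float(best.fun)


def _make_fit(model: _Family, family: str, theta: np.ndarray, ll: float, n: int,
              **extra) -> SurvivalFit:
    params = model.natural(theta)
    k = len(theta)
    return SurvivalFit(
        family=family, params=params, loglik=ll,
        aic=2 * k - 2 * ll, bic=k * math.log(n) - 2 * ll, n=n,
        _model=model, _theta=theta, **extra,
    )


def fit(
    ipd: PseudoIPD,
    family: str,
    n_knots: int | None = None,
    knots_logtime=None,
    powers: tuple[float, ...] | None = None,
    uncured_family: str = "weibull",
) -> SurvivalFit:
    """Maximum-likelihood fit of one family to right-censored pseudo-IPD.

    Parameters
    ----------
    n_knots : internal knot count for spline families; default: chosen from
        {1, 2, 3} by AIC (0 may be forced explicitly).
    powers : fixed FP powers; default: best subset of the standard power set.
    """
    t = np.asarray(ipd.times_days, dtype=float)
    d = np.asarray(ipd.events, dtype=int)
    n = len(t)
    if n < 10:
        raise ValueError("need at least 10 records to fit")
    if d.sum() < 1:
        raise ValueError("need at least one event to fit")
    if family not in ALL_FAMILIES:
        raise ValueError(f"unknown family {family!r}")

    if family in _STANDARD:
        model = _STANDARD[family]()
        theta, ll = _maximize(model, t, d)
        return _make_fit(model, family, theta, ll, n)

    eps = max(float(np.min(t[t > 0]) / 50.0), 1e-3) if np.any(t > 0) else 1e-3

    if family in ("rp_hazard", "rp_odds", "rp_normal", "rcs"):
        scale = {"rp_hazard": "hazard", "rp_odds": "odds", "rp_normal": "normal"}.get(family)
        candidates = [n_knots] if n_knots is not None else [1, 2, 3]
        best = None
        for m in candidates:
            kn = (np.asarray(knots_logtime, float) if knots_logtime is not None
                  else _default_knots(t, d, m))
            model = (_RoystonParmar(scale, kn) if scale is not None
                     else _RCSHazard(kn, eps))
            try:
                theta, ll = _maximize(model, t, d)
            except RuntimeError:
                continue
            f = _make_fit(model, family, theta, ll, n, knots_logtime=kn)
            if best is None or f.aic < best.aic:
                best = f
        if best is None:
            raise RuntimeError(f"{family}: no knot configuration converged")
        return best

    if family in ("fp1", "fp2"):
        t_scale = float(np.median(t[d == 1])) if d.sum() else float(np.median(t))
        if powers is not None:
            combos = [tuple(powers)]
        elif family == "fp1":
            combos = [(p,) for p in _FP_POWERS]
        else:
            combos = [(p1, p2) for i, p1 in enumerate(_FP_POWERS)
                      for p2 in _FP_POWERS[i:]]
        best = None
        for pw in combos:
            model = _FracPoly(pw, t_scale, eps)
            try:
                theta, ll = _maximize(model, t, d, n_jitter=0)
            except RuntimeError:
                continue
            f = _make_fit(model, family, theta, ll, n, powers=pw)
            if best is None or f.aic < best.aic:
                best = f
        if best is None:
            raise RuntimeError(f"{family}: no power combination converged")
        return best

    if family == "mcm":
        if uncured_family not in _STANDARD:
            raise ValueError(f"mcm uncured family must be standard, got {uncured_family!r}")
        model = _MixtureCure(_STANDARD[uncured_family]())
        theta, ll = _maximize(model, t, d)
        f = _make_fit(model, family, theta, ll, n)
        f.cure_fraction = f.params["cure_fraction"]
        return f

    raise AssertionError(family)


def select(fits: list[SurvivalFit]) -> pd.DataFrame:
    """Rank fitted models by AIC (with BIC ranks alongside) for one dataset.

    The visual plausibility check of extrapolations remains a human step;
    this table is what gets inspected.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to rank")
    ns = {f.n for f in fits}
    if len(ns) != 1:
        raise ValueError("fits were made on different data (n differs)")
    df = pd.DataFrame(
        {
            "family": [f.family for f in fits],
            "k": [f.k for f in fits],
            "loglik": [f.loglik for f in fits],
            "aic": [f.aic for f in fits],
            "bic": [f.bic for f in fits],
        }
    )
    df["bic_rank"] = df["bic"].rank(method="min").astype(int)
    df = df.sort_values("aic", kind="stable").reset_index(drop=True)
    df.index = df.index + 1
    df.index.name = "aic_rank"
    return df


def survival_at(fit_: SurvivalFit, t_days) -> np.ndarray:
    """Evaluate S(t) of a fitted model; t must be >= 0."""
    return fit_.survival(t_days)


class HRCurve:
    """Proportional-hazards transform of a base curve: S_new(t) = S_base(t)^hr."""

    def __init__(self, base, hr: float):
        if hr <= 0:
            raise ValueError("hazard ratio must be > 0")
        self.base = base
        self.hr = float(hr)

    def survival(self, t):
        return np.asarray(self.base.survival(t), dtype=float) ** self.hr


def apply_hr(base, hr: float) -> HRCurve:
    """Generate a curve from a reference fit/curve under proportional hazards."""
    return HRCurve(base, hr)


@dataclass
class CurveSet:
    """Extrapolated OS and PFS curves per strategy, with the PFS<=OS repair.

    Extrapolated tails of independently fitted OS and PFS models can cross;
    the three-state partition requires progression-free patients to be a
    subset of those alive, so evaluation clips S_PFS to S_OS pointwise.
    """

    curves: dict[str, dict[str, object]]  # name -> {"os": curve, "pfs": curve}
    horizon_days: float

    def strategies(self) -> list[str]:
        return list(self.curves)

    def evaluate(self, strategy: str, t_days) -> tuple[np.ndarray, np.ndarray]:
        t = np.asarray(t_days, dtype=float)
        pair = self.curves[strategy]
        s_os = np.asarray(pair["os"].survival(t), dtype=float)
        s_pfs = np.minimum(np.asarray(pair["pfs"].survival(t), dtype=float), s_os)
        return s_os, s_pfs
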