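"""Pseudo individual-patient-data reconstruction from digitized Kaplan-Meier curves.

Published survival figures usually come with a number-at-risk table but no
patient-level data.  Given step coordinates read off a KM plot plus that risk
table, the iterative algorithm of Guyot et al. solves, interval by interval,
for the event and censoring counts that reproduce both the digitized survival
steps and the reported numbers at risk, yielding a pseudo-IPD sample of
(time, event-indicator) records suitable for parametric model fitting.

Times are handled in days throughout; months convert at 30.4375 days/month.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

DAYS_PER_MONTH = 365.25 / 12.0

__all__ = [
    "DAYS_PER_MONTH",
    "DigitizedKM",
    "PseudoIPD",
    "monotonize",
    "reconstruct_ipd",
    "km_step_function",
    "read_digitized",
    "write_ipd",
    "read_ipd",
]


@dataclass
class DigitizedKM:
    """Digitized survival-step coordinates plus the number-at-risk table for one arm/endpoint."""

    arm: str
    endpoint: str
    times_days: np.ndarray
    survival: np.ndarray
    risk_times_days: np.ndarray
    n_risk: np.ndarray
    total_events_reported: int | None = None

    def __post_init__(self) -> None:
        self.times_days = np.asarray(self.times_days, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        self.risk_times_days = np.asarray(self.risk_times_days, dtype=float)
        self.n_risk = np.asarray(self.n_risk, dtype=int)
        if self.times_days.shape != self.survival.shape:
            raise ValueError("times_days and survival must have equal length")
        if self.risk_times_days.shape != self.n_risk.shape:
            raise ValueError("risk_times_days and n_risk must have equal length")
        if np.any(np.diff(self.times_days) < 0):
            raise ValueError("times_days must be sorted ascending")
        if np.any(np.diff(self.n_risk) > 0):
            raise ValueError("n_risk must be non-increasing")


@dataclass
class PseudoIPD:
    """Reconstructed or simulated (time, event) survival records."""

    times_days: np.ndarray
    events: np.ndarray
    arm: str = ""
    endpoint: str = ""

    def __post_init__(self) -> None:
        self.times_days = np.asarray(self.times_days, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        if self.times_days.shape != self.events.shape:
            raise ValueError("times and events must have equal length")
        if np.any(self.times_days < 0):
            raise ValueError("negative survival times")
        if not np.isin(self.events, (0, 1)).all():
            raise ValueError("events must be 0/1")

    def __len__(self) -> int:
        return len(self.times_days)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_days": self.times_days, "event": self.events})


def monotonize(curve: DigitizedKM, clip_tol: float = 0.01) -> DigitizedKM:
    """Repair digitization noise: clip to [0, 1], force S(0)=1, enforce running minimum.

    Values outside [-clip_tol, 1 + clip_tol] are treated as corrupt input.
    """
    s = np.asarray(curve.survival, dtype=float)
    if np.any(s < -clip_tol) or np.any(s > 1.0 + clip_tol):
        raise ValueError("survival values outside [0, 1] beyond clip tolerance")
    s = np.clip(s, 0.0, 1.0)
    if len(s) and curve.times_days[0] == 0.0:
        s[0] = 1.0
    s = np.minimum.accumulate(s)
    return replace(curve, survival=s)


def km_step_function(times: np.ndarray, survival: np.ndarray):
    """Right-continuous step interpolator S(t) for KM coordinates (S=1 before the first time)."""
    times = np.asarray(times, dtype=float)
    survival = np.asarray(survival, dtype=float)

    def step(t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(times, t, side="right") - 1
        out = np.where(idx >= 0, survival[np.clip(idx, 0, len(times) - 1)], 1.0)
        return out if out.ndim else float(out)

    return step


def _interval_counts(
    S: np.ndarray, n_start: float, n_censor: int, k_slice: slice, t: np.ndarray,
    t_lo: float, t_hi: float,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Walk the digitized steps of one risk interval with a fixed censoring total.

    Censor times are spread uniformly on (t_lo, t_hi); events at each step are
    chosen so the reconstructed KM matches the digitized ratio, rounding to
    integers with the fractional remainder carried to the next step so the
    cumulative event count is preserved.
    Returns (events per step, censor times, n at risk at interval end).
    """
    ks = np.arange(k_slice.start, k_slice.stop)
    if n_censor > 0:
        cens_times = t_lo + (np.arange(1, n_censor + 1)) * (t_hi - t_lo) / (n_censor + 1)
    else:
        cens_times = np.empty(0)
    # bucket 0: censors before the first step; bucket j+1: censors after step j
    edges = np.concatenate([[t_lo - 1e-9], t[ks], [t_hi + 1e-9]])
    edges = np.maximum.accumulate(edges)
    cbuckets = np.histogram(cens_times, bins=edges)[0] if len(ks) else np.array([n_censor])

    d = np.zeros(len(ks))
    n = float(n_start) - cbuckets[0]
    s_prev = S[ks[0] - 1] if len(ks) and ks[0] > 0 else 1.0
    carry = 0.0
    for j, k in enumerate(ks):
        if s_prev > 0 and n > 0:
            frac = n * (1.0 - S[k] / s_prev) + carry
        else:
            frac = carry
        dj = max(0.0, min(np.round(frac), n))
        carry = frac - dj
        d[j] = dj
        if n > 0 and dj < n:
            s_prev = s_prev * (1.0 - dj / n)
        elif dj >= n and n > 0:
            s_prev = 0.0
        n = n - dj - cbuckets[j + 1]
        n = max(n, 0.0)
    return d, cens_times, n


def reconstruct_ipd(
    curve: DigitizedKM,
    use_reported_events: bool = True,
    max_iter: int = 60,
) -> PseudoIPD:
    """Reconstruct pseudo-IPD from a digitized KM curve by the Guyot iterative algorithm.

    Within each interval between consecutive risk-table times, a censoring
    total is guessed from the survival drop, spread uniformly over the
    interval, and adjusted iteratively until the implied number at risk at the
    next risk time matches the reported one.  After the last risk time, no
    censoring is assumed unless ``total_events_reported`` is available to pin
    the final event count (``use_reported_events``).

    Parameters
    ----------
    curve : monotonized digitized KM curve with >= 2 risk-table entries
            (a baseline-only table falls back to the no-censoring assumption).
    """
    curve = monotonize(curve)
    t, S = curve.times_days, curve.survival
    if len(t) == 0:
        raise ValueError("empty digitized curve")
    rt, R = curve.risk_times_days, curve.n_risk
    if len(rt) == 0:
        raise ValueError("empty risk table")
    if np.any(np.diff(R) > 0):
        raise ValueError("inconsistent risk table: n_risk increases")

    # index of first digitized step at/after each risk time
    lower = np.searchsorted(t, rt, side="left")
    # sentinel interval from last risk time to last digitized time
    bounds = list(zip(lower[:-1], lower[1:])) + [(lower[-1], len(t))]

    times_ev: list[float] = []
    times_cn: list[float] = []
    n_at = float(R[0])

    for i, (lo, hi) in enumerate(bounds):
        is_last = i == len(bounds) - 1
        t_lo = rt[i]
        t_hi = t[-1] if is_last else rt[i + 1]
        ks = slice(lo, hi)
        s_lo = S[lo - 1] if lo > 0 else 1.0
        s_hi = S[hi - 1] if hi > 0 else 1.0
        if not is_last:
            target = float(R[i + 1])
            # initial censoring guess from the survival drop over the interval
            nc = int(round(n_at * (s_hi / s_lo if s_lo > 0 else 0.0) - target)) if s_lo > 0 else 0
            nc = max(nc, 0)
            best = None
            for _ in range(max_iter):
                d, c, n_end = _interval_counts(S, n_at, nc, ks, t, t_lo, t_hi)
                diff = n_end - target
                if best is None or abs(diff) < abs(best[3]):
                    best = (d, c, n_end, diff, nc)
                if abs(diff) < 0.5:
                    break
                step = int(round(diff)) or int(np.sign(diff))
                nc = max(0, nc + step)
            d, c, n_end, diff, nc = best
            if abs(diff) >= 2.0:
                raise RuntimeError(
                    f"Guyot reconstruction did not converge in interval {i} "
                    f"(residual at-risk mismatch {diff:+.1f})"
                )
        else:
            nc = 0
            if use_reported_events and curve.total_events_reported is not None:
                # adjust last-interval censoring toward the reported event total
                remaining = curve.total_events_reported - len(times_ev)
                best = None
                for nc_try in range(0, int(n_at) + 1):
                    d, c, n_end = _interval_counts(S, n_at, nc_try, ks, t, t_lo, t_hi)
                    diff = d.sum() - remaining
                    if best is None or abs(diff) < abs(best[3]):
                        best = (d, c, n_end, diff, nc_try)
                    if diff <= 0 and nc_try > 0:
                        break
                d, c, n_end, _, nc = best
            else:
                d, c, n_end = _interval_counts(S, n_at, nc, ks, t, t_lo, t_hi)

        for j, k in enumerate(range(lo, hi)):
            times_ev.extend([t[k]] * int(d[j]))
        times_cn.extend(np.asarray(c).tolist())
        n_at = n_end
        if is_last and n_at > 0.5:
            # patients still at risk at the last digitized time: administratively censored
            times_cn.extend([t[-1]] * int(round(n_at)))
            n_at = 0.0

    times = np.array(times_ev + times_cn)
    events = np.array([1] * len(times_ev) + [0] * len(times_cn))
    order = np.argsort(times, kind="stable")
    return PseudoIPD(times[order], events[order], arm=curve.arm, endpoint=curve.endpoint)


# ---------------------------------------------------------------------------
# delimited-text I/O (same schema as synthetic_trial writes)

def read_digitized(curve_path, risk_path, arm: str = "", endpoint: str = "",
                   total_events_reported: int | None = None) -> DigitizedKM:
    cf = pd.read_csv(curve_path)
    rf = pd.read_csv(risk_path)
    return DigitizedKM(
        arm=arm, endpoint=endpoint,
        times_days=cf["time_days"].to_numpy(),
        survival=cf["survival"].to_numpy(),
        risk_times_days=rf["time_days"].to_numpy(),
        n_risk=rf["n_risk"].to_numpy(),
        total_events_reported=total_events_reported,
    )


def write_ipd(ipd: PseudoIPD, path) -> None:
    ipd.to_frame().to_csv(path, index=False)


def read_ipd(path, arm: str = "", endpoint: str = "") -> PseudoIPD:
    df = pd.read_csv(path)
    return PseudoIPD(df["time_days"].to_numpy(), df["event"].to_numpy(), arm, endpoint)
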