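"""Per-physician response metrics: response rate and winsorized response time.

For physician P_i receiving N consultation requests of which N_R were
answered, the response rate is R = N_R / N.  The mean response time is
S_T / N_R where S_T sums the (winsorized) response times of the answered
requests.  Winsorization clamps each time to the corpus-level 5th/95th
percentile bounds so that a handful of instant or week-long replies do not
dominate the mean.

Quantiles use the linear-interpolation definition (numpy's default), so the
bounds are reproducible from the stated fractions alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PhysicianStats",
    "WinsorBounds",
    "fit_winsor_bounds",
    "winsorize",
    "compute_physician_stats",
    "global_mean_response_time",
]


@dataclass(frozen=True)
class WinsorBounds:
    """Clamping bounds in minutes; lower_min <= upper_min."""

    lower_min: float
    upper_min: float

    def __post_init__(self) -> None:
        if self.lower_min > self.upper_min:
            raise ValueError("lower_min must not exceed upper_min")


@dataclass(frozen=True)
class PhysicianStats:
    """Response behaviour of one physician.

    ``mean_response_time_min`` is None exactly when the physician answered
    nothing (N_R = 0).
    """

    physician_code: str
    n_total: int
    n_responded: int
    response_rate: float
    total_response_time_min: float
    mean_response_time_min: float | None


def fit_winsor_bounds(
    times_min, lower_q: float = 0.05, upper_q: float = 0.95
) -> WinsorBounds:
    """Empirical quantile bounds of a sample of response times (minutes)."""
    times = np.asarray(list(times_min), dtype=float)
    if times.size == 0:
        raise ValueError("cannot fit winsor bounds on empty times")
    if not (0.0 <= lower_q < upper_q <= 1.0):
        raise ValueError("require 0 <= lower_q < upper_q <= 1")
    lo, hi = np.quantile(times, [lower_q, upper_q], method="linear")
    return WinsorBounds(lower_min=float(lo), upper_min=float(hi))


def winsorize(t_min: float, bounds: WinsorBounds) -> float:
    """Clamp a response time into [lower_min, upper_min]; idempotent."""
    if t_min < 0:
        raise ValueError("response time must be non-negative")
    return float(min(max(t_min, bounds.lower_min), bounds.upper_min))


def compute_physician_stats(
    records, bounds: WinsorBounds | None = None
) -> dict[str, PhysicianStats]:
    """Response rate and winsorized mean response time per physician.

    One entry per physician appearing in ``records``.  When ``bounds`` is
    given, each response time is winsorized before summation into S_T.
    """
    n_total: dict[str, int] = {}
    n_resp: dict[str, int] = {}
    s_t: dict[str, float] = {}
    for r in records:
        code = r.physician_code
        n_total[code] = n_total.get(code, 0) + 1
        if r.response_status:
            n_resp[code] = n_resp.get(code, 0) + 1
            if r.response_time_min is not None:
                t = r.response_time_min
                if bounds is not None:
                    t = winsorize(t, bounds)
                s_t[code] = s_t.get(code, 0.0) + t
    out = {}
    for code, n in n_total.items():
        nr = n_resp.get(code, 0)
        st = s_t.get(code, 0.0)
        out[code] = PhysicianStats(
            physician_code=code,
            n_total=n,
            n_responded=nr,
            response_rate=nr / n,
            total_response_time_min=st,
            mean_response_time_min=(st / nr) if nr > 0 else None,
        )
    return out


def global_mean_response_time(
    records, bounds: WinsorBounds | None = None
) -> float:
    """Corpus-level mean of (winsorized) per-request response times.

    Averaged over all answered requests — not the mean of per-physician
    means — this is the reference against which the service-quality metric
    classifies a physician as fast.
    """
    total = 0.0
    n = 0
    for r in records:
        if r.response_status and r.response_time_min is not None:
            t = r.response_time_min
            if bounds is not None:
                t = winsorize(t, bounds)
            total += t
            n += 1
    if n == 0:
        raise ValueError("no responded records with response times")
    return total / n
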