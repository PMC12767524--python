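"""Paused Pol II selection, half-life fitting and quintile binning.

Promoter-proximal paused Pol II leaves a strong stranded footprint just
downstream of the TSS.  After blocking initiation, the paused signal
decays approximately exponentially; fitting s(t) = s0 * 2**(-t/h) to a
time course yields the pausing half-life h, floored at 60 min to suppress
noise-inflated estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .coverage import ProfileMatrix

__all__ = [
    "PausingPromoter",
    "HalfLifeEstimate",
    "select_paused_promoters",
    "fit_half_life",
    "assign_quintiles",
]


@dataclass
class PausingPromoter:
    promoter_id: str
    avg_signal: float
    pos_max_offset: int
    neg_max_offset: int
    passes_filters: bool
    pass_signal: bool
    pass_footprint: bool
    pass_position: bool

    @property
    def pause_position(self) -> float:
        return (self.pos_max_offset + self.neg_max_offset) / 2.0


@dataclass
class HalfLifeEstimate:
    promoter_id: str
    half_life_min: float
    floored: bool
    s0: float
    fit_rss: float
    fallback: bool = False
    quintile: int | None = None


def select_paused_promoters(
    matrix: ProfileMatrix,
    min_avg_signal: float = 20.0,
    max_strand_distance: int = 80,
    max_downstream: int = 80,
    signal_window: tuple[int, int] = (-50, 50),
) -> list[PausingPromoter]:
    """Apply the three paused-promoter filters to a Pol II profile matrix.

    A promoter passes when 1) its average per-base signal (both strands,
    over ``signal_window``) exceeds ``min_avg_signal``, 2) the distance
    from the positive- to the negative-strand maximum is in (0,
    ``max_strand_distance``), and 3) the pause position (midpoint of the
    strand maxima) is less than ``max_downstream`` bp downstream of the
    TSS.  All three flags are recorded per promoter.
    """
    sl = matrix.window_slice(*signal_window)
    offsets = matrix.offsets
    results = []
    n_positions = sl.stop - sl.start
    for i, pid in enumerate(matrix.promoter_ids):
        pos = matrix.sense_positive[i]
        neg = matrix.sense_negative[i]
        avg = (pos[sl].sum() + neg[sl].sum()) / n_positions
        pos_max = int(offsets[np.argmax(pos)])
        neg_max = int(offsets[np.argmax(neg)])
        pause_pos = (pos_max + neg_max) / 2.0
        pass_signal = avg > min_avg_signal
        pass_footprint = 0 < (neg_max - pos_max) < max_strand_distance
        pass_position = pause_pos < max_downstream
        results.append(
            PausingPromoter(
                promoter_id=pid,
                avg_signal=float(avg),
                pos_max_offset=pos_max,
                neg_max_offset=neg_max,
                passes_filters=pass_signal and pass_footprint and pass_position,
                pass_signal=pass_signal,
                pass_footprint=pass_footprint,
                pass_position=pass_position,
            )
        )
    return results


def pause_window_signal(
    matrix: ProfileMatrix, pause_position: float, half_width: int = 25
) -> np.ndarray:
    """Per-promoter both-strand signal in a window centered on the pause
    position (51 bp at the default half-width)."""
    center = int(round(pause_position))
    lo = max(center - half_width, -matrix.window_half_width)
    hi = min(center + half_width, matrix.window_half_width)
    sl = matrix.window_slice(lo, hi)
    return matrix.sense_positive[:, sl].sum(axis=1) + matrix.sense_negative[:, sl].sum(axis=1)


def _decay(t: np.ndarray, s0: float, h: float) -> np.ndarray:
    return s0 * np.power(2.0, -t / h)


def fit_half_life(
    timecourse: list[tuple[float, float]],
    floor_min: float = 60.0,
    promoter_id: str = "",
) -> HalfLifeEstimate:
    """Least-squares fit of s(t) = s0 * 2**(-t/h) to a decay time course.

    The fit is initialized from the closed-form log-linear regression of
    log2(s) on t and refined by bounded nonlinear least squares; if the
    refinement fails the log-linear estimate is kept (flagged).  Fitted
    half-lives above ``floor_min`` are floored there with ``floored``
    set, eliminating noise-inflated values.
    """
    tc = sorted(timecourse)
    if len(tc) < 3:
        raise ValueError("need >= 3 timepoints")
    t = np.array([p[0] for p in tc], dtype=float)
    s = np.array([p[1] for p in tc], dtype=float)
    if 0.0 not in t:
        raise ValueError("time course must include t = 0")
    if np.any(s < 0):
        raise ValueError("negative signal")
    if np.all(s == 0):
        raise ValueError("all-zero signal")

    # log-linear initialization on the positive part of the decay
    positive = s > 0
    if positive.sum() >= 2 and np.ptp(t[positive]) > 0:
        slope, intercept = np.polyfit(t[positive], np.log2(s[positive]), 1)
        h0 = -1.0 / slope if slope < 0 else floor_min * 10
        s0_init = float(2.0**intercept)
    else:
        h0, s0_init = floor_min, float(s.max())
    h0 = float(np.clip(h0, 1e-3, 1e6))

    fallback = False
    try:
        popt, _ = curve_fit(
            _decay,
            t,
            s,
            p0=[max(s0_init, 1e-12), h0],
            bounds=([1e-12, 1e-6], [np.inf, np.inf]),
            maxfev=10000,
        )
        s0_hat, h_hat = float(popt[0]), float(popt[1])
    except RuntimeError:
        s0_hat, h_hat = s0_init, h0
        fallback = True
    rss = float(np.sum((s - _decay(t, s0_hat, h_hat)) ** 2))
    floored = h_hat > floor_min
    if floored:
        h_hat = floor_min
    return HalfLifeEstimate(
        promoter_id=promoter_id,
        half_life_min=h_hat,
        floored=floored,
        s0=s0_hat,
        fit_rss=rss,
        fallback=fallback,
    )


def assign_quintiles(estimates: list[HalfLifeEstimate]) -> list[HalfLifeEstimate]:
    """Rank promoters by half-life (ascending) and split into 5 bins.

    With n = 5q + r, the r extra promoters go to the outermost bins first
    (bins 1 and 5, then 2 and 4), so n = 1307 gives sizes
    (262, 261, 261, 261, 262).  Ties in half-life break by promoter id.
    """
    n = len(estimates)
    if n < 5:
        raise ValueError("need >= 5 promoters")
    base, r = divmod(n, 5)
    sizes = [base] * 5
    for bin_idx in (0, 4, 1, 3):
        if r == 0:
            break
        sizes[bin_idx] += 1
        r -= 1
    order = sorted(
        range(n), key=lambda i: (estimates[i].half_life_min, estimates[i].promoter_id)
    )
    bounds = np.cumsum([0] + sizes)
    for q in range(5):
        for i in order[bounds[q] : bounds[q + 1]]:
            estimates[i].quintile = q + 1
    return estimates


def estimates_to_frame(estimates: list[HalfLifeEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "promoter_id": [e.promoter_id for e in estimates],
            "half_life_min": [e.half_life_min for e in estimates],
            "floored": [e.floored for e in estimates],
            "quintile": [e.quintile for e in estimates],
            "rss": [e.fit_rss for e in estimates],
        }
    )
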