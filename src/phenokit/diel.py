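"""Diel gas-exchange and stomatal analysis.

Summarises a day/night (diel) net CO₂ assimilation trace into per-day phase
statistics, detects the C₃→CAM transition by the nocturnal-assimilation
criterion, flags the dawn/dusk anticipation transients characteristic of CAM
gas exchange, and computes stomatal aperture statistics with day/night
inversion detection.

Conventions
-----------
* A night belongs to the day it begins in: "day 8's night" is the dark period
  following day 8's light period.
* CAM onset is the first day whose nightly mean assimilation reaches a
  threshold, default −0.1 μmol m⁻² s⁻¹ — a tolerant reading of "almost zero"
  nocturnal exchange that still rejects a −1 C₃ baseline.
* Stomata are classed open at aperture ≥ 1.4 μm, the midpoint between the
  closed-state ceiling (1.1 μm) and the open-state floor (1.7 μm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DielTrace",
    "PhaseSummary",
    "TransitionReport",
    "EdgeReport",
    "phase_summaries",
    "detect_cam_onset",
    "detect_anticipation",
    "aperture_stats",
    "detect_inversion",
    "TraceGapError",
]

DEFAULT_ONSET_THRESHOLD = -0.1
DEFAULT_OPEN_THRESHOLD = 1.4
TIMEPOINTS = ("4pm", "4am")


class TraceGapError(ValueError):
    """Trace has sampling gaps beyond tolerance."""


@dataclass
class DielTrace:
    """A logged net-assimilation time series with its light schedule.

    ``time`` is seconds since experiment start (strictly increasing),
    ``assimilation`` is net CO₂ exchange in μmol m⁻² s⁻¹, ``light_on`` the
    schedule-derived light state per sample, and ``day_index`` the 1-based
    day each sample belongs to (days start at lights-on).
    """

    time: np.ndarray
    assimilation: np.ndarray
    light_on: np.ndarray
    day_index: np.ndarray
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.assimilation = np.asarray(self.assimilation, float)
        self.light_on = np.asarray(self.light_on, bool)
        self.day_index = np.asarray(self.day_index, int)
        n = len(self.time)
        if not (len(self.assimilation) == len(self.light_on) == len(self.day_index) == n):
            raise ValueError("trace arrays must have equal length")
        if n > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time)

    def validate_gaps(self, tolerance_factor: float = 2.0) -> None:
        """Raise TraceGapError listing intervals larger than tolerance.

        Tolerance is ``tolerance_factor`` times the median sampling interval.
        """
        if len(self.time) < 3:
            return
        dt = np.diff(self.time)
        tol = tolerance_factor * float(np.median(dt))
        bad = np.nonzero(dt > tol)[0]
        if bad.size:
            gaps = [(float(self.time[i]), float(self.time[i + 1])) for i in bad[:10]]
            raise TraceGapError(
                f"{bad.size} sampling gap(s) exceed {tol:.1f} s; first: {gaps}"
            )

    @classmethod
    def from_samples(cls, time, assimilation, light_hours: float = 12.0,
                     dark_hours: float = 12.0, truth: dict | None = None
                     ) -> "DielTrace":
        """Build a trace from times and values under a fixed photoperiod.

        Samples are assigned light state and day index from the schedule:
        each 24 h cycle starts with ``light_hours`` of light at t = 0.
        """
        time = np.asarray(time, float)
        period = (light_hours + dark_hours) * 3600.0
        tod = np.mod(time, period)
        light_on = tod < light_hours * 3600.0
        day_index = (time // period).astype(int) + 1
        return cls(time, np.asarray(assimilation, float), light_on, day_index,
                   truth=truth or {})


@dataclass
class PhaseSummary:
    """Day/night statistics of one diel cycle."""

    day_index: int
    day_mean: float
    day_max: float
    day_min: float
    night_mean: float
    night_max: float
    night_min: float
    n_day: int
    n_night: int


@dataclass
class TransitionReport:
    """Outcome of the nocturnal-assimilation CAM-onset scan."""

    onset_day: int | None
    threshold: float
    nightly_means: dict[int, float]
    criterion: str = "first day with nightly mean assimilation >= threshold"


def phase_summaries(trace: DielTrace, gap_tolerance: float = 2.0
                    ) -> list[PhaseSummary]:
    """Per-day day/night phase statistics.

    Every sample lands in exactly one (day, phase) cell; a day with no light
    or no dark samples reports that phase with n = 0 and NaN statistics are
    never emitted (the day is included only for phases it has samples in —
    both phases are present for complete diel cycles).
    """
    trace.validate_gaps(gap_tolerance)
    out = []
    for day in np.unique(trace.day_index):
        sel = trace.day_index == day
        day_vals = trace.assimilation[sel & trace.light_on]
        night_vals = trace.assimilation[sel & ~trace.light_on]
        if day_vals.size == 0 and night_vals.size == 0:
            continue
        out.append(PhaseSummary(
            day_index=int(day),
            day_mean=float(day_vals.mean()) if day_vals.size else float("nan"),
            day_max=float(day_vals.max()) if day_vals.size else float("nan"),
            day_min=float(day_vals.min()) if day_vals.size else float("nan"),
            night_mean=float(night_vals.mean()) if night_vals.size else float("nan"),
            night_max=float(night_vals.max()) if night_vals.size else float("nan"),
            night_min=float(night_vals.min()) if night_vals.size else float("nan"),
            n_day=int(day_vals.size),
            n_night=int(night_vals.size),
        ))
    return out


def detect_cam_onset(summaries: list[PhaseSummary],
                     threshold: float = DEFAULT_ONSET_THRESHOLD
                     ) -> TransitionReport:
    """First day whose nightly mean assimilation reaches ``threshold``.

    Nocturnal CO₂ uptake approaching (or exceeding) zero is the gas-exchange
    signature of CAM induction; ``onset_day`` is None when no night
    qualifies.
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 days of summaries to scan for onset")
    nightly = {s.day_index: s.night_mean for s in summaries if s.n_night > 0}
    onset = None
    for day in sorted(nightly):
        if nightly[day] >= threshold:
            onset = day
            break
    return TransitionReport(onset_day=onset, threshold=threshold,
                            nightly_means=nightly)


@dataclass
class EdgeReport:
    """Assimilation behaviour across the light-on and light-off edges."""

    day_index: int
    light_on_delta: float       # mean(first light window) - mean(last dark window)
    light_off_delta: float      # mean(first dark window) - mean(last light window)
    pre_dawn_min: float
    post_dawn_max: float
    pre_dusk_max: float
    post_dusk_min: float
    cam_like: bool


def _smoothed(values: np.ndarray, block: int) -> np.ndarray:
    """Rolling mean over ``block`` samples (valid mode); raw if too short."""
    if block <= 1 or values.size < block:
        return values
    kernel = np.full(block, 1.0 / block)
    return np.convolve(values, kernel, mode="valid")


def detect_anticipation(trace: DielTrace, day: int,
                        window_s: float = 15 * 60.0,
                        smooth_s: float = 150.0) -> EdgeReport:
    """Dawn/dusk transient analysis for one day.

    Compares the 15 min before vs after the light-on edge of ``day`` and the
    light-off edge within it.  The "CAM-like" flag fires when the dawn
    transient spans from below −2 to above +2 μmol m⁻² s⁻¹ — the burst of
    stored-CO₂ turnover seen once the plant runs CAM.  Window extremes are
    taken on a ``smooth_s``-second rolling mean (default 2.5 min) so a single
    noisy 30-s sample cannot fake a transient.
    """
    sel = trace.day_index == day
    if not sel.any():
        raise ValueError(f"day {day} not present in trace")
    light_times = trace.time[sel & trace.light_on]
    dark_times = trace.time[sel & ~trace.light_on]
    if light_times.size == 0 or dark_times.size == 0:
        raise ValueError(f"day {day} lacks a complete light/dark cycle")
    t_on = light_times[0]
    t_off = dark_times[0]

    def window(lo, hi):
        m = (trace.time >= lo) & (trace.time < hi)
        return trace.assimilation[m]

    pre_dawn = window(t_on - window_s, t_on)
    post_dawn = window(t_on, t_on + window_s)
    pre_dusk = window(t_off - window_s, t_off)
    post_dusk = window(t_off, t_off + window_s)
    min_n = 2
    for name, w in [("pre-dawn", pre_dawn), ("post-dawn", post_dawn),
                    ("pre-dusk", pre_dusk), ("post-dusk", post_dusk)]:
        if w.size < min_n:
            raise ValueError(
                f"{name} window of day {day} has {w.size} samples; "
                f"day too short for {window_s:.0f}-s edge windows"
            )
    if len(trace.time) > 1:
        dt = float(np.median(np.diff(trace.time)))
        block = max(1, int(round(smooth_s / dt)))
    else:
        block = 1
    pre_dawn_min = float(_smoothed(pre_dawn, block).min())
    post_dawn_max = float(_smoothed(post_dawn, block).max())
    return EdgeReport(
        day_index=int(day),
        light_on_delta=float(post_dawn.mean() - pre_dawn.mean()),
        light_off_delta=float(post_dusk.mean() - pre_dusk.mean()),
        pre_dawn_min=pre_dawn_min,
        post_dawn_max=post_dawn_max,
        pre_dusk_max=float(_smoothed(pre_dusk, block).max()),
        post_dusk_min=float(_smoothed(post_dusk, block).min()),
        cam_like=bool(pre_dawn_min < -2.0 and post_dawn_max > 2.0),
    )


def aperture_stats(table: pd.DataFrame,
                   open_threshold: float = DEFAULT_OPEN_THRESHOLD
                   ) -> pd.DataFrame:
    """Mean aperture, SE and open proportion per (day, timepoint).

    Open proportion is the plain count division: stomata with aperture ≥
    ``open_threshold`` over all stomata in the cell.  Empty cells are simply
    absent from the output (never NaN rows).
    """
    if not {"day", "timepoint", "aperture_um"}.issubset(table.columns):
        raise ValueError("stomata table needs day, timepoint, aperture_um columns")
    rows = []
    for (day, tp), sub in table.groupby(["day", "timepoint"], sort=True):
        ap = sub["aperture_um"].to_numpy(float)
        if ap.size == 0:
            continue
        se = float(np.std(ap, ddof=1) / np.sqrt(ap.size)) if ap.size > 1 else 0.0
        rows.append({
            "day": day, "timepoint": tp,
            "mean_aperture_um": float(ap.mean()),
            "se": se,
            "open_proportion": float((ap >= open_threshold).sum() / ap.size),
            "n": int(ap.size),
        })
    return pd.DataFrame(rows, columns=["day", "timepoint", "mean_aperture_um",
                                       "se", "open_proportion", "n"])


def detect_inversion(stats: pd.DataFrame) -> int | None:
    """First day whose 4 am mean aperture exceeds the 4 pm mean.

    Nocturnal apertures beating diurnal ones is the stomatal signature of
    CAM.  Days missing either timepoint are not scanned.  Returns None when
    no day inverts.
    """
    pivot = stats.pivot_table(index="day", columns="timepoint",
                              values="mean_aperture_um", aggfunc="mean")
    for day in sorted(pivot.index):
        row = pivot.loc[day]
        if "4am" in row and "4pm" in row and not (pd.isna(row["4am"]) or pd.isna(row["4pm"])):
            if row["4am"] > row["4pm"]:
                return int(day)
    return None
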