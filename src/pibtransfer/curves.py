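"""Core data containers for dynamic PET analysis.

Two measured signals drive every model in this package:

* :class:`PlasmaCurve` — the arterial input function ca(t): tracer activity
  concentration in arterial plasma (or whole blood for the water sessions)
  sampled at discrete times, optionally with the parent (unmetabolized)
  fraction of the measured radioactivity.
* :class:`TimeActivityCurve` — the regional tissue signal m(T): frame-averaged
  activity concentration over a dynamic emission recording.

Both are thin, validated wrappers around numpy arrays with CSV round-tripping
(plain UTF-8, header row, "." decimal).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .exceptions import InvalidInputError

__all__ = ["PlasmaCurve", "TimeActivityCurve", "read_tac_table", "write_tac_table"]


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise InvalidInputError(f"{name} must be a nonempty 1-D array")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class PlasmaCurve:
    """Arterial input function: activity concentration in plasma or blood.

    Parameters
    ----------
    times
        Sample times in minutes post-injection, strictly increasing.
    activity
        Activity concentration in kBq/mL, nonnegative.
    parent_fraction
        Optional unmetabolized (parent) fraction in [0, 1] aligned with
        ``times``; must start at 1 and be nonincreasing.
    tracer_label
        ``"PiB"`` or ``"water"``.
    """

    times: np.ndarray
    activity: np.ndarray
    parent_fraction: np.ndarray | None = None
    tracer_label: str = "PiB"

    def __post_init__(self):
        times = _as_float_array(self.times, "times")
        activity = _as_float_array(self.activity, "activity")
        if times.size != activity.size:
            raise InvalidInputError("times and activity must have equal length")
        if np.any(np.diff(times) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if np.any(activity < 0):
            raise InvalidInputError("activity must be nonnegative")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "activity", activity)
        if self.parent_fraction is not None:
            pf = _as_float_array(self.parent_fraction, "parent_fraction")
            if pf.size != times.size:
                raise InvalidInputError("parent_fraction must align with times")
            if np.any((pf < 0) | (pf > 1)):
                raise InvalidInputError("parent_fraction must lie in [0, 1]")
            if not np.isclose(pf[0], 1.0, atol=1e-9):
                raise InvalidInputError("parent_fraction must equal 1 at the first sample")
            if np.any(np.diff(pf) > 1e-12):
                raise InvalidInputError("parent_fraction must be nonincreasing")
            object.__setattr__(self, "parent_fraction", pf)
        for arr in (self.times, self.activity, self.parent_fraction):
            if arr is not None:
                arr.setflags(write=False)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])

    def interp_activity(self, t) -> np.ndarray:
        """Linear interpolation of ca onto times ``t``."""
        return np.interp(t, self.times, self.activity)

    def cumulative_integral(self) -> np.ndarray:
        """Trapezoidal running integral of ca on the sampling grid, from t[0]."""
        return cumulative_trapezoid(self.activity, self.times, initial=0.0)

    def interp_cumulative(self, t) -> np.ndarray:
        """Cumulative integral of ca interpolated onto times ``t``."""
        return np.interp(t, self.times, self.cumulative_integral())

    def auc(self) -> float:
        """Trapezoidal area under the curve over the full sampling span."""
        return float(np.trapezoid(self.activity, self.times))

    def parent_corrected(self) -> "PlasmaCurve":
        """Return the metabolite-corrected curve: activity x parent fraction."""
        if self.parent_fraction is None:
            raise InvalidInputError("curve has no parent_fraction to apply")
        return PlasmaCurve(
            times=self.times.copy(),
            activity=self.activity * self.parent_fraction,
            parent_fraction=None,
            tracer_label=self.tracer_label,
        )

    def scaled(self, factor: float) -> "PlasmaCurve":
        if factor < 0:
            raise InvalidInputError("scale factor must be nonnegative")
        return replace(self, activity=self.activity * factor)

    def to_csv(self, path) -> None:
        cols = {"time_min": self.times, "activity_kBq_per_mL": self.activity}
        if self.parent_fraction is not None:
            cols["parent_fraction"] = self.parent_fraction
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, tracer_label: str = "PiB") -> "PlasmaCurve":
        df = pd.read_csv(path)
        pf = df["parent_fraction"].to_numpy() if "parent_fraction" in df.columns else None
        return cls(
            times=df["time_min"].to_numpy(),
            activity=df["activity_kBq_per_mL"].to_numpy(),
            parent_fraction=pf,
            tracer_label=tracer_label,
        )


@dataclass(frozen=True)
class TimeActivityCurve:
    """Frame-averaged regional tissue activity m(T) over a dynamic session.

    Frames are contiguous, nonoverlapping and sorted; activity is the
    time-average over each frame in kBq/cm^3 of tissue.
    """

    frame_start: np.ndarray
    frame_end: np.ndarray
    activity: np.ndarray
    region_label: str = "CTX"

    def __post_init__(self):
        start = _as_float_array(self.frame_start, "frame_start")
        end = _as_float_array(self.frame_end, "frame_end")
        activity = np.asarray(self.activity, dtype=float)
        if activity.ndim != 1 or activity.size != start.size or start.size != end.size:
            raise InvalidInputError("frame_start, frame_end and activity must align")
        if not np.all(np.isfinite(activity)):
            raise InvalidInputError("activity contains non-finite values")
        if np.any(end <= start):
            raise InvalidInputError("frame_end must exceed frame_start for every frame")
        if np.any(start[1:] < end[:-1] - 1e-9):
            raise InvalidInputError("frames must be sorted and nonoverlapping")
        object.__setattr__(self, "frame_start", start)
        object.__setattr__(self, "frame_end", end)
        object.__setattr__(self, "activity", activity)
        for arr in (self.frame_start, self.frame_end, self.activity):
            arr.setflags(write=False)

    @property
    def mid_times(self) -> np.ndarray:
        return 0.5 * (self.frame_start + self.frame_end)

    @property
    def durations(self) -> np.ndarray:
        return self.frame_end - self.frame_start

    @property
    def span(self) -> tuple[float, float]:
        return float(self.frame_start[0]), float(self.frame_end[-1])


def write_tac_table(tacs: dict[str, TimeActivityCurve], path) -> None:
    """Write regional TACs sharing one frame schedule as a single CSV.

    Columns: ``frame_start_min, frame_end_min, <region>...``.
    """
    regions = list(tacs)
    if not regions:
        raise InvalidInputError("no TACs to write")
    first = tacs[regions[0]]
    cols = {"frame_start_min": first.frame_start, "frame_end_min": first.frame_end}
    for name in regions:
        tac = tacs[name]
        if not np.allclose(tac.frame_start, first.frame_start) or not np.allclose(
            tac.frame_end, first.frame_end
        ):
            raise InvalidInputError("all regions must share one frame schedule")
        cols[name] = tac.activity
    pd.DataFrame(cols).to_csv(path, index=False)


def read_tac_table(path) -> dict[str, TimeActivityCurve]:
    """Read a regional TAC table written by :func:`write_tac_table`."""
    df = pd.read_csv(path)
    start = df["frame_start_min"].to_numpy()
    end = df["frame_end_min"].to_numpy()
    out = {}
    for col in df.columns:
        if col in ("frame_start_min", "frame_end_min"):
            continue
        out[col] = TimeActivityCurve(
            frame_start=start, frame_end=end, activity=df[col].to_numpy(), region_label=col
        )
    return out
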