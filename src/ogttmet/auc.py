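"""Windowed trapezoidal AUC features for oGTT metabolite trajectories.

Each subject's metabolite trajectory over the sampling grid (0, 15, 30, 60,
120 min by default) is summarized as the trapezoid-rule area under the curve
over a set of named time windows. Seven canonical windows are used: the
cumulative 0-15, 0-30, 0-60, 0-120 and the incremental 15-30, 30-60, 60-120
segments, letter-coded A-G for network display. The fasting (0 min) value is
carried along as a covariate for downstream baseline adjustment; AUC here is
total, not baseline-subtracted.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import TimeCourseDataset


@dataclasses.dataclass(frozen=True)
class TimeWindow:
    """A named [start, end] sub-interval of the oGTT sampling grid."""

    start_min: float
    end_min: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.start_min >= self.end_min:
            raise ValueError("window start must precede end")
        if not self.label:
            object.__setattr__(
                self, "label", f"{self.start_min:g}-{self.end_min:g}"
            )


#: The canonical seven analysis windows.
CANONICAL_WINDOWS: tuple[TimeWindow, ...] = (
    TimeWindow(0, 15),
    TimeWindow(0, 30),
    TimeWindow(0, 60),
    TimeWindow(0, 120),
    TimeWindow(15, 30),
    TimeWindow(30, 60),
    TimeWindow(60, 120),
)

#: Display letter per window used in network figures: "A" = 0-15 only, ...,
#: "G" = 60-120.
WINDOW_LETTERS: dict[str, str] = {
    "0-15": "A",
    "0-30": "B",
    "0-60": "C",
    "0-120": "D",
    "15-30": "E",
    "30-60": "F",
    "60-120": "G",
}


def trapezoid_weights(times: np.ndarray, window: TimeWindow) -> np.ndarray:
    """Per-gridpoint quadrature weights of the trapezoid rule on a window.

    The returned vector has one entry per element of ``times``; entries
    outside the window are zero. ``sum(w * y)`` equals the trapezoid AUC of
    the trajectory ``y`` over the window.
    """
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    for endpoint in (window.start_min, window.end_min):
        if not np.isclose(times, endpoint).any():
            raise ValueError(
                f"window endpoint {endpoint:g} min is not on the sampling grid"
            )
    inside = (times >= window.start_min - 1e-9) & (times <= window.end_min + 1e-9)
    idx = np.where(inside)[0]
    w = np.zeros_like(times)
    for a, b in zip(idx[:-1], idx[1:]):
        half = (times[b] - times[a]) / 2.0
        w[a] += half
        w[b] += half
    return w


def trapezoid_auc(
    times: Sequence[float], values: Sequence[float], window: TimeWindow
) -> float:
    """Trapezoid-rule AUC of ``values`` over ``window``.

    Sums ``(t[i+1]-t[i]) * (y[i]+y[i+1]) / 2`` over adjacent grid pairs inside
    the window. Raises if a window endpoint is off the grid or if any value
    inside the window is missing (imputation must precede integration).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.shape != values.shape:
        raise ValueError("times and values must have equal length")
    inside = (times >= window.start_min - 1e-9) & (times <= window.end_min + 1e-9)
    if not np.isfinite(values[inside]).all():
        raise ValueError(
            f"missing/non-finite value inside window {window.label}; impute first"
        )
    idx = np.where(inside)[0]
    t, y = times[idx], values[idx]
    if not (np.isclose(t[0], window.start_min) and np.isclose(t[-1], window.end_min)):
        raise ValueError(
            f"window endpoint not on the sampling grid for {window.label}"
        )
    segs = (t[1:] - t[:-1]) * (y[1:] + y[:-1]) / 2.0
    return float(np.sum(segs))


@dataclasses.dataclass
class AUCFeatureTable:
    """Long-format per-(subject, metabolite, window) AUC features.

    ``table`` columns: subject, group, metabolite, window, auc, time0.
    ``incomplete`` lists (subject, window) pairs dropped because the subject
    lacked a sample at a grid point inside the window.
    """

    table: pd.DataFrame
    incomplete: pd.DataFrame

    def wide(self, window: str) -> pd.DataFrame:
        """Subject x metabolite AUC matrix for one window (plus group/time0 via table)."""
        sub = self.table[self.table["window"] == window]
        return sub.pivot(index="subject", columns="metabolite", values="auc")

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def build_auc_table(
    dataset: TimeCourseDataset,
    windows: Iterable[TimeWindow] = CANONICAL_WINDOWS,
    log10: bool = False,
) -> AUCFeatureTable:
    """Compute the windowed AUC feature table for every study subject.

    With ``log10=True`` trajectories are log10-transformed before
    integration, putting downstream group contrasts on the multiplicative
    scale the rest of the pipeline works on. Subjects missing a grid point
    are excluded from windows containing it and listed in the completeness
    report; NaN intensities on present samples are an error (impute first).
    """
    windows = list(windows)
    subjects, times, cube = dataset.study_array()
    present = ~np.all(np.isnan(cube), axis=2)  # subject x timepoint sample present
    if log10:
        with np.errstate(divide="ignore", invalid="ignore"):
            if np.nanmin(cube) <= 0:
                raise ValueError("log10 requires strictly positive intensities")
            cube = np.log10(cube)
    groups = dataset.subjects()["group"]
    mets = dataset.metabolites
    t0_idx = int(np.argmin(np.abs(times - 0.0)))

    rows: list[pd.DataFrame] = []
    dropped: list[tuple[str, str]] = []
    for win in windows:
        w = trapezoid_weights(times, win)
        needed = w > 0
        ok = present[:, needed].all(axis=1)
        for s_i in np.where(~ok)[0]:
            dropped.append((subjects[s_i], win.label))
        block = cube[ok][:, needed, :]
        if np.isnan(block).any():
            bad = np.argwhere(np.isnan(block))[0]
            raise ValueError(
                f"missing intensity for subject {subjects[int(np.where(ok)[0][bad[0]])]}"
                f" inside window {win.label}; impute before AUC"
            )
        auc = np.tensordot(block, w[needed], axes=([1], [0]))  # subj x met
        sub_ids = [subjects[i] for i in np.where(ok)[0]]
        t0 = cube[ok, t0_idx, :]
        frame = pd.DataFrame(
            {
                "subject": np.repeat(sub_ids, len(mets)),
                "group": np.repeat(groups.loc[sub_ids].to_numpy(), len(mets)),
                "metabolite": np.tile(mets, len(sub_ids)),
                "window": win.label,
                "auc": auc.ravel(),
                "time0": t0.ravel(),
            }
        )
        rows.append(frame)
    table = pd.concat(rows, ignore_index=True)
    incomplete = pd.DataFrame(dropped, columns=["subject", "window"])
    return AUCFeatureTable(table=table, incomplete=incomplete)
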