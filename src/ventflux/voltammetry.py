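"""Voltammetric scan-series processing.

Effluent chemistry is measured as bursts of electrochemical scans on a
cyclic multi-channel schedule: each 30-min interval belongs to one aquarium
channel and contains two 21-scan bursts (one at minute 0, one at minute 15,
~2 s cadence), i.e. 42 measurements. The first scans of an interval carry
over material from the previously sampled channel, so a fixed number of
head scans is discarded before averaging; the retained scans collapse to a
single *interval concentration* per analyte, with below-detection-limit
bookkeeping.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

ANALYTES = ("sulfide", "thiosulfate", "polysulfide")

#: substitution policies for censored (below-detection-limit) scans
CENSOR_POLICIES = ("zero", "half_limit", "limit")


class ScheduleMismatchError(ValueError):
    """A scan's channel disagrees with the scheduled channel for its window."""


@dataclass(frozen=True)
class ScanRecord:
    """One voltammetric measurement of one analyte in one channel."""

    time_s: float
    channel: str
    analyte: str
    concentration_uM: float
    censored: bool = False

    def __post_init__(self) -> None:
        if self.analyte not in ANALYTES:
            raise ValueError(f"unknown analyte {self.analyte!r}")
        if self.time_s < 0:
            raise ValueError("time_s must be >= 0")
        if not self.censored and self.concentration_uM < 0:
            raise ValueError("uncensored concentration must be >= 0")


@dataclass(frozen=True)
class DetectionLimits:
    """Per-analyte detection limits in µM.

    Defaults are the microelectrode limits for total sulfide (0.20 µM),
    polysulfides (0.20 µM) and thiosulfate (30 µM).
    """

    sulfide: float = 0.20
    thiosulfate: float = 30.0
    polysulfide: float = 0.20

    def __post_init__(self) -> None:
        for a in ANALYTES:
            if getattr(self, a) <= 0:
                raise ValueError(f"detection limit for {a} must be > 0")

    def limit(self, analyte: str) -> float:
        if analyte not in ANALYTES:
            raise ValueError(f"unknown analyte {analyte!r}")
        return float(getattr(self, analyte))

    def substitution(self, analyte: str, policy: str = "zero") -> float:
        """Value a censored scan contributes to the interval mean."""
        if policy == "zero":
            return 0.0
        if policy == "half_limit":
            return self.limit(analyte) / 2.0
        if policy == "limit":
            return self.limit(analyte)
        raise ValueError(f"unknown censoring policy {policy!r}")


@dataclass(frozen=True)
class SetSchedule:
    """Channel cycle for one 2-h set: four 30-min intervals.

    Experimental aquaria come first; the last interval is the reference
    channel (control effluent in rate experiments, input water in
    variation experiments).
    """

    channels: tuple[str, str, str, str]
    interval_s: float = 1800.0
    set_duration_s: float = 7200.0

    def __post_init__(self) -> None:
        if len(self.channels) != 4:
            raise ValueError("a set is exactly four 30-min intervals")
        if not math.isclose(self.set_duration_s, 4 * self.interval_s):
            raise ValueError("set duration must be four intervals")

    @property
    def reference_channel(self) -> str:
        return self.channels[-1]

    def channel_at(self, time_s: float) -> str:
        pos = int(time_s // self.interval_s) % 4
        return self.channels[pos]

    def window(self, time_s: float) -> tuple[int, int, float]:
        """(set_index, position_in_set, window_start_s) for a timestamp."""
        idx = int(time_s // self.interval_s)
        return idx // 4, idx % 4, idx * self.interval_s


@dataclass
class Interval:
    """All scans of one channel inside one 30-min window."""

    channel: str
    start_s: float
    duration_s: float = 1800.0
    scans: list[ScanRecord] = field(default_factory=list)
    set_index: int = 0
    position: int = 0
    incomplete: bool = False

    def scans_for(self, analyte: str) -> list[ScanRecord]:
        return [s for s in self.scans if s.analyte == analyte]

    @property
    def analytes(self) -> tuple[str, ...]:
        return tuple(a for a in ANALYTES if any(s.analyte == a for s in self.scans))


@dataclass(frozen=True)
class IntervalConcentration:
    """The single concentration assigned to a 30-min window for one analyte."""

    channel: str
    analyte: str
    start_s: float
    mean_uM: float
    n_used: int
    n_discarded: int
    frac_censored: float
    is_bdl: bool
    set_index: int = 0
    position: int = 0
    incomplete: bool = False

    def reported(self) -> str:
        """Rendered value: 'BDL' when below detection, numeric otherwise."""
        return "BDL" if self.is_bdl else f"{self.mean_uM:.6g}"


def assemble_intervals(
    scans: Sequence[ScanRecord],
    schedule: SetSchedule,
    min_scans: int = 22,
) -> list[Interval]:
    """Partition time-ordered scans into scheduled 30-min channel intervals.

    Scans are binned by timestamp window (cadence jitter tolerated); each
    window's scans must all belong to the channel the schedule places
    there, otherwise a :class:`ScheduleMismatchError` names the offending
    window. Intervals whose scan count per analyte falls below
    ``min_scans`` are flagged incomplete with a warning.
    """
    out: dict[int, Interval] = {}
    for scan in scans:
        set_idx, pos, start = schedule.window(scan.time_s)
        expected = schedule.channels[pos]
        if scan.channel != expected:
            raise ScheduleMismatchError(
                f"scan at t={scan.time_s:.0f}s in window [{start:.0f}, "
                f"{start + schedule.interval_s:.0f})s has channel "
                f"{scan.channel!r} but schedule expects {expected!r}"
            )
        key = int(start // schedule.interval_s)
        iv = out.get(key)
        if iv is None:
            iv = Interval(
                channel=expected,
                start_s=start,
                duration_s=schedule.interval_s,
                set_index=set_idx,
                position=pos,
            )
            out[key] = iv
        iv.scans.append(scan)

    intervals = [out[k] for k in sorted(out)]
    for iv in intervals:
        iv.scans.sort(key=lambda s: s.time_s)
        counts = [len(iv.scans_for(a)) for a in iv.analytes]
        if counts and min(counts) < min_scans:
            iv.incomplete = True
            warnings.warn(
                f"interval {iv.channel} @ {iv.start_s:.0f}s has only "
                f"{min(counts)} scans (< {min_scans}); flagged incomplete",
                stacklevel=2,
            )
    return intervals


def interval_concentration(
    interval: Interval,
    analyte: str,
    limits: DetectionLimits | None = None,
    discard_n: int = 10,
    censor_policy: str = "zero",
) -> IntervalConcentration:
    """Average an interval's retained scans into one concentration.

    The first ``discard_n`` scans (time order) are removed as transitory;
    censored scans among the remainder contribute the substitution value
    set by ``censor_policy``. The result is flagged below detection limit
    when the mean falls under the analyte's limit.
    """
    limits = limits or DetectionLimits()
    scans = interval.scans_for(analyte)
    if not scans:
        raise ValueError(f"analyte {analyte!r} absent from interval")
    if len(scans) < discard_n + 1:
        raise ValueError(
            f"interval has {len(scans)} {analyte} scans; need > {discard_n}"
        )
    retained = scans[discard_n:]
    sub = limits.substitution(analyte, censor_policy)
    values = [sub if s.censored else s.concentration_uM for s in retained]
    mean = sum(values) / len(values)
    n_censored = sum(1 for s in retained if s.censored)
    return IntervalConcentration(
        channel=interval.channel,
        analyte=analyte,
        start_s=interval.start_s,
        mean_uM=mean,
        n_used=len(retained),
        n_discarded=discard_n,
        frac_censored=n_censored / len(retained),
        is_bdl=mean < limits.limit(analyte),
        set_index=interval.set_index,
        position=interval.position,
        incomplete=interval.incomplete,
    )


def discard_fraction(total_scans: int, discard_n: int) -> int:
    """Percent of scans discarded, rounded half-up to the nearest integer.

    E.g. discarding 10 of 42 scans is 23.8% -> 24%.
    """
    if total_scans == 0:
        raise ValueError("total_scans must be > 0")
    if not 0 <= discard_n <= total_scans:
        raise ValueError("discard_n must be in [0, total_scans]")
    return int(math.floor(100.0 * discard_n / total_scans + 0.5))


# ---------------------------------------------------------------------------
# CSV interfaces

SCAN_COLUMNS = ["time_s", "channel", "analyte", "concentration_uM", "censored"]


def read_scans(path) -> list[ScanRecord]:
    """Read a tidy scan CSV (one row per scan per analyte).

    Lines starting with '#' (e.g. a seed header) are ignored.
    """
    df = pd.read_csv(path, comment="#")
    missing = set(SCAN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"scan CSV missing columns: {sorted(missing)}")
    return [
        ScanRecord(
            time_s=float(r.time_s),
            channel=str(r.channel),
            analyte=str(r.analyte),
            concentration_uM=float(r.concentration_uM),
            censored=bool(int(r.censored)),
        )
        for r in df.itertuples(index=False)
    ]


def intervals_to_frame(ics: Iterable[IntervalConcentration]) -> pd.DataFrame:
    rows = [
        {
            "channel": ic.channel,
            "analyte": ic.analyte,
            "set_index": ic.set_index,
            "interval_index": ic.position,
            "start_s": ic.start_s,
            "mean_uM": ic.mean_uM,
            "is_bdl": int(ic.is_bdl),
            "n_used": ic.n_used,
            "n_discarded": ic.n_discarded,
            "frac_censored": ic.frac_censored,
        }
        for ic in ics
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "channel", "analyte", "set_index", "interval_index", "start_s",
            "mean_uM", "is_bdl", "n_used", "n_discarded", "frac_censored",
        ],
    )


def frame_to_concentrations(df: pd.DataFrame) -> list[IntervalConcentration]:
    """Inverse of :func:`intervals_to_frame` (for CLI round-trips)."""
    return [
        IntervalConcentration(
            channel=str(r.channel),
            analyte=str(r.analyte),
            start_s=float(r.start_s),
            mean_uM=float(r.mean_uM),
            n_used=int(r.n_used),
            n_discarded=int(r.n_discarded),
            frac_censored=float(r.frac_censored),
            is_bdl=bool(int(r.is_bdl)),
            set_index=int(r.set_index),
            position=int(r.interval_index),
        )
        for r in df.itertuples(index=False)
    ]
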