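"""DAM activity-monitor reading and sleep-bout analysis.

Drosophila Activity Monitors (Trikinetics) record infrared beam crossings in
one-minute bins, 32 channels (flies) per monitor.  Fly sleep is defined as
five or more consecutive minutes without any beam crossing; a *sleep bout*
is a maximal run of zero-count minutes with length >= 5.

Conventions
-----------
* Analysis starts at the first midnight after recording begins; earlier
  minutes are treated as acclimation and trimmed.
* A bout spanning the day/night boundary contributes its minutes to each
  phase's sleep proportion, but is counted once, in the phase holding the
  majority of its minutes.  This conserves total sleep time.
* Bouts touching the trace start or end are kept (and flagged); dropping
  them would bias bout length downward.
* The activity-to-sleep-bout-length ratio is defined here as
  (mean counts per waking minute) / (mean sleep bout length in minutes).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import statcore

MIN_BOUT_MIN = 5

__all__ = [
    "ActivityTrace",
    "SleepBout",
    "SleepSummary",
    "read_dam",
    "write_dam",
    "detect_sleep_bouts",
    "summarize_sleep",
    "analyze_trace",
    "compare_sleep_groups",
]


def _parse_clock(s) -> dt.time:
    if isinstance(s, dt.time):
        return s
    h, m = str(s).split(":")[:2]
    return dt.time(int(h), int(m))


@dataclass
class ActivityTrace:
    """Minute-binned activity counts for one fly plus its light schedule."""

    fly_id: str
    start: pd.Timestamp
    counts: np.ndarray
    lights_on: dt.time = dt.time(8, 0)
    lights_off: dt.time = dt.time(20, 0)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts < 0):
            raise ValueError("activity counts must be >= 0")
        self.lights_on = _parse_clock(self.lights_on)
        self.lights_off = _parse_clock(self.lights_off)

    @property
    def n_minutes(self) -> int:
        return int(self.counts.size)

    def minute_times(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=self.n_minutes, freq="min")

    def day_mask(self) -> np.ndarray:
        """True for minutes with lights on (day phase)."""
        t = self.minute_times()
        minutes = t.hour * 60 + t.minute
        on = self.lights_on.hour * 60 + self.lights_on.minute
        off = self.lights_off.hour * 60 + self.lights_off.minute
        if on <= off:
            return (minutes >= on) & (minutes < off)
        return (minutes >= on) | (minutes < off)

    def trimmed_to_midnight(self) -> "ActivityTrace":
        """Drop acclimation minutes before the first midnight on or after start."""
        start = self.start
        if start == start.normalize():
            return self
        first_mid = (start + pd.Timedelta(days=1)).normalize()
        skip = int((first_mid - start).total_seconds() // 60)
        if skip >= self.n_minutes:
            raise ValueError("trace ends before the first midnight")
        return ActivityTrace(
            self.fly_id, first_mid, self.counts[skip:], self.lights_on, self.lights_off
        )


@dataclass
class SleepBout:
    start_minute: int
    duration_min: int
    phase: str  # day | night
    day_minutes: int = 0
    night_minutes: int = 0
    at_edge: bool = False

    def __post_init__(self):
        if self.duration_min < MIN_BOUT_MIN:
            raise ValueError(f"bout shorter than {MIN_BOUT_MIN} min")


@dataclass
class SleepSummary:
    fly_id: str
    day_sleep_fraction: float
    night_sleep_fraction: float
    bout_count_day: int
    bout_count_night: int
    mean_bout_length_day: float | None
    mean_bout_length_night: float | None
    activity_to_sleep_bout_ratio: float | None
    total_sleep_min: int
    total_min: int
    partial_phase: bool = False
    metadata: dict = field(default_factory=dict)


def _zero_runs(counts: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of maximal runs of zeros."""
    runs = []
    n = counts.size
    i = 0
    while i < n:
        if counts[i] == 0:
            j = i
            while j < n and counts[j] == 0:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def detect_sleep_bouts(trace: ActivityTrace) -> list[SleepBout]:
    """Maximal runs of >= 5 consecutive zero-count minutes.

    Runs of 1-4 zero minutes are wake.  Each bout records how many of its
    minutes fall in day vs night and is attributed to its majority phase
    (ties go to the phase of the bout's first minute).
    """
    if trace.n_minutes < MIN_BOUT_MIN:
        raise ValueError("trace shorter than the 5-minute sleep definition")
    day = trace.day_mask()
    bouts = []
    for start, length in _zero_runs(trace.counts):
        if length < MIN_BOUT_MIN:
            continue
        seg = day[start : start + length]
        d = int(seg.sum())
        n = length - d
        if d != n:
            phase = "day" if d > n else "night"
        else:
            phase = "day" if seg[0] else "night"
        bouts.append(
            SleepBout(
                start_minute=start,
                duration_min=length,
                phase=phase,
                day_minutes=d,
                night_minutes=n,
                at_edge=(start == 0 or start + length == trace.n_minutes),
            )
        )
    return bouts


def sleep_mask(trace: ActivityTrace, bouts: list[SleepBout] | None = None) -> np.ndarray:
    """Boolean minute mask of sleep (True) according to the 5-minute rule."""
    if bouts is None:
        bouts = detect_sleep_bouts(trace)
    m = np.zeros(trace.n_minutes, dtype=bool)
    for b in bouts:
        m[b.start_minute : b.start_minute + b.duration_min] = True
    return m


def summarize_sleep(
    trace: ActivityTrace, bouts: list[SleepBout] | None = None
) -> SleepSummary:
    """Per-fly sleep summary over the trace.

    Phase sleep proportions use minute-level accounting (a boundary-spanning
    bout contributes to both phases); bout counts and mean lengths use
    whole bouts attributed to their majority phase.
    """
    if bouts is None:
        bouts = detect_sleep_bouts(trace)
    day = trace.day_mask()
    asleep = sleep_mask(trace, bouts)
    day_total = int(day.sum())
    night_total = int((~day).sum())
    partial = day_total == 0 or night_total == 0

    day_sleep = int((asleep & day).sum())
    night_sleep = int((asleep & ~day).sum())
    by_phase = {"day": [], "night": []}
    for b in bouts:
        by_phase[b.phase].append(b.duration_min)

    wake_minutes = ~asleep
    n_wake = int(wake_minutes.sum())
    mean_wake_activity = (
        float(trace.counts[wake_minutes].mean()) if n_wake else None
    )
    all_lengths = [b.duration_min for b in bouts]
    mean_bout = float(np.mean(all_lengths)) if all_lengths else None
    ratio = (
        mean_wake_activity / mean_bout
        if mean_wake_activity is not None and mean_bout
        else None
    )
    return SleepSummary(
        fly_id=trace.fly_id,
        day_sleep_fraction=day_sleep / day_total if day_total else float("nan"),
        night_sleep_fraction=night_sleep / night_total if night_total else float("nan"),
        bout_count_day=len(by_phase["day"]),
        bout_count_night=len(by_phase["night"]),
        mean_bout_length_day=float(np.mean(by_phase["day"])) if by_phase["day"] else None,
        mean_bout_length_night=(
            float(np.mean(by_phase["night"])) if by_phase["night"] else None
        ),
        activity_to_sleep_bout_ratio=ratio,
        total_sleep_min=int(asleep.sum()),
        total_min=trace.n_minutes,
        partial_phase=partial,
        metadata={
            "ratio_formula": "mean_counts_per_waking_minute / mean_sleep_bout_length_min"
        },
    )


def analyze_trace(trace: ActivityTrace, trim: bool = True) -> SleepSummary:
    """Trim acclimation to the first midnight, segment bouts, summarize."""
    t = trace.trimmed_to_midnight() if trim else trace
    return summarize_sleep(t)


def summary_table(summaries: list[SleepSummary], **labels) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {
            "fly_id": s.fly_id,
            "day_sleep_fraction": s.day_sleep_fraction,
            "night_sleep_fraction": s.night_sleep_fraction,
            "bout_count_day": s.bout_count_day,
            "bout_count_night": s.bout_count_night,
            "mean_bout_length_day": s.mean_bout_length_day,
            "mean_bout_length_night": s.mean_bout_length_night,
            "activity_to_sleep_bout_ratio": s.activity_to_sleep_bout_ratio,
        }
        row.update(labels)
        rows.append(row)
    return pd.DataFrame(rows)


def compare_sleep_groups(
    table: pd.DataFrame,
    variables: list[str] | None = None,
    group: str = "genotype",
    sex: str | None = "sex",
) -> dict:
    """Nonparametric cascade per sleep variable, sexes analyzed separately."""
    variables = variables or [
        "day_sleep_fraction",
        "night_sleep_fraction",
        "bout_count_night",
        "mean_bout_length_night",
    ]
    out = {}
    strata = table.groupby(sex) if sex and sex in table.columns else [("all", table)]
    for label, sub in strata:
        per_var = {}
        for v in variables:
            data = sub.dropna(subset=[v])
            omni, pairs = statcore.kw_then_pairwise_wilcoxon(
                data[v].to_numpy(), data[group].to_numpy()
            )
            per_var[v] = {"omnibus": omni, "pairwise": statcore.results_table(pairs)}
        out[label] = per_var
    return out


# --------------------------------------------------------------------------
# Trikinetics monitor file I/O
#
# DAMSystem monitor files are tab-delimited with one row per minute:
# record index, date (dd mon yy), time (HH:MM:SS), a status field (1 = ok),
# five unused fields, a light-sensor field, then 32 channel counts.


N_CHANNELS = 32
_STATUS_OK = 1


def write_dam(
    traces: list[ActivityTrace], path, monitor_start: pd.Timestamp | None = None
) -> None:
    """Write traces as one DAMSystem-format monitor file (<= 32 channels).

    All traces must share start time and length; missing channels are
    zero-filled.
    """
    if len(traces) > N_CHANNELS:
        raise ValueError(f"a monitor holds at most {N_CHANNELS} channels")
    if not traces:
        raise ValueError("no traces to write")
    start = traces[0].start
    n = traces[0].n_minutes
    for t in traces:
        if t.start != start or t.n_minutes != n:
            raise ValueError("traces must share start time and length")
    times = pd.date_range(start, periods=n, freq="min")
    mat = np.zeros((n, N_CHANNELS), dtype=int)
    for j, t in enumerate(traces):
        mat[:, j] = t.counts
    with open(path, "w") as fh:
        for i, ts in enumerate(times):
            date = ts.strftime("%d %b %y")
            clock = ts.strftime("%H:%M:%S")
            fields = [str(i + 1), date, clock, str(_STATUS_OK)] + ["0"] * 6
            fields += [str(c) for c in mat[i]]
            fh.write("\t".join(fields) + "\n")


def read_dam(
    path,
    lights_on="08:00",
    lights_off="20:00",
    n_flies: int | None = None,
    fly_prefix: str = "ch",
) -> list[ActivityTrace]:
    """Read a DAMSystem monitor file into one trace per channel.

    Rows with a non-OK status are dropped (listed in each trace's metadata
    is not needed; a count is attached to the returned list's ``attrs`` via
    the first trace).  Gaps longer than one minute after dropping are
    rejected, since bout segmentation assumes contiguous minutes.
    """
    times, rows = [], []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 10 + N_CHANNELS:
                raise ValueError(f"malformed DAM row at line {lineno}")
            try:
                status = int(parts[3])
                ts = pd.to_datetime(
                    parts[1] + " " + parts[2], format="%d %b %y %H:%M:%S"
                )
                counts = [int(v) for v in parts[10 : 10 + N_CHANNELS]]
            except (ValueError, TypeError) as e:
                raise ValueError(f"malformed DAM row at line {lineno}") from e
            if status != _STATUS_OK:
                dropped += 1
                continue
            times.append(ts)
            rows.append(counts)
    if not rows:
        return []
    times = pd.DatetimeIndex(times)
    deltas = np.diff(times.asi8) / 60e9
    if np.any(deltas > 2):
        raise ValueError("gap longer than 1 minute in monitor file")
    mat = np.asarray(rows, dtype=int)
    # a single dropped minute (delta == 2) is imputed from its neighbours so
    # the trace stays contiguous; a zero-run is preserved only if both sides
    # were at zero
    holes = np.where(deltas == 2)[0]
    if holes.size:
        full = pd.date_range(times[0], times[-1], freq="min")
        filled = np.zeros((len(full), N_CHANNELS), dtype=int)
        pos = ((times.asi8 - times.asi8[0]) // 60_000_000_000).astype(int)
        filled[pos] = mat
        missing = np.setdiff1d(np.arange(len(full)), pos)
        for i in missing:
            filled[i] = np.maximum(filled[i - 1], filled[i + 1])
        times, mat = full, filled
    k = n_flies if n_flies is not None else N_CHANNELS
    traces = [
        ActivityTrace(
            fly_id=f"{fly_prefix}{j + 1:02d}",
            start=times[0],
            counts=mat[:, j],
            lights_on=lights_on,
            lights_off=lights_off,
        )
        for j in range(k)
    ]
    if traces:
        traces[0].__dict__.setdefault("dropped_rows", dropped)
    return traces
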