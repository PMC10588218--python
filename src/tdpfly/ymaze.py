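"""Y-maze spontaneous alternation: arm-entry detection and scoring.

Spontaneous alternation is a working-memory proxy.  A fly explores a
symmetric three-arm maze for ten one-minute trials; every window of three
consecutive arm entries is an *alternation attempt* (A_max) and counts as an
*alternation* (N_alt) when the three entries are pairwise distinct.  The
alternation score is N_alt / A_max.  Windows slide by one entry and never
span trial boundaries.  Same-arm re-entries are kept as entries (they can
only break alternations).

Arm bias is the per-fly fraction of entries into each arm, tested against
the unbiased null of 1/3 with a Wilcoxon signed-rank test across the cohort.

A distance-scaled variant (alternations per mm moved) controls for
genotype-dependent differences in overall locomotion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import statcore

ARMS = ("A", "B", "C")

__all__ = [
    "ArmEntrySequence",
    "AlternationResult",
    "score_alternations",
    "arm_bias",
    "distance_scaled_alternation",
    "detect_arm_entries",
    "compare_ymaze_groups",
    "make_maze_geometry",
    "score_table",
]


@dataclass
class ArmEntrySequence:
    """Ordered arm labels per trial for one fly, with distance moved per trial."""

    fly_id: str
    trials: list[list[str]]
    distances_mm: list[float]

    def __post_init__(self):
        if len(self.trials) != len(self.distances_mm):
            raise ValueError("one distance per trial required")
        for t in self.trials:
            bad = set(t) - set(ARMS)
            if bad:
                raise ValueError(f"unknown arm labels {bad}")
        if any(d < 0 for d in self.distances_mm):
            raise ValueError("distances must be >= 0")

    @property
    def all_entries(self) -> list[str]:
        return [e for t in self.trials for e in t]

    @property
    def total_distance_mm(self) -> float:
        return float(sum(self.distances_mm))


@dataclass
class AlternationResult:
    """Per-fly alternation bookkeeping.

    ``score`` is the mean over trials (with >=1 attempt) of the per-trial
    ratio N_alt / A_max; ``pooled_score`` is total N_alt / total A_max.
    Both are None when no trial has an attempt (the fly is flagged
    ``no_score`` and excluded from score statistics).
    """

    fly_id: str
    n_alt: int
    a_max: int
    score: float | None
    pooled_score: float | None
    distance_mm: float
    distance_scaled_score: float | None
    per_trial: list[tuple[int, int]] = field(default_factory=list)

    @property
    def no_score(self) -> bool:
        return self.a_max == 0


def _count_windows(entries: list[str]) -> tuple[int, int]:
    """(n_alt, attempts) over sliding 3-windows of one trial."""
    attempts = max(len(entries) - 2, 0)
    n_alt = sum(
        1
        for i in range(attempts)
        if len({entries[i], entries[i + 1], entries[i + 2]}) == 3
    )
    return n_alt, attempts


def score_alternations(seq: ArmEntrySequence) -> AlternationResult:
    """Score one fly's entries with the sliding-window alternation rule.

    Within each trial every window of three consecutive entries is an
    attempt; an attempt alternates iff its entries are three distinct arms.
    Counts are summed within a trial, the per-trial ratio is formed, and the
    fly's score is the mean of per-trial ratios over trials with at least one
    attempt.
    """
    per_trial = [_count_windows(t) for t in seq.trials]
    n_alt = sum(a for a, _ in per_trial)
    a_max = sum(m for _, m in per_trial)
    ratios = [a / m for a, m in per_trial if m > 0]
    score = float(np.mean(ratios)) if ratios else None
    pooled = n_alt / a_max if a_max > 0 else None
    dist = seq.total_distance_mm
    return AlternationResult(
        fly_id=seq.fly_id,
        n_alt=n_alt,
        a_max=a_max,
        score=score,
        pooled_score=pooled,
        distance_mm=dist,
        distance_scaled_score=(n_alt / dist) if dist > 0 else None,
        per_trial=per_trial,
    )


def distance_scaled_alternation(result: AlternationResult) -> float:
    """Total alternations per mm moved; undefined (error) at zero distance."""
    if result.distance_mm <= 0:
        raise ValueError("distance-scaled alternation undefined at zero distance")
    return result.n_alt / result.distance_mm


def score_table(seqs: list[ArmEntrySequence]) -> pd.DataFrame:
    """Score a cohort; one row per fly (no-score flies flagged, not dropped)."""
    rows = []
    for s in seqs:
        r = score_alternations(s)
        rows.append(
            {
                "fly_id": r.fly_id,
                "n_alt": r.n_alt,
                "a_max": r.a_max,
                "score": r.score,
                "pooled_score": r.pooled_score,
                "distance_mm": r.distance_mm,
                "distance_scaled": r.distance_scaled_score,
                "no_score": r.no_score,
            }
        )
    return pd.DataFrame(rows)


def arm_bias(
    seqs: list[ArmEntrySequence], null_value: float = 1 / 3
) -> tuple[pd.DataFrame, dict[str, statcore.TestResult]]:
    """Per-fly arm-entry fractions and cohort signed-rank tests per arm.

    Flies with zero entries are excluded (noted in the returned frame's
    attrs).  Each arm's fractions across flies are tested against 1/3.
    """
    rows, skipped = [], []
    for s in seqs:
        entries = s.all_entries
        if not entries:
            skipped.append(s.fly_id)
            continue
        n = len(entries)
        row = {"fly_id": s.fly_id}
        for arm in ARMS:
            row[arm] = entries.count(arm) / n
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame.attrs["excluded_zero_entry_flies"] = skipped
    tests = {}
    for arm in ARMS:
        vals = frame[arm].to_numpy()
        try:
            tests[arm] = statcore.signed_rank_vs_value(vals, null_value)
        except ValueError:
            tests[arm] = None
    return frame, tests


# --------------------------------------------------------------------------
# entry detection from 2-D trajectories


def make_maze_geometry(arm_length: float = 10.0, arm_width: float = 3.0) -> dict:
    """Default symmetric Y geometry: three rectangular arms at 120 degrees
    around a central zone.  Units are arbitrary (mm by convention).

    Returns a dict with, per arm, the rectangle corners in arm-local frame
    plus the rotation angle; and ``center_radius`` for the central zone.
    """
    return {
        "arm_length": arm_length,
        "arm_width": arm_width,
        "center_radius": arm_width / np.sqrt(3),
        "angles": {"A": 90.0, "B": 210.0, "C": 330.0},
    }


def _arm_coords(x, y, geometry, arm):
    """Project points into the arm's local frame: (along-axis, across-axis)."""
    th = np.deg2rad(geometry["angles"][arm])
    u = x * np.cos(th) + y * np.sin(th)
    v = -x * np.sin(th) + y * np.cos(th)
    return u, v


def _classify(x, y, geometry, debounce_frac):
    """Zone per sample: 'center', an arm label (beyond debounce depth), or None."""
    r0 = geometry["center_radius"]
    L = geometry["arm_length"]
    w2 = geometry["arm_width"] / 2
    depth = r0 + debounce_frac * L
    zones = np.full(len(x), None, dtype=object)
    r = np.hypot(x, y)
    zones[r <= r0] = "center"
    for arm in ARMS:
        u, v = _arm_coords(np.asarray(x), np.asarray(y), geometry, arm)
        inside = (u > depth) & (u <= r0 + L) & (np.abs(v) <= w2)
        zones[inside] = arm
    return zones


def detect_arm_entries(
    trajectory: pd.DataFrame,
    geometry: dict | None = None,
    debounce_frac: float = 0.1,
    fly_id: str = "fly",
    trial_col: str | None = "trial",
    distance_col: str | None = None,
) -> ArmEntrySequence:
    """Detect arm entries from a timestamped (x, y) trajectory.

    An entry is recorded when the position passes from the central zone into
    an arm beyond a debounce depth (default 10% of arm length, guarding
    against boundary jitter).  Consecutive samples in the same arm are one
    entry; returning to center and re-entering (even the same arm) is a new
    entry.  Distance per trial is the summed step length unless a distance
    column is supplied.
    """
    geometry = geometry or make_maze_geometry()
    if geometry["center_radius"] <= 0 or geometry["arm_length"] <= 0:
        raise ValueError("malformed geometry")
    if trial_col and trial_col in trajectory.columns:
        groups = [g for _, g in trajectory.groupby(trial_col, sort=True)]
    else:
        groups = [trajectory]

    trials, dists = [], []
    for g in groups:
        x = g["x"].to_numpy(float)
        y = g["y"].to_numpy(float)
        zones = _classify(x, y, geometry, debounce_frac)
        entries: list[str] = []
        armed = True  # ready to record (at start or after returning to center)
        for z in zones:
            if z == "center":
                armed = True
            elif z in ARMS and armed:
                # deep arm entry from center; repeats without an intervening
                # center visit are the same entry and are ignored
                entries.append(z)
                armed = False
        trials.append(entries)
        if distance_col and distance_col in g.columns:
            dists.append(float(g[distance_col].sum()))
        else:
            dists.append(float(np.hypot(np.diff(x), np.diff(y)).sum()))
    return ArmEntrySequence(fly_id=fly_id, trials=trials, distances_mm=dists)


def compare_ymaze_groups(
    table: pd.DataFrame,
    value: str = "score",
    group: str = "genotype",
    sex: str | None = "sex",
    replicate: str | None = "replicate",
) -> dict:
    """Group comparisons of a Y-maze variable, sexes analyzed separately.

    With multiple replicates the parametric path is used (linear model with
    replicate as a fixed effect, ANOVA, Tukey HSD); with a single replicate
    the nonparametric cascade (Kruskal-Wallis then pairwise rank-sum with
    BH adjustment) is used instead, mirroring the study's dual convention.
    """
    if group not in table.columns:
        raise ValueError(f"missing group column {group!r}")
    out = {}
    strata = table.groupby(sex) if sex and sex in table.columns else [("all", table)]
    for label, sub in strata:
        sub = sub.dropna(subset=[value])
        multi_rep = (
            replicate is not None
            and replicate in sub.columns
            and sub[replicate].nunique() > 1
        )
        if multi_rep:
            anova, tukey = statcore.anova_tukey(sub, value, group, block=replicate)
            out[label] = {"path": "parametric", "anova": anova, "tukey": tukey}
        else:
            omni, pairs = statcore.kw_then_pairwise_wilcoxon(
                sub[value].to_numpy(), sub[group].to_numpy()
            )
            out[label] = {
                "path": "nonparametric",
                "omnibus": omni,
                "pairwise": statcore.results_table(pairs),
            }
    return out
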