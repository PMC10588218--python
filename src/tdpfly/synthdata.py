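"""Seeded generators emulating every raw input the pipeline consumes.

Each generator has a controllable effect size and a ground-truth return
value so every downstream stage has a parameter-recovery test.  All
generators are deterministic given (params, seed): a single master seed is
combined with a fixed per-generator stream offset via numpy's SeedSequence,
so generators never share or perturb each other's streams.

What is emulated, and what is not: arm entries follow a first-order Markov
choice process (no locomotor dynamics); activity traces follow a two-state
per-minute Markov chain with phase-dependent rates (geometric bout lengths,
no circadian ramping); wake minutes emit zero-truncated Poisson counts so
that wakefulness registers on the beam, which is what makes the 5-minute
sleep rule well-posed; survival times are Weibull or Gompertz rounded UP to
the 2-day census grid (a death is discovered at the next count); cell
stacks are noisy spheres and rims with an explicit nuclear-depletion
fraction; count tables are negative binomial with planted enrichment.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sleepdam import ActivityTrace
from .ymaze import ARMS, ArmEntrySequence, make_maze_geometry

# fixed stream offsets per generator (master seed + offset -> independent stream)
_STREAMS = {
    "ymaze": 11,
    "dam": 23,
    "survival": 37,
    "cell_stack": 41,
    "lobe_image": 53,
    "counts": 67,
}

__all__ = [
    "YmazeSimParams",
    "DamSimParams",
    "SurvivalSimParams",
    "ImageSimParams",
    "CountSimParams",
    "gen_ymaze",
    "gen_ymaze_trajectory",
    "gen_dam",
    "gen_survival",
    "gen_cell_stack",
    "gen_lobe_image",
    "gen_counts",
]


def _rng(kind: str, seed: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[kind]])


# --------------------------------------------------------------------------
# Y-maze


@dataclass
class YmazeSimParams:
    """Markov arm-entry process.

    ``p_alternate`` is the probability, given no same-arm re-entry, that the
    next arm completes a 3-distinct window (i.e. differs from the arm two
    entries back).  ``p_reentry`` is the probability of re-entering the arm
    just left.  The unbiased null is p_alternate = 0.5, p_reentry = 0:
    uniform choice between the two available arms.
    """

    n_flies: int = 30
    entries_per_trial: float = 12.0
    n_trials: int = 10
    p_alternate: float = 0.5
    p_reentry: float = 0.0
    distance_rate: float = 5.0  # mm per entry
    arm_weights: tuple | None = None  # plant an arm bias; overrides p_alternate
    seed: int = 0

    def validate(self):
        for name in ("p_alternate", "p_reentry"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_trials < 1 or self.n_flies < 1:
            raise ValueError("n_trials and n_flies must be >= 1")
        if self.distance_rate < 0:
            raise ValueError("distance_rate must be >= 0")
        if self.arm_weights is not None:
            if len(self.arm_weights) != 3 or any(w <= 0 for w in self.arm_weights):
                raise ValueError("arm_weights must be 3 positive values")


def _gen_entries(rng, n, p_alt, p_re, weights=None) -> list[str]:
    entries: list[str] = []
    for i in range(n):
        if i == 0:
            entries.append(ARMS[rng.integers(3)])
            continue
        if p_re > 0 and rng.random() < p_re:
            entries.append(entries[-1])
            continue
        others = [a for a in ARMS if a != entries[-1]]
        if weights is not None:
            # planted arm preference: choose among the two available arms
            # proportional to the per-arm weights (the alternation rule is
            # bypassed by design)
            w = np.array([weights[ARMS.index(a)] for a in others], float)
            entries.append(others[rng.choice(2, p=w / w.sum())])
            continue
        if i == 1:
            entries.append(others[rng.integers(2)])
            continue
        back2 = entries[-2]
        if back2 == entries[-1]:
            # both available arms complete a distinct window; choose uniformly
            entries.append(others[rng.integers(2)])
        else:
            alt = [a for a in others if a != back2][0]
            entries.append(alt if rng.random() < p_alt else back2)
    return entries


def gen_ymaze(params: YmazeSimParams) -> tuple[list[ArmEntrySequence], dict]:
    """Per-fly arm-entry sequences; truth holds the generating probabilities."""
    params.validate()
    rng = _rng("ymaze", params.seed)
    seqs = []
    for f in range(params.n_flies):
        trials, dists = [], []
        for _ in range(params.n_trials):
            n = int(rng.poisson(params.entries_per_trial))
            trials.append(
                _gen_entries(
                    rng, n, params.p_alternate, params.p_reentry, params.arm_weights
                )
            )
            dists.append(n * params.distance_rate)
        seqs.append(
            ArmEntrySequence(fly_id=f"fly{f + 1:03d}", trials=trials, distances_mm=dists)
        )
    truth = {
        "p_alternate": params.p_alternate,
        "p_reentry": params.p_reentry,
        "distance_rate": params.distance_rate,
    }
    return seqs, truth


def gen_ymaze_trajectory(
    entries: list[str], geometry: dict | None = None, points_per_leg: int = 20
) -> pd.DataFrame:
    """Render an entry list as a 2-D center-arm-center path (for testing
    entry detection).  Each entry walks from the centre to 90% of the arm
    length and back."""
    geometry = geometry or make_maze_geometry()
    L = geometry["arm_length"]
    pts = [(0.0, 0.0)]
    for arm in entries:
        th = np.deg2rad(geometry["angles"][arm])
        tip = (0.9 * L * np.cos(th), 0.9 * L * np.sin(th))
        for frac in np.linspace(0, 1, points_per_leg)[1:]:
            pts.append((tip[0] * frac, tip[1] * frac))
        for frac in np.linspace(1, 0, points_per_leg)[1:]:
            pts.append((tip[0] * frac, tip[1] * frac))
    df = pd.DataFrame(pts, columns=["x", "y"])
    df["t"] = np.arange(len(df), dtype=float)
    return df


# --------------------------------------------------------------------------
# DAM activity


@dataclass
class DamSimParams:
    """Two-state (sleep/wake) per-minute Markov chain with 12:12 photoperiod.

    ``p_sleep_day``/``p_sleep_night`` are the stationary sleep probabilities
    per phase; ``mean_bout_min_*`` the geometric mean sleep-bout lengths.
    Wake minutes emit zero-truncated Poisson(activity_rate) counts by
    default, so a waking fly always trips the beam; ``truncate_wake=False``
    allows silent wake minutes to study misclassification by the 5-minute
    rule.
    """

    n_flies: int = 32
    n_days: int = 3
    p_sleep_day: float = 0.4
    p_sleep_night: float = 0.7
    mean_bout_min_day: float = 20.0
    mean_bout_min_night: float = 60.0
    activity_rate: float = 2.0
    lights_on: str = "08:00"
    lights_off: str = "20:00"
    acclimation_minutes: int = 360
    truncate_wake: bool = True
    start_date: str = "2024-01-01"
    seed: int = 0

    def validate(self):
        for name in ("p_sleep_day", "p_sleep_night"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mean_bout_min_day < 1 or self.mean_bout_min_night < 1:
            raise ValueError("mean bout lengths must be >= 1 minute")
        if self.activity_rate < 0:
            raise ValueError("activity_rate must be >= 0")


def _transition_rates(p_sleep: float, mean_bout: float) -> tuple[float, float]:
    """(P(wake->sleep), P(sleep->wake)) hitting the stationary sleep
    probability and geometric mean bout length."""
    q_sw = 1.0 / mean_bout
    if p_sleep >= 1.0:
        return 1.0, 0.0
    q_ws = q_sw * p_sleep / (1.0 - p_sleep)
    return min(q_ws, 1.0), q_sw


def _ztp(rng, lam, size):
    """Zero-truncated Poisson by inversion of the conditional CDF."""
    if lam <= 0:
        return np.ones(size, dtype=int)  # degenerate: a single crossing
    u = rng.random(size)
    # sample from Poisson conditioned on >= 1
    p0 = np.exp(-lam)
    target = p0 + u * (1 - p0)
    k = np.zeros(size, dtype=int)
    cdf = np.full(size, p0)
    pk = np.full(size, p0)
    active = cdf < target
    while active.any():
        k[active] += 1
        pk[active] = pk[active] * lam / k[active]
        cdf[active] += pk[active]
        active = cdf < target
    return k


def gen_dam(params: DamSimParams) -> tuple[list[ActivityTrace], dict]:
    """Simulated activity traces; truth holds the stationary sleep targets.

    The trace starts ``acclimation_minutes`` before midnight of
    ``start_date`` + 1 (mirroring evening loading with monitoring analysed
    from midnight) and runs for ``n_days`` full days after that midnight.
    """
    params.validate()
    rng = _rng("dam", params.seed)
    midnight = pd.Timestamp(params.start_date) + pd.Timedelta(days=1)
    start = midnight - pd.Timedelta(minutes=params.acclimation_minutes)
    n_min = params.acclimation_minutes + params.n_days * 24 * 60
    times = pd.date_range(start, periods=n_min, freq="min")
    on_h, on_m = (int(v) for v in params.lights_on.split(":"))
    off_h, off_m = (int(v) for v in params.lights_off.split(":"))
    minute_of_day = times.hour * 60 + times.minute
    day_mask = (minute_of_day >= on_h * 60 + on_m) & (minute_of_day < off_h * 60 + off_m)

    rates = {
        True: _transition_rates(params.p_sleep_day, params.mean_bout_min_day),
        False: _transition_rates(params.p_sleep_night, params.mean_bout_min_night),
    }
    traces = []
    for f in range(params.n_flies):
        asleep = np.zeros(n_min, dtype=bool)
        p0 = params.p_sleep_day if day_mask[0] else params.p_sleep_night
        state = rng.random() < p0
        for i in range(n_min):
            q_ws, q_sw = rates[bool(day_mask[i])]
            if state:
                if rng.random() < q_sw:
                    state = False
            else:
                if rng.random() < q_ws:
                    state = True
            asleep[i] = state
        counts = np.zeros(n_min, dtype=int)
        wake_idx = np.nonzero(~asleep)[0]
        if wake_idx.size:
            if params.truncate_wake:
                counts[wake_idx] = _ztp(rng, params.activity_rate, wake_idx.size)
            else:
                counts[wake_idx] = rng.poisson(params.activity_rate, wake_idx.size)
        traces.append(
            ActivityTrace(
                fly_id=f"fly{f + 1:03d}",
                start=times[0],
                counts=counts,
                lights_on=params.lights_on,
                lights_off=params.lights_off,
            )
        )
    truth = {
        "p_sleep_day": params.p_sleep_day,
        "p_sleep_night": params.p_sleep_night,
        "mean_bout_min_day": params.mean_bout_min_day,
        "mean_bout_min_night": params.mean_bout_min_night,
    }
    return traces, truth


# --------------------------------------------------------------------------
# survival


@dataclass
class SurvivalSimParams:
    """Death-time distributions per group, censused on a 2-day grid.

    ``groups`` maps a group label to ("weibull", shape k, scale lam) or
    ("gompertz", a, b).  Death times round UP to the census grid (a death is
    discovered at the next every-other-day count) and times past ``max_day``
    are right-censored there.
    """

    groups: dict = field(
        default_factory=lambda: {"control": ("weibull", 5.0, 90.0)}
    )
    n_per_group: int = 150
    census_interval_days: int = 2
    max_day: int = 100
    seed: int = 0

    def validate(self):
        if self.max_day <= 0 or self.census_interval_days <= 0:
            raise ValueError("max_day and census interval must be positive")
        for g, dist in self.groups.items():
            kind, a, b = dist
            if kind not in ("weibull", "gompertz"):
                raise ValueError(f"unknown distribution {kind!r} for group {g!r}")
            if a <= 0 or b <= 0:
                raise ValueError("distribution parameters must be > 0")


def _draw_death_times(rng, dist, n):
    kind, a, b = dist
    if kind == "weibull":
        k, lam = a, b
        return lam * rng.weibull(k, size=n)
    # Gompertz(a, b): hazard a*exp(b*t); inverse CDF
    u = rng.random(n)
    return np.log1p(-b / a * np.log1p(-u)) / b


def gen_survival(params: SurvivalSimParams) -> pd.DataFrame:
    """Survival records (fly_id, genotype, time_days, event) on the census grid."""
    params.validate()
    rng = _rng("survival", params.seed)
    rows = []
    c = params.census_interval_days
    for gname, dist in params.groups.items():
        raw = _draw_death_times(rng, dist, params.n_per_group)
        grid = np.ceil(raw / c) * c
        grid = np.maximum(grid, c)
        for i, t in enumerate(grid):
            died = t <= params.max_day
            rows.append(
                {
                    "fly_id": f"{gname}_{i + 1:04d}",
                    "genotype": gname,
                    "time_days": float(min(t, params.max_day)),
                    "event": 1 if died else 0,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# imaging


@dataclass
class ImageSimParams:
    """Synthetic confocal inputs.

    For cell stacks: spheres of radius ``nucleus_radius_um`` are nuclei, a
    concentric shell of width ``rim_width_um`` is cytoplasm, and
    ``depletion`` in [0, 1] is the fraction of tagged signal moved from the
    nucleus to the rim (per-voxel nuclear intensity (1 - depletion) x I0,
    rim intensity raised so the whole-cell mean stays at I0).  For lobe
    images: puncta are ellipses with specified area and eccentricity on a
    textured background.
    """

    shape: tuple = (8, 128, 128)  # (z, y, x)
    pixel_size_um: float = 0.25
    z_step_um: float = 1.0
    n_cells: int = 6
    nucleus_radius_um: float = 1.5
    rim_width_um: float = 0.5
    depletion: float = 0.0
    base_intensity: float = 100.0
    puncta: list = field(default_factory=list)  # [(area_um2, eccentricity), ...]
    puncta_intensity: float = 200.0
    background_level: float = 10.0
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self):
        if self.nucleus_radius_um <= 0 or self.rim_width_um <= 0:
            raise ValueError("radii must be positive")
        if not 0 <= self.depletion <= 1:
            raise ValueError("depletion must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValueError("pixel sizes must be positive")


def gen_cell_stack(params: ImageSimParams) -> tuple[np.ndarray, dict]:
    """Two-channel stack (channel 0 nuclear dye, channel 1 tagged protein).

    Returns (stack of shape (2, z, y, x), truth) where truth carries the
    label images for nuclei and whole cells and the per-voxel design
    intensities.
    """
    params.validate()
    rng = _rng("cell_stack", params.seed)
    nz, ny, nx = params.shape
    psz, zst = params.pixel_size_um, params.z_step_um
    r_n = params.nucleus_radius_um
    r_c = r_n + params.rim_width_um
    margin = int(np.ceil(r_c / psz)) + 1
    zc, yc, xc = np.meshgrid(
        np.arange(nz) * zst, np.arange(ny) * psz, np.arange(nx) * psz, indexing="ij"
    )
    nuc_labels = np.zeros(params.shape, dtype=np.int32)
    cell_labels = np.zeros(params.shape, dtype=np.int32)
    centers = []
    attempts = 0
    while len(centers) < params.n_cells and attempts < 2000:
        attempts += 1
        cy = rng.uniform(margin, ny - margin) * psz
        cx = rng.uniform(margin, nx - margin) * psz
        cz = rng.uniform(0, (nz - 1) * zst)
        if all(
            np.hypot(cy - oy, cx - ox) > 2.2 * r_c or abs(cz - oz) > 2.2 * r_c
            for oz, oy, ox in centers
        ):
            centers.append((cz, cy, cx))
    for i, (cz, cy, cx) in enumerate(centers, start=1):
        d2 = (zc - cz) ** 2 + (yc - cy) ** 2 + (xc - cx) ** 2
        nuc = d2 <= r_n**2
        cell = d2 <= r_c**2
        nuc_labels[nuc] = i
        cell_labels[cell] = i

    nuc_mask = nuc_labels > 0
    rim_mask = (cell_labels > 0) & ~nuc_mask
    I0 = params.base_intensity
    v_n, v_r = max(int(nuc_mask.sum()), 1), max(int(rim_mask.sum()), 1)
    yfp = np.full(params.shape, params.background_level, dtype=float)
    yfp[nuc_mask] = I0 * (1 - params.depletion)
    yfp[rim_mask] = I0 * (1 + params.depletion * v_n / v_r)
    dye = np.full(params.shape, params.background_level, dtype=float)
    dye[nuc_mask] = I0
    if params.noise_sd > 0:
        yfp = yfp + rng.normal(0, params.noise_sd, params.shape)
        dye = dye + rng.normal(0, params.noise_sd, params.shape)
    stack = np.stack([dye, yfp]).clip(min=0)
    truth = {
        "nucleus_labels": nuc_labels,
        "cell_labels": cell_labels,
        "n_cells": len(centers),
        "depletion": params.depletion,
        "expected_ratio": 1 - params.depletion,
    }
    return stack, truth


def gen_lobe_image(params: ImageSimParams) -> tuple[np.ndarray, dict]:
    """Single-channel section with planted elliptical puncta.

    Each entry of ``params.puncta`` is (area_um2, eccentricity); ellipses
    are placed on a non-overlapping grid over a noisy background.  Truth
    carries the planted mask and per-punctum areas.
    """
    params.validate()
    rng = _rng("lobe_image", params.seed)
    ny, nx = params.shape[-2:]
    psz = params.pixel_size_um
    img = params.background_level + rng.normal(0, params.noise_sd, (ny, nx))
    mask = np.zeros((ny, nx), dtype=bool)
    yy, xx = np.mgrid[0:ny, 0:nx]
    n = len(params.puncta)
    if n:
        grid = int(np.ceil(np.sqrt(n)))
        cell_y, cell_x = ny / grid, nx / grid
        for i, (area_um2, ecc) in enumerate(params.puncta):
            gy, gx = divmod(i, grid)
            cy = (gy + 0.5) * cell_y
            cx = (gx + 0.5) * cell_x
            area_px = area_um2 / psz**2
            # ellipse semi-axes from area and eccentricity e^2 = 1 - (b/a)^2
            ratio = np.sqrt(max(1 - ecc**2, 1e-6))  # b/a
            a = np.sqrt(area_px / (np.pi * ratio))
            b = a * ratio
            th = rng.uniform(0, np.pi)
            u = (yy - cy) * np.cos(th) + (xx - cx) * np.sin(th)
            v = -(yy - cy) * np.sin(th) + (xx - cx) * np.cos(th)
            ell = (u / a) ** 2 + (v / b) ** 2 <= 1
            mask |= ell
    img[mask] = params.puncta_intensity
    truth = {
        "mask": mask,
        "n_puncta": n,
        "areas_um2": [a for a, _ in params.puncta],
    }
    return img, truth


def write_stack_tiff(stack: np.ndarray, path) -> None:
    """Write a (channels, z, y, x) stack as a multi-page 32-bit TIFF."""
    import tifffile

    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


def read_stack_tiff(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path)


# --------------------------------------------------------------------------
# RNA-IP count tables


@dataclass
class CountSimParams:
    """Negative-binomial count tables for input, TDP-IP and YFP-IP libraries.

    ``enriched_set`` genes carry true log2 enrichment ``log2fc`` in the
    TDP-43 IP only; ``nonspecific_set`` genes are enriched in both IPs
    (sticky background binding) with ``nonspecific_log2fc``.  Three
    replicates per condition by default.
    """

    n_genes: int = 2000
    n_replicates: int = 3
    dispersion: float = 0.05
    log2fc: float = 3.0
    nonspecific_log2fc: float = 2.0
    n_enriched: int = 100
    n_nonspecific: int = 50
    library_size_factors: dict = field(default_factory=dict)
    base_mean_log: float = 4.5
    base_mean_sd: float = 1.0
    base_mean_min: float = 20.0
    seed: int = 0

    def validate(self):
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if not np.isfinite(self.log2fc):
            raise ValueError("planted log2FC must be finite")
        if self.n_enriched + self.n_nonspecific > self.n_genes:
            raise ValueError("planted sets exceed the gene universe")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per condition")


def _nb(rng, mean, dispersion):
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def gen_counts(params: CountSimParams) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """(counts, samples, truth).

    ``counts`` is genes x samples; ``samples`` maps sample id to condition
    (input / tdp_ip / yfp_ip) and replicate; ``truth`` lists the planted
    gene sets and per-gene true log2FC.
    """
    params.validate()
    rng = _rng("counts", params.seed)
    genes = [f"g{i + 1:05d}" for i in range(params.n_genes)]
    base = np.exp(rng.normal(params.base_mean_log, params.base_mean_sd, params.n_genes))
    base = np.maximum(base, params.base_mean_min)
    enriched = genes[: params.n_enriched]
    nonspecific = genes[params.n_enriched : params.n_enriched + params.n_nonspecific]
    lfc_tdp = np.zeros(params.n_genes)
    lfc_yfp = np.zeros(params.n_genes)
    lfc_tdp[: params.n_enriched] = params.log2fc
    idx_ns = slice(params.n_enriched, params.n_enriched + params.n_nonspecific)
    lfc_tdp[idx_ns] = params.nonspecific_log2fc
    lfc_yfp[idx_ns] = params.nonspecific_log2fc

    conditions = ["input", "tdp_ip", "yfp_ip"]
    cols, data, meta = [], [], []
    for cond in conditions:
        lfc = {"input": 0.0, "tdp_ip": lfc_tdp, "yfp_ip": lfc_yfp}[cond]
        for r in range(1, params.n_replicates + 1):
            sample = f"{cond}_{r}"
            sf = params.library_size_factors.get(sample, 1.0)
            mu = base * sf * 2.0 ** (lfc if np.ndim(lfc) else np.full(params.n_genes, lfc))
            data.append(_nb(rng, mu, params.dispersion))
            cols.append(sample)
            meta.append({"sample": sample, "condition": cond, "replicate": r})
    counts = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    samples = pd.DataFrame(meta)
    truth = {
        "enriched_set": set(enriched),
        "nonspecific_set": set(nonspecific),
        "log2fc_tdp": pd.Series(lfc_tdp, index=genes),
        "log2fc_yfp": pd.Series(lfc_yfp, index=genes),
    }
    return counts, samples, truth
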