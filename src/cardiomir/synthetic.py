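"""Synthetic clinical-cohort simulator with known ground truth.

Emulates the study design the downstream pipeline expects: four clinical
groups (NHF normal cardiac function, AMHF acute MI with heart failure,
AMNHF acute MI without heart failure, OMHF heart failure after old MI) of
10 patients each, a plasma miRNA microarray intensity matrix with planted
differential miRNAs, echocardiographic records in physiological ranges,
exponential survival with a planted hazard ratio between expression groups,
and 5-day optical-density viability trajectories.

Every generator is deterministic under a fixed seed, and the expression
generator emits a truth table of the planted effects so parameter-recovery
tests never need an external reference at run time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "PLANTED_EFFECTS",
    "SimConfig",
    "ODTimeSeries",
    "default_de_table",
    "generate_expression",
    "generate_replicate_stack",
    "generate_echo",
    "generate_survival",
    "generate_od",
]

GROUPS = ("NHF", "AMHF", "AMNHF", "OMHF")

# Published screen hits used as simulator defaults: for each case group,
# the top-5 up- and top-5 down-regulated plasma miRNAs versus the NHF
# control and their linear fold changes (case mean / control mean).
PLANTED_EFFECTS: dict[str, list[tuple[str, float]]] = {
    "AMNHF": [
        ("hsa-miR-409-3p", 6.653),
        ("hsa-miR-26b-5p", 5.765),
        ("hsa-miR-369-3p", 5.543),
        ("hsa-miR-148b-3p", 4.432),
        ("hsa-miR-329", 4.132),
        ("hsa-miR-320", 0.765),
        ("hsa-miR-204", 0.643),
        ("hsa-miR-20b-3p", 0.543),
        ("hsa-miR-767-5p", 0.532),
        ("hsa-miR-299-5p", 0.412),
    ],
    "OMHF": [
        ("hsa-miR-3941", 6.753),
        ("hsa-miR-338-5p", 5.755),
        ("hsa-miR-433", 4.546),
        ("hsa-miR-19a-3p", 4.432),
        ("hsa-miR-329", 4.165),
        ("hsa-miR-320", 0.865),
        ("hsa-miR-204", 0.748),
        ("hsa-miR-2110", 0.663),
        ("hsa-miR-1247-5p", 0.542),
        ("hsa-miR-296-5p", 0.432),
    ],
    "AMHF": [
        ("hsa-miR-3667-5p", 8.753),
        ("hsa-miR-4275", 7.751),
        ("hsa-miR-647", 7.548),
        ("hsa-miR-1284", 6.433),
        ("hsa-miR-1306-3p", 6.165),
        ("hsa-miR-320", 0.785),
        ("hsa-miR-204", 0.758),
        ("hsa-miR-205-5p", 0.675),
        ("hsa-miR-423-5p", 0.641),
        ("hsa-miR-21-3p", 0.572),
    ],
}


def default_de_table() -> list[tuple[str, tuple[str, str], float]]:
    """Planted differential effects as (miRNA, (control, case), fold change)."""
    table = []
    for case, rows in PLANTED_EFFECTS.items():
        for name, fc in rows:
            table.append((name, ("NHF", case), fc))
    return table


@dataclass
class SimConfig:
    """Parameters of the expression simulator.

    group_sizes
        Patients per clinical group; the study design is 10 per group.
    de_table
        Planted effects as (miRNA id, (control, case) pair, true linear
        fold change). Defaults to the published top-5 up/down screens of
        the three case-vs-NHF comparisons.
    baseline_intensity
        Control-group mean intensity of planted rows, arbitrary
        fluorescence units.
    noise_cv
        Coefficient of variation of the multiplicative log-normal
        measurement noise applied per cell (post replicate averaging).
    n_background_mirnas
        Non-differential rows, with row baselines spread log-uniformly
        around ``baseline_intensity``.
    below_floor_fraction
        Fraction of rows simulated with baselines under the detection
        floor so the intensity filter has work to do.
    intensity_floor
        Reference detection floor in fluorescence units.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {g: 10 for g in GROUPS}
    )
    de_table: list[tuple[str, tuple[str, str], float]] = field(
        default_factory=default_de_table
    )
    baseline_intensity: float = 1000.0
    noise_cv: float = 0.15
    n_background_mirnas: int = 200
    below_floor_fraction: float = 0.1
    intensity_floor: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ValueError(f"group {g!r} needs >= 2 patients, got {n}")
        for name, (ctrl, case), fc in self.de_table:
            if fc <= 0:
                raise ValueError(f"non-positive fold change {fc} for {name}")
            for g in (ctrl, case):
                if g not in self.group_sizes:
                    raise ValueError(f"unknown group {g!r} in de_table")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.baseline_intensity <= 0:
            raise ValueError("baseline_intensity must be > 0")
        if not 0 <= self.below_floor_fraction < 1:
            raise ValueError("below_floor_fraction must be in [0, 1)")


@dataclass
class ODTimeSeries:
    """Optical-density readings (490 nm) of replicate wells on one day."""

    day: int
    well_ods: list[float]

    def __post_init__(self) -> None:
        if self.day < 1:
            raise ValueError("day numbering starts at 1")
        if not self.well_ods or any(od <= 0 for od in self.well_ods):
            raise ValueError("well ODs must be positive and non-empty")


def _lognormal_noise(rng: np.random.Generator, mean: np.ndarray, cv: float) -> np.ndarray:
    """Multiplicative log-normal noise, mean-corrected so E[X] = mean."""
    if cv == 0:
        return np.asarray(mean, dtype=float).copy()
    sigma = math.sqrt(math.log1p(cv * cv))
    z = rng.standard_normal(mean.shape)
    return mean * np.exp(sigma * z - 0.5 * sigma * sigma)


def _design_frame(group_sizes: dict[str, int]) -> pd.DataFrame:
    sample_ids, groups = [], []
    for g, n in group_sizes.items():
        for i in range(1, n + 1):
            sample_ids.append(f"{g}-{i:02d}")
            groups.append(g)
    return pd.DataFrame({"sample_id": sample_ids, "group": groups})


def _mean_matrix(config: SimConfig, rng: np.random.Generator):
    """Per-cell expectation matrix, row labels and the truth table."""
    design = _design_frame(config.group_sizes)
    planted_ids = list(dict.fromkeys(name for name, _, _ in config.de_table))

    # per planted row: group -> relative level (control groups at 1)
    levels = {name: {g: 1.0 for g in config.group_sizes} for name in planted_ids}
    truth_rows = []
    for name, (ctrl, case), fc in config.de_table:
        levels[name][case] = fc
        truth_rows.append(
            {"mirna": name, "control": ctrl, "case": case, "fold_change": fc}
        )
    truth = pd.DataFrame(truth_rows)

    n_total = len(planted_ids) + config.n_background_mirnas
    n_floor = int(round(config.below_floor_fraction * n_total))
    n_bg = max(config.n_background_mirnas - n_floor, 0)

    bg_ids = [f"bg-miR-{i:04d}" for i in range(1, n_bg + 1)]
    floor_ids = [f"low-miR-{i:04d}" for i in range(1, n_floor + 1)]
    row_ids = planted_ids + bg_ids + floor_ids

    group_of = dict(zip(design["sample_id"], design["group"]))
    means = np.empty((len(row_ids), len(design)), dtype=float)
    base = config.baseline_intensity
    # background baselines spread over ~1.5 decades; floor rows straddle
    # the detection limit from below
    bg_base = base * 10 ** rng.uniform(-0.7, 0.7, size=n_bg)
    floor_base = rng.uniform(0.4, 0.9, size=n_floor) * config.intensity_floor
    for i, name in enumerate(planted_ids):
        means[i] = [base * levels[name][group_of[s]] for s in design["sample_id"]]
    for j, b in enumerate(bg_base):
        means[len(planted_ids) + j] = b
    for j, b in enumerate(floor_base):
        means[len(planted_ids) + n_bg + j] = b
    return means, row_ids, design, truth


def generate_expression(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a replicate-averaged miRNA intensity matrix.

    Returns ``(matrix, design, truth)`` where *matrix* is miRNA × sample
    with non-negative intensities, *design* maps sample ids to clinical
    groups and *truth* lists every planted effect. Each planted miRNA's
    expected case-group mean is ``baseline_intensity × fold change``; with
    ``noise_cv=0`` the planted fold changes are reproduced exactly.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_mean, rng_noise = (np.random.Generator(np.random.PCG64(s)) for s in ss.spawn(2))
    means, row_ids, design, truth = _mean_matrix(config, rng_mean)
    values = _lognormal_noise(rng_noise, means, config.noise_cv)
    matrix = pd.DataFrame(values, index=pd.Index(row_ids, name="miRNA"),
                          columns=design["sample_id"].tolist())
    return matrix, design, truth


def generate_replicate_stack(
    config: SimConfig, n_replicates: int = 10
) -> list[pd.DataFrame]:
    """Simulate the individual technical reads behind one averaged matrix.

    Each read carries noise ``noise_cv × sqrt(n_replicates)`` so the
    arithmetic mean of the stack has per-cell noise close to ``noise_cv``,
    matching what :func:`generate_expression` emits directly.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    ss = np.random.SeedSequence(config.seed)
    rng_mean, rng_noise = (np.random.Generator(np.random.PCG64(s)) for s in ss.spawn(2))
    means, row_ids, design, _ = _mean_matrix(config, rng_mean)
    cv = config.noise_cv * math.sqrt(n_replicates)
    cols = design["sample_id"].tolist()
    return [
        pd.DataFrame(_lognormal_noise(rng_noise, means, cv),
                     index=pd.Index(row_ids, name="miRNA"), columns=cols)
        for _ in range(n_replicates)
    ]


# Group-level echocardiographic targets: (mean, sd) per parameter.
# Heart-failure groups get dilated ventricles, depressed ejection fraction
# and fractional shortening, shorter ejection time and faster heart rate
# than the NHF controls; heights/weights follow the cohort demographics.
_ECHO_PROFILES: dict[str, dict[str, tuple[float, float]]] = {
    "NHF": dict(lvedv=(110, 10), ef=(0.65, 0.04), lvidd=(4.7, 0.25),
                fs=(0.36, 0.03), ivs=(0.95, 0.07), pwts=(1.45, 0.10),
                sbp=(125, 8), lvet=(0.30, 0.015), hr=(72, 5),
                height=(162, 3), weight=(55.34, 4)),
    "AMHF": dict(lvedv=(170, 14), ef=(0.34, 0.05), lvidd=(6.0, 0.3),
                 fs=(0.17, 0.03), ivs=(1.05, 0.08), pwts=(1.30, 0.10),
                 sbp=(108, 9), lvet=(0.26, 0.015), hr=(88, 7),
                 height=(164, 3), weight=(55.87, 4)),
    "AMNHF": dict(lvedv=(130, 12), ef=(0.52, 0.04), lvidd=(5.2, 0.25),
                  fs=(0.27, 0.03), ivs=(1.00, 0.07), pwts=(1.38, 0.10),
                  sbp=(118, 8), lvet=(0.28, 0.015), hr=(78, 6),
                  height=(165, 3), weight=(52.78, 4)),
    "OMHF": dict(lvedv=(175, 14), ef=(0.32, 0.05), lvidd=(6.1, 0.3),
                 fs=(0.16, 0.03), ivs=(1.08, 0.08), pwts=(1.28, 0.10),
                 sbp=(110, 9), lvet=(0.26, 0.015), hr=(86, 7),
                 height=(165, 3), weight=(57.54, 4)),
}


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Normal draws resampled into (lo, hi); keeps contract bounds hard."""
    out = rng.normal(mean, sd, size)
    bad = (out <= lo) | (out >= hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out <= lo) | (out >= hi)
    return out


def generate_echo(group: str, n: int, seed: int):
    """Simulate ``n`` echocardiographic records for one clinical group.

    Volumes are generated from end-diastolic volume and ejection fraction,
    diameters from end-diastolic diameter and fractional shortening, so
    LVESV < LVEDV and LVIDs < LVIDd hold by construction.
    """
    from .energetics import EchoRecord

    if group not in _ECHO_PROFILES:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    if n < 1:
        raise ValueError("n must be >= 1")
    prof = _ECHO_PROFILES[group]
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))

    def draw(key, lo, hi):
        m, s = prof[key]
        return _truncated_normal(rng, m, s, lo, hi, n)

    lvedv = draw("lvedv", 50, 300)
    ef = draw("ef", 0.05, 0.85)
    lvidd = draw("lvidd", 3.0, 8.5)
    fs = draw("fs", 0.05, 0.60)
    ivs = draw("ivs", 0.5, 2.0)
    pwts = draw("pwts", 0.6, 2.5)
    sbp = draw("sbp", 70, 220)
    lvet = draw("lvet", 0.15, 0.45)
    hr = draw("hr", 40, 140)
    height = draw("height", 140, 200)
    weight = draw("weight", 35, 110)
    lvesv = lvedv * (1 - ef)
    return [
        EchoRecord(
            lvedv=float(lvedv[i]), lvesv=float(lvesv[i]), ivs=float(ivs[i]),
            pwts=float(pwts[i]), lvidd=float(lvidd[i]),
            lvids=float(lvidd[i] * (1 - fs[i])), sbp=float(sbp[i]),
            lvet=float(lvet[i]), lvsv=float(lvedv[i] - lvesv[i]),
            heart_rate=float(hr[i]), height=float(height[i]),
            weight=float(weight[i]),
        )
        for i in range(n)
    ]


def generate_survival(
    n: int,
    split: float = 0.5,
    hazard_ratio: float = 3.0,
    censor_rate: float = 0.2,
    seed: int = 0,
    baseline_hazard: float = 0.05,
):
    """Simulate a cohort split into high/low target-gene expression groups.

    Event times are exponential; the high-expression group's hazard is
    ``baseline_hazard × hazard_ratio``. Censoring is independent and
    uniform on (0, τ), with τ calibrated so the cohort's expected censored
    fraction equals ``censor_rate``; a record is censored when its censor
    time precedes its event time, so the faster-failing high group keeps
    more observed events. Expression levels are drawn around 1 (low) and
    3 (high) so a median split recovers the planted groups.
    """
    from .survival import SurvivalRecord

    if not 0 < split < 1:
        raise ValueError("split must be in (0, 1)")
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be > 0")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    n_high = int(round(n * split))
    hazards = np.where(np.arange(n) < n_high,
                       baseline_hazard * hazard_ratio, baseline_hazard)
    tau = _censor_horizon(hazards, censor_rate) if censor_rate > 0 else None
    records = []
    for i in range(n):
        high = i < n_high
        t = float(rng.exponential(1.0 / hazards[i]))
        expr = float(max(rng.normal(3.0 if high else 1.0, 0.15), 1e-6))
        event = True
        if tau is not None:
            c = float(rng.uniform(0, tau))
            if c < t:
                t, event = c, False
        records.append(
            SurvivalRecord(patient_id=f"P{i + 1:03d}", time=t, event=event,
                           expression=expr)
        )
    return records


def _censor_horizon(hazards: np.ndarray, censor_rate: float) -> float:
    """Uniform-censoring horizon τ with E[censored fraction] = censor_rate.

    For T ~ Exp(h) and C ~ U(0, τ), P(C < T) = (1 − e^{−hτ})/(hτ), which
    decreases from 1 to 0 in τ; the cohort mean is bracketed and solved by
    bisection.
    """
    from scipy.optimize import brentq

    def pooled(tau: float) -> float:
        x = hazards * tau
        return float(np.mean(-np.expm1(-x) / x)) - censor_rate

    lo, hi = 1e-9, 1.0
    while pooled(hi) > 0:
        hi *= 2.0
    return float(brentq(pooled, lo, hi))


def generate_od(
    days: int = 5,
    start_od: float = 2.4,
    end_od: float = 1.75,
    n_wells: int = 4,
    noise_sd: float = 0.03,
    seed: int = 0,
) -> list[ODTimeSeries]:
    """Simulate a declining viability (OD 490 nm) trajectory.

    Per-day expected OD interpolates linearly from ``start_od`` on day 1 to
    ``end_od`` on the last day; each of ``n_wells`` replicate wells adds
    independent Gaussian noise. With ``noise_sd=0`` the day-5 mean equals
    ``end_od`` exactly.
    """
    if days < 2:
        raise ValueError("days must be >= 2")
    if n_wells < 1:
        raise ValueError("n_wells must be >= 1")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    series = []
    for d in range(1, days + 1):
        mean = start_od + (end_od - start_od) * (d - 1) / (days - 1)
        wells = mean + rng.normal(0.0, noise_sd, n_wells) if noise_sd > 0 else (
            np.full(n_wells, mean)
        )
        series.append(ODTimeSeries(day=d, well_ods=[float(w) for w in wells]))
    return series
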