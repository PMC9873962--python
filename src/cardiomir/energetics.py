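"""Heart-failure-degree indices from echocardiographic measurements.

Six derived indices per patient:

* LVEF — ejection fraction, (LVEDV − LVESV)/LVEDV × 100 (%).
* LVM  — left-ventricular mass by a Devereux-type cube formula,
  0.8 × c × [(LVIDd + IVS + PWTs)³ − LVIDd³] + 0.6 with linear
  dimensions in cm. The source protocol prints the wall constant c = 1.4;
  the conventional Devereux value is 1.04 and is available via
  ``wall_constant=1.04``.
* BSA  — body surface area, 0.0061·height + 0.0128·weight − 0.1529
  (height in cm, weight in kg — the cm/kg anthropometric convention).
* LVFS_printed — LVM/BSA (g/m²). The source protocol labels this ratio
  "LVFS"; it is conventionally the LV mass index. The ordinary fractional
  shortening (LVIDd − LVIDs)/LVIDd × 100 is provided separately as
  :func:`fractional_shortening`.
* cESS — circumferential end-systolic wall stress. With a = LVIDs/2,
  b = a + PWTs, c = a + PWTs/2:  SBP · a² · (1 + b²/c²) / (b² − a²).
  This is the standard midwall (Gaasch-type) form; the source prints the
  expression with its grouping typeset away, and this reconstruction is
  consistent with every fragment of the printed string.
* MEE  — myocardial energy expenditure,
  cESS × LVET × LVSV × heart rate × 4.3×10⁻⁷, the constant applied
  verbatim; units are the formula's own.

All indices are pure deterministic functions of a single record.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

__all__ = [
    "EchoRecord",
    "EnergeticsResult",
    "MEE_CONSTANT",
    "PRINTED_WALL_CONSTANT",
    "DEVEREUX_WALL_CONSTANT",
    "lvef",
    "lvm",
    "bsa",
    "lvfs_printed",
    "fractional_shortening",
    "cess",
    "mee",
    "compute_indices",
    "energetics_batch",
]

MEE_CONSTANT = 4.3e-7
PRINTED_WALL_CONSTANT = 1.4
DEVEREUX_WALL_CONSTANT = 1.04

_FIELDS = ("lvedv", "lvesv", "ivs", "pwts", "lvidd", "lvids",
           "sbp", "lvet", "lvsv", "heart_rate", "height", "weight")


@dataclass(frozen=True)
class EchoRecord:
    """One patient's echocardiographic measurements.

    Units: volumes mL, linear dimensions cm, SBP mmHg, LVET s,
    heart rate beats/min, height cm, weight kg.
    """

    lvedv: float  # LV end-diastolic volume
    lvesv: float  # LV end-systolic volume
    ivs: float    # interventricular septal thickness
    pwts: float   # posterior wall thickness at end-systole
    lvidd: float  # LV internal diameter, end-diastole
    lvids: float  # LV internal diameter, end-systole
    sbp: float    # systolic blood pressure (cuff)
    lvet: float   # LV ejection time
    lvsv: float   # LV stroke volume
    heart_rate: float
    height: float
    weight: float

    def __post_init__(self) -> None:
        for name in _FIELDS:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.lvesv >= self.lvedv:
            raise ValueError("LVESV must be < LVEDV")
        if self.lvids >= self.lvidd:
            raise ValueError("LVIDs must be < LVIDd")


@dataclass(frozen=True)
class EnergeticsResult:
    lvef: float          # %
    lvm: float           # g (formula units)
    bsa: float           # m²
    lvfs_printed: float  # LVM/BSA, g/m²
    cess: float          # wall stress, formula units
    mee: float           # energy rate, formula units


def lvef(r: EchoRecord) -> float:
    """Ejection fraction in percent."""
    if r.lvedv <= 0:
        raise ValueError("LVEDV must be > 0")
    return (r.lvedv - r.lvesv) / r.lvedv * 100.0


def lvm(r: EchoRecord, wall_constant: float = PRINTED_WALL_CONSTANT) -> float:
    """Left-ventricular mass by the cube formula (dimensions in cm)."""
    return 0.8 * wall_constant * (
        (r.lvidd + r.ivs + r.pwts) ** 3 - r.lvidd ** 3
    ) + 0.6


def bsa(height: float, weight: float) -> float:
    """Body surface area (m²) from height (cm) and weight (kg)."""
    if height <= 0 or weight <= 0:
        raise ValueError("height and weight must be > 0")
    out = 0.0061 * height + 0.0128 * weight - 0.1529
    if out <= 0:
        raise ValueError("implausible anthropometrics: BSA <= 0")
    return out


def lvfs_printed(r: EchoRecord, wall_constant: float = PRINTED_WALL_CONSTANT) -> float:
    """LVM / BSA (g/m²), the mass index the source protocol calls LVFS."""
    return lvm(r, wall_constant) / bsa(r.height, r.weight)


def fractional_shortening(r: EchoRecord) -> float:
    """Conventional fractional shortening, (LVIDd − LVIDs)/LVIDd × 100."""
    return (r.lvidd - r.lvids) / r.lvidd * 100.0


def cess(r: EchoRecord) -> float:
    """Circumferential end-systolic wall stress."""
    a = r.lvids / 2.0
    b = a + r.pwts
    c = a + r.pwts / 2.0
    return r.sbp * a * a * (1.0 + b * b / (c * c)) / (b * b - a * a)


def mee(r: EchoRecord, wall_constant: float = PRINTED_WALL_CONSTANT) -> float:
    """Myocardial energy expenditure."""
    return cess(r) * r.lvet * r.lvsv * r.heart_rate * MEE_CONSTANT


def compute_indices(
    r: EchoRecord, wall_constant: float = PRINTED_WALL_CONSTANT
) -> EnergeticsResult:
    """All six indices for one record."""
    return EnergeticsResult(
        lvef=lvef(r),
        lvm=lvm(r, wall_constant),
        bsa=bsa(r.height, r.weight),
        lvfs_printed=lvfs_printed(r, wall_constant),
        cess=cess(r),
        mee=mee(r, wall_constant),
    )


def energetics_batch(
    records: Iterable[EchoRecord | Mapping[str, float]],
    wall_constant: float = PRINTED_WALL_CONSTANT,
) -> tuple[list[EnergeticsResult], list[tuple[int, str]]]:
    """Compute indices for many records, collecting validation failures.

    Mapping inputs are coerced to :class:`EchoRecord`; a record that fails
    validation contributes a ``(position, message)`` entry to the failure
    list while the remaining records are still processed.
    """
    results: list[EnergeticsResult] = []
    failures: list[tuple[int, str]] = []
    for i, rec in enumerate(records):
        try:
            if not isinstance(rec, EchoRecord):
                rec = EchoRecord(**{k: float(rec[k]) for k in _FIELDS})
            results.append(compute_indices(rec, wall_constant))
        except (ValueError, KeyError, TypeError) as exc:
            failures.append((i, str(exc)))
    return results, failures
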