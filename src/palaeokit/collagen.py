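"""Collagen yield, elemental QC, and stable-isotope scale normalization.

Well-preserved collagen is expected to fall in C% ~30-45, N% ~11-16 and
atomic C/N 2.9-3.6, with at least ~1% collagen yield by mass; extracts in
the upper C/N band (3.5-3.6) pass but are flagged as possibly carrying low
levels of carbon contamination.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd

__all__ = [
    "CollagenSample",
    "QcFlag",
    "QcReport",
    "collagen_yield",
    "atomic_cn",
    "qc_flags",
    "two_point_normalize",
    "qc_table",
]

# IUPAC standard atomic weights
_MASS_C = 12.011
_MASS_N = 14.007

YIELD_MIN_PCT = 1.0
C_PCT_WINDOW = (30.0, 45.0)
N_PCT_WINDOW = (11.0, 16.0)
CN_WINDOW = (2.9, 3.6)
CN_WARN_WINDOW = (3.5, 3.6)


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class CollagenSample:
    """One collagen extract with its elemental and isotopic measurements."""

    sample_id: str
    sampled_mass_mg: float
    collagen_mass_mg: float
    pct_c: float
    pct_n: float
    d13c: float | None = None  # permil vs VPDB
    d15n: float | None = None  # permil vs AIR
    # lab-reported C/N, computed from unrounded elemental measurements; when
    # absent, QC recomputes it from pct_c/pct_n (which may be rounded)
    cn_reported: float | None = None

    def __post_init__(self) -> None:
        if self.sampled_mass_mg <= 0:
            raise ValidationError("sampled mass must be > 0")
        if self.collagen_mass_mg < 0:
            raise ValidationError("collagen mass must be >= 0")
        for name, v in (("pct_c", self.pct_c), ("pct_n", self.pct_n)):
            if not 0 < v <= 100:
                raise ValidationError(f"{name}={v} outside (0, 100]")


@dataclass(frozen=True)
class QcFlag:
    criterion: str
    value: float
    window: tuple[float, float]
    status: str  # pass / warn / fail


@dataclass(frozen=True)
class QcReport:
    sample_id: str
    yield_pct: float
    atomic_cn: float
    flags: tuple[QcFlag, ...]

    @property
    def passed(self) -> bool:
        return all(f.status != "fail" for f in self.flags)

    @property
    def warnings(self) -> tuple[QcFlag, ...]:
        return tuple(f for f in self.flags if f.status == "warn")


def round_half_up(x: float, decimals: int = 1) -> float:
    """Half-up decimal rounding, matching lab reporting conventions."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def collagen_yield(sampled_mass_mg: float, collagen_mass_mg: float) -> float:
    """Collagen yield in percent of sampled mass (full precision)."""
    if sampled_mass_mg <= 0:
        raise ValidationError("sampled mass must be > 0")
    if collagen_mass_mg > sampled_mass_mg:
        raise ValidationError("collagen mass exceeds sampled mass")
    return 100.0 * collagen_mass_mg / sampled_mass_mg


def atomic_cn(pct_c: float, pct_n: float) -> float:
    """Molar (atomic) carbon-to-nitrogen ratio from mass percentages."""
    if pct_n <= 0:
        raise ValidationError("pct_n must be > 0")
    return (pct_c / _MASS_C) / (pct_n / _MASS_N)


def two_point_normalize(
    measured_delta: float,
    std1: tuple[float, float],
    std2: tuple[float, float],
) -> float:
    """Two-point scale normalization against certified reference materials.

    ``std1`` and ``std2`` are (measured, certified) pairs; the linear map
    sending each measured standard to its certified value is applied to
    ``measured_delta``.
    """
    (m1, c1), (m2, c2) = std1, std2
    if m1 == m2:
        raise ValidationError("degenerate standards: equal measured values")
    slope = (c2 - c1) / (m2 - m1)
    return c1 + slope * (measured_delta - m1)


def qc_flags(sample: CollagenSample) -> QcReport:
    """Apply the preservation windows and return per-criterion flags.

    Yield >= 1%, C% in 30-45, N% in 11-16, atomic C/N in 2.9-3.6; a C/N in
    3.5-3.6 passes with a contamination warning.
    """
    y = collagen_yield(sample.sampled_mass_mg, sample.collagen_mass_mg)
    cn = sample.cn_reported if sample.cn_reported is not None else atomic_cn(
        sample.pct_c, sample.pct_n)
    flags = [
        QcFlag("yield_pct", y, (YIELD_MIN_PCT, float("inf")),
               "pass" if y >= YIELD_MIN_PCT else "fail"),
        QcFlag("pct_c", sample.pct_c, C_PCT_WINDOW,
               "pass" if C_PCT_WINDOW[0] <= sample.pct_c <= C_PCT_WINDOW[1] else "fail"),
        QcFlag("pct_n", sample.pct_n, N_PCT_WINDOW,
               "pass" if N_PCT_WINDOW[0] <= sample.pct_n <= N_PCT_WINDOW[1] else "fail"),
    ]
    # compare C/N at reporting precision: printed windows refer to 1-dp values
    cn_1dp = round_half_up(cn, 1)
    if not CN_WINDOW[0] <= cn_1dp <= CN_WINDOW[1]:
        cn_status = "fail"
    elif CN_WARN_WINDOW[0] <= cn_1dp <= CN_WARN_WINDOW[1]:
        cn_status = "warn"
    else:
        cn_status = "pass"
    flags.append(QcFlag("atomic_cn", cn, CN_WINDOW, cn_status))
    return QcReport(
        sample_id=sample.sample_id,
        yield_pct=y,
        atomic_cn=cn,
        flags=tuple(flags),
    )


def qc_table(samples: list[CollagenSample]) -> pd.DataFrame:
    """QC report for a batch of samples, one row each, at reporting precision."""
    rows = []
    for s in samples:
        rep = qc_flags(s)
        rows.append(
            {
                "sample_id": s.sample_id,
                "yield_pct": round_half_up(rep.yield_pct, 1),
                "atomic_cn": round_half_up(rep.atomic_cn, 2),
                "status": "fail" if not rep.passed else ("warn" if rep.warnings else "pass"),
                "failed": ";".join(f.criterion for f in rep.flags if f.status == "fail"),
                "warned": ";".join(f.criterion for f in rep.flags if f.status == "warn"),
            }
        )
    return pd.DataFrame(rows)
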