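"""Molecular sex determination from SNP-capture coverage.

Because X, Y and autosomal targets differ in number on a capture array,
raw chromosome hit fractions are adjusted by the panel composition:
x_ratio = (Nx_o/Nauto_o)/(Nx_e/Nauto_e) and likewise for Y. A Y-ratio
below 0.05 indicates a female, above 0.2 a male; values between are
indeterminate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import SamRecord, SnpPanel

__all__ = [
    "CoverageCounts",
    "SexCall",
    "count_covered_targets",
    "sex_ratios",
    "classify_sex",
    "FEMALE_MAX_Y_RATIO",
    "MALE_MIN_Y_RATIO",
]

FEMALE_MAX_Y_RATIO = 0.05
MALE_MIN_Y_RATIO = 0.2


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class CoverageCounts:
    """Observed covered-target counts and panel totals per chromosome class."""

    n_auto_obs: int
    n_x_obs: int
    n_y_obs: int
    n_auto_exp: int
    n_x_exp: int
    n_y_exp: int

    def __post_init__(self) -> None:
        for obs, exp, name in (
            (self.n_auto_obs, self.n_auto_exp, "auto"),
            (self.n_x_obs, self.n_x_exp, "X"),
            (self.n_y_obs, self.n_y_exp, "Y"),
        ):
            if exp <= 0:
                raise ValidationError(f"{name}: expected target count must be > 0")
            if not 0 <= obs <= exp:
                raise ValidationError(f"{name}: observed {obs} outside [0, {exp}]")


@dataclass(frozen=True)
class SexCall:
    x_ratio: float
    y_ratio: float
    call: str  # female / male / indeterminate


def count_covered_targets(reads, panel: SnpPanel) -> CoverageCounts:
    """Count targets overlapped by at least one retained fragment.

    A target counts as covered (once) if any read's aligned reference span
    contains its position; per-base depth is irrelevant here.
    """
    from .damage import ReadSet

    items = reads.reads if isinstance(reads, ReadSet) else tuple(reads)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in items:
        by_chrom.setdefault(r.rname, []).append((r.pos, r.reference_end))

    covered = {"auto": 0, "x": 0, "y": 0}
    classes = panel.targets["chrom"].map(
        {str(i): "auto" for i in range(1, 23)} | {"X": "x", "Y": "y"}
    )
    for chrom, sub in panel.targets.groupby("chrom"):
        ivs = by_chrom.get(str(chrom))
        if not ivs:
            continue
        # sweep: prefix-sum of interval starts minus ends gives depth at a point
        starts = np.sort(np.array([s for s, _ in ivs]))
        ends = np.sort(np.array([e for _, e in ivs]))
        pos = sub["pos"].to_numpy()
        depth = np.searchsorted(starts, pos, side="right") - np.searchsorted(
            ends, pos, side="right"
        )
        cls = classes.loc[sub.index].iloc[0]
        covered[cls] += int((depth > 0).sum())
    return CoverageCounts(
        n_auto_obs=covered["auto"],
        n_x_obs=covered["x"],
        n_y_obs=covered["y"],
        n_auto_exp=panel.n_auto,
        n_x_exp=panel.n_x,
        n_y_exp=panel.n_y,
    )


def sex_ratios(c: CoverageCounts) -> tuple[float, float]:
    """Panel-adjusted (x_ratio, y_ratio)."""
    if c.n_auto_obs == 0:
        raise ValidationError("no autosomal targets covered; ratios undefined")
    x_ratio = (c.n_x_obs / c.n_auto_obs) / (c.n_x_exp / c.n_auto_exp)
    y_ratio = (c.n_y_obs / c.n_auto_obs) / (c.n_y_exp / c.n_auto_exp)
    return x_ratio, y_ratio


def classify_sex(
    c: CoverageCounts,
    female_max: float = FEMALE_MAX_Y_RATIO,
    male_min: float = MALE_MIN_Y_RATIO,
) -> SexCall:
    """Classify genetic sex from the adjusted Y-ratio.

    Strict inequalities: a Y-ratio exactly at a threshold is
    indeterminate. The X-ratio is reported as supporting evidence only.
    """
    x_ratio, y_ratio = sex_ratios(c)
    if y_ratio < female_max:
        call = "female"
    elif y_ratio > male_min:
        call = "male"
    else:
        call = "indeterminate"
    return SexCall(x_ratio=x_ratio, y_ratio=y_ratio, call=call)
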