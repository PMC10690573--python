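"""Pseudo-haploid genotyping and f3/D statistics with block-jackknife errors.

Outgroup-f3(X, Y; O) measures shared drift of X and Y relative to an
outgroup O as the mean over SNPs of (pO - pX)(pO - pY); the D statistic
D(W, X; Y, Z) tests treeness as a normalized sum of (pW - pX)(pY - pZ).
Standard errors come from a weighted (Busing-style) leave-one-block-out
jackknife over physical genome blocks, which is robust to linkage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import SamRecord

__all__ = [
    "GenoTable",
    "FStatResult",
    "pseudohaploid_call",
    "outgroup_f3",
    "d_stat",
    "block_jackknife",
    "assign_blocks",
]

DEFAULT_BLOCK_SIZE = 5_000_000  # bp; ~0.05 Morgan at a typical human rate


class ValidationError(ValueError):
    pass


@dataclass
class GenoTable:
    """Pseudo-haploid genotype matrix with SNP metadata.

    snps: DataFrame (chrom, pos, ref, alt), one row per SNP, positions
    sorted within chromosome. geno: (n_snp, n_ind) over {0,1,9}.
    individuals: (id, sex, population) per column.
    """

    snps: pd.DataFrame
    geno: np.ndarray
    individuals: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        self.geno = np.asarray(self.geno)
        if self.geno.shape != (len(self.snps), len(self.individuals)):
            raise ValidationError("geno shape does not match snps x individuals")
        if not np.isin(self.geno, (0, 1, 9)).all():
            raise ValidationError("pseudo-haploid calls must be in {0, 1, 9}")

    def populations(self) -> list[str]:
        return sorted({pop for _, _, pop in self.individuals})

    def pop_columns(self, pop: str) -> np.ndarray:
        cols = [i for i, (_, _, p) in enumerate(self.individuals) if p == pop]
        if not cols:
            raise ValidationError(f"no individuals in population {pop!r}")
        return np.array(cols)

    def allele_freq(self, pop: str) -> np.ndarray:
        """Derived-allele sample frequency per SNP; NaN where all missing."""
        sub = self.geno[:, self.pop_columns(pop)].astype(float)
        sub[sub == 9] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(sub, axis=1)


@dataclass(frozen=True)
class FStatResult:
    statistic: str
    value: float
    se: float
    z: float
    n_snps: int
    n_blocks: int


def pseudohaploid_call(
    bases_positions: Sequence[tuple[str, int, int]],
    ref_allele: str,
    alt_allele: str,
    trim: int = 3,
    rng: np.random.Generator | int = 0,
) -> int:
    """One random-read pseudo-haploid call at a SNP.

    ``bases_positions``: (base, read_position_from_5', read_length) for
    each read overlapping the site. Bases within ``trim`` of either
    fragment end are discarded to avoid deamination artefacts; one
    surviving base is drawn uniformly. Returns 0 (ref), 1 (alt) or 9.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    usable = [
        b
        for b, pos, length in bases_positions
        if trim <= pos < length - trim
    ]
    if not usable:
        return 9
    base = usable[rng.integers(0, len(usable))]
    if base == ref_allele:
        return 0
    if base == alt_allele:
        return 1
    return 9


def assign_blocks(snps: pd.DataFrame, block_size: int = DEFAULT_BLOCK_SIZE) -> np.ndarray:
    """Physical block index per SNP: chromosome x floor(pos/block_size)."""
    keys = list(
        zip(snps["chrom"].astype(str), (snps["pos"] // block_size).astype(int))
    )
    uniq = {k: i for i, k in enumerate(dict.fromkeys(keys))}
    return np.array([uniq[k] for k in keys])


def block_jackknife(
    numerators: np.ndarray,
    blocks: np.ndarray,
    denominators: np.ndarray | None = None,
) -> tuple[float, float]:
    """Weighted delete-one-block jackknife for a ratio-of-sums estimator.

    The estimate is sum(num)/sum(den) (den defaults to 1 per term, i.e. a
    mean). Returns (estimate, standard error) using Busing-style weights
    h_j = n/m_j with m_j the block weight.
    """
    numerators = np.asarray(numerators, dtype=float)
    blocks = np.asarray(blocks)
    if denominators is None:
        denominators = np.ones_like(numerators)
    denominators = np.asarray(denominators, dtype=float)
    uniq = np.unique(blocks)
    if len(uniq) < 2:
        raise ValidationError("block jackknife needs >= 2 blocks")
    num_tot = numerators.sum()
    den_tot = denominators.sum()
    if den_tot == 0:
        raise ValidationError("zero denominator across all SNPs")
    est = num_tot / den_tot
    m = np.array([denominators[blocks == b].sum() for b in uniq])
    uniq = uniq[m > 0]  # zero-weight blocks carry no information
    m = m[m > 0]
    if len(uniq) < 2:
        raise ValidationError("block jackknife needs >= 2 blocks with weight")
    g = len(uniq)
    loo = np.array(
        [
            (num_tot - numerators[blocks == b].sum())
            / (den_tot - denominators[blocks == b].sum())
            for b in uniq
        ]
    )
    h = den_tot / m
    theta_j = g * est - float(np.sum((1.0 - m / den_tot) * loo))
    tau = h * est - (h - 1.0) * loo
    var = float(np.sum((tau - theta_j) ** 2 / (h - 1.0)) / g)
    return float(theta_j), float(np.sqrt(var))


def outgroup_f3(
    geno: GenoTable,
    pop_x: str,
    pop_y: str,
    outgroup: str,
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> FStatResult:
    """f3(X, Y; O) = mean over usable SNPs of (pO - pX)(pO - pY).

    A SNP is usable when every involved population has at least one
    non-missing call. No small-sample bias correction is applied, the
    standard convention for outgroup-f3 on pseudo-haploid data.
    """
    p_x = geno.allele_freq(pop_x)
    p_y = geno.allele_freq(pop_y)
    p_o = geno.allele_freq(outgroup)
    use = ~(np.isnan(p_x) | np.isnan(p_y) | np.isnan(p_o))
    if not use.any():
        raise ValidationError("no SNPs with data in all three populations")
    terms = (p_o[use] - p_x[use]) * (p_o[use] - p_y[use])
    blocks = assign_blocks(geno.snps[use], block_size)
    est, se = block_jackknife(terms, blocks)
    return FStatResult(
        statistic=f"f3({pop_x},{pop_y};{outgroup})",
        value=est,
        se=se,
        z=est / se if se > 0 else np.nan,
        n_snps=int(use.sum()),
        n_blocks=len(np.unique(blocks)),
    )


def d_stat(
    geno: GenoTable,
    pop_w: str,
    pop_x: str,
    pop_y: str,
    pop_z: str,
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> FStatResult:
    """D(W, X; Y, Z) with block-jackknife error.

    D = sum (pW - pX)(pY - pZ) / sum (pW + pX - 2 pW pX)(pY + pZ - 2 pY pZ).
    Under treeness ((W,X),(Y,Z)) without gene flow, E[D] = 0.
    """
    p_w = geno.allele_freq(pop_w)
    p_x = geno.allele_freq(pop_x)
    p_y = geno.allele_freq(pop_y)
    p_z = geno.allele_freq(pop_z)
    use = ~(np.isnan(p_w) | np.isnan(p_x) | np.isnan(p_y) | np.isnan(p_z))
    if not use.any():
        raise ValidationError("no SNPs with data in all four populations")
    num = (p_w[use] - p_x[use]) * (p_y[use] - p_z[use])
    den = (p_w[use] + p_x[use] - 2 * p_w[use] * p_x[use]) * (
        p_y[use] + p_z[use] - 2 * p_y[use] * p_z[use]
    )
    if den.sum() == 0:
        raise ValidationError("zero D denominator over all usable SNPs")
    blocks = assign_blocks(geno.snps[use], block_size)
    est, se = block_jackknife(num, blocks, den)
    return FStatResult(
        statistic=f"D({pop_w},{pop_x};{pop_y},{pop_z})",
        value=est,
        se=se,
        z=est / se if se > 0 else np.nan,
        n_snps=int(use.sum()),
        n_blocks=len(np.unique(blocks)),
    )
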