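"""Pileup construction and mtDNA consensus calling.

A consensus base is called only where coverage is at least 5-fold and the
majority base is supported by at least 80% of overlapping reads; all
other sites are N. The reference is treated as linear: reads overhanging
the end are rejected (the circular origin is not modelled).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .damage import ReadSet
from .io import FastaRecord

__all__ = [
    "Pileup",
    "ConsensusGenome",
    "HaplotypeComparison",
    "build_pileup",
    "call_consensus",
    "compare_haplotypes",
    "contamination_check",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_DEL = 4
_IDX_BASE = "ACGT"


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class Pileup:
    """Per-site counts of A, C, G, T and spanning deletions."""

    counts: np.ndarray  # (L, 5)
    ref: FastaRecord

    @property
    def coverage(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass(frozen=True)
class ConsensusGenome:
    sequence: str
    coverage: np.ndarray
    support: np.ndarray  # majority-base fraction; NaN where coverage 0
    variants: tuple[tuple[int, str, str], ...]  # (0-based pos, ref, called)
    ref_id: str = ""

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_called(self) -> int:
        return sum(1 for b in self.sequence if b != "N")


@dataclass(frozen=True)
class HaplotypeComparison:
    n_overlap: int
    n_diff: int
    diff_positions: tuple[int, ...]
    shared_variants: tuple[tuple[int, str, str], ...]
    private_a: tuple[tuple[int, str, str], ...]
    private_b: tuple[tuple[int, str, str], ...]
    missing_a: int
    missing_b: int


def build_pileup(reads, ref: FastaRecord) -> Pileup:
    """Count aligned bases per reference site; deletions counted, insertions
    ignored (they do not correspond to a reference site)."""
    items = reads.reads if isinstance(reads, ReadSet) else tuple(reads)
    counts = np.zeros((len(ref), 5), dtype=np.int64)
    for rec in items:
        if rec.reference_end > len(ref):
            raise ValidationError(f"read {rec.qname!r} overhangs reference end")
        for q, r in rec.aligned_pairs():
            if r is None:
                continue
            if q is None:
                counts[r, _DEL] += 1
            else:
                b = rec.seq[q]
                if b in _BASE_INDEX:
                    counts[r, _BASE_INDEX[b]] += 1
    return Pileup(counts=counts, ref=ref)


def call_consensus(
    p: Pileup, min_cov: int = 5, min_support: float = 0.8
) -> ConsensusGenome:
    """Call each site to its majority base where coverage and support
    thresholds (both inclusive) are met; otherwise N. A deletion majority
    or an exact tie for the top count also yields N."""
    counts = p.counts
    cov = counts.sum(axis=1)
    top = counts.max(axis=1)
    # a tie for the majority is not a majority
    tied = (counts == top[:, None]).sum(axis=1) > 1
    argmax = counts.argmax(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        support = np.where(cov > 0, top / np.where(cov > 0, cov, 1), np.nan)
    callable_ = (cov >= min_cov) & (support >= min_support) & ~tied & (argmax != _DEL)
    seq = np.full(len(cov), "N", dtype="U1")
    seq[callable_] = np.array(list(_IDX_BASE))[argmax[callable_]]
    sequence = "".join(seq)
    variants = tuple(
        (i, p.ref.sequence[i], sequence[i])
        for i in range(len(sequence))
        if sequence[i] != "N" and sequence[i] != p.ref.sequence[i]
    )
    return ConsensusGenome(
        sequence=sequence,
        coverage=cov,
        support=support,
        variants=variants,
        ref_id=p.ref.id,
    )


def compare_haplotypes(a: ConsensusGenome, b: ConsensusGenome) -> HaplotypeComparison:
    """Compare two consensus genomes at jointly called (non-N) sites."""
    if len(a) != len(b):
        raise ValidationError("consensus genomes have different lengths")
    sa, sb = a.sequence, b.sequence
    both = [i for i in range(len(sa)) if sa[i] != "N" and sb[i] != "N"]
    diffs = tuple(i for i in both if sa[i] != sb[i])
    va = {v[0]: v for v in a.variants}
    vb = {v[0]: v for v in b.variants}
    shared = tuple(va[i] for i in sorted(set(va) & set(vb)) if va[i] == vb[i])
    return HaplotypeComparison(
        n_overlap=len(both),
        n_diff=len(diffs),
        diff_positions=diffs,
        shared_variants=shared,
        private_a=tuple(va[i] for i in sorted(set(va) - set(vb))),
        private_b=tuple(vb[i] for i in sorted(set(vb) - set(va))),
        missing_a=sa.count("N"),
        missing_b=sb.count("N"),
    )


def contamination_check(
    sample: ConsensusGenome, negative_control: ConsensusGenome
) -> dict:
    """Flag variants shared with a negative control.

    Variants present in both the sample and a laboratory negative control
    point to contamination introduced during processing (common
    population-wide variants, e.g. at position 73 of the human mtDNA,
    may be benign; the report lists them for review rather than failing).
    """
    shared = compare_haplotypes(sample, negative_control).shared_variants
    return {
        "shared_variants": shared,
        "warning": len(shared) > 0,
    }
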