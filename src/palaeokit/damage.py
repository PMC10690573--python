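"""Read filtering, duplicate collapse, and terminal-deamination analysis.

Ancient DNA authenticates itself through post-mortem cytosine deamination,
read as elevated C->T mismatches at fragment ends. All damage accounting
here is done in read orientation: minus-strand reads are reverse-
complemented (together with their reference window) before counting, so
single-stranded-library damage appears as C->T at both ends.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .io import FastaRecord, SamRecord

__all__ = [
    "DamageProfile",
    "ReadSet",
    "filter_reads",
    "remove_duplicates",
    "damage_profile",
    "filter_deaminated",
    "oriented_pairs",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class ReadSet:
    reads: tuple[SamRecord, ...]
    flags: frozenset[str] = frozenset()

    def __len__(self) -> int:
        return len(self.reads)

    def with_flag(self, flag: str) -> "ReadSet":
        return ReadSet(reads=self.reads, flags=self.flags | {flag})


@dataclass(frozen=True)
class DamageProfile:
    """C->T mismatch frequency at the first/last K aligned read positions.

    Frequencies are NaN where no reference-C opportunity exists; the
    denominators record the number of opportunities per position.
    """

    pos5: np.ndarray
    pos3: np.ndarray
    denom5: np.ndarray
    denom3: np.ndarray


def oriented_pairs(
    rec: SamRecord, ref: FastaRecord, min_baseq: int = 0
) -> list[tuple[str, str]]:
    """(read_base, ref_base) along the read in its sequencing orientation.

    Insertions (no reference base) and deletions (no read base) are
    skipped; soft clips are never aligned. Minus-strand reads have both
    read and reference bases complemented and the order reversed.
    """
    out = []
    for q, r in rec.aligned_pairs():
        if q is None or r is None:
            continue
        if r >= len(ref):
            raise ValueError(f"read {rec.qname!r} overhangs reference end")
        if min_baseq > 0 and ord(rec.qual[q]) - 33 < min_baseq:
            continue
        out.append((rec.seq[q], ref.sequence[r]))
    if rec.strand == "-":
        out = [(b.translate(_COMPLEMENT), r.translate(_COMPLEMENT)) for b, r in out[::-1]]
    return out


def filter_reads(
    reads, min_len: int = 35, min_mapq: int = 25
) -> ReadSet:
    """Drop reads shorter than ``min_len`` aligned bases or below ``min_mapq``."""
    kept = tuple(
        r for r in reads if r.aligned_length >= min_len and r.mapq >= min_mapq
    )
    return ReadSet(reads=kept, flags=frozenset({"filtered"}))


def remove_duplicates(reads) -> tuple[ReadSet, float]:
    """Collapse PCR duplicates sharing (reference, start, end, strand).

    Within a duplicate group of equal-length sequences the representative
    is built by per-column majority vote, ties resolved by higher summed
    base quality; groups of unequal lengths keep the highest-quality read.
    Returns the deduplicated set and the duplication rate n_in/n_out.
    """
    if isinstance(reads, ReadSet):
        flags = reads.flags
        items = reads.reads
    else:
        flags = frozenset({"filtered"})
        items = tuple(reads)
    groups: dict[tuple, list[SamRecord]] = defaultdict(list)
    for r in items:
        groups[(r.rname, r.pos, r.reference_end, r.strand)].append(r)
    survivors = []
    for key in sorted(groups):
        group = sorted(groups[key], key=lambda r: r.qname)
        if len(group) == 1:
            survivors.append(group[0])
            continue
        lengths = {len(g.seq) for g in group}
        if len(lengths) != 1:
            survivors.append(max(group, key=lambda r: sum(r.qual.encode()) ))
            continue
        n = lengths.pop()
        cols = []
        quals = []
        for i in range(n):
            counts: dict[str, int] = defaultdict(int)
            qsum: dict[str, int] = defaultdict(int)
            for g in group:
                counts[g.seq[i]] += 1
                qsum[g.seq[i]] += ord(g.qual[i]) - 33
            best = max(counts, key=lambda b: (counts[b], qsum[b], b))
            cols.append(best)
            quals.append(max(ord(g.qual[i]) for g in group))
        rep = group[0]
        survivors.append(
            SamRecord(
                qname=rep.qname,
                strand=rep.strand,
                rname=rep.rname,
                pos=rep.pos,
                mapq=max(g.mapq for g in group),
                cigar=rep.cigar,
                seq="".join(cols),
                qual="".join(chr(q) for q in quals),
            )
        )
    rate = len(items) / len(survivors) if survivors else float("nan")
    return ReadSet(reads=tuple(survivors), flags=flags | {"deduplicated"}), rate


def damage_profile(
    reads, ref: FastaRecord, k: int = 15, min_baseq: int = 0
) -> DamageProfile:
    """C->T frequency at the first and last ``k`` aligned read positions."""
    items = reads.reads if isinstance(reads, ReadSet) else tuple(reads)
    num5 = np.zeros(k)
    den5 = np.zeros(k)
    num3 = np.zeros(k)
    den3 = np.zeros(k)
    for rec in items:
        pairs = oriented_pairs(rec, ref, min_baseq=min_baseq)
        n = len(pairs)
        for i in range(min(k, n)):
            b, r = pairs[i]
            if r == "C":
                den5[i] += 1
                if b == "T":
                    num5[i] += 1
        for j in range(min(k, n)):
            b, r = pairs[n - 1 - j]
            if r == "C":
                den3[j] += 1
                if b == "T":
                    num3[j] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        pos5 = np.where(den5 > 0, num5 / np.where(den5 > 0, den5, 1), np.nan)
        pos3 = np.where(den3 > 0, num3 / np.where(den3 > 0, den3, 1), np.nan)
    return DamageProfile(pos5=pos5, pos3=pos3, denom5=den5, denom3=den3)


def is_deaminated(rec: SamRecord, ref: FastaRecord, n_terminal: int = 3) -> bool:
    """True if the read carries a C->T mismatch within the first or last
    ``n_terminal`` aligned positions (read orientation)."""
    pairs = oriented_pairs(rec, ref)
    n = len(pairs)
    head = pairs[: min(n_terminal, n)]
    tail = pairs[max(0, n - n_terminal):]
    return any(r == "C" and b == "T" for b, r in head + tail)


def filter_deaminated(reads, ref: FastaRecord, n_terminal: int = 3) -> ReadSet:
    """Restrict to putatively deaminated fragments.

    Retains reads with at least one terminal C->T; this enriches for
    endogenous ancient molecules because present-day contaminants carry
    no deamination (they can only enter via sequencing error).
    """
    if isinstance(reads, ReadSet):
        flags = reads.flags
        items = reads.reads
    else:
        flags = frozenset({"filtered"})
        items = tuple(reads)
    kept = tuple(r for r in items if is_deaminated(r, ref, n_terminal))
    return ReadSet(reads=kept, flags=flags | {"deaminated-only"})
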