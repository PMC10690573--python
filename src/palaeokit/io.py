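"""Readers and writers for the plain-text formats the pipeline touches.

Coordinates are 0-based half-open everywhere inside the package; SAM's
1-based inclusive coordinates are converted at this boundary and nowhere
else. Only the text flavours of each format are supported (SAM not BAM,
uncompressed FASTA, IntCal-style ``.14c``, EIGENSTRAT triple).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FormatError",
    "FastaRecord",
    "SamRecord",
    "CalCurve",
    "SnpPanel",
    "read_fasta",
    "write_fasta",
    "read_sam",
    "write_sam",
    "read_cal_curve",
    "write_cal_curve",
    "read_snp_panel",
    "write_snp_panel",
    "read_eigenstrat",
    "write_eigenstrat",
]

_ALPHABET = set("ACGTN")
# N/H/P never occur in short ancient-DNA fragments; rejecting them keeps the
# alignment arithmetic in one simple code path.
_SUPPORTED_CIGAR_OPS = set("MIDS=X")
_QUERY_OPS = set("MIS=X")
_REF_OPS = set("MDN=X")


class FormatError(ValueError):
    """A file does not conform to the expected text format."""


@dataclass(frozen=True)
class FastaRecord:
    """A named nucleotide sequence restricted to the {A,C,G,T,N} alphabet."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("FASTA record with empty id")
        if not self.sequence:
            raise FormatError(f"FASTA record {self.id!r} has empty sequence")
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise FormatError(
                f"FASTA record {self.id!r} contains invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    """Split a CIGAR string into (op, length) tuples, validating the ops."""
    if not cigar or cigar == "*":
        raise FormatError("missing CIGAR string")
    out: list[tuple[str, int]] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if not num:
                raise FormatError(f"malformed CIGAR {cigar!r}")
            if ch not in _SUPPORTED_CIGAR_OPS:
                raise FormatError(
                    f"CIGAR op {ch!r} not supported (only M,I,D,S,=,X): {cigar!r}"
                )
            out.append((ch, int(num)))
            num = ""
    if num:
        raise FormatError(f"malformed CIGAR {cigar!r}")
    return out


@dataclass(frozen=True)
class SamRecord:
    """One aligned read.

    ``pos`` is the 0-based leftmost reference coordinate. ``seq``/``qual``
    are stored as in the SAM file, i.e. on the forward reference strand;
    ``strand`` records the original orientation (flag bit 0x10).
    """

    qname: str
    strand: str
    rname: str
    pos: int
    mapq: int
    cigar: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.pos < 0:
            raise FormatError("negative reference position")
        if not 0 <= self.mapq <= 255:
            raise FormatError(f"mapq {self.mapq} outside 0..255")
        if len(self.seq) != len(self.qual):
            raise FormatError(
                f"read {self.qname!r}: seq length {len(self.seq)} != qual length {len(self.qual)}"
            )
        qlen = sum(n for op, n in parse_cigar(self.cigar) if op in _QUERY_OPS)
        if qlen != len(self.seq):
            raise FormatError(
                f"read {self.qname!r}: CIGAR query length {qlen} != seq length {len(self.seq)}"
            )

    @property
    def reference_end(self) -> int:
        """0-based exclusive end of the alignment on the reference."""
        return self.pos + sum(n for op, n in parse_cigar(self.cigar) if op in _REF_OPS)

    @property
    def aligned_length(self) -> int:
        """Number of query bases consumed by alignment ops (soft clips excluded)."""
        return sum(n for op, n in parse_cigar(self.cigar) if op in ("M", "I", "=", "X"))

    def aligned_pairs(self) -> list[tuple[int | None, int | None]]:
        """(query_pos, ref_pos) pairs; None marks a gap on that side.

        Soft-clipped query bases are omitted entirely: they are not aligned.
        """
        pairs: list[tuple[int | None, int | None]] = []
        q, r = 0, self.pos
        for op, n in parse_cigar(self.cigar):
            if op in ("M", "=", "X"):
                pairs.extend((q + i, r + i) for i in range(n))
                q += n
                r += n
            elif op == "I":
                pairs.extend((q + i, None) for i in range(n))
                q += n
            elif op == "D":
                pairs.extend((None, r + i) for i in range(n))
                r += n
            elif op == "S":
                q += n
        return pairs


@dataclass(frozen=True)
class CalCurve:
    """A gridded radiocarbon calibration curve.

    cal_bp: strictly ascending calendar ages (cal BP)
    c14_bp: conventional radiocarbon age of the curve at each calendar age
    err:    1-sigma curve uncertainty in 14C years (all > 0)
    """

    cal_bp: np.ndarray
    c14_bp: np.ndarray
    err: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "cal_bp", np.asarray(self.cal_bp, dtype=float))
        object.__setattr__(self, "c14_bp", np.asarray(self.c14_bp, dtype=float))
        object.__setattr__(self, "err", np.asarray(self.err, dtype=float))
        n = len(self.cal_bp)
        if n < 2 or len(self.c14_bp) != n or len(self.err) != n:
            raise FormatError("calibration curve needs >= 2 rows of equal length")
        if not np.all(np.diff(self.cal_bp) > 0):
            raise FormatError("calibration curve cal BP ages must be strictly ascending")
        if not np.all(self.err > 0):
            raise FormatError("calibration curve errors must be positive")
        if not (np.all(np.isfinite(self.cal_bp)) and np.all(np.isfinite(self.c14_bp))):
            raise FormatError("calibration curve contains non-finite values")

    def interp(self, cal_ages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Linearly interpolated (mu, sigma_curve) at the given calendar ages."""
        cal_ages = np.asarray(cal_ages, dtype=float)
        mu = np.interp(cal_ages, self.cal_bp, self.c14_bp)
        sig = np.interp(cal_ages, self.cal_bp, self.err)
        return mu, sig


_CHROM_CLASSES = {str(i): "auto" for i in range(1, 23)} | {"X": "x", "Y": "y"}


@dataclass
class SnpPanel:
    """A capture-array target list with per-chromosome-class totals."""

    targets: pd.DataFrame  # columns: chrom (str), pos (0-based int), ref, alt

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "ref", "alt"}
        if not required <= set(self.targets.columns):
            raise FormatError(f"SNP panel needs columns {sorted(required)}")
        self.targets = self.targets.copy()
        self.targets["chrom"] = self.targets["chrom"].astype(str)
        unknown = set(self.targets["chrom"]) - set(_CHROM_CLASSES)
        if unknown:
            raise FormatError(f"unknown chromosome labels {sorted(unknown)}")
        if self.targets.duplicated(["chrom", "pos"]).any():
            raise FormatError("duplicate target positions within a chromosome")

    def _class_mask(self, cls: str) -> pd.Series:
        return self.targets["chrom"].map(_CHROM_CLASSES) == cls

    @property
    def n_auto(self) -> int:
        return int(self._class_mask("auto").sum())

    @property
    def n_x(self) -> int:
        return int(self._class_mask("x").sum())

    @property
    def n_y(self) -> int:
        return int(self._class_mask("y").sum())


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[FastaRecord]:
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
        if first != ">":
            raise FormatError(f"{path}: FASTA must begin with '>'")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(FastaRecord(id=rec.id, sequence=str(rec.seq).upper()))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta(records: Iterable[FastaRecord], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# SAM (text). pysam does the heavy lifting; unmapped records are dropped and
# pysam's 0-based coordinates are kept as-is.

def read_sam(path: str | Path) -> list[SamRecord]:
    try:
        af = pysam.AlignmentFile(str(path), "r", check_sq=False)
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: cannot parse SAM: {exc}") from exc
    records = []
    with af:
        try:
            for read in af:
                if read.is_unmapped:
                    continue
                records.append(
                    SamRecord(
                        qname=read.query_name,
                        strand="-" if read.is_reverse else "+",
                        rname=read.reference_name,
                        pos=read.reference_start,
                        mapq=read.mapping_quality,
                        cigar=read.cigarstring,
                        seq=read.query_sequence,
                        qual="".join(chr(q + 33) for q in read.query_qualities)
                        if read.query_qualities is not None
                        else "I" * len(read.query_sequence),
                    )
                )
        except (ValueError, OSError) as exc:
            raise FormatError(f"{path}: malformed SAM record: {exc}") from exc
    return records


def write_sam(
    records: Iterable[SamRecord],
    references: Sequence[FastaRecord],
    path: str | Path,
) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": r.id, "LN": len(r)} for r in references],
    }
    name_to_tid = {r.id: i for i, r in enumerate(references)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.qname
            a.flag = 16 if rec.strand == "-" else 0
            a.reference_id = name_to_tid[rec.rname]
            a.reference_start = rec.pos
            a.mapping_quality = rec.mapq
            a.cigarstring = rec.cigar
            a.query_sequence = rec.seq
            a.query_qualities = pysam.qualitystring_to_array(rec.qual)
            out.write(a)


# ---------------------------------------------------------------------------
# IntCal-style .14c calibration curve

def read_cal_curve(path: str | Path) -> CalCurve:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 3:
                raise FormatError(f"{path}: curve row needs >= 3 columns: {line!r}")
            try:
                rows.append(tuple(float(x) for x in parts[:3]))
            except ValueError as exc:
                raise FormatError(f"{path}: non-numeric curve row {line!r}") from exc
    if len(rows) < 2:
        raise FormatError(f"{path}: calibration curve needs >= 2 usable rows")
    arr = np.array(sorted(rows), dtype=float)
    return CalCurve(cal_bp=arr[:, 0], c14_bp=arr[:, 1], err=arr[:, 2])


def write_cal_curve(curve: CalCurve, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# cal BP, 14C age BP, error (1 sigma)\n")
        for c, m, e in zip(curve.cal_bp, curve.c14_bp, curve.err):
            fh.write(f"{c:.1f},{m:.3f},{e:.3f}\n")


# ---------------------------------------------------------------------------
# SNP panel (TSV) and EIGENSTRAT triple

def read_snp_panel(path: str | Path) -> SnpPanel:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return SnpPanel(targets=df)


def write_snp_panel(panel: SnpPanel, path: str | Path) -> None:
    panel.targets.to_csv(path, sep="\t", index=False)


def write_eigenstrat(
    prefix: str | Path,
    snps: pd.DataFrame,
    geno: np.ndarray,
    individuals: Sequence[tuple[str, str, str]],
) -> None:
    """Write a .geno/.snp/.ind triple.

    snps: DataFrame with chrom, pos (0-based), ref, alt; one row per SNP.
    geno: (n_snp, n_ind) int array over {0,1,9} (pseudo-haploid: 0=ref,1=alt).
    individuals: (id, sex, population) per column of geno.
    """
    prefix = str(prefix)
    geno = np.asarray(geno)
    if geno.shape != (len(snps), len(individuals)):
        raise FormatError("geno shape does not match snps x individuals")
    if not np.isin(geno, (0, 1, 9)).all():
        raise FormatError("pseudo-haploid genotypes must be in {0,1,9}")
    with open(prefix + ".geno", "w") as fh:
        for row in geno:
            fh.write("".join(map(str, row)) + "\n")
    with open(prefix + ".snp", "w") as fh:
        for i, row in enumerate(snps.itertuples(index=False)):
            # EIGENSTRAT .snp positions are 1-based
            fh.write(
                f"rs{i}\t{row.chrom}\t0.0\t{int(row.pos) + 1}\t{row.ref}\t{row.alt}\n"
            )
    with open(prefix + ".ind", "w") as fh:
        for ind_id, sex, pop in individuals:
            fh.write(f"{ind_id}\t{sex}\t{pop}\n")


def read_eigenstrat(
    prefix: str | Path,
) -> tuple[pd.DataFrame, np.ndarray, list[tuple[str, str, str]]]:
    """Read a .geno/.snp/.ind triple written by :func:`write_eigenstrat`."""
    prefix = str(prefix)
    individuals = []
    with open(prefix + ".ind") as fh:
        for line in fh:
            parts = line.split()
            if len(parts) != 3:
                raise FormatError(f".ind line needs 3 fields: {line!r}")
            individuals.append(tuple(parts))
    snp_rows = []
    with open(prefix + ".snp") as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 6:
                raise FormatError(f".snp line needs 6 fields: {line!r}")
            snp_rows.append((parts[1], int(parts[3]) - 1, parts[4], parts[5]))
    snps = pd.DataFrame(snp_rows, columns=["chrom", "pos", "ref", "alt"])
    rows = []
    with open(prefix + ".geno") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if not set(line) <= {"0", "1", "2", "9"}:
                raise FormatError(f"bad .geno line {line!r}")
            rows.append([int(c) for c in line])
    geno = np.array(rows, dtype=np.int8)
    if geno.shape != (len(snps), len(individuals)):
        raise FormatError("EIGENSTRAT triple is inconsistent")
    return snps, geno, individuals


def revcomp(seq: str) -> str:
    """Reverse complement preserving N."""
    return str(Seq(seq).reverse_complement())
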