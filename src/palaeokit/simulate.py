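"""Synthetic inputs for every pipeline stage.

Each generator is a pure function of its parameters and a seed: the same
call yields byte-identical output. Defaults mirror the study conditions the
pipeline is designed for — short single-stranded-library fragments with
~20-35% terminal C-to-T deamination, ~55% present-day contamination,
replicated small-sample AMS measurements with a laboratory blank, and
allele-frequency drift over a small population tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import CalCurve, FastaRecord, SamRecord, SnpPanel, revcomp
from .radiocarbon import LIBBY_MEAN_LIFE, RadiocarbonAge, age_to_f14c, f14c_to_age
from .sextyping import CoverageCounts

__all__ = [
    "ReadSimConfig",
    "SimTruth",
    "PopNode",
    "simulate_ancient_reads",
    "simulate_snp_coverage",
    "simulate_c14_replicates",
    "synthesize_calibration_curve",
    "simulate_genotypes",
    "random_reference",
]

_BASES = np.array(list("ACGT"))


class ParameterError(ValueError):
    """A simulation parameter is outside its valid range."""


@dataclass(frozen=True)
class ReadSimConfig:
    """Parameters of the ancient-read simulator.

    Fragment lengths are log-normal (``frag_len_median`` bp, dispersion =
    sigma of log length). Deamination is C->T with probability
    ``deam_rate_5p * deam_decay_5p**i`` at 0-based read position ``i`` from
    the 5' end (and mirrored from the 3' end), the single-stranded-library
    pattern; ``library='ds'`` switches the 3' end to G->A as in
    double-stranded libraries. Contaminant reads carry no damage.
    """

    n_reads: int = 20_000
    frag_len_median: float = 50.0
    frag_len_dispersion: float = 0.25
    deam_rate_5p: float = 0.25
    deam_rate_3p: float = 0.20
    deam_decay_5p: float = 0.6
    deam_decay_3p: float = 0.6
    contamination_fraction: float = 0.55
    error_rate: float = 0.001
    library: str = "ss"
    mapq: int = 37
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "deam_rate_5p",
            "deam_rate_3p",
            "deam_decay_5p",
            "deam_decay_3p",
            "contamination_fraction",
            "error_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1]")
        if self.n_reads < 1:
            raise ParameterError("n_reads must be >= 1")
        if self.library not in ("ss", "ds"):
            raise ParameterError("library must be 'ss' or 'ds'")


@dataclass
class SimTruth:
    """Ground truth attached to a simulated data set."""

    is_contaminant: np.ndarray | None = None  # per-read, aligned with output order
    true_sequence: str | None = None
    true_sex: str | None = None
    true_age_bp: float | None = None
    pop_frequencies: dict[str, np.ndarray] = field(default_factory=dict)


def _apply_deamination(seq: np.ndarray, cfg: ReadSimConfig, rng) -> np.ndarray:
    """C->T near the 5' end and C->T (ss) or G->A (ds) near the 3' end."""
    n = len(seq)
    idx = np.arange(n)
    p5 = cfg.deam_rate_5p * cfg.deam_decay_5p ** idx
    p3 = cfg.deam_rate_3p * cfg.deam_decay_3p ** idx[::-1]
    u5 = rng.random(n)
    hit5 = (seq == "C") & (u5 < p5)
    seq = seq.copy()
    seq[hit5] = "T"
    u3 = rng.random(n)
    if cfg.library == "ss":
        hit3 = (seq == "C") & (u3 < p3)
        seq[hit3] = "T"
    else:
        hit3 = (seq == "G") & (u3 < p3)
        seq[hit3] = "A"
    return seq


def simulate_ancient_reads(
    ref: FastaRecord, cfg: ReadSimConfig
) -> tuple[list[SamRecord], SimTruth]:
    """Simulate aligned short fragments from ``ref``.

    Endogenous reads carry terminal deamination per ``cfg``; a
    ``contamination_fraction`` of reads are undamaged contaminants.
    Fragment start positions are uniform over the reference; strands are
    random. Damage and sequencing error are applied in read orientation
    and records are stored SAM-style on the forward reference strand.
    """
    rng = np.random.default_rng(cfg.seed)
    L = len(ref)
    lengths = np.round(
        rng.lognormal(np.log(cfg.frag_len_median), cfg.frag_len_dispersion, cfg.n_reads)
    ).astype(int)
    lengths = np.clip(lengths, 20, L - 1)
    if lengths.max() >= L:
        raise ParameterError("reference shorter than maximum fragment length")
    starts = rng.integers(0, L - lengths + 1)
    minus = rng.random(cfg.n_reads) < 0.5
    contam = rng.random(cfg.n_reads) < cfg.contamination_fraction
    ref_arr = np.array(list(ref.sequence))

    records: list[SamRecord] = []
    for i in range(cfg.n_reads):
        n, s = lengths[i], starts[i]
        frag = ref_arr[s : s + n]
        if minus[i]:
            read = np.array(list(revcomp("".join(frag))))
        else:
            read = frag.copy()
        if not contam[i]:
            read = _apply_deamination(read, cfg, rng)
        if cfg.error_rate > 0:
            err = rng.random(n) < cfg.error_rate
            if err.any():
                # substitute with a uniformly chosen different base
                repl = _BASES[rng.integers(0, 4, int(err.sum()))]
                same = repl == read[err]
                while same.any():
                    repl[same] = _BASES[rng.integers(0, 4, int(same.sum()))]
                    same = repl == read[err]
                read[err] = repl
        seq = "".join(read)
        if minus[i]:
            seq = revcomp(seq)  # SAM stores forward-strand sequence
        records.append(
            SamRecord(
                qname=f"sim_{i}",
                strand="-" if minus[i] else "+",
                rname=ref.id,
                pos=int(s),
                mapq=cfg.mapq,
                cigar=f"{n}M",
                seq=seq,
                qual="I" * n,
            )
        )
    truth = SimTruth(is_contaminant=contam, true_sequence=ref.sequence)
    return records, truth


def simulate_snp_coverage(
    panel: SnpPanel,
    true_sex: str,
    per_copy_depth: float,
    y_noise: float = 0.0,
    seed: int = 0,
) -> CoverageCounts:
    """Draw per-class covered-target counts under XX/XY truth.

    Each target is covered independently with probability
    ``1 - exp(-lambda * copies / 2)`` where copies is the chromosome copy
    number (autosomes 2; X 2/1; Y 0/1 for XX/XY). Zero-copy chromosomes
    are covered at the mismapping floor ``y_noise`` instead.
    """
    if per_copy_depth <= 0:
        raise ParameterError("per_copy_depth must be > 0")
    if y_noise < 0:
        raise ParameterError("y_noise must be >= 0")
    if true_sex not in ("XX", "XY"):
        raise ParameterError("true_sex must be 'XX' or 'XY'")
    n_auto, n_x, n_y = panel.n_auto, panel.n_x, panel.n_y
    if min(n_auto, n_x, n_y) == 0:
        raise ParameterError("SNP panel must contain targets in every class")
    rng = np.random.default_rng(seed)
    lam = per_copy_depth
    copies = {"auto": 2, "x": 2 if true_sex == "XX" else 1, "y": 0 if true_sex == "XX" else 1}

    def cover_prob(c: int) -> float:
        return y_noise if c == 0 else 1.0 - np.exp(-lam * c / 2.0)

    return CoverageCounts(
        n_auto_obs=int(rng.binomial(n_auto, cover_prob(copies["auto"]))),
        n_x_obs=int(rng.binomial(n_x, cover_prob(copies["x"]))),
        n_y_obs=int(rng.binomial(n_y, cover_prob(copies["y"]))),
        n_auto_exp=n_auto,
        n_x_exp=n_x,
        n_y_exp=n_y,
    )


def simulate_c14_replicates(
    true_age_bp: float,
    errors: Sequence[float],
    blank_f14c: float = 0.0,
    seed: int = 0,
    sample_id: str = "sim",
) -> list[RadiocarbonAge]:
    """Replicate AMS measurements of one sample.

    The true F14C is blended with a laboratory blank by mass balance
    (``F_m = F_true + F_b * (1 - F_true)``, exactly inverted by
    ``blank_correct``) and each replicate is drawn normally in F14C space
    with its quoted age error converted consistently.
    """
    if true_age_bp < 0:
        raise ParameterError("true_age_bp must be >= 0")
    errors = np.asarray(errors, dtype=float)
    if np.any(errors <= 0):
        raise ParameterError("replicate errors must be > 0")
    rng = np.random.default_rng(seed)
    f_true = age_to_f14c(true_age_bp)
    f_mean = f_true + blank_f14c * (1.0 - f_true)
    out = []
    for i, sig in enumerate(errors):
        sigma_f = f_mean * sig / LIBBY_MEAN_LIFE
        f = rng.normal(f_mean, sigma_f)
        age = -LIBBY_MEAN_LIFE * np.log(f)
        out.append(
            RadiocarbonAge(
                lab_id=f"{sample_id}.{i + 1}",
                age_bp=float(age),
                sigma=float(sig),
                sample_id=sample_id,
            )
        )
    return out


def synthesize_calibration_curve(
    cal_min: float,
    cal_max: float,
    wiggle_amplitude: float = 0.0,
    wiggle_period: float = 500.0,
    err_level: float = 10.0,
) -> CalCurve:
    """A smooth stand-in calibration curve on a 1-yr grid.

    mu(theta) = theta + A*sin(2*pi*theta/P); strictly monotone whenever
    A*2*pi/P < 1. The curve error is constant at ``err_level``.
    """
    if not cal_min < cal_max:
        raise ParameterError("cal_min must be < cal_max")
    if err_level <= 0:
        raise ParameterError("err_level must be > 0")
    if wiggle_period <= 0:
        raise ParameterError("wiggle_period must be > 0")
    grid = np.arange(float(cal_min), float(cal_max) + 1.0)
    mu = grid + wiggle_amplitude * np.sin(2.0 * np.pi * grid / wiggle_period)
    if not np.all(np.isfinite(mu)):
        raise ParameterError("curve parameters produce non-finite values")
    return CalCurve(cal_bp=grid, c14_bp=mu, err=np.full_like(grid, float(err_level)))


# ---------------------------------------------------------------------------
# Population-genetic generator


@dataclass
class PopNode:
    """A node of a population tree; ``drift`` is accumulated on the branch
    from the parent (Balding-Nichols F, in (0,1); 0 means no drift)."""

    name: str
    drift: float = 0.0
    children: list["PopNode"] = field(default_factory=list)

    def leaves(self) -> list["PopNode"]:
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


def _drift_frequencies(p: np.ndarray, f: float, rng) -> np.ndarray:
    """One Balding-Nichols step: p' ~ Beta(p(1-f)/f, (1-p)(1-f)/f)."""
    if f == 0.0:
        return p.copy()
    if not 0.0 < f < 1.0:
        raise ParameterError(f"drift amount {f} outside [0, 1)")
    out = p.copy()
    interior = (p > 0.0) & (p < 1.0)  # fixed alleles stay fixed
    a = p[interior] * (1.0 - f) / f
    b = (1.0 - p[interior]) * (1.0 - f) / f
    out[interior] = rng.beta(a, b)
    return out


def simulate_genotypes(
    tree: PopNode,
    n_snps: int,
    samples_per_pop: int = 1,
    seed: int = 0,
    admixture: tuple[str, str, float] | None = None,
    n_chrom: int = 22,
    snp_spacing: int = 100_000,
):
    """Pseudo-haploid genotypes under allele-frequency drift on a tree.

    Ancestral frequencies are Uniform(0.05, 0.95); each branch applies a
    Balding-Nichols Beta step with its ``drift``. ``admixture=(src, dst,
    alpha)`` optionally mixes alpha of the source leaf's frequencies into
    the destination leaf (a one-pulse gene flow). Individual calls are
    Bernoulli(frequency). SNPs are laid out round-robin-free: contiguous
    chunks across ``n_chrom`` chromosomes at ``snp_spacing`` bp so physical
    block jackknifing is meaningful. Returns a :class:`~palaeokit.fstats.GenoTable`
    and a :class:`SimTruth` with the leaf frequencies.
    """
    from .fstats import GenoTable
    import pandas as pd

    if n_snps < 1:
        raise ParameterError("n_snps must be >= 1")
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(0.05, 0.95, n_snps)

    freqs: dict[str, np.ndarray] = {}

    def walk(node: PopNode, p: np.ndarray) -> None:
        p_here = _drift_frequencies(p, node.drift, rng)
        if not node.children:
            freqs[node.name] = p_here
        for child in node.children:
            walk(child, p_here)

    walk(tree, p_anc)

    if admixture is not None:
        src, dst, alpha = admixture
        if not 0.0 <= alpha <= 1.0:
            raise ParameterError("admixture proportion outside [0, 1]")
        freqs[dst] = (1.0 - alpha) * freqs[dst] + alpha * freqs[src]

    pops = sorted(freqs)
    individuals = []
    cols = []
    for pop in pops:
        for j in range(samples_per_pop):
            individuals.append((f"{pop}_{j}", "U", pop))
            cols.append((rng.random(n_snps) < freqs[pop]).astype(np.int8))
    geno = np.column_stack(cols)

    per_chrom = int(np.ceil(n_snps / n_chrom))
    chroms = [str(1 + i // per_chrom) for i in range(n_snps)]
    pos = [(i % per_chrom) * snp_spacing for i in range(n_snps)]
    snps = pd.DataFrame({"chrom": chroms, "pos": pos, "ref": "A", "alt": "G"})

    table = GenoTable(snps=snps, geno=geno, individuals=individuals)
    return table, SimTruth(pop_frequencies=freqs)


def random_reference(length: int, seed: int = 0, name: str = "ref") -> FastaRecord:
    """A uniform-random A/C/G/T reference sequence."""
    rng = np.random.default_rng(seed)
    return FastaRecord(id=name, sequence="".join(_BASES[rng.integers(0, 4, length)]))
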