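"""Dinucleotide background model and promoter-set handling.

The background is a first-order Markov chain over {A,C,G,T}: an initial
distribution plus a 4x4 row-stochastic transition matrix estimated from the
dinucleotide counts of a promoter pool.  It plays three roles: it defines the
transition probabilities between the HMM's background states, it generates
synthetic promoter sequences for simulations and threshold calibration, and
its marginal (stationary) distribution is the reference for log-odds window
scores.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._utils import ALPHABET, N_CODE, as_rng, encode_sequence, reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "DinucleotideBackground",
    "PromoterSet",
    "estimate_background",
    "generate_sequence",
    "generate_promoter_set",
    "sample_random_set",
    "extract_promoters",
    "uniform_background",
    "promoter_like_background",
]

DEFAULT_REGION_LEN = 500


@dataclass
class DinucleotideBackground:
    """First-order Markov model over A,C,G,T (rows/cols in that order)."""

    initial: np.ndarray  # (4,)
    transition: np.ndarray  # (4, 4) row-stochastic
    n_observed: int = 0

    def __post_init__(self) -> None:
        self.initial = np.asarray(self.initial, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        if self.initial.shape != (4,) or self.transition.shape != (4, 4):
            raise ValueError("background must have a 4-vector initial and 4x4 transition")
        if not np.isclose(self.initial.sum(), 1.0, atol=1e-9):
            raise ValueError("initial distribution must sum to 1")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("every transition row must sum to 1")
        if (self.initial < 0).any() or (self.transition < 0).any():
            raise ValueError("negative probability in background model")

    @property
    def marginal(self) -> np.ndarray:
        """Stationary nucleotide distribution of the transition matrix."""
        vals, vecs = np.linalg.eig(self.transition.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        v = np.real(vecs[:, i])
        v = np.abs(v)
        return v / v.sum()

    def digest(self) -> str:
        h = hashlib.sha256()
        h.update(np.round(self.initial, 12).tobytes())
        h.update(np.round(self.transition, 12).tobytes())
        return h.hexdigest()[:16]


def uniform_background() -> DinucleotideBackground:
    """Uniform iid background (all transitions 0.25); handy for tests and toys."""
    return DinucleotideBackground(np.full(4, 0.25), np.full((4, 4), 0.25), 0)


def promoter_like_background() -> DinucleotideBackground:
    """Synthetic stand-in for promoter dinucleotide statistics.

    Mildly GC-rich with a depleted C->G step — the qualitative signature of
    vertebrate promoter regions — used as the generating chain for simulated
    promoter pools when no real promoter collection is supplied.
    """
    initial = np.array([0.23, 0.27, 0.27, 0.23])
    transition = np.array(
        [
            [0.26, 0.24, 0.30, 0.20],  # from A
            [0.25, 0.30, 0.15, 0.30],  # from C (CpG depletion)
            [0.22, 0.30, 0.30, 0.18],  # from G
            [0.18, 0.26, 0.32, 0.24],  # from T
        ]
    )
    return DinucleotideBackground(initial, transition, 0)


@dataclass
class PromoterSet:
    """Named promoter collection keyed by gene id.

    ``metadata`` carries provenance (e.g. which promoters received planted
    motif instances in simulations).
    """

    name: str
    sequences: dict[str, str]
    region_len: int | None = DEFAULT_REGION_LEN
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, seq in self.sequences.items():
            encode_sequence(seq)  # validates alphabet
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError("duplicate gene ids in promoter set")

    def __len__(self) -> int:
        return len(self.sequences)

    def __contains__(self, gene: str) -> bool:
        return gene in self.sequences

    @property
    def gene_ids(self) -> list[str]:
        return list(self.sequences)

    def subset(self, gene_ids: Iterable[str], name: str | None = None) -> "PromoterSet":
        ids = list(gene_ids)
        missing = [g for g in ids if g not in self.sequences]
        if missing:
            raise KeyError(f"gene ids not in set: {missing[:5]}")
        return PromoterSet(
            name=name or f"{self.name}:subset",
            sequences={g: self.sequences[g] for g in ids},
            region_len=self.region_len,
            metadata=dict(self.metadata),
        )

    def to_fasta(self, path) -> None:
        records = [SeqRecord(Seq(s), id=g, description="") for g, s in self.sequences.items()]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path, name: str | None = None,
                   region_len: int | None = None) -> "PromoterSet":
        seqs: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seqs:
                raise ValueError(f"duplicate gene id {rec.id!r} in {path}")
            seqs[rec.id] = str(rec.seq).upper()
        return cls(name=name or str(path), sequences=seqs, region_len=region_len)


# ---------------------------------------------------------------------------
# Estimation and generation
# ---------------------------------------------------------------------------

def estimate_background(pool: PromoterSet, smoothing: float = 1.0) -> DinucleotideBackground:
    """Estimate the dinucleotide model from a promoter pool.

    Transition counts are smoothed additively (default 1 per cell);
    dinucleotides spanning an N are skipped.  The initial distribution is the
    smoothed frequency of each sequence's first (non-ambiguous) nucleotide.
    Rows with no counts and no smoothing fall back to uniform.
    """
    if len(pool) == 0:
        raise ValueError("cannot estimate a background from an empty pool")
    if smoothing < 0:
        raise ValueError("smoothing must be >= 0")
    trans_counts = np.zeros((4, 4))
    init_counts = np.zeros(4)
    n_observed = 0
    for seq in pool.sequences.values():
        codes = encode_sequence(seq)
        if codes.size and codes[0] != N_CODE:
            init_counts[codes[0]] += 1
        a, b = codes[:-1], codes[1:]
        ok = (a != N_CODE) & (b != N_CODE)
        if ok.any():
            np.add.at(trans_counts, (a[ok], b[ok]), 1)
            n_observed += int(ok.sum())
    if n_observed == 0 and init_counts.sum() == 0:
        raise ValueError("promoter pool contains no unambiguous nucleotides")

    trans = trans_counts + smoothing
    row_sums = trans.sum(axis=1, keepdims=True)
    uniform_rows = (row_sums == 0).ravel()
    trans[uniform_rows] = 0.25
    row_sums[row_sums == 0] = 1.0
    trans = trans / trans.sum(axis=1, keepdims=True)

    init = init_counts + smoothing
    if init.sum() == 0:
        init = np.full(4, 0.25)
    init = init / init.sum()
    return DinucleotideBackground(init, trans, n_observed)


def generate_promoter_set(
    bg: DinucleotideBackground,
    n: int,
    length: int,
    seed: int | np.random.Generator,
    name: str = "synthetic",
    prefix: str = "g",
) -> PromoterSet:
    """Generate ``n`` background promoters of equal length (vectorised)."""
    if n < 1 or length < 1:
        raise ValueError("n and length must be >= 1")
    rng = as_rng(seed)
    init_cum = np.cumsum(bg.initial)
    trans_cum = np.cumsum(bg.transition, axis=1)
    u = rng.random((n, length))
    states = np.empty((n, length), dtype=np.int8)
    states[:, 0] = np.searchsorted(init_cum, u[:, 0], side="right").clip(0, 3)
    for t in range(1, length):
        rows = trans_cum[states[:, t - 1]]
        states[:, t] = (u[:, t, None] >= rows).sum(axis=1).clip(0, 3)
    lut = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)
    width = len(str(n))
    seqs = {
        f"{prefix}{i + 1:0{width}d}": lut[states[i]].tobytes().decode("ascii")
        for i in range(n)
    }
    return PromoterSet(name=name, sequences=seqs, region_len=length)


def generate_sequence(bg: DinucleotideBackground, length: int,
                      seed: int | np.random.Generator) -> str:
    """One random sequence from the background chain; reproducible given seed."""
    ps = generate_promoter_set(bg, 1, length, seed, name="tmp")
    return next(iter(ps.sequences.values()))


def sample_random_set(pool: PromoterSet, n: int,
                      seed: int | np.random.Generator) -> PromoterSet:
    """Draw ``n`` distinct promoters uniformly without replacement from the pool.

    Target genes are *not* excluded: the null mirrors drawing any promoters
    from the full collection.  The draw is taken over the sorted gene ids so
    it is invariant to pool insertion order.
    """
    if not (1 <= n <= len(pool)):
        raise ValueError(f"need 1 <= n <= pool size ({len(pool)}), got {n}")
    rng = as_rng(seed)
    ids = sorted(pool.sequences)
    chosen = rng.choice(len(ids), size=n, replace=False)
    picked = [ids[i] for i in sorted(chosen)]
    return pool.subset(picked, name=f"{pool.name}:random{n}")


# ---------------------------------------------------------------------------
# Promoter extraction from a genome
# ---------------------------------------------------------------------------

def extract_promoters(genome_path, tss_table_path, upstream_bp: int = DEFAULT_REGION_LEN,
                      name: str | None = None) -> PromoterSet:
    """Extract strand-aware upstream promoter regions from a genome FASTA.

    The TSS table is BED6 (chrom, start, end, gene, score, strand); the TSS is
    the 5' end of the interval on the annotated strand (start for +, end for
    -; BED is 0-based half-open).  For + genes the region is
    [TSS - upstream_bp, TSS) on the forward strand; for - genes the reverse
    complement of [TSS, TSS + upstream_bp).  Regions are clipped at chromosome
    edges (with a logged warning) and uppercased.
    """
    from pyfaidx import Fasta

    genome = Fasta(str(genome_path), as_raw=True, sequence_always_upper=True)
    seqs: dict[str, str] = {}
    with open(tss_table_path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 6:
                raise ValueError(f"{tss_table_path}:{lineno}: BED6 requires 6 columns")
            chrom, start, end, gene, _score, strand = fields[:6]
            start, end = int(start), int(end)
            if gene in seqs:
                raise ValueError(f"duplicate gene id {gene!r} in TSS table")
            if chrom not in genome:
                raise ValueError(f"chromosome {chrom!r} not present in genome FASTA")
            chrom_len = len(genome[chrom])
            if strand == "-":
                tss = end
                lo, hi = tss, min(chrom_len, tss + upstream_bp)
                region = str(genome[chrom][lo:hi])
                region = reverse_complement(region)
            else:
                tss = start
                lo, hi = max(0, tss - upstream_bp), tss
                region = str(genome[chrom][lo:hi])
            if len(region) < upstream_bp:
                logger.warning(
                    "promoter for %s truncated to %d bp at chromosome edge", gene, len(region)
                )
            seqs[gene] = region.upper()
    return PromoterSet(name=name or f"promoters:{genome_path}", sequences=seqs,
                       region_len=upstream_bp)
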