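"""Planted-motif simulation benchmark.

Target sets of background promoters receive motif instances — sampled
column-wise from a PWM — planted into a chosen fraction of the promoters
(default three instances per planted promoter), so sensitivity and false
positive rate are known quantities.  The harness runs either the HMM
enrichment method or the hard-threshold scanner against a motif library
(planted motif plus random decoy PWMs) over a grid of plant fractions and
replicates, and aggregates:

* sensitivity — fraction of replicates in which the planted motif passes the
  FDR threshold;
* FPR — fraction of (non-planted motif, replicate) pairs called significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._utils import ALPHABET, as_rng, substream
from .background import DinucleotideBackground, PromoterSet, generate_promoter_set
from .enrichment import DEFAULT_FDR, DEFAULT_N_RANDOM, bh_fdr, run_enrichment
from .hmm import learn_entry_probabilities
from .matrices import ProbabilityMatrix, compute_scan_threshold
from .scanner import count_occurrences, scanner_enrichment

logger = logging.getLogger(__name__)

__all__ = [
    "PlantedSetSpec",
    "BenchmarkOutcome",
    "generate_planted_set",
    "random_probability_matrix",
    "make_decoy_library",
    "planted_test_motif",
    "run_benchmark",
    "outcomes_to_frame",
    "plot_benchmark",
]

DEFAULT_GRID = tuple(round(0.1 * i, 1) for i in range(1, 10))


@dataclass(frozen=True)
class PlantedSetSpec:
    """Parameters of one simulated target set."""

    motif_id: str
    n_promoters: int = 100
    promoter_len: int = 500
    plant_fraction: float = 0.5
    instances_per_promoter: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.plant_fraction <= 1.0):
            raise ValueError("plant_fraction must lie in [0, 1]")
        if self.n_promoters < 1 or self.promoter_len < 1 or self.instances_per_promoter < 0:
            raise ValueError("sizes must be positive")

    @property
    def n_planted(self) -> int:
        return int(round(self.plant_fraction * self.n_promoters))


@dataclass
class BenchmarkOutcome:
    method: str
    spec: PlantedSetSpec
    replicates: int
    sensitivity: float  # NaN when nothing was planted
    fpr: float
    rank1_fraction: float = float("nan")
    rank1_sig_fraction: float = float("nan")  # rank 1 AND significant


def sample_motif_instance(motif: ProbabilityMatrix, rng: np.random.Generator) -> str:
    """Draw one site column-wise from the PWM's per-position distributions."""
    u = rng.random(motif.length)
    cum = np.cumsum(motif.probs, axis=1)
    idx = (u[:, None] >= cum).sum(axis=1).clip(0, 3)
    return "".join(ALPHABET[i] for i in idx)


def _place_instances(length: int, L: int, k: int, rng: np.random.Generator,
                     max_attempts: int = 1000) -> list[int]:
    """Uniform non-overlapping instance start positions by rejection sampling."""
    if k == 0:
        return []
    for _ in range(max_attempts):
        starts = np.sort(rng.integers(0, length - L + 1, size=k))
        if (np.diff(starts) >= L).all():
            return [int(s) for s in starts]
    raise ValueError(
        f"could not place {k} non-overlapping {L} bp instances in {length} bp "
        f"after {max_attempts} attempts; use longer promoters"
    )


def generate_planted_set(
    spec: PlantedSetSpec,
    motif: ProbabilityMatrix,
    bg: DinucleotideBackground,
    rng: np.random.Generator | None = None,
    name: str = "planted",
) -> PromoterSet:
    """Background promoters with motif instances planted into a known subset.

    Instances replace background bases in place on the forward strand; which
    promoters were planted is recorded in the set's metadata under
    ``planted_genes``.
    """
    L = motif.length
    if spec.promoter_len < spec.instances_per_promoter * L:
        raise ValueError("promoters are too short for the requested instances")
    rng = rng if rng is not None else substream(spec.seed, "planted-set", spec.motif_id)
    promoters = generate_promoter_set(bg, spec.n_promoters, spec.promoter_len, rng, name=name)
    genes = promoters.gene_ids
    planted = sorted(rng.choice(len(genes), size=spec.n_planted, replace=False).tolist())
    planted_genes = [genes[i] for i in planted]
    for gene in planted_genes:
        seq = list(promoters.sequences[gene])
        starts = _place_instances(spec.promoter_len, L, spec.instances_per_promoter, rng)
        for s in starts:
            seq[s:s + L] = sample_motif_instance(motif, rng)
        promoters.sequences[gene] = "".join(seq)
    promoters.metadata["planted_genes"] = planted_genes
    promoters.metadata["spec"] = spec
    return promoters


def random_probability_matrix(
    motif_id: str,
    rng: np.random.Generator,
    length_range: tuple[int, int] = (8, 14),
    concentration: float = 0.5,
) -> ProbabilityMatrix:
    """Decoy PWM: per-position Dirichlet(concentration) rows, random length."""
    L = int(rng.integers(length_range[0], length_range[1] + 1))
    probs = rng.dirichlet(np.full(4, concentration), size=L)
    probs = np.clip(probs, 1e-6, None)
    probs /= probs.sum(axis=1, keepdims=True)
    return ProbabilityMatrix(motif_id=motif_id, probs=probs, name=motif_id)


def planted_test_motif(motif_id: str, length: int = 10,
                       ic_bits: float = 12.0) -> ProbabilityMatrix:
    """Synthetic motif of prescribed information content for simulations.

    Each position gives probability ``p`` to a dominant base (cycling
    A,C,G,T) and (1-p)/3 to the rest; ``p`` is solved by bisection so the
    total information content matches ``ic_bits`` (capped at 2 bits per
    position).
    """
    if not (0.0 <= ic_bits <= 2.0 * length):
        raise ValueError(f"ic_bits must lie in [0, {2.0 * length}]")
    target_per_pos = ic_bits / length

    def pos_ic(p: float) -> float:
        q = (1.0 - p) / 3.0
        h = -(p * np.log2(p) + 3.0 * q * np.log2(q)) if 0 < p < 1 else 0.0
        return 2.0 - h

    lo, hi = 0.25, 1.0 - 1e-9
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if pos_ic(mid) < target_per_pos:
            lo = mid
        else:
            hi = mid
    p = 0.5 * (lo + hi)
    q = (1.0 - p) / 3.0
    probs = np.full((length, 4), q)
    for i in range(length):
        probs[i, i % 4] = p
    probs /= probs.sum(axis=1, keepdims=True)
    return ProbabilityMatrix(motif_id=motif_id, probs=probs, name=motif_id)


def make_decoy_library(n: int, seed: int | np.random.Generator,
                       length_range: tuple[int, int] = (8, 14),
                       concentration: float = 0.5) -> list[ProbabilityMatrix]:
    rng = as_rng(seed)
    width = len(str(n))
    return [
        random_probability_matrix(f"decoy{i + 1:0{width}d}", rng, length_range, concentration)
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# Benchmark harness
# ---------------------------------------------------------------------------

def _run_hmm_replicate(
    targets: PromoterSet,
    pool: PromoterSet,
    bg: DinucleotideBackground,
    motif_library: Sequence[ProbabilityMatrix],
    seed: int,
    n_random: int,
    fdr: float,
    tol: float,
    max_iter: int,
) -> dict[str, tuple[bool, int]]:
    """(significant?, rank) per motif from the HMM enrichment method."""
    hmms = [
        learn_entry_probabilities(w, bg, list(pool.sequences.values()),
                                  tol=tol, max_iter=max_iter)
        for w in motif_library
    ]
    report = run_enrichment(hmms, targets, pool, n_random=n_random, seed=seed,
                            fdr_threshold=fdr)
    return {r.motif_id: (r.q_value < fdr, r.rank) for r in report.results}


def _run_scanner_replicate(
    targets: PromoterSet,
    pool: PromoterSet,
    bg: DinucleotideBackground,
    motif_library: Sequence[ProbabilityMatrix],
    seed: int,
    fdr: float,
    n_threshold_scores: int,
) -> dict[str, tuple[bool, int]]:
    """(significant?, rank) per motif from the hard-threshold comparator."""
    rng = substream(seed, "scan-thresholds")
    pool_seqs = list(pool.sequences.values())
    pvals: dict[str, float] = {}
    for w in motif_library:
        # background collections sized so each yields >= n_threshold_scores
        # window scores (both strands)
        region_len = pool.region_len or 500
        per_seq = 2 * (region_len - w.length + 1)
        n_seqs = max(1, int(np.ceil(n_threshold_scores / max(per_seq, 1))) + 1)
        bg_random = list(
            generate_promoter_set(bg, n_seqs, region_len, rng).sequences.values()
        )
        seg_idx = rng.integers(0, len(pool_seqs), size=n_seqs)
        bg_segments = [pool_seqs[i] for i in seg_idx]
        t = compute_scan_threshold(w, bg_random, bg_segments, bg)
        prof_pool = count_occurrences(w, t, pool, bg)
        prof_target = _profile_subset(prof_pool, targets)
        pvals[w.motif_id] = scanner_enrichment(prof_target, prof_pool)
    qs = bh_fdr(list(pvals.values()))
    order = sorted(range(len(pvals)), key=lambda i: (list(pvals.values())[i],
                                                     list(pvals.keys())[i]))
    ranks = {list(pvals.keys())[i]: rank for rank, i in enumerate(order, start=1)}
    return {
        m: (q < fdr, ranks[m]) for (m, _p), q in zip(pvals.items(), qs)
    }


def _profile_subset(profile, targets: PromoterSet):
    """Restrict a pool occurrence profile to the target genes."""
    from .scanner import OccurrenceProfile

    counts = {g: profile.counts[g] for g in targets.sequences if g in profile.counts}
    return OccurrenceProfile(
        motif_id=profile.motif_id,
        counts=counts,
        categories={g: profile.categories[g] for g in counts},
    )


def run_benchmark(
    spec_grid: Sequence[PlantedSetSpec],
    motif_library: Sequence[ProbabilityMatrix],
    method: str,
    replicates: int,
    seed: int,
    bg: DinucleotideBackground,
    n_background_promoters: int = 100,
    n_random: int = DEFAULT_N_RANDOM,
    fdr: float = DEFAULT_FDR,
    em_tol: float = 1e-5,
    em_max_iter: int = 50,
    n_threshold_scores: int = 2000,
) -> list[BenchmarkOutcome]:
    """Sensitivity/FPR of a method over a grid of planted-set specifications.

    Each replicate builds a fresh planted target set plus
    ``n_background_promoters`` extra background promoters; the pool for the
    empirical null is their union.  The planted motif must be the first
    library entry whose id matches ``spec.motif_id``; all other library
    members are decoys for the FPR.
    """
    if method not in ("hmm", "scanner"):
        raise ValueError(f"unknown method {method!r}; use 'hmm' or 'scanner'")
    if len(motif_library) < 2:
        raise ValueError("motif library needs the planted motif plus at least one decoy")
    lib_ids = {w.motif_id for w in motif_library}
    outcomes: list[BenchmarkOutcome] = []
    for spec in spec_grid:
        planted_id = spec.motif_id
        planted_matrix = next((w for w in motif_library if w.motif_id == planted_id), None)
        if planted_id and planted_matrix is None and spec.plant_fraction > 0:
            raise ValueError(f"planted motif {planted_id!r} not in library")
        hits = 0
        rank1 = 0
        rank1_sig = 0
        fp = 0
        n_decoy_calls = 0
        for rep in range(replicates):
            rng = substream(seed, "benchmark", method, planted_id, spec.plant_fraction, rep)
            rep_seed = int(rng.integers(0, 2**31 - 1))
            if spec.plant_fraction > 0:
                targets = generate_planted_set(spec, planted_matrix, bg, rng=rng)
            else:
                targets = generate_promoter_set(bg, spec.n_promoters, spec.promoter_len,
                                                rng, name="null-targets")
            extra = generate_promoter_set(bg, n_background_promoters, spec.promoter_len,
                                          rng, name="pool-extra", prefix="bgp")
            pool = PromoterSet(
                name="benchmark-pool",
                sequences={**targets.sequences, **extra.sequences},
                region_len=spec.promoter_len,
            )
            if method == "hmm":
                calls = _run_hmm_replicate(targets, pool, bg, motif_library, rep_seed,
                                             n_random, fdr, em_tol, em_max_iter)
            else:
                calls = _run_scanner_replicate(targets, pool, bg, motif_library, rep_seed,
                                               fdr, n_threshold_scores)
            for motif_id, (sig, rank) in calls.items():
                if spec.plant_fraction > 0 and motif_id == planted_id:
                    hits += int(sig)
                    rank1 += int(rank == 1)
                    rank1_sig += int(sig and rank == 1)
                else:
                    n_decoy_calls += 1
                    fp += int(sig)
            logger.info("benchmark method=%s x=%.2f rep=%d done", method,
                        spec.plant_fraction, rep)
        planted_run = spec.plant_fraction > 0
        sensitivity = hits / replicates if planted_run else float("nan")
        rank1_fraction = rank1 / replicates if planted_run else float("nan")
        rank1_sig_fraction = rank1_sig / replicates if planted_run else float("nan")
        fpr = fp / n_decoy_calls if n_decoy_calls else float("nan")
        outcomes.append(
            BenchmarkOutcome(method=method, spec=spec, replicates=replicates,
                             sensitivity=sensitivity, fpr=fpr,
                             rank1_fraction=rank1_fraction,
                             rank1_sig_fraction=rank1_sig_fraction)
        )
    return outcomes


def outcomes_to_frame(outcomes: Sequence[BenchmarkOutcome]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "method": o.method,
                "motif_id": o.spec.motif_id,
                "n_promoters": o.spec.n_promoters,
                "promoter_len": o.spec.promoter_len,
                "plant_fraction": o.spec.plant_fraction,
                "instances_per_promoter": o.spec.instances_per_promoter,
                "replicates": o.replicates,
                "sensitivity": o.sensitivity,
                "rank1_fraction": o.rank1_fraction,
                "rank1_sig_fraction": o.rank1_sig_fraction,
                "fpr": o.fpr,
            }
            for o in outcomes
        ]
    )


def plot_benchmark(outcomes: Sequence[BenchmarkOutcome], path) -> None:
    """Sensitivity vs plant fraction, one line per method."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = outcomes_to_frame(outcomes)
    fig, ax = plt.subplots(figsize=(5, 4))
    for method, sub in df.groupby("method"):
        sub = sub.sort_values("plant_fraction")
        ax.plot(100 * sub["plant_fraction"], sub["sensitivity"], marker="o", label=method)
    ax.set_xlabel("% promoters with planted motif")
    ax.set_ylabel("sensitivity")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
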