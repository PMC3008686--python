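"""Motif enrichment testing against an empirical null of random promoter sets.

For each motif the per-promoter log likelihood-ratio scores of the target set
are summed; the same sum is computed for ``n_random`` (default 100) random
promoter sets of the same size drawn from the full pool.  Treating the random
sums as normal, the target sum is standardised (z) and assigned the
upper-tail normal probability; p-values are corrected across motifs by
Benjamini-Hochberg and findings are reported at FDR < 5% by default.

One shared collection of random sets is used for all motifs in a run, which
keeps motif ranks comparable and — because a promoter's score does not depend
on which set it sits in — lets the whole null be formed from a single pass of
per-promoter scores over the pool.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from ._utils import substream
from .background import PromoterSet, sample_random_set
from .hmm import MotifHMM, PromoterScore, background_loglik_set, score_set

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "EnrichmentReport",
    "sum_scores",
    "empirical_pvalue",
    "bh_fdr",
    "run_enrichment",
    "score_table",
    "write_report",
    "read_gene_list",
]

DEFAULT_N_RANDOM = 100
DEFAULT_FDR = 0.05
MIN_P = 1e-300


@dataclass
class EnrichmentResult:
    motif_id: str
    target_sum: float
    null_mean: float
    null_sd: float
    z: float
    p_value: float
    q_value: float
    rank: int


@dataclass
class EnrichmentReport:
    results: list[EnrichmentResult]
    n_random_sets: int
    fdr_threshold: float
    seed: int
    config_digest: str
    n_targets: int = 0
    n_dropped: int = 0

    def significant(self) -> list[EnrichmentResult]:
        return [r for r in self.results if r.q_value < self.fdr_threshold]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "motif_id": r.motif_id,
                    "target_sum": r.target_sum,
                    "null_mean": r.null_mean,
                    "null_sd": r.null_sd,
                    "z": r.z,
                    "p_value": r.p_value,
                    "q_value": r.q_value,
                    "rank": r.rank,
                }
                for r in self.results
            ]
        )


def sum_scores(scores: Sequence[PromoterScore]) -> float:
    """Set-level statistic: the sum of per-promoter log-ratio scores."""
    motifs = {s.motif_id for s in scores}
    if len(motifs) > 1:
        raise ValueError(f"scores mix motifs: {sorted(motifs)}")
    return float(sum(s.log_ratio for s in scores))


def empirical_pvalue(target_sum: float, null_sums: Sequence[float]) -> tuple[float, float]:
    """Standardise the target sum against the random-set sums; upper-tail p.

    z = (target_sum - mean) / sd (sample sd); p = 1 - Phi(z).  A degenerate
    null (sd = 0) yields p = 1 when the target does not exceed the mean and a
    floored minimum p otherwise.
    """
    null = np.asarray(null_sums, dtype=float)
    if null.size < 2:
        raise ValueError("need at least 2 null sums")
    mean = float(null.mean())
    sd = float(null.std(ddof=1))
    if sd == 0.0:
        if target_sum <= mean:
            return 0.0, 1.0
        return float("inf"), MIN_P
    z = (target_sum - mean) / sd
    p = float(norm.sf(z))
    return float(z), max(p, MIN_P)


def rank_pvalue(target_sum: float, null_sums: Sequence[float]) -> tuple[float, float]:
    """Rank-based alternative: smoothed fraction of random sets scoring >= target."""
    null = np.asarray(null_sums, dtype=float)
    if null.size < 2:
        raise ValueError("need at least 2 null sums")
    mean = float(null.mean())
    sd = float(null.std(ddof=1))
    z = (target_sum - mean) / sd if sd > 0 else 0.0
    p = (1.0 + int((null >= target_sum).sum())) / (1.0 + null.size)
    return float(z), float(p)


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in q]


def read_gene_list(path) -> list[str]:
    """One gene id per line; '#' comments and blank lines ignored."""
    genes: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                genes.append(line)
    return genes


def score_table(motifs: Sequence[MotifHMM], pool: PromoterSet) -> dict[str, dict[str, float]]:
    """Per-motif per-gene log-ratio scores over a pool (shared background pass)."""
    if not motifs:
        return {}
    bg_ll = background_loglik_set(motifs[0].background, pool)
    return {h.motif.motif_id: score_set(h, pool, bg_loglik=bg_ll) for h in motifs}


def _config_digest(payload: dict) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def run_enrichment(
    motifs: Sequence[MotifHMM],
    targets: PromoterSet | Sequence[str],
    pool: PromoterSet,
    n_random: int = DEFAULT_N_RANDOM,
    seed: int = 0,
    fdr_threshold: float = DEFAULT_FDR,
    p_value_mode: str = "normal_cdf",
    score_mode: str = "log_ratio",
    precomputed_scores: dict[str, dict[str, float]] | None = None,
    exclude_targets: bool = False,
    per_motif_draws: bool = False,
) -> EnrichmentReport:
    """Score every motif on the target set against the random-set null.

    ``targets`` may be a PromoterSet or a plain list of gene ids; either way
    target genes are matched into the pool by id and ids absent from the pool
    are dropped (logged).  Per-promoter scores are computed once over the
    pool; target and null sums are subset sums of those scores.  The
    ``n_random`` random sets are drawn once (seeded) and shared by all motifs.

    ``precomputed_scores`` (motif_id -> gene -> log ratio) lets callers that
    re-test many target draws against one pool skip rescoring; scores do not
    depend on set membership, so this is exact.  ``exclude_targets`` removes
    the target genes from the null draws; ``per_motif_draws`` redraws the
    random sets independently for every motif instead of sharing one
    collection (both off by default).
    """
    if p_value_mode not in ("normal_cdf", "rank"):
        raise ValueError(f"unknown p_value_mode {p_value_mode!r}")
    if score_mode not in ("log_ratio", "raw_ratio"):
        raise ValueError(f"unknown score_mode {score_mode!r}")
    target_ids = list(targets.sequences) if isinstance(targets, PromoterSet) else list(targets)
    matched = [g for g in target_ids if g in pool]
    dropped = len(target_ids) - len(matched)
    if dropped:
        logger.info("dropped %d target gene(s) absent from the promoter pool", dropped)
    if not matched:
        raise ValueError("no target gene matches the promoter pool")

    draw_pool = pool
    if exclude_targets:
        held_out = [g for g in pool.gene_ids if g not in set(matched)]
        if len(held_out) < len(matched):
            raise ValueError("pool too small to draw target-free random sets")
        draw_pool = pool.subset(held_out, name=f"{pool.name}:null")
    pool_genes = pool.gene_ids
    gene_pos = {g: i for i, g in enumerate(pool_genes)}
    target_idx = np.array([gene_pos[g] for g in matched])

    def _draw_null_idx(tag: object) -> np.ndarray:
        rng = substream(seed, "random-sets", tag)
        sets = [sample_random_set(draw_pool, len(matched), rng) for _ in range(n_random)]
        return np.array([[gene_pos[g] for g in rs.gene_ids] for rs in sets])

    null_idx = None if per_motif_draws else _draw_null_idx("shared")

    bg_ll = None
    if precomputed_scores is None and motifs:
        bg_ll = background_loglik_set(motifs[0].background, pool)
    rows: list[dict] = []
    for hmm in motifs:
        if precomputed_scores is not None:
            per_gene = precomputed_scores[hmm.motif.motif_id]
        else:
            per_gene = score_set(hmm, pool, bg_loglik=bg_ll)
        scores = np.array([per_gene[g] for g in pool_genes])
        if score_mode == "raw_ratio":
            scores = np.exp(scores)
        target_sum = float(scores[target_idx].sum())
        idx = _draw_null_idx(hmm.motif.motif_id) if per_motif_draws else null_idx
        null_sums = scores[idx].sum(axis=1)
        pfun = empirical_pvalue if p_value_mode == "normal_cdf" else rank_pvalue
        z, p = pfun(target_sum, null_sums)
        rows.append(
            dict(
                motif_id=hmm.motif.motif_id,
                target_sum=target_sum,
                null_mean=float(null_sums.mean()),
                null_sd=float(null_sums.std(ddof=1)),
                z=z,
                p_value=p,
            )
        )

    qs = bh_fdr([r["p_value"] for r in rows])
    for r, q in zip(rows, qs):
        r["q_value"] = float(q)
    order = sorted(range(len(rows)),
                   key=lambda i: (rows[i]["p_value"], -rows[i]["z"], rows[i]["motif_id"]))
    results = []
    for rank, i in enumerate(order, start=1):
        r = rows[i]
        results.append(EnrichmentResult(rank=rank, **r))

    digest = _config_digest(
        dict(
            n_random=n_random, seed=seed, fdr=fdr_threshold, p_value_mode=p_value_mode,
            score_mode=score_mode, exclude_targets=exclude_targets,
            per_motif_draws=per_motif_draws,
            n_targets=len(matched), pool=sorted(pool.sequences),
            motifs=sorted(h.motif.motif_id for h in motifs),
            entries={h.motif.motif_id: (h.entry_prob, h.rev_entry_prob) for h in motifs},
        )
    )
    return EnrichmentReport(
        results=results, n_random_sets=n_random, fdr_threshold=fdr_threshold, seed=seed,
        config_digest=digest, n_targets=len(matched), n_dropped=dropped,
    )


def write_report(report: EnrichmentReport, tsv_path, sidecar_path=None) -> None:
    """TSV table (sorted by p) plus a JSON sidecar with seed/config digest."""
    df = report.to_frame()
    df.to_csv(tsv_path, sep="\t", index=False, float_format="%.10g")
    if sidecar_path is not None:
        payload = {
            "n_random_sets": report.n_random_sets,
            "fdr_threshold": report.fdr_threshold,
            "seed": report.seed,
            "config_digest": report.config_digest,
            "n_targets": report.n_targets,
            "n_dropped": report.n_dropped,
        }
        with open(sidecar_path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
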