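"""Hard-threshold occurrence counting and enrichment — the comparator baseline.

Promoters are scanned with the log-odds PWM score; windows at or above the
motif's empirical threshold are hard occurrence calls.  Overlapping calls on
the same strand merge into a single occurrence (a strong site should not be
counted once per shifted window), and each promoter is categorised by its
occurrence count as 0, 1, 2 or >2 — the categorisation used by
threshold-based enrichment methods.  The enrichment test supplied here is an
upper-tail hypergeometric on the number of target promoters carrying at
least one occurrence; the categories are exported so alternative statistics
can be plugged in.
"""

from __future__ import annotations

from dataclasses import dataclass
import pandas as pd
from scipy.stats import hypergeom

from .background import DinucleotideBackground, PromoterSet
from .matrices import ProbabilityMatrix, ScanThreshold, pwm_scan_scores

__all__ = ["OccurrenceProfile", "count_occurrences", "scanner_enrichment"]

CATEGORIES = ("0", "1", "2", ">2")


@dataclass
class OccurrenceProfile:
    """Per-gene hard occurrence counts for one motif at its threshold."""

    motif_id: str
    counts: dict[str, int]
    categories: dict[str, str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": list(self.counts),
                "count": list(self.counts.values()),
                "category": [self.categories[g] for g in self.counts],
            }
        )


def _categorise(count: int) -> str:
    if count > 2:
        return ">2"
    return str(count)


def _merged_occurrences(hits: list[tuple[int, str]], L: int) -> int:
    """Count occurrences after merging same-strand overlapping windows."""
    n = 0
    for strand in ("+", "-"):
        positions = sorted(p for p, s in hits if s == strand)
        end = None
        for p in positions:
            if end is None or p >= end:
                n += 1
                end = p + L
            else:
                end = max(end, p + L)
    return n


def count_occurrences(
    w: ProbabilityMatrix,
    t: ScanThreshold,
    promoters: PromoterSet,
    background: DinucleotideBackground,
    strands: str = "both",
) -> OccurrenceProfile:
    """Above-threshold occurrence counts and 0/1/2/>2 categories per promoter."""
    if t.motif_id != w.motif_id:
        raise ValueError(f"threshold is for {t.motif_id}, matrix is {w.motif_id}")
    if t.background_digest is not None and t.background_digest != background.digest():
        raise ValueError(
            f"{w.motif_id}: scan threshold was computed against a different background"
        )
    counts: dict[str, int] = {}
    for gene, seq in promoters.sequences.items():
        hits = [
            (pos, strand)
            for (pos, strand, score) in pwm_scan_scores(w, seq, background, strands)
            if score >= t.threshold
        ]
        counts[gene] = _merged_occurrences(hits, w.length)
    categories = {g: _categorise(c) for g, c in counts.items()}
    return OccurrenceProfile(motif_id=w.motif_id, counts=counts, categories=categories)


def scanner_enrichment(
    profile_target: OccurrenceProfile,
    profile_pool: OccurrenceProfile,
) -> float:
    """Hypergeometric upper-tail p for >= 1-occurrence promoters, target vs pool."""
    if not profile_target.counts or not profile_pool.counts:
        raise ValueError("empty occurrence profile")
    if profile_target.motif_id != profile_pool.motif_id:
        raise ValueError("profiles describe different motifs")
    missing = set(profile_target.counts) - set(profile_pool.counts)
    if missing:
        raise ValueError(f"target genes absent from pool profile: {sorted(missing)[:5]}")
    N = len(profile_pool.counts)
    K = sum(1 for c in profile_pool.counts.values() if c >= 1)
    n = len(profile_target.counts)
    k = sum(1 for c in profile_target.counts.values() if c >= 1)
    return float(hypergeom.sf(k - 1, N, K, n))
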