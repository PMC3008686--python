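"""TFBS count/probability matrices: parsing, normalisation, scanning, clustering.

Column order is fixed as A, C, G, T everywhere. A :class:`CountMatrix` holds
raw per-position nucleotide counts as distributed (e.g. TRANSFAC flat files);
:func:`to_probability` converts it, with a pseudocount, into a
:class:`ProbabilityMatrix` whose rows are strictly positive probability
distributions — a requirement of the downstream HMM, whose motif-state
emissions are exactly these rows.

The scanning/threshold/clustering half of the module is the *hard-threshold*
side of the package: log-odds window scores against the background marginal,
an empirical score threshold calibrated on two background sequence sets
(the "100th-highest score" rule, FPR 0.01 by construction), and a redundancy
pruning step that removes, from every pair of matrices whose above-threshold
hits overlap too much on a promoter pool, the member with lower information
content.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._utils import ALPHABET, encode_sequence

__all__ = [
    "CountMatrix",
    "ProbabilityMatrix",
    "ScanThreshold",
    "parse_transfac",
    "write_transfac",
    "parse_matrix_table",
    "to_probability",
    "pwm_scan_scores",
    "compute_scan_threshold",
    "cluster_matrices",
]

DEFAULT_PSEUDOCOUNT = 0.25


@dataclass
class CountMatrix:
    """Raw per-position nucleotide counts for one motif (columns A,C,G,T)."""

    motif_id: str
    name: str
    counts: np.ndarray  # (L, 4) non-negative reals
    source_tag: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4 or self.counts.shape[0] < 1:
            raise ValueError(f"{self.motif_id}: counts must be an L x 4 matrix with L >= 1")
        if (self.counts < 0).any():
            raise ValueError(f"{self.motif_id}: negative count")
        if not (self.counts.sum(axis=1) > 0).all():
            raise ValueError(f"{self.motif_id}: every position needs at least one positive count")

    @property
    def length(self) -> int:
        return self.counts.shape[0]


def _information_content(probs: np.ndarray) -> float:
    # 2 + sum_b p log2 p per position, summed over positions; 0*log(0) -> 0.
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(probs > 0, probs * np.log2(probs), 0.0)
    return float(np.sum(2.0 + plogp.sum(axis=1)))


@dataclass
class ProbabilityMatrix:
    """Per-position nucleotide probabilities (PWM) with information content."""

    motif_id: str
    probs: np.ndarray  # (L, 4), rows sum to 1, entries in (0, 1]
    pseudocount: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] < 1:
            raise ValueError(f"{self.motif_id}: probs must be an L x 4 matrix with L >= 1")
        if self.pseudocount < 0:
            raise ValueError(f"{self.motif_id}: pseudocount must be >= 0")
        row_sums = self.probs.sum(axis=1)
        if not np.allclose(row_sums, 1.0, atol=1e-9):
            raise ValueError(f"{self.motif_id}: probability rows must sum to 1")
        if (self.probs <= 0).any():
            raise ValueError(
                f"{self.motif_id}: zero emission probability; "
                "use a positive pseudocount when counts contain zeros"
            )

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @property
    def information_content(self) -> float:
        """Motif specificity in bits: sum over positions of 2 + sum_b p log2 p."""
        return _information_content(self.probs)

    def reverse_complement(self) -> "ProbabilityMatrix":
        """PWM of the motif read on the opposite strand (reversed, complemented)."""
        return ProbabilityMatrix(
            motif_id=self.motif_id,
            probs=self.probs[::-1, ::-1].copy(),
            pseudocount=self.pseudocount,
            name=self.name,
        )

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))


@dataclass
class ScanThreshold:
    """Empirical score cutoff for calling hard occurrences of one motif.

    ``threshold`` is the larger of the 100th-highest window scores obtained
    on two background sequence collections, so with 10,000 window scores per
    collection it sits at the 99th percentile (FPR 0.01).
    """

    motif_id: str
    threshold: float
    fpr: float
    n_background_scores: int
    background_digest: str | None = None


# ---------------------------------------------------------------------------
# TRANSFAC flat-file dialect
# ---------------------------------------------------------------------------

def parse_transfac(path_or_handle) -> list[CountMatrix]:
    """Parse a TRANSFAC-style flat file into count matrices.

    Recognised tags per block: AC (accession, used as motif_id), ID/NA (name),
    P0/PO (column header introducing the count rows), ``//`` (block end).
    Count rows are ``<index> <A> <C> <G> <T> [consensus]``.  Raises
    ValueError naming the offending accession and line on malformed blocks.
    """
    if hasattr(path_or_handle, "read"):
        text = path_or_handle.read()
    else:
        with open(path_or_handle, "r", encoding="utf-8") as fh:
            text = fh.read()

    matrices: list[CountMatrix] = []
    acc = name = None
    rows: list[list[float]] = []
    in_matrix = False
    seen_any_tag = False
    block_no = 1

    def finish(lineno: int) -> None:
        nonlocal acc, name, rows, in_matrix, seen_any_tag, block_no
        if not seen_any_tag:
            return
        label = acc or f"block {block_no}"
        if not in_matrix or not rows:
            raise ValueError(
                f"{label} (block {block_no}, near line {lineno}): missing P0 matrix section"
            )
        matrices.append(
            CountMatrix(
                motif_id=acc or f"block{block_no}",
                name=name or (acc or f"block{block_no}"),
                counts=np.array(rows, dtype=float),
                source_tag="transfac",
            )
        )
        acc = name = None
        rows = []
        in_matrix = False
        seen_any_tag = False
        block_no += 1

    lineno = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip()
        if not line.strip() or line.startswith(("XX", "CC", "BF", "BA", "DE")):
            continue
        if line.startswith("//"):
            finish(lineno)
            continue
        tag, _, rest = line.partition(" ")
        rest = rest.strip()
        if tag == "AC":
            acc, seen_any_tag = rest.split()[0], True
        elif tag in ("ID", "NA"):
            if name is None or tag == "NA":
                name = rest
            seen_any_tag = True
        elif tag in ("P0", "PO"):
            in_matrix, seen_any_tag = True, True
        elif in_matrix and tag[:1].isdigit():
            fields = rest.split()
            # trailing consensus symbol is optional and non-numeric
            if fields and not _is_number(fields[-1]):
                fields = fields[:-1]
            if len(fields) != 4 or not all(_is_number(f) for f in fields):
                label = acc or f"block {block_no}"
                raise ValueError(
                    f"{label} (block {block_no}, line {lineno}): "
                    f"matrix row must have 4 counts, got {rest!r}"
                )
            rows.append([float(f) for f in fields])
            seen_any_tag = True
        else:
            seen_any_tag = seen_any_tag or bool(tag)
    # truncated trailing block (no final //)
    finish(lineno)
    return matrices


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_transfac(matrices: Iterable[CountMatrix | ProbabilityMatrix], path_or_handle) -> None:
    """Serialise matrices in the TRANSFAC flat-file dialect (lossless counts)."""
    buf = io.StringIO()
    for m in matrices:
        values = m.counts if isinstance(m, CountMatrix) else m.probs
        buf.write(f"AC  {m.motif_id}\nXX\nNA  {m.name or m.motif_id}\nXX\n")
        buf.write("P0      A      C      G      T\n")
        for i, row in enumerate(values, start=1):
            cells = "  ".join(repr(float(v)) for v in row)
            buf.write(f"{i:02d}  {cells}\n")
        buf.write("XX\n//\n")
    if hasattr(path_or_handle, "write"):
        path_or_handle.write(buf.getvalue())
    else:
        with open(path_or_handle, "w", encoding="utf-8") as fh:
            fh.write(buf.getvalue())


def parse_matrix_table(path_or_handle, motif_id: str = "matrix", name: str = "") -> CountMatrix:
    """Minimal whitespace matrix format: one line per position, 4 columns (A C G T)."""
    if hasattr(path_or_handle, "read"):
        lines = path_or_handle.read().splitlines()
    else:
        with open(path_or_handle, "r", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    rows = []
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 4:
            raise ValueError(f"{motif_id} line {lineno}: expected 4 columns, got {len(fields)}")
        rows.append([float(f) for f in fields])
    if not rows:
        raise ValueError(f"{motif_id}: empty matrix table")
    return CountMatrix(motif_id=motif_id, name=name or motif_id, counts=np.array(rows),
                       source_tag="table")


# ---------------------------------------------------------------------------
# Normalisation
# ---------------------------------------------------------------------------

def to_probability(m: CountMatrix, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> ProbabilityMatrix:
    """Counts -> probabilities: (c + pseudocount) / (row_sum + 4*pseudocount).

    A positive pseudocount is required whenever any cell is zero, so that the
    resulting rows can serve as strictly positive HMM emissions.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount == 0 and (m.counts == 0).any():
        raise ValueError(
            f"{m.motif_id}: zero counts require a positive pseudocount "
            "(zero emission probabilities are not representable in the HMM)"
        )
    row_sums = m.counts.sum(axis=1, keepdims=True)
    probs = (m.counts + pseudocount) / (row_sums + 4.0 * pseudocount)
    return ProbabilityMatrix(motif_id=m.motif_id, probs=probs, pseudocount=pseudocount,
                             name=m.name)


# ---------------------------------------------------------------------------
# Log-odds window scanning
# ---------------------------------------------------------------------------

def _window_logodds(w: ProbabilityMatrix, codes: np.ndarray, log_ratio: np.ndarray) -> np.ndarray:
    """Scores of all |seq|-L+1 windows; windows containing N get -inf."""
    L = w.length
    n_win = codes.size - L + 1
    if n_win <= 0:
        return np.empty(0)
    # pad lookup with a -inf column for N, then sliding sum over diagonals
    lut = np.concatenate([log_ratio, np.full((L, 1), -np.inf)], axis=1)  # (L, 5)
    per_pos = lut[np.arange(L)[None, :], codes[np.add.outer(np.arange(n_win), np.arange(L))]]
    with np.errstate(invalid="ignore"):
        return per_pos.sum(axis=1)


def pwm_scan_scores(
    w: ProbabilityMatrix,
    seq: str,
    background: "DinucleotideBackground",
    strands: str = "both",
) -> list[tuple[int, str, float]]:
    """Log-odds scores for every L-length window of ``seq`` (0-based starts).

    score = sum_i log2( p_i(b_i) / q(b_i) ) with q the background's marginal
    nucleotide distribution.  The reverse-strand score of a window is the
    forward score of its reverse complement against the same matrix. Windows
    containing N are omitted.  Returns (position, strand, score) tuples.
    """
    if strands not in ("both", "forward"):
        raise ValueError(f"unknown strands mode {strands!r}")
    codes = encode_sequence(seq)
    L = w.length
    if codes.size < L:
        return []
    q = background.marginal
    out: list[tuple[int, str, float]] = []
    log_ratio = np.log2(w.probs) - np.log2(q)[None, :]
    fwd = _window_logodds(w, codes, log_ratio)
    for pos, s in enumerate(fwd):
        if np.isfinite(s):
            out.append((pos, "+", float(s)))
    if strands == "both":
        rc = w.reverse_complement()
        log_ratio_rc = np.log2(rc.probs) - np.log2(q)[None, :]
        rev = _window_logodds(rc, codes, log_ratio_rc)
        for pos, s in enumerate(rev):
            if np.isfinite(s):
                out.append((pos, "-", float(s)))
    return out


def _kth_highest(scores: np.ndarray, k: int) -> float:
    return float(np.sort(scores)[-k])


def compute_scan_threshold(
    w: ProbabilityMatrix,
    bg_random: Sequence[str],
    bg_segments: Sequence[str],
    background: "DinucleotideBackground",
    k: int = 100,
    strands: str = "both",
) -> ScanThreshold:
    """Hard-occurrence threshold: max of the two 100th-highest background scores.

    Each of the two background collections (model-generated sequences and real
    promoter segments) is scanned in full; the threshold is the maximum of the
    two collections' k-th (default 100th) highest window scores. With 10,000
    scores per collection this is the 99th percentile, i.e. an FPR of 0.01.
    """
    per_list = []
    for label, seqs in (("bg_random", bg_random), ("bg_segments", bg_segments)):
        scores = np.array(
            [s for seq in seqs for (_, _, s) in pwm_scan_scores(w, seq, background, strands)]
        )
        if scores.size < k:
            raise ValueError(
                f"{w.motif_id}: {label} yields only {scores.size} window scores; "
                f"need at least {k} — supply larger background sets"
            )
        per_list.append(scores)
    t = max(_kth_highest(per_list[0], k), _kth_highest(per_list[1], k))
    n = int(min(per_list[0].size, per_list[1].size))
    return ScanThreshold(
        motif_id=w.motif_id,
        threshold=t,
        fpr=k / n,
        n_background_scores=n,
        background_digest=background.digest(),
    )


# ---------------------------------------------------------------------------
# Redundancy clustering
# ---------------------------------------------------------------------------

def _hits_on_pool(
    w: ProbabilityMatrix,
    pool: "PromoterSet",
    threshold: float,
    background: "DinucleotideBackground",
    strands: str,
) -> dict[str, list[tuple[int, int]]]:
    """Above-threshold hit intervals [start, start+L) per gene (strand-agnostic)."""
    L = w.length
    hits: dict[str, list[tuple[int, int]]] = {}
    for gene, seq in pool.sequences.items():
        ivals = [
            (pos, pos + L)
            for (pos, _strand, score) in pwm_scan_scores(w, seq, background, strands)
            if score >= threshold
        ]
        if ivals:
            hits[gene] = sorted(ivals)
    return hits


def _count_intersecting(a: dict, b: dict) -> int:
    """Number of intervals in `a` that intersect at least one interval in `b`."""
    n = 0
    for gene, ivals in a.items():
        other = b.get(gene)
        if not other:
            continue
        starts = np.array([s for s, _ in other])
        ends = np.array([e for _, e in other])
        for s, e in ivals:
            # half-open intersection: exists j with starts[j] < e and ends[j] > s
            if bool(((starts < e) & (ends > s)).any()):
                n += 1
    return n


def overlap_fraction(hits1: dict, hits2: dict, denominator: str = "total") -> float:
    """Symmetric overlap fraction between two hit sets.

    ``total`` (default): (#hits of 1 touching 2 + #hits of 2 touching 1) /
    (total hits of both). ``min``: same numerator halved conceptually —
    max of per-matrix overlapping fractions, i.e. numerator over the smaller
    hit count (stricter).
    """
    n1 = sum(len(v) for v in hits1.values())
    n2 = sum(len(v) for v in hits2.values())
    if n1 + n2 == 0:
        return 0.0
    c12 = _count_intersecting(hits1, hits2)
    c21 = _count_intersecting(hits2, hits1)
    if denominator == "total":
        return (c12 + c21) / (n1 + n2)
    if denominator == "min":
        if min(n1, n2) == 0:
            return 0.0
        return max(c12 / n1 if n1 else 0.0, c21 / n2 if n2 else 0.0)
    raise ValueError(f"unknown denominator mode {denominator!r}")


def cluster_matrices(
    matrices: Sequence[ProbabilityMatrix],
    promoter_pool: "PromoterSet",
    thresholds: Mapping[str, ScanThreshold],
    overlap_x: float = 0.2,
    background: "DinucleotideBackground | None" = None,
    strands: str = "both",
    denominator: str = "total",
) -> list[ProbabilityMatrix]:
    """Remove redundant matrices by hit overlap on a promoter pool.

    Every pair whose overlap fraction reaches ``overlap_x`` is collapsed by
    discarding the lower-information-content member.  Pairs are processed in
    decreasing overlap fraction (ties by lexicographic motif-id pair) so the
    result is deterministic; raising ``overlap_x`` can only retain more
    matrices.
    """
    if not (0.0 < overlap_x <= 1.0):
        raise ValueError("overlap_x must be in (0, 1]")
    if len(promoter_pool) == 0:
        raise ValueError("promoter pool is empty")
    from .background import estimate_background  # local import to avoid cycle

    bg = background if background is not None else estimate_background(promoter_pool)
    for w in matrices:
        if w.motif_id not in thresholds:
            raise ValueError(f"matrix {w.motif_id} has no scan threshold")

    hit_sets = {
        w.motif_id: _hits_on_pool(w, promoter_pool, thresholds[w.motif_id].threshold, bg, strands)
        for w in matrices
    }
    ic = {w.motif_id: w.information_content for w in matrices}
    pairs = []
    ids = sorted(hit_sets)
    for i, m1 in enumerate(ids):
        for m2 in ids[i + 1:]:
            frac = overlap_fraction(hit_sets[m1], hit_sets[m2], denominator)
            if frac >= overlap_x:
                pairs.append((frac, m1, m2))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))

    removed: set[str] = set()
    for _frac, m1, m2 in pairs:
        if m1 in removed or m2 in removed:
            continue
        # discard lower IC; tie -> discard the lexicographically larger id
        if ic[m1] < ic[m2] or (ic[m1] == ic[m2] and m1 > m2):
            removed.add(m1)
        else:
            removed.add(m2)
    return [w for w in matrices if w.motif_id not in removed]
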