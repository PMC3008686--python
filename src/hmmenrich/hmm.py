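"""Motif + background hidden Markov model: forward scoring and entry learning.

The machine has a silent start state, four background states (one per
nucleotide, each emitting its own base with probability 1 and transitioning
according to the dinucleotide background), and a chain of motif states whose
emissions are the PWM rows and whose internal transitions are 1.  From every
background state (and from the start) the chain may be entered with a learned
*entry probability*; the last motif state exits to the background states
according to the background's initial distribution.  With the default
double-stranded mode a second chain carrying the reverse-complement PWM
shares a single entry parameter, split equally between the two branches.

A promoter's score is the log likelihood ratio
``log P(seq | motif HMM) - log P(seq | background-only HMM)`` computed with
the forward algorithm — a threshold-free measure of motif presence that
accumulates evidence from every potential site, however weak.  The entry
probability is fitted by Baum-Welch restricted to the entry transitions
(emissions, within-motif transitions and the shape of the background
transition block stay fixed; the background block is rescaled by
``1 - entry`` so rows remain stochastic).

Numerics: the forward/backward recursions run in linear space with
per-position renormalisation, accumulating log scale factors, which is exact
in log likelihood and immune to underflow on 500 bp promoters.  The
machine's sparsity (indicator background emissions, deterministic motif
chains) lets whole same-length sequence batches be processed in one
vectorised sweep.  N bases emit probability 1 in every state (neutral
pass-through for masked sequence).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from ._utils import ALPHABET, encode_sequence
from .background import DinucleotideBackground, PromoterSet
from .matrices import ProbabilityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "MotifHMM",
    "PromoterScore",
    "MotifHMMScorer",
    "build_hmm",
    "forward_loglik",
    "learn_entry_probabilities",
    "score_promoter",
    "score_set",
    "background_loglik_set",
]

DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 100
DEFAULT_INIT_ENTRY = 0.01
_MAX_ENTRY = 1.0 - 1e-9


@dataclass
class MotifHMM:
    """The motif + background machine (see module docstring)."""

    motif: ProbabilityMatrix
    background: DinucleotideBackground
    entry_prob: float = 0.0  # background/start -> first forward-motif state
    rev_entry_prob: float = 0.0  # background/start -> first reverse-branch state
    include_reverse: bool = True
    training_history: list[float] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.entry_prob < 1.0) or not (0.0 <= self.rev_entry_prob < 1.0):
            raise ValueError("entry probabilities must lie in [0, 1)")
        if self.entry_prob + self.rev_entry_prob >= 1.0:
            raise ValueError("total entry probability must be < 1")
        if not self.include_reverse and self.rev_entry_prob != 0.0:
            raise ValueError("rev_entry_prob requires include_reverse")

    # -- structure -----------------------------------------------------------
    @property
    def n_states(self) -> int:
        """Emitting states: 4 background + L per included motif branch."""
        L = self.motif.length
        return 4 + L + (L if self.include_reverse else 0)

    @property
    def stay_prob(self) -> float:
        """Mass left for background->background moves: 1 - total entry."""
        return 1.0 - self.entry_prob - self.rev_entry_prob

    def _branch_emissions(self) -> list[tuple[float, np.ndarray]]:
        """(entry probability, L x 5 emission table incl. N column) per branch."""
        branches = [(self.entry_prob, _with_n_column(self.motif.probs))]
        if self.include_reverse:
            branches.append(
                (self.rev_entry_prob, _with_n_column(self.motif.reverse_complement().probs))
            )
        return branches

    def background_only(self) -> "MotifHMM":
        """Same background chain with the motif branches switched off."""
        return MotifHMM(
            motif=self.motif,
            background=self.background,
            entry_prob=0.0,
            rev_entry_prob=0.0,
            include_reverse=self.include_reverse,
        )

    def to_dense(self) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
        """Explicit (state_names, initial, transition, emission) representation.

        Emission columns are A,C,G,T,N (N emits 1 everywhere).  Used for
        serialisation and as the reference structure for path-sum checks.
        """
        L = self.motif.length
        init = self.background.initial
        T = self.background.transition
        names = [f"bg_{b}" for b in ALPHABET] + [f"fwd_{i}" for i in range(L)]
        if self.include_reverse:
            names += [f"rev_{i}" for i in range(L)]
        S = len(names)
        pi = np.zeros(S)
        A = np.zeros((S, S))
        B = np.zeros((S, 5))
        c = self.stay_prob
        pi[:4] = c * init
        A[:4, :4] = c * T
        for b in range(4):
            B[b, b] = 1.0
        B[:, 4] = 1.0
        offsets = [4] + ([4 + L] if self.include_reverse else [])
        for (e, emis), off in zip(self._branch_emissions(), offsets):
            pi[off] = e
            A[:4, off] = e
            B[off:off + L, :] = emis
            for i in range(L - 1):
                A[off + i, off + i + 1] = 1.0
            A[off + L - 1, :4] = init
        return names, pi, A, B

    # -- serialisation -------------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "motif_id": self.motif.motif_id,
            "motif_name": self.motif.name,
            "motif_probs": self.motif.probs.tolist(),
            "pseudocount": self.motif.pseudocount,
            "background": {
                "initial": self.background.initial.tolist(),
                "transition": self.background.transition.tolist(),
                "n_observed": self.background.n_observed,
            },
            "entry_prob": self.entry_prob,
            "rev_entry_prob": self.rev_entry_prob,
            "include_reverse": self.include_reverse,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "MotifHMM":
        d = json.loads(text)
        motif = ProbabilityMatrix(
            motif_id=d["motif_id"], probs=np.array(d["motif_probs"]),
            pseudocount=d.get("pseudocount", 0.0), name=d.get("motif_name", ""),
        )
        bg = DinucleotideBackground(
            np.array(d["background"]["initial"]),
            np.array(d["background"]["transition"]),
            d["background"].get("n_observed", 0),
        )
        return cls(motif=motif, background=bg, entry_prob=d["entry_prob"],
                   rev_entry_prob=d["rev_entry_prob"], include_reverse=d["include_reverse"])


@dataclass
class PromoterScore:
    """Per-promoter likelihood-ratio score (natural log)."""

    gene_id: str
    motif_id: str
    log_ratio: float


def _with_n_column(probs: np.ndarray) -> np.ndarray:
    return np.concatenate([probs, np.ones((probs.shape[0], 1))], axis=1)


def build_hmm(
    motif: ProbabilityMatrix,
    bg: DinucleotideBackground,
    entry_prob: float = 0.0,
    include_reverse: bool = True,
) -> MotifHMM:
    """Assemble the machine; ``entry_prob`` is the *total* entry mass.

    With the reverse branch included the mass is split equally between the
    forward and reverse-complement chains (one shared occurrence parameter).
    """
    if not (0.0 <= entry_prob < 1.0):
        raise ValueError(f"entry_prob must lie in [0, 1), got {entry_prob}")
    if include_reverse:
        return MotifHMM(motif=motif, background=bg, entry_prob=entry_prob / 2.0,
                        rev_entry_prob=entry_prob / 2.0, include_reverse=True)
    return MotifHMM(motif=motif, background=bg, entry_prob=entry_prob,
                    include_reverse=False)


# ---------------------------------------------------------------------------
# Batched scaled forward / backward
# ---------------------------------------------------------------------------

def _emission_tensors(hmm: MotifHMM, enc: np.ndarray):
    """Per-position emission lookups for a batch of same-length sequences.

    enc: (n, T) int codes.  Returns (Ebg, Em) with Ebg of shape (T, n, 4)
    and Em of shape (T, n, nbr*L), the motif-branch emissions concatenated
    (forward chain first, reverse-complement chain second).
    """
    n, T = enc.shape
    is_n = enc == 4
    Ebg = ((enc[..., None] == np.arange(4)) | is_n[..., None]).astype(float)  # (n,T,4)
    Ebg = np.ascontiguousarray(Ebg.transpose(1, 0, 2))  # (T,n,4)
    branch_emis = []
    for _e, emis in hmm._branch_emissions():
        # emis: (L,5); emis[:, enc] has shape (L, n, T) -> reorder to (T, n, L)
        branch_emis.append(emis[:, enc].transpose(2, 1, 0))
    Em = np.ascontiguousarray(np.concatenate(branch_emis, axis=2))
    return Ebg, Em


def _entries_and_branches(hmm: MotifHMM, Em: np.ndarray):
    entries = [hmm.entry_prob] + ([hmm.rev_entry_prob] if hmm.include_reverse else [])
    nbr = len(entries)
    L = Em.shape[2] // nbr
    views = [Em[:, :, br * L:(br + 1) * L] for br in range(nbr)]
    return entries, views


def _forward_batch(hmm: MotifHMM, Ebg: np.ndarray, Em: np.ndarray,
                   keep_alphas: bool = False):
    """Scaled forward pass over a batch; returns per-sequence log likelihoods.

    When ``keep_alphas`` the scaled forward variables and scale factors are
    returned as well (needed by the backward pass).  Dispatches to the
    compiled kernel when numba is available; the numpy fallback implements
    the identical recurrence.
    """
    from . import _kernels

    if _kernels.HAS_NUMBA:
        entries, _ = _entries_and_branches(hmm, Em)
        loglik, alphas_bg, z = _kernels.forward_kernel(
            Ebg, Em, np.asarray(entries, dtype=float), hmm.stay_prob,
            hmm.background.transition, hmm.background.initial, keep_alphas,
        )
        if not np.isfinite(loglik).all():
            raise ValueError("non-finite forward likelihood (zero-probability sequence)")
        if keep_alphas:
            return loglik, alphas_bg, z
        return loglik
    return _forward_batch_np(hmm, Ebg, Em, keep_alphas)


def _forward_batch_np(hmm: MotifHMM, Ebg: np.ndarray, Em: np.ndarray,
                      keep_alphas: bool = False):
    """Pure-numpy reference implementation of the scaled forward pass."""
    T, n, _ = Ebg.shape
    entries, branch_emis = _entries_and_branches(hmm, Em)
    c = hmm.stay_prob
    init = hmm.background.initial
    cT = c * hmm.background.transition

    a_bg = c * init[None, :] * Ebg[0]  # (n,4)
    a_br = [np.zeros((n, Em.shape[2])) for Em in branch_emis]
    for e, Em, a in zip(entries, branch_emis, a_br):
        a[:, 0] = e * Em[0][:, 0]
    z = np.empty((T, n))
    tot = a_bg.sum(axis=1) + sum(a.sum(axis=1) for a in a_br)
    z[0] = tot
    a_bg /= tot[:, None]
    for a in a_br:
        a /= tot[:, None]
    alphas_bg = np.empty((T, n, 4)) if keep_alphas else None
    if keep_alphas:
        alphas_bg[0] = a_bg

    for t in range(1, T):
        exit_mass = sum(a[:, -1] for a in a_br) if a_br else 0.0
        bg_sum = a_bg.sum(axis=1)
        a_bg = (a_bg @ cT + np.multiply.outer(exit_mass, init)) * Ebg[t]
        new_br = []
        for e, Em, a in zip(entries, branch_emis, a_br):
            nb = np.empty_like(a)
            nb[:, 0] = bg_sum * e * Em[t][:, 0]
            nb[:, 1:] = a[:, :-1] * Em[t][:, 1:]
            new_br.append(nb)
        a_br = new_br
        tot = a_bg.sum(axis=1) + sum(a.sum(axis=1) for a in a_br)
        z[t] = tot
        a_bg /= tot[:, None]
        for a in a_br:
            a /= tot[:, None]
        if keep_alphas:
            alphas_bg[t] = a_bg

    loglik = np.log(z).sum(axis=0)
    if not np.isfinite(loglik).all():
        raise ValueError("non-finite forward likelihood (zero-probability sequence)")
    if keep_alphas:
        return loglik, alphas_bg, z
    return loglik


def _forward_backward_counts(hmm: MotifHMM, Ebg: np.ndarray, Em: np.ndarray):
    """E-step: log likelihoods plus expected entry / background-exit counts.

    Returns (loglik (n,), expected entry transitions (n,), expected
    transitions leaving {start, background} states (n,)).
    """
    from . import _kernels

    loglik, alphas_bg, z = _forward_batch(hmm, Ebg, Em, keep_alphas=True)
    if _kernels.HAS_NUMBA:
        entries, _ = _entries_and_branches(hmm, Em)
        num, den = _kernels.backward_counts_kernel(
            Ebg, Em, np.asarray(entries, dtype=float), hmm.stay_prob,
            hmm.background.transition, hmm.background.initial, alphas_bg, z,
        )
        return loglik, num, den
    return _backward_counts_np(hmm, Ebg, Em, loglik, alphas_bg, z)


def _backward_counts_np(hmm: MotifHMM, Ebg: np.ndarray, Em: np.ndarray,
                        loglik: np.ndarray, alphas_bg: np.ndarray, z: np.ndarray):
    """Pure-numpy reference implementation of the counting backward pass."""
    T, n, _ = Ebg.shape
    entries, branch_emis = _entries_and_branches(hmm, Em)
    c = hmm.stay_prob
    init = hmm.background.initial
    cT_T = (c * hmm.background.transition).T

    b_bg = np.ones((n, 4))
    b_br = [np.ones((n, Em.shape[2])) for Em in branch_emis]
    num = np.zeros(n)  # expected entries into motif branches
    den = np.ones(n)  # start always makes exactly one transition

    for t in range(T - 2, -1, -1):
        zt1 = z[t + 1]
        bb = Ebg[t + 1] * b_bg  # (n,4)
        entry_flux = np.zeros(n)
        for e, Em, b in zip(entries, branch_emis, b_br):
            entry_flux += e * Em[t + 1][:, 0] * b[:, 0]
        # xi(bg -> entry) summed over source bg states
        num += alphas_bg[t].sum(axis=1) * entry_flux / zt1
        new_b_bg = (bb @ cT_T + entry_flux[:, None]) / zt1[:, None]
        new_b_br = []
        for Em, b in zip(branch_emis, b_br):
            nb = np.empty_like(b)
            nb[:, :-1] = Em[t + 1][:, 1:] * b[:, 1:]
            nb[:, -1] = bb @ init
            nb /= zt1[:, None]
            new_b_br.append(nb)
        b_bg, b_br = new_b_bg, new_b_br
        # occupancy of background states at time t (each emits one transition)
        den += (alphas_bg[t] * b_bg).sum(axis=1)

    # start -> motif entry
    start_flux = np.zeros(n)
    for e, Em, b in zip(entries, branch_emis, b_br):
        start_flux += e * Em[0][:, 0] * b[:, 0]
    num += start_flux / z[0]
    return loglik, num, den


def _group_by_length(seqs: Sequence[str]) -> dict[int, list[int]]:
    groups: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        groups.setdefault(len(s), []).append(i)
    return groups


def _encode_batch(seqs: Sequence[str], idx: list[int]) -> np.ndarray:
    return np.stack([encode_sequence(seqs[i]) for i in idx])


def forward_loglik(hmm: MotifHMM, seq: str) -> float:
    """Exact log P(seq | hmm), summed over all state paths (forward algorithm)."""
    if len(seq) == 0:
        raise ValueError("cannot score an empty sequence")
    enc = encode_sequence(seq)[None, :]
    Ebg, branch_emis = _emission_tensors(hmm, enc)
    return float(_forward_batch(hmm, Ebg, branch_emis)[0])


def forward_loglik_batch(hmm: MotifHMM, seqs: Sequence[str]) -> np.ndarray:
    """Vectorised forward_loglik over many sequences (any mix of lengths)."""
    out = np.empty(len(seqs))
    for length, idx in _group_by_length(list(seqs)).items():
        if length == 0:
            raise ValueError("cannot score an empty sequence")
        enc = _encode_batch(list(seqs), idx)
        Ebg, branch_emis = _emission_tensors(hmm, enc)
        out[idx] = _forward_batch(hmm, Ebg, branch_emis)
    return out


# ---------------------------------------------------------------------------
# Baum-Welch restricted to the entry transitions
# ---------------------------------------------------------------------------

def learn_entry_probabilities(
    motif: ProbabilityMatrix,
    bg: DinucleotideBackground,
    training_seqs: Sequence[str],
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    include_reverse: bool = True,
    init_entry: float = DEFAULT_INIT_ENTRY,
) -> MotifHMM:
    """Fit the motif entry probability by EM on a training corpus.

    Only the background/start -> motif entry transitions are re-estimated
    (single parameter shared between the two strand branches); the
    background<->background block is rescaled by ``1 - entry`` so rows stay
    stochastic.  The training log likelihood is non-decreasing across
    iterations; iteration stops when the per-sequence gain drops below
    ``tol`` or after ``max_iter`` rounds (with a warning).
    """
    seqs = list(training_seqs)
    if not seqs:
        raise ValueError("training corpus is empty")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    hmm = build_hmm(motif, bg, entry_prob=init_entry, include_reverse=include_reverse)

    # emission tensors do not depend on the entry parameter: build once
    batches = []
    for length, idx in _group_by_length(seqs).items():
        if length == 0:
            raise ValueError("cannot train on an empty sequence")
        enc = _encode_batch(seqs, idx)
        batches.append(_emission_tensors(hmm, enc))

    history: list[float] = []
    prev_ll = -np.inf
    for iteration in range(1, max_iter + 1):
        total_ll = 0.0
        num = den = 0.0
        for Ebg, branch_emis in batches:
            ll, n_i, d_i = _forward_backward_counts(hmm, Ebg, branch_emis)
            total_ll += float(ll.sum())
            num += float(n_i.sum())
            den += float(d_i.sum())
        if not np.isfinite(total_ll):
            raise ValueError("non-finite training likelihood")
        history.append(total_ll)
        logger.info(
            "baum-welch motif=%s iter=%d loglik=%.6f entry=%.6g",
            motif.motif_id, iteration, total_ll, hmm.entry_prob + hmm.rev_entry_prob,
        )
        gain = total_ll - prev_ll
        prev_ll = total_ll
        if iteration > 1 and gain / len(seqs) < tol:
            break
        e_tot = min(num / den, _MAX_ENTRY) if den > 0 else 0.0
        hmm = build_hmm(motif, bg, entry_prob=e_tot, include_reverse=include_reverse)
    else:
        warnings.warn(
            f"Baum-Welch for {motif.motif_id} hit max_iter={max_iter} before "
            f"reaching tol={tol}", RuntimeWarning,
        )
    hmm.training_history = history
    return hmm


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def score_promoter(hmm: MotifHMM, hmm_bg_only: MotifHMM, gene_id: str, seq: str) -> PromoterScore:
    """Likelihood-ratio score of one promoter against the background-only machine."""
    if hmm.background.digest() != hmm_bg_only.background.digest():
        raise ValueError("motif HMM and background-only HMM use different backgrounds")
    if hmm_bg_only.entry_prob != 0.0 or hmm_bg_only.rev_entry_prob != 0.0:
        raise ValueError("background-only machine must have zero entry probability")
    lr = forward_loglik(hmm, seq) - forward_loglik(hmm_bg_only, seq)
    return PromoterScore(gene_id=gene_id, motif_id=hmm.motif.motif_id, log_ratio=lr)


def background_loglik_set(bg: DinucleotideBackground, promoters: PromoterSet) -> dict[str, float]:
    """log P(seq | background-only machine) per gene; shared across motifs."""
    dummy = ProbabilityMatrix("__bg__", np.full((1, 4), 0.25))
    machine = MotifHMM(motif=dummy, background=bg, entry_prob=0.0, rev_entry_prob=0.0,
                       include_reverse=False)
    genes = promoters.gene_ids
    vals = forward_loglik_batch(machine, [promoters.sequences[g] for g in genes])
    return dict(zip(genes, vals))


def score_set(
    hmm: MotifHMM,
    promoters: PromoterSet,
    bg_loglik: dict[str, float] | None = None,
) -> dict[str, float]:
    """Per-gene log likelihood ratios for a whole promoter set (batched).

    ``bg_loglik`` may carry precomputed background-only log likelihoods so
    the (motif-independent) denominator is shared across motifs.
    """
    if bg_loglik is None:
        bg_loglik = background_loglik_set(hmm.background, promoters)
    genes = promoters.gene_ids
    vals = forward_loglik_batch(hmm, [promoters.sequences[g] for g in genes])
    return {g: float(v - bg_loglik[g]) for g, v in zip(genes, vals)}


# ---------------------------------------------------------------------------
# sklearn-style estimator surface
# ---------------------------------------------------------------------------

class MotifHMMScorer(BaseEstimator):
    """Estimator wrapper: fit the entry probability, score promoter sequences.

    Parameters mirror :func:`learn_entry_probabilities`; ``entry_prob=None``
    (default) learns the entry probability from the sequences passed to
    ``fit``, a fixed value skips learning.  ``score_samples`` returns the
    per-sequence log likelihood ratios; ``score`` their sum (the set-level
    statistic used by the enrichment test).

    Attributes set by fit: ``hmm_``, ``entry_prob_``, ``rev_entry_prob_``,
    ``history_`` (training log likelihoods), ``n_iter_``.
    """

    def __init__(
        self,
        motif: ProbabilityMatrix | None = None,
        background: DinucleotideBackground | None = None,
        entry_prob: float | None = None,
        include_reverse: bool = True,
        tol: float = DEFAULT_TOL,
        max_iter: int = DEFAULT_MAX_ITER,
        init_entry: float = DEFAULT_INIT_ENTRY,
    ):
        self.motif = motif
        self.background = background
        self.entry_prob = entry_prob
        self.include_reverse = include_reverse
        self.tol = tol
        self.max_iter = max_iter
        self.init_entry = init_entry

    @staticmethod
    def _as_sequences(X) -> list[str]:
        if isinstance(X, PromoterSet):
            return list(X.sequences.values())
        return list(X)

    def fit(self, X, y=None) -> "MotifHMMScorer":
        if self.motif is None or self.background is None:
            raise ValueError("motif and background are required")
        seqs = self._as_sequences(X)
        if self.entry_prob is None:
            self.hmm_ = learn_entry_probabilities(
                self.motif, self.background, seqs, tol=self.tol, max_iter=self.max_iter,
                include_reverse=self.include_reverse, init_entry=self.init_entry,
            )
            self.history_ = list(self.hmm_.training_history or [])
        else:
            self.hmm_ = build_hmm(self.motif, self.background, entry_prob=self.entry_prob,
                                  include_reverse=self.include_reverse)
            self.history_ = []
        self.entry_prob_ = self.hmm_.entry_prob
        self.rev_entry_prob_ = self.hmm_.rev_entry_prob
        self.n_iter_ = len(self.history_)
        return self

    def score_samples(self, X) -> np.ndarray:
        if not hasattr(self, "hmm_"):
            raise ValueError("call fit before score_samples")
        seqs = self._as_sequences(X)
        bg_machine = self.hmm_.background_only()
        return (
            forward_loglik_batch(self.hmm_, seqs)
            - forward_loglik_batch(bg_machine, seqs)
        )

    def score(self, X, y=None) -> float:
        return float(self.score_samples(X).sum())
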