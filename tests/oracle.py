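"""Independent brute-force oracles used by the test suite.

Everything here deliberately avoids the package's dynamic-programming code
paths: likelihoods are obtained by explicit enumeration of *all* state paths,
window scores by per-window recomputation, order statistics by full sorts.
"""

from __future__ import annotations

import numpy as np

from hmmenrich._utils import BASE_INDEX


def encode(seq: str) -> list[int]:
    return [BASE_INDEX[c] for c in seq.upper()]


def enumerate_paths_loglik(pi: np.ndarray, A: np.ndarray, B: np.ndarray, seq: str) -> float:
    """log P(seq) as an explicit sum over every state path (vectorised frontier).

    The frontier holds one weight per distinct partial path; each step every
    path is extended by every nonzero transition, so the final weights are
    exactly the per-path probabilities, summed at the end.
    """
    obs = encode(seq)
    S = pi.size
    states = np.arange(S)
    weights = pi * B[:, obs[0]]
    keep = weights > 0
    states, weights = states[keep], weights[keep]
    for x in obs[1:]:
        new_states = []
        new_weights = []
        for s in range(S):
            mask = states == s
            if not mask.any():
                continue
            w_here = weights[mask]
            for s2 in np.nonzero(A[s] > 0)[0]:
                emit = B[s2, x]
                if emit == 0:
                    continue
                new_states.append(np.full(w_here.size, s2))
                new_weights.append(w_here * A[s, s2] * emit)
        if not new_states:
            return float("-inf")
        states = np.concatenate(new_states)
        weights = np.concatenate(new_weights)
    return float(np.log(weights.sum()))


def enumerate_entry_counts(pi: np.ndarray, A: np.ndarray, B: np.ndarray, seq: str,
                           entry_targets: set[int], source_states: set[int]):
    """Posterior expected transition counts by explicit path enumeration.

    Returns (loglik, E[# transitions from a source state or start into an
    entry-target state], E[# transitions leaving a source state, the start
    included]).  Recursive; only for tiny machines/sequences.
    """
    obs = encode(seq)
    S = pi.size
    total = 0.0
    num = 0.0
    den = 0.0

    def rec(t: int, s: int, w: float, entries: int, outs: int) -> None:
        nonlocal total, num, den
        if t == len(obs) - 1:
            total += w
            num += w * entries
            den += w * outs
            return
        for s2 in range(S):
            a = A[s, s2]
            if a == 0:
                continue
            emit = B[s2, obs[t + 1]]
            if emit == 0:
                continue
            from_source = s in source_states
            rec(
                t + 1, s2, w * a * emit,
                entries + (1 if from_source and s2 in entry_targets else 0),
                outs + (1 if from_source else 0),
            )

    for s in range(S):
        w = pi[s] * B[s, obs[0]]
        if w > 0:
            # the silent start makes one transition; entries from start count
            rec(0, s, w, 1 if s in entry_targets else 0, 1)
    if total == 0:
        return float("-inf"), float("nan"), float("nan")
    return float(np.log(total)), num / total, den / total


def windows_logodds(probs: np.ndarray, seq: str, q: np.ndarray) -> list[float]:
    """Per-window forward-strand log-odds by naive recomputation (N -> skip)."""
    L = probs.shape[0]
    out = []
    for i in range(len(seq) - L + 1):
        win = seq[i:i + L]
        if "N" in win:
            out.append(None)
            continue
        s = 0.0
        for j, c in enumerate(win):
            b = BASE_INDEX[c]
            s += np.log2(probs[j, b] / q[b])
        out.append(s)
    return out
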