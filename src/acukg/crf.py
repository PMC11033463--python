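"""Linear-chain CRF: path scoring, log-partition, NLL loss and Viterbi decoding.

A path's score is the sum of per-position emission scores and tag-to-tag
transition scores, plus scores for starting and ending in the path's first
and last tag.  Training minimizes the negative log-probability of the gold
path, where the probability of a path is its exponentiated score normalized
by the sum over all paths (the partition), computed with the forward
algorithm in log space.

BIO validity can be enforced structurally by adding a large negative
constant to transitions that would produce an orphan ``I`` tag.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .autodiff import Tensor

#: Additive penalty for disallowed transitions.
DEFAULT_MASK_PENALTY = -1e4


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def crf_path_score(
    emissions, transitions, path: Sequence[int], start=None, end=None
) -> float:
    """Score of one tag path: emissions + transitions + start/end scores."""
    return crf_path_score_t(
        _as_tensor(emissions), _as_tensor(transitions), list(path),
        None if start is None else _as_tensor(start),
        None if end is None else _as_tensor(end),
    ).item()


def crf_path_score_t(
    emissions: Tensor,
    transitions: Tensor,
    path: Sequence[int],
    start: Tensor | None = None,
    end: Tensor | None = None,
) -> Tensor:
    n, l = emissions.shape
    if len(path) != n:
        raise ValueError(f"path length {len(path)} != sequence length {n}")
    score = emissions[0, path[0]]
    if start is not None:
        score = score + start[path[0]]
    for t in range(1, n):
        score = score + transitions[path[t - 1], path[t]] + emissions[t, path[t]]
    if end is not None:
        score = score + end[path[-1]]
    return score


def crf_log_partition(emissions, transitions, start=None, end=None) -> float:
    """Log of the sum of exponentiated scores over all l^n paths (forward algorithm)."""
    return crf_log_partition_t(
        _as_tensor(emissions), _as_tensor(transitions),
        None if start is None else _as_tensor(start),
        None if end is None else _as_tensor(end),
    ).item()


def crf_log_partition_t(
    emissions: Tensor,
    transitions: Tensor,
    start: Tensor | None = None,
    end: Tensor | None = None,
) -> Tensor:
    n, l = emissions.shape
    alpha = emissions[0]
    if start is not None:
        alpha = alpha + start
    for t in range(1, n):
        # alpha[i] + trans[i, j] + emit[t, j], reduced over i
        scores = alpha.reshape(l, 1) + transitions + emissions[t].reshape(1, l)
        alpha = scores.logsumexp(axis=0)
    if end is not None:
        alpha = alpha + end
    return alpha.logsumexp(axis=0)


def crf_loss(emissions, transitions, gold_path: Sequence[int], start=None, end=None) -> float:
    """Negative log-probability of the gold path; always >= 0."""
    return crf_loss_t(
        _as_tensor(emissions), _as_tensor(transitions), list(gold_path),
        None if start is None else _as_tensor(start),
        None if end is None else _as_tensor(end),
    ).item()


def crf_loss_t(
    emissions: Tensor,
    transitions: Tensor,
    gold_path: Sequence[int],
    start: Tensor | None = None,
    end: Tensor | None = None,
) -> Tensor:
    if not np.all(np.isfinite(emissions.data)):
        raise ValueError("emissions contain non-finite values")
    log_z = crf_log_partition_t(emissions, transitions, start, end)
    gold = crf_path_score_t(emissions, transitions, gold_path, start, end)
    return log_z - gold


def viterbi(emissions, transitions, start=None, end=None) -> list[int]:
    """Maximum-score path; ties broken toward the lowest tag index."""
    emissions = np.asarray(emissions, dtype=np.float64)
    transitions = np.asarray(transitions, dtype=np.float64)
    if not np.all(np.isfinite(emissions)):
        raise ValueError("emissions contain non-finite values")
    n, l = emissions.shape
    delta = emissions[0].copy()
    if start is not None:
        delta = delta + np.asarray(start, dtype=np.float64)
    backptr = np.zeros((n, l), dtype=np.int64)
    for t in range(1, n):
        scores = delta[:, None] + transitions  # (prev, cur)
        best_prev = scores.argmax(axis=0)  # argmax returns lowest index on ties
        delta = scores[best_prev, np.arange(l)] + emissions[t]
        backptr[t] = best_prev
    if end is not None:
        delta = delta + np.asarray(end, dtype=np.float64)
    path = [int(delta.argmax())]
    for t in range(n - 1, 0, -1):
        path.append(int(backptr[t, path[-1]]))
    return path[::-1]


def bio_transition_mask(
    tags: Sequence[str], penalty: float = DEFAULT_MASK_PENALTY
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Additive (transition, start, end) masks enforcing BIO validity.

    ``I-t`` may only follow ``B-t`` or ``I-t``; it may not open a sequence.
    Returns zero matrices with ``penalty`` at the disallowed entries.
    """
    l = len(tags)
    trans = np.zeros((l, l))
    start = np.zeros(l)
    end = np.zeros(l)
    for j, tag_j in enumerate(tags):
        if not tag_j.startswith("I-"):
            continue
        t = tag_j[2:]
        start[j] = penalty
        for i, tag_i in enumerate(tags):
            if tag_i not in (f"B-{t}", f"I-{t}"):
                trans[i, j] = penalty
    return trans, start, end
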