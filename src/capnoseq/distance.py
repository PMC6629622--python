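"""Dissimilarities between respiratory state sequences.

Sequences are compared through their state-occupancy distributions — the
fraction of (non-missing) monitored time spent in each state — which makes
the measures sensitive to durations rather than to timing or ordering, and
length-invariant by construction. Two metrics are provided:

* Euclidean distance between occupancy distributions;
* chi-squared distance, which weights each state's squared difference by the
  inverse of the pooled (cohort-wide) proportion of time spent in that state,
  so that rare states (e.g. bradypnea) carry more weight.

Both generalize to ``n_intervals`` equal-width spans of the sequence; the
default of 1 compares whole-sequence distributions. Distances are divided by
``sqrt(n_intervals)`` so values are comparable across interval settings.
Missing (artifact) seconds are excluded from numerators and denominators.

Both metrics are Euclidean norms in a weighted coordinate system, so the
full metric axioms (including the triangle inequality) hold exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .states import MISSING, STATE_ALPHABET, StateSequence


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise sequence dissimilarities for a cohort."""

    ids: list[str]
    values: np.ndarray  # (n, n) symmetric, zero diagonal
    metric: str
    marginal: dict[str, float]  # pooled state proportions used as chi2 weights
    n_intervals: int = 1

    @property
    def n(self) -> int:
        return len(self.ids)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.n, self.n):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(v, v.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(v < 0) or not np.allclose(np.diag(v), 0.0):
            raise ValueError("dissimilarities must be >= 0 with a zero diagonal")
        self.values = v


def state_counts(seq: StateSequence, n_intervals: int = 1) -> np.ndarray:
    """Per-interval counts of non-missing seconds in each state.

    Returns an ``(n_intervals, n_states)`` array over :data:`STATE_ALPHABET`.
    Intervals are the equal-width spans obtained by splitting second indices
    as evenly as possible (first ``len % n_intervals`` spans one second longer).
    """
    if n_intervals < 1:
        raise ValueError("n_intervals must be >= 1")
    chunks = np.array_split(seq.states, n_intervals)
    out = np.zeros((n_intervals, len(STATE_ALPHABET)), dtype=float)
    for i, chunk in enumerate(chunks):
        for j, state in enumerate(STATE_ALPHABET):
            out[i, j] = np.sum(chunk == state)
    return out


def state_distribution(seq: StateSequence, n_intervals: int = 1) -> np.ndarray:
    """Per-interval state-occupancy proportions among non-missing seconds.

    An interval consisting entirely of missing seconds yields a zero row
    (no occupancy information); an entirely missing sequence is rejected.
    """
    counts = state_counts(seq, n_intervals)
    totals = counts.sum(axis=1, keepdims=True)
    if counts.sum() == 0:
        raise ValueError(f"sequence for patient {seq.patient_id} is entirely missing")
    with np.errstate(invalid="ignore", divide="ignore"):
        props = np.where(totals > 0, counts / np.where(totals > 0, totals, 1.0), 0.0)
    return props


def overall_marginal(seqs: list[StateSequence]) -> dict[str, float]:
    """Pooled time-in-state proportions across all patients' non-missing seconds.

    Pooling is by total seconds (counts), not by averaging per-patient
    proportions, so longer procedures weigh more. States with zero pooled
    time are dropped from the returned support (they cannot be chi2-weighted).
    """
    if not seqs:
        raise ValueError("need at least one sequence")
    pooled = np.zeros(len(STATE_ALPHABET))
    for seq in seqs:
        pooled += state_counts(seq, 1)[0]
    total = pooled.sum()
    if total == 0:
        raise ValueError("all sequences entirely missing")
    return {
        s: float(c / total) for s, c in zip(STATE_ALPHABET, pooled) if c > 0
    }


def _embed(props: np.ndarray, marginal: dict[str, float], metric: str) -> np.ndarray:
    """Flatten per-interval distributions into the coordinate system in which
    the requested metric is a plain Euclidean norm (divided by sqrt(K))."""
    support = [s for s in STATE_ALPHABET if s in marginal]
    idx = [STATE_ALPHABET.index(s) for s in support]
    p = props[:, idx]
    if metric == "chi2":
        w = np.array([marginal[s] for s in support])
        p = p / np.sqrt(w)
    elif metric != "euclid":
        raise ValueError(f"unknown metric {metric!r}")
    return p.ravel() / np.sqrt(props.shape[0])


def chi2_distance(
    p: np.ndarray, q: np.ndarray, marginal: dict[str, float]
) -> float:
    """Chi-squared distance between two per-interval distribution arrays.

    ``d = sqrt( sum_intervals sum_states (p_s - q_s)^2 / m_s ) / sqrt(K)``
    with ``m_s`` the pooled marginal proportion of state ``s``. States absent
    from ``marginal`` are excluded (both sequences must have zero occupancy
    there, else the supports are inconsistent).
    """
    p, q = np.atleast_2d(p), np.atleast_2d(q)
    if p.shape != q.shape:
        raise ValueError("interval counts differ between sequences")
    _check_support(p, marginal)
    _check_support(q, marginal)
    return float(
        np.linalg.norm(_embed(p, marginal, "chi2") - _embed(q, marginal, "chi2"))
    )


def euclid_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Euclidean distance between per-interval distributions, / sqrt(K)."""
    p, q = np.atleast_2d(p), np.atleast_2d(q)
    if p.shape != q.shape:
        raise ValueError("interval counts differ between sequences")
    full = {s: 1.0 for s in STATE_ALPHABET}
    return float(
        np.linalg.norm(_embed(p, full, "euclid") - _embed(q, full, "euclid"))
    )


def _check_support(props: np.ndarray, marginal: dict[str, float]) -> None:
    for j, s in enumerate(STATE_ALPHABET):
        if s not in marginal and np.any(props[:, j] > 0):
            raise ValueError(
                f"state {s} occupied but absent from the marginal support"
            )


def pairwise_dissimilarity(
    seqs: list[StateSequence],
    metric: str = "chi2",
    n_intervals: int = 1,
    marginal: dict[str, float] | None = None,
) -> DissimilarityMatrix:
    """Full symmetric dissimilarity matrix for a cohort of sequences.

    The chi2 weights default to the pooled marginal of the analyzed cohort
    itself. Entirely-missing sequences are rejected with their ids listed.
    """
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    bad = [s.patient_id for s in seqs if np.all(s.states == MISSING)]
    if bad:
        raise ValueError(f"entirely-missing sequences for patients: {bad}")
    if marginal is None:
        marginal = overall_marginal(seqs)
    if metric == "euclid":
        emb_marg = {s: 1.0 for s in STATE_ALPHABET}
    else:
        emb_marg = marginal
    coords = np.array(
        [_embed(state_distribution(s, n_intervals), emb_marg, metric) for s in seqs]
    )
    d = squareform(pdist(coords, metric="euclidean"))
    return DissimilarityMatrix(
        ids=[s.patient_id for s in seqs],
        values=d,
        metric=metric,
        marginal=marginal,
        n_intervals=n_intervals,
    )
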