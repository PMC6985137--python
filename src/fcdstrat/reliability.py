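"""Test-retest reliability of FCD maps.

Two complementary views: (1) connectome-style fingerprinting — each
subject's baseline map is correlated with every subject's follow-up map and
the rank of the self-match records how identifiable the subject is; (2)
consistency of classifier outcomes — a transition matrix of follow-up
confusion outcome (TN/FP/FN/TP) given the baseline outcome, compared with a
group-preserving permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FingerprintResult",
    "fingerprint",
    "outcome_labels",
    "TransitionMatrix",
    "transition_matrix",
    "transition_null",
    "OUTCOMES",
]

OUTCOMES = ("TN", "FP", "FN", "TP")


@dataclass
class FingerprintResult:
    n_subjects: int
    self_ranks: np.ndarray        # 1 = best match
    correlation_matrix: np.ndarray  # baseline x followup

    @property
    def identification_rate(self) -> float:
        return float((self.self_ranks == 1).mean())

    @property
    def chance_level(self) -> float:
        return 1.0 / self.n_subjects


def _rowwise_corr(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    Az = (A - A.mean(axis=1, keepdims=True))
    Bz = (B - B.mean(axis=1, keepdims=True))
    Az /= np.linalg.norm(Az, axis=1, keepdims=True)
    Bz /= np.linalg.norm(Bz, axis=1, keepdims=True)
    return Az @ Bz.T


def fingerprint(baseline_maps, followup_maps, subject_ids=None) -> FingerprintResult:
    """Rank of each subject's self-match among follow-up correlations.

    Rows of both matrices are subjects in the same order, columns voxels.
    For subject i, the N correlations baseline(i) x followup(j) are ranked
    descending; ties are broken against the self-match (it gets the worst
    rank among tied values).
    """
    A = np.asarray(baseline_maps, dtype=float)
    B = np.asarray(followup_maps, dtype=float)
    if A.shape != B.shape:
        raise ValueError("baseline and follow-up map sets must match in shape")
    if subject_ids is not None and len(set(subject_ids)) != A.shape[0]:
        raise ValueError("subject ids must be unique and match the map count")
    n = A.shape[0]
    corr = _rowwise_corr(A, B)
    ranks = np.empty(n, dtype=int)
    for i in range(n):
        row = corr[i]
        others = np.delete(row, i)
        # worst rank among ties: count every other correlation >= self
        ranks[i] = 1 + int((others >= row[i]).sum())
    return FingerprintResult(n_subjects=n, self_ranks=ranks,
                             correlation_matrix=corr)


def outcome_labels(predictions, truth) -> np.ndarray:
    """Confusion outcome per subject: TN, FP (controls), FN, TP (pre-HD).

    ``truth`` is 1 for pre-HD (positive class), 0 for control;
    ``predictions`` are binary classifier outputs at a fixed threshold.
    """
    pred = np.asarray(predictions).astype(int)
    t = np.asarray(truth).astype(int)
    out = np.empty(pred.shape, dtype=object)
    out[(t == 0) & (pred == 0)] = "TN"
    out[(t == 0) & (pred == 1)] = "FP"
    out[(t == 1) & (pred == 0)] = "FN"
    out[(t == 1) & (pred == 1)] = "TP"
    return out.astype("U2")


@dataclass
class TransitionMatrix:
    """P(follow-up outcome | baseline outcome), rows = baseline."""

    probabilities: np.ndarray     # 4 x 4, rows/cols ordered as OUTCOMES
    counts: np.ndarray
    outcomes: tuple = OUTCOMES

    def row(self, outcome: str) -> np.ndarray:
        return self.probabilities[self.outcomes.index(outcome)]

    def diagonal(self) -> dict:
        return {o: float(self.probabilities[i, i])
                for i, o in enumerate(self.outcomes)
                if self.counts[i].sum() > 0}


def transition_matrix(baseline_outcomes, followup_outcomes) -> TransitionMatrix:
    """Empirical conditional outcome frequencies between the two visits.

    Controls can only occupy {TN, FP} and pre-HD {FN, TP} on both visits,
    so the matrix is block-diagonal by group.
    """
    b = np.asarray(baseline_outcomes)
    f = np.asarray(followup_outcomes)
    if b.shape != f.shape:
        raise ValueError("visit outcome vectors must have equal length")
    ctrl = {"TN", "FP"}
    for bo, fo in zip(b, f):
        if (bo in ctrl) != (fo in ctrl):
            raise ValueError("subject changes group between visits")
    counts = np.zeros((4, 4))
    idx = {o: i for i, o in enumerate(OUTCOMES)}
    for bo, fo in zip(b, f):
        counts[idx[bo], idx[fo]] += 1
    probs = np.zeros_like(counts)
    row_tot = counts.sum(axis=1)
    nz = row_tot > 0
    probs[nz] = counts[nz] / row_tot[nz, None]
    return TransitionMatrix(probabilities=probs, counts=counts)


def transition_null(baseline_outcomes, followup_outcomes, groups,
                    n_perm: int = 1000, seed: int = 0
                    ) -> tuple[np.ndarray, dict]:
    """Group-preserving permutation null for outcome consistency.

    Follow-up outcomes are permuted among subjects of the same group,
    preserving each group's outcome proportions per visit while destroying
    the within-subject correspondence.  Returns the chance matrix (mean
    permuted transition matrix) and two-sided add-one p-values for each
    occupied diagonal cell (consistency at least as extreme as observed in
    either direction).
    """
    b = np.asarray(baseline_outcomes)
    f = np.asarray(followup_outcomes)
    groups = np.asarray(groups)
    obs = transition_matrix(b, f)
    rng = np.random.default_rng(seed)
    group_idx = {g: np.where(groups == g)[0] for g in np.unique(groups)}
    for g, idx in group_idx.items():
        if len(idx) == 1:
            import warnings
            warnings.warn(f"group {g!r} has one subject; its follow-up is "
                          "fixed under permutation", RuntimeWarning,
                          stacklevel=2)
    null_probs = np.zeros((n_perm, 4, 4))
    for k in range(n_perm):
        fp = f.copy()
        for idx in group_idx.values():
            fp[idx] = fp[rng.permutation(idx)]
        null_probs[k] = transition_matrix(b, fp).probabilities
    chance = null_probs.mean(axis=0)
    pvals = {}
    for i, o in enumerate(OUTCOMES):
        if obs.counts[i].sum() == 0:
            continue
        obs_c = obs.probabilities[i, i]
        null_c = null_probs[:, i, i]
        hi = (null_c >= obs_c - 1e-12).sum()
        lo = (null_c <= obs_c + 1e-12).sum()
        pvals[o] = min(1.0, 2.0 * (1 + min(hi, lo)) / (1 + n_perm))
    return chance, pvals
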