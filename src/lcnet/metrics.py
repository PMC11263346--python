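"""Event-segmentation and clustering evaluation.

Boundary extraction from inferred latent-cause sequences, cluster purity,
adjusted mutual information (AMI), point-biserial correlation between
binary model boundaries and continuous human boundary probabilities —
with min-max scaling by the extremal correlations achievable at the
model's boundary count — and permutation-based significance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import adjusted_mutual_info_score
from sklearn.metrics.cluster import contingency_matrix

__all__ = [
    "SegmentationResult",
    "extract_boundaries",
    "cluster_purity",
    "adjusted_mutual_information",
    "point_biserial",
    "scaled_point_biserial",
    "permutation_pvalue",
]


@dataclass
class SegmentationResult:
    """Inferred LC sequence, its switch-point boundaries, and metric scores."""

    lc_sequence: np.ndarray
    boundaries: np.ndarray = field(default=None)
    metrics: dict = field(default_factory=dict)

    def __post_init__(self):
        self.lc_sequence = np.asarray(self.lc_sequence)
        if self.boundaries is None:
            self.boundaries = extract_boundaries(self.lc_sequence)


def extract_boundaries(lc_sequence) -> np.ndarray:
    """Binary vector marking switch points of the inferred LC sequence.

    ``out[t] == 1`` iff ``lc_sequence[t] != lc_sequence[t-1]``; the first
    entry is 0 (a stream cannot open with a switch).
    """
    seq = np.asarray(lc_sequence)
    if seq.size == 0:
        raise ValueError("empty LC sequence")
    out = np.zeros(seq.size, dtype=int)
    out[1:] = (seq[1:] != seq[:-1]).astype(int)
    return out


def cluster_purity(assignments, truth) -> float:
    """Purity(Ĉ, C) = (1/n) Σ_k max_j |Ĉ_k ∩ C_j|.

    For each inferred cluster, count its overlap with its best-matching
    true class; 1.0 means every inferred cluster is class-pure.
    """
    assignments = np.asarray(assignments)
    truth = np.asarray(truth)
    if assignments.shape != truth.shape or assignments.size == 0:
        raise ValueError("assignments and truth must be equal-length, non-empty")
    cont = contingency_matrix(truth, assignments)   # rows: true classes, cols: clusters
    return float(cont.max(axis=0).sum() / assignments.size)


def adjusted_mutual_information(assignments, truth) -> float:
    """AMI with the max-entropy normalizer:
    (MI − E[MI]) / (max(H(C), H(Ĉ)) − E[MI]), E[MI] under the fixed-marginals
    permutation (hypergeometric) model.

    When both partitions are single-cluster the denominator vanishes; by
    convention the score is 1.0 for identical partitions, else 0.0 (the
    scikit-learn convention, kept explicit here).
    """
    assignments = np.asarray(assignments)
    truth = np.asarray(truth)
    if assignments.shape != truth.shape:
        raise ValueError("assignments and truth must have equal length")
    return float(adjusted_mutual_info_score(truth, assignments, average_method="max"))


def point_biserial(model_boundaries, human_prob) -> float:
    """r_pb = ((M1 − M0) / s_n) · sqrt(n1 · n0 / n²).

    M1/M0 are the mean human boundary probabilities at frames with/without
    a model boundary, n1/n0 the corresponding frame counts, and s_n the
    population standard deviation of the probability track.  Numerically
    identical to the Pearson correlation of the two vectors.
    """
    b = np.asarray(model_boundaries, dtype=float)
    p = np.asarray(human_prob, dtype=float)
    if b.shape != p.shape:
        raise ValueError("boundary and probability vectors must have equal length")
    n = b.size
    n1 = int(b.sum())
    n0 = n - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("model boundary vector must contain both 0s and 1s")
    s = p.std()
    if s == 0:
        raise ValueError("human probability track is constant; correlation undefined")
    m1 = p[b == 1].mean()
    m0 = p[b == 0].mean()
    return float((m1 - m0) / s * np.sqrt(n1 * n0 / n**2))


def scaled_point_biserial(model_boundaries, human_prob) -> float:
    """Min-max rescaling of r_pb by the extremal values achievable at the
    model's boundary count.

    r_max (r_min) is the correlation when the same number of boundary
    indicators is placed on the frames with the highest (lowest) human
    probabilities — the optimal placements for a fixed number of ones.
    Returns (r − r_min) / (r_max − r_min) in [0, 1].
    """
    b = np.asarray(model_boundaries, dtype=float)
    p = np.asarray(human_prob, dtype=float)
    r = point_biserial(b, p)
    n1 = int(b.sum())
    order = np.argsort(p, kind="stable")
    best = np.zeros_like(b)
    best[order[-n1:]] = 1
    worst = np.zeros_like(b)
    worst[order[:n1]] = 1
    r_max = point_biserial(best, p)
    r_min = point_biserial(worst, p)
    if r_max == r_min:
        raise ValueError("degenerate scaling: r_max == r_min")
    return float((r - r_min) / (r_max - r_min))


def permutation_pvalue(
    observed_stat: float,
    model_boundaries,
    human_prob,
    statistic_fn,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    max_redraws: int = 100,
) -> float:
    """Permutation test preserving the number of model boundaries.

    Shuffles the positions of the binary boundary vector, recomputes
    ``statistic_fn(boundaries, human_prob)`` for each draw, and returns the
    add-one estimator ``p = (1 + #{perm ≥ observed}) / (1 + n_perm)``.
    Permutations on which the statistic is undefined are redrawn.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(0) if rng is None else rng
    b = np.asarray(model_boundaries)
    count = 0
    for _ in range(n_perm):
        for _attempt in range(max_redraws):
            perm = rng.permutation(b)
            try:
                stat = statistic_fn(perm, human_prob)
            except ValueError:
                continue
            break
        else:  # pragma: no cover
            raise RuntimeError("statistic undefined on all redrawn permutations")
        if stat >= observed_stat:
            count += 1
    return (1 + count) / (1 + n_perm)
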