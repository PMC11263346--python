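"""Seeded generators for the three simulated environments.

1. Polynomial function-learning tasks: each task is the sum of one shared
   polynomial term and a task-specific idiosyncratic term, plus a noisy
   128-bit context-indicative signal (CIS) per task.
2. The cafe/bar schema graph: six aliased states whose transition
   structure depends on a context announced by an opening CIS state, with
   blocked / interleaved training curricula.
3. A synthetic naturalistic-event corpus: streams of 30-dimensional frame
   vectors driven by temporally persistent latent event classes, with
   ground-truth labels and simulated human boundary annotations.  This is
   a stand-in with the same structure as a real annotated video corpus,
   not derived from any real footage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.polynomial import polynomial as P

__all__ = [
    "PolynomialTaskSet",
    "SchemaTask",
    "SchemaTrial",
    "CurriculumSchedule",
    "SyntheticEventCorpus",
    "sample_polynomial_taskset",
    "make_noisy_cis",
    "sample_schema_trial",
    "make_curriculum",
    "generate_event_corpus",
]

CIS_LENGTH = 128


# ---------------------------------------------------------------- Sim 1

@dataclass
class PolynomialTaskSet:
    """Tasks ``task_i(x) = shared(x) + idio_i(x)`` with per-task CIS vectors.

    Coefficients are in ascending-power order.  The additive decomposition
    holds exactly by construction.
    """

    shared_coeffs: np.ndarray
    idio_coeffs: np.ndarray          # (n_tasks, degree+1)
    cis_vectors: np.ndarray          # (n_tasks, CIS_LENGTH), {0,1}
    x_range: tuple[float, float] = (-1.0, 1.0)
    cis_noise_rate: float = 0.1

    @property
    def n_tasks(self) -> int:
        return self.idio_coeffs.shape[0]

    def shared(self, x) -> np.ndarray:
        return P.polyval(x, self.shared_coeffs)

    def idio(self, i: int, x) -> np.ndarray:
        return P.polyval(x, self.idio_coeffs[i])

    def task(self, i: int, x) -> np.ndarray:
        # summing the evaluated terms (not the coefficients) keeps the
        # additive decomposition bit-exact
        return self.shared(x) + self.idio(i, x)

    def sample_x(self, size: int, rng: np.random.Generator) -> np.ndarray:
        lo, hi = self.x_range
        return rng.uniform(lo, hi, size=size)


def sample_polynomial_taskset(
    n_tasks: int = 4,
    degree: int = 3,
    coeff_scale: float = 1.0,
    x_range: tuple[float, float] = (-1.0, 1.0),
    rng: np.random.Generator | None = None,
    cis_noise_rate: float = 0.1,
    shared_scale: float = 2.0,
) -> PolynomialTaskSet:
    """Draw shared (±shared_scale) and idiosyncratic (±coeff_scale)
    coefficients uniformly.

    The shared term dominates by default (2:1): tasks are variations on a
    common shape, so knowledge of the shared term makes a new task's
    residual genuinely smaller than learning from scratch.
    """
    if n_tasks < 1 or degree < 1:
        raise ValueError("n_tasks and degree must be >= 1")
    if not x_range[1] > x_range[0]:
        raise ValueError(f"empty x_range {x_range}")
    rng = np.random.default_rng(0) if rng is None else rng
    shared = rng.uniform(-shared_scale, shared_scale, size=degree + 1)
    idio = rng.uniform(-coeff_scale, coeff_scale, size=(n_tasks, degree + 1))
    cis = rng.integers(0, 2, size=(n_tasks, CIS_LENGTH))
    return PolynomialTaskSet(
        shared_coeffs=shared, idio_coeffs=idio, cis_vectors=cis,
        x_range=tuple(x_range), cis_noise_rate=cis_noise_rate,
    )


def make_noisy_cis(cis: np.ndarray, noise_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Flip each bit of a binary CIS vector independently with ``noise_rate``."""
    cis = np.asarray(cis)
    if not np.isin(cis, (0, 1)).all():
        raise ValueError("CIS must be a binary vector")
    if not 0 <= noise_rate < 0.5:
        raise ValueError(f"noise_rate must be in [0, 0.5), got {noise_rate}")
    flips = rng.random(cis.shape) < noise_rate
    return np.where(flips, 1 - cis, cis)


# ---------------------------------------------------------------- Sim 2

# Context-conditional successor maps on the six aliased states.  In
# context 1 the walks 1-4-5 and 2-3-6 can occur; in context 2, 1-3-5 and
# 2-4-6.  The states themselves are identical across contexts.
_SUCCESSORS = {
    1: {1: 4, 4: 5, 2: 3, 3: 6},
    2: {1: 3, 3: 5, 2: 4, 4: 6},
}
_PATHS = {
    1: ([1, 4, 5], [2, 3, 6]),
    2: ([1, 3, 5], [2, 4, 6]),
}
# State ids 7 and 8 are the CIS opening states (cafe, bar) for contexts 1, 2.
CIS_STATE = {1: 7, 2: 8}


@dataclass
class SchemaTask:
    """The two-context schema graph with fixed random state vectors.

    ``state_vectors[i]`` is the vector for state id ``i`` (1-6 are the
    in-event states, shared verbatim across contexts; 7 and 8 are the two
    CIS opening states).  Inputs presented to a model are recency-smoothed:
    ``w * current + (1 - w) * previous``.
    """

    state_vectors: dict[int, np.ndarray]
    smoothing_weight: float = 0.7
    dim: int = 32

    def __post_init__(self):
        if not 0 < self.smoothing_weight <= 1:
            raise ValueError("smoothing_weight must be in (0, 1]")

    @classmethod
    def sample(cls, dim: int = 32, smoothing_weight: float = 0.7,
               rng: np.random.Generator | None = None) -> "SchemaTask":
        rng = np.random.default_rng(0) if rng is None else rng
        vecs = {i: rng.standard_normal(dim) for i in range(1, 9)}
        return cls(state_vectors=vecs, smoothing_weight=smoothing_weight, dim=dim)

    def paths(self, context: int):
        return _PATHS[context]

    def successor(self, context: int, state: int) -> int | None:
        return _SUCCESSORS[context].get(state)


@dataclass
class SchemaTrial:
    """One trial: CIS opening state followed by a three-state walk.

    ``inputs[j]`` is the smoothed observation at step j; ``targets[j]`` is
    the raw vector of the next state (j = 0..2); ``foil_ids[j]`` is the
    state that would follow under the other context (None where the
    transition is not a schema-discriminating choice);
    ``inference_enabled[j]`` is False at the inherently unpredictable
    CIS-to-first-state transition.
    """

    context: int
    states: list[int]                # 4 raw state ids, states[0] is the CIS state
    inputs: np.ndarray               # (4, dim) smoothed observations
    targets: np.ndarray              # (3, dim) next-state vectors
    foil_ids: list[int | None]       # length 3, aligned with targets
    inference_enabled: np.ndarray    # (4,) bool


def sample_schema_trial(
    task: SchemaTask,
    context: int,
    rng: np.random.Generator,
    prev_obs: np.ndarray | None = None,
) -> SchemaTrial:
    """Draw one trial in the given context (uniform over its two walks).

    ``prev_obs`` is the last observation of the preceding trial, used to
    smooth the opening CIS input; zeros for the first trial.
    """
    if context not in (1, 2):
        raise ValueError(f"context must be 1 or 2, got {context}")
    w = task.smoothing_weight
    path = list(_PATHS[context][int(rng.integers(2))])
    states = [CIS_STATE[context], *path]
    prev = np.zeros(task.dim) if prev_obs is None else np.asarray(prev_obs)
    inputs = np.empty((4, task.dim))
    for j, s in enumerate(states):
        cur = task.state_vectors[s]
        inputs[j] = w * cur + (1 - w) * prev
        prev = inputs[j]
    targets = np.stack([task.state_vectors[s] for s in states[1:]])
    other = 2 if context == 1 else 1
    foil_ids: list[int | None] = [None]
    for s in states[1:3]:
        foil_ids.append(task.successor(other, s))
    # Full Bayesian inference fires once per event, at the CIS opening
    # state that announces it; the context cannot change mid-trial, so the
    # within-trial steps (including the inherently unpredictable CIS->s1/2
    # transition) carry the committed LC.
    enabled = np.array([True, False, False, False])
    return SchemaTrial(
        context=context, states=states, inputs=inputs, targets=targets,
        foil_ids=foil_ids, inference_enabled=enabled,
    )


@dataclass
class CurriculumSchedule:
    """Per-trial phase labels and context ids for one condition."""

    condition: str                   # "blocked" | "interleaved"
    phases: list[str]                # "train" | "test" per trial
    contexts: list[int]

    @property
    def n_trials(self) -> int:
        return len(self.phases)


def make_curriculum(
    condition: str, n_train: int, n_test: int, rng: np.random.Generator
) -> CurriculumSchedule:
    """Blocked (all context 1, then all context 2) or strictly alternating
    interleaved training, followed by uniformly random test contexts."""
    if condition not in ("blocked", "interleaved"):
        raise ValueError(f"unknown condition {condition!r}")
    if n_train % 2 != 0:
        raise ValueError(f"n_train must be even, got {n_train}")
    if condition == "blocked":
        train = [1] * (n_train // 2) + [2] * (n_train // 2)
    else:
        train = [1 if i % 2 == 0 else 2 for i in range(n_train)]
    test = [int(rng.integers(1, 3)) for _ in range(n_test)]
    return CurriculumSchedule(
        condition=condition,
        phases=["train"] * n_train + ["test"] * n_test,
        contexts=train + test,
    )


# ---------------------------------------------------------------- Sim 3

@dataclass
class SyntheticEventCorpus:
    """Synthetic stand-in for an annotated naturalistic video corpus.

    Each "video" is a (T, frame_dim) float matrix whose frames are emitted
    by per-class linear dynamical generators; the active class evolves by
    a sticky Markov chain.  ``subject_boundary_prob`` pools simulated
    annotators who press near each true boundary with timing jitter.
    """

    videos: list[np.ndarray]
    event_labels: list[np.ndarray]
    boundary_truth: list[np.ndarray]
    subject_boundary_prob: list[np.ndarray]
    params: dict = field(default_factory=dict)

    @property
    def n_videos(self) -> int:
        return len(self.videos)

    def save(self, outdir) -> None:
        """Write frames, a tidy annotation table, and a JSON manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = []
        for v, (frames, labels, bnd, prob) in enumerate(
            zip(self.videos, self.event_labels, self.boundary_truth, self.subject_boundary_prob)
        ):
            np.savetxt(outdir / f"video_{v:03d}.csv", frames, delimiter=",")
            for t in range(len(labels)):
                rows.append((v, t, int(labels[t]), int(bnd[t]), float(prob[t])))
        import pandas as pd

        pd.DataFrame(rows, columns=["video_id", "t", "label", "boundary", "subject_prob"]).to_csv(
            outdir / "annotations.csv", index=False
        )
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.params, fh, indent=2)


def _stable_matrix(dim: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    A = rng.standard_normal((dim, dim)) / np.sqrt(dim)
    eig = np.max(np.abs(np.linalg.eigvals(A)))
    return A * (radius / eig)


def generate_event_corpus(
    n_videos: int = 4,
    n_classes: int = 12,
    frames_per_video: int = 500,
    frame_dim: int = 30,
    persistence: float = 0.99,
    obs_noise: float = 0.1,
    n_subjects: int = 20,
    rng: np.random.Generator | None = None,
    jitter: int = 2,
    spectral_radius: float = 0.7,
    drift_scale: float = 1.0,
) -> SyntheticEventCorpus:
    """Generate a corpus of event streams with ground truth and annotations.

    Event classes are temporally persistent (stay probability
    ``persistence``, so mean event length 1/(1-persistence) frames).  Each
    class k owns a stable state-update matrix A_k (spectral radius < 1)
    and a drift d_k; within an event the latent state follows
    ``s_t = A_k s_{t-1} + d_k`` and frames are ``s_t`` plus Gaussian
    observation noise.  Each simulated annotator presses once per true
    boundary, jittered uniformly within ±``jitter`` frames.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if not 0 < persistence < 1:
        raise ValueError(f"persistence must be in (0, 1), got {persistence}")
    rng = np.random.default_rng(0) if rng is None else rng
    A = [_stable_matrix(frame_dim, spectral_radius, rng) for _ in range(n_classes)]
    d = [drift_scale * rng.standard_normal(frame_dim) for _ in range(n_classes)]

    videos, labels_all, bounds_all, probs_all = [], [], [], []
    for _ in range(n_videos):
        labels = np.empty(frames_per_video, dtype=int)
        labels[0] = rng.integers(n_classes)
        for t in range(1, frames_per_video):
            if rng.random() < persistence:
                labels[t] = labels[t - 1]
            else:
                choices = [k for k in range(n_classes) if k != labels[t - 1]]
                labels[t] = choices[rng.integers(len(choices))]
        boundaries = np.zeros(frames_per_video, dtype=int)
        boundaries[1:] = (labels[1:] != labels[:-1]).astype(int)

        s = rng.standard_normal(frame_dim)
        frames = np.empty((frames_per_video, frame_dim))
        for t in range(frames_per_video):
            k = labels[t]
            s = A[k] @ s + d[k]
            frames[t] = s + obs_noise * rng.standard_normal(frame_dim)

        presses = np.zeros(frames_per_video)
        bt = np.flatnonzero(boundaries)
        for _ in range(n_subjects):
            pressed = np.zeros(frames_per_video, dtype=bool)  # at most one press/frame
            for t in bt:
                off = int(rng.integers(-jitter, jitter + 1)) if jitter > 0 else 0
                pressed[np.clip(t + off, 0, frames_per_video - 1)] = True
            presses += pressed
        probs = presses / n_subjects

        videos.append(frames)
        labels_all.append(labels)
        bounds_all.append(boundaries)
        probs_all.append(probs)

    params = dict(
        n_videos=n_videos, n_classes=n_classes, frames_per_video=frames_per_video,
        frame_dim=frame_dim, persistence=persistence, obs_noise=obs_noise,
        n_subjects=n_subjects, jitter=jitter, spectral_radius=spectral_radius,
        drift_scale=drift_scale,
    )
    return SyntheticEventCorpus(videos, labels_all, bounds_all, probs_all, params)
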