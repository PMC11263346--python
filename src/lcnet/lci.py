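"""Latent cause inference: sticky-CRP prior, loss-based likelihood, local MAP.

A latent cause (LC) is a hidden context assumed to generate a contiguous
stretch of observations.  Each LC is indexed by a fixed random context
vector drawn from a standard Gaussian; the inference engine decides, one
observation at a time, whether the current observation is best explained
by a known LC or by opening a new one.

The prior over the next LC assignment is the sticky Chinese Restaurant
Process (sCRP): an existing LC ``k`` receives unnormalized mass
``count_k + stickiness * I[prev == k]`` and a new LC receives mass
``alpha``.  The likelihood of LC ``k`` is ``softmax(-loss / temperature)``
where ``loss_k`` is the mean squared error of the predictive model, run
with context vector ``c_k``, at predicting the current observation from
the previous one.  The posterior is prior x likelihood (local MAP: the
argmax is committed to, no assignment history is maintained).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import log_softmax, logsumexp

__all__ = [
    "SCRPParams",
    "LatentCauseRegistry",
    "PosteriorTrace",
    "sample_context_vector",
    "scrp_prior",
    "lc_likelihoods",
    "lc_posterior_map",
    "update_registry",
    "infer_step",
    "traces_to_frame",
]


@dataclass(frozen=True)
class SCRPParams:
    """Sticky-CRP hyperparameters.

    alpha : concentration; unnormalized mass on opening a new LC.
    stickiness : bonus mass on the immediately preceding LC (temporal
        persistence of contexts).
    """

    alpha: float = 0.5
    stickiness: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.stickiness < 0:
            raise ValueError(f"stickiness must be >= 0, got {self.stickiness}")


def sample_context_vector(dim: int, rng: np.random.Generator) -> np.ndarray:
    """Draw a context vector of i.i.d. standard-normal entries."""
    if dim < 1:
        raise ValueError(f"dim must be >= 1, got {dim}")
    return rng.standard_normal(dim)


class LatentCauseRegistry:
    """The growing set of LC context vectors and their bookkeeping.

    Holds one fixed context vector per inferred LC, the per-LC observation
    counts used by the sCRP prior, the previously active LC, and one
    preallocated candidate vector used to score the not-yet-created LC.
    On spawn the candidate is adopted verbatim as the new LC's vector and
    a fresh candidate is drawn; vectors never change after creation.
    """

    def __init__(self, dim: int, rng: np.random.Generator, unit_norm: bool = False):
        """``unit_norm`` rescales each sampled vector to unit length (a
        random direction; high-dimensional draws remain near-orthogonal).
        This balances the learning speed of the context-to-hidden pathway
        against low-dimensional observation inputs."""
        if dim < 1:
            raise ValueError(f"dim must be >= 1, got {dim}")
        self.dim = int(dim)
        self.unit_norm = bool(unit_norm)
        self.context_vectors: list[np.ndarray] = []
        self.counts: list[int] = []
        self.prev_lc: int | None = None
        self.candidate_vector = self._draw(rng)

    def _draw(self, rng: np.random.Generator) -> np.ndarray:
        v = sample_context_vector(self.dim, rng)
        return v / np.linalg.norm(v) if self.unit_norm else v

    @property
    def K(self) -> int:
        return len(self.context_vectors)

    def all_vectors(self) -> list[np.ndarray]:
        """Existing context vectors followed by the candidate (length K+1)."""
        return [*self.context_vectors, self.candidate_vector]

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"LatentCauseRegistry(K={self.K}, dim={self.dim}, "
            f"counts={self.counts}, prev_lc={self.prev_lc})"
        )


@dataclass
class PosteriorTrace:
    """Record of one inference step.

    ``prior``, ``likelihood`` and ``posterior`` have length K+1 (existing
    LCs then the new-LC slot).  ``map_lc`` is the committed assignment
    (0-based); ``spawned_new`` is true when the new-LC slot won.  On
    inference-disabled steps only ``map_lc`` and ``losses`` are filled and
    ``inference_enabled`` is False.
    """

    t: int
    map_lc: int
    spawned_new: bool
    losses: np.ndarray | None = None
    prior: np.ndarray | None = None
    likelihood: np.ndarray | None = None
    posterior: np.ndarray | None = None
    inference_enabled: bool = True
    K_after: int = 0


def scrp_prior(registry: LatentCauseRegistry, params: SCRPParams) -> np.ndarray:
    """sCRP prior over the K existing LCs plus the new-LC slot.

    Entry k < K is proportional to ``count_k + stickiness * I[prev == k]``;
    entry K is proportional to ``alpha``.
    """
    K = registry.K
    mass = np.empty(K + 1)
    mass[:K] = registry.counts
    if registry.prev_lc is not None:
        mass[registry.prev_lc] += params.stickiness
    mass[K] = params.alpha
    total = mass.sum()
    if total <= 0:
        raise ValueError("degenerate sCRP prior: no unnormalized mass (K=0 and alpha=0)")
    return mass / total


def lc_likelihoods(
    predict_fn,
    registry: LatentCauseRegistry,
    x_prev: np.ndarray,
    x_curr: np.ndarray,
    temperature: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Softmax(-MSE/temperature) likelihood over the K+1 LC slots.

    ``predict_fn(x_prev, c)`` maps the previous observation and a context
    vector to a predicted current observation; ``loss_k`` is the mean
    squared error of that prediction against ``x_curr``.  The new-LC slot
    is scored with the registry's preallocated candidate vector.  Computed
    in log space; returns (likelihood, losses).
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0, got {temperature}")
    x_curr = np.asarray(x_curr, dtype=float)
    losses = np.empty(registry.K + 1)
    for k, c in enumerate(registry.all_vectors()):
        pred = np.asarray(predict_fn(x_prev, c), dtype=float)
        if pred.shape != x_curr.shape:
            raise ValueError(
                f"predict_fn returned shape {pred.shape}, expected {x_curr.shape}"
            )
        losses[k] = np.mean((pred - x_curr) ** 2)
    if not np.all(np.isfinite(losses)):
        raise FloatingPointError(f"non-finite prediction losses: {losses}")
    lik = np.exp(log_softmax(-losses / temperature))
    return lik, losses


def lc_posterior_map(prior: np.ndarray, likelihood: np.ndarray) -> tuple[np.ndarray, int]:
    """Posterior ∝ prior ⊙ likelihood; returns (posterior, argmax index).

    Computed in log space; ties in the argmax break toward the lowest
    index (favoring older LCs).  Entries with zero prior mass keep zero
    posterior mass.
    """
    prior = np.asarray(prior, dtype=float)
    likelihood = np.asarray(likelihood, dtype=float)
    if prior.shape != likelihood.shape:
        raise ValueError("prior and likelihood must have the same length")
    with np.errstate(divide="ignore"):
        log_post = np.log(prior) + np.log(likelihood)
    if np.all(np.isneginf(log_post)):
        raise FloatingPointError("zero total posterior mass (prior and likelihood disjoint)")
    posterior = np.exp(log_post - logsumexp(log_post))
    posterior /= posterior.sum()
    return posterior, int(np.argmax(posterior))


def update_registry(
    registry: LatentCauseRegistry, map_lc: int, rng: np.random.Generator
) -> LatentCauseRegistry:
    """Commit an assignment: bump its count, set prev_lc, spawn if new.

    ``map_lc == K`` adopts the candidate vector as LC K and draws a fresh
    candidate.  Mutates and returns the registry.
    """
    K = registry.K
    if not 0 <= map_lc <= K:
        raise ValueError(f"map_lc {map_lc} out of range for K={K}")
    if map_lc == K:
        registry.context_vectors.append(registry.candidate_vector)
        registry.counts.append(0)
        registry.candidate_vector = registry._draw(rng)
    registry.counts[map_lc] += 1
    registry.prev_lc = map_lc
    return registry


def infer_step(
    predict_fn,
    registry: LatentCauseRegistry,
    params: SCRPParams,
    x_prev: np.ndarray,
    x_curr: np.ndarray,
    rng: np.random.Generator,
    t: int = 0,
    inference_enabled: bool = True,
    temperature: float = 1.0,
) -> PosteriorTrace:
    """One full inference step: prior x likelihood -> MAP -> registry update.

    When ``inference_enabled`` is False the previously active LC is carried
    forward without computing a posterior (used at transitions the learner
    knows to be unpredictable); its count is still incremented, since the
    observation is still explained by that LC.
    """
    if not inference_enabled:
        if registry.prev_lc is None:
            raise RuntimeError("inference-disabled step requires an active previous LC")
        carried = registry.prev_lc
        update_registry(registry, carried, rng)
        return PosteriorTrace(
            t=t, map_lc=carried, spawned_new=False,
            inference_enabled=False, K_after=registry.K,
        )
    prior = scrp_prior(registry, params)
    likelihood, losses = lc_likelihoods(predict_fn, registry, x_prev, x_curr, temperature)
    posterior, map_lc = lc_posterior_map(prior, likelihood)
    spawned = map_lc == registry.K
    update_registry(registry, map_lc, rng)
    return PosteriorTrace(
        t=t, map_lc=map_lc, spawned_new=spawned, losses=losses,
        prior=prior, likelihood=likelihood, posterior=posterior,
        K_after=registry.K,
    )


def traces_to_frame(traces: list[PosteriorTrace]) -> pd.DataFrame:
    """Tidy table of an inference trajectory (posterior as a JSON string)."""
    rows = []
    for tr in traces:
        rows.append(
            {
                "t": tr.t,
                "map_lc": tr.map_lc,
                "spawned_new": tr.spawned_new,
                "K": tr.K_after,
                "inference_enabled": tr.inference_enabled,
                "posterior": json.dumps(
                    None if tr.posterior is None else [round(p, 12) for p in tr.posterior]
                ),
            }
        )
    return pd.DataFrame(rows)
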