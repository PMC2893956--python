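"""Monte Carlo expectations for run-length distributions under deletion models.

The null mechanism deletes blocks of m consecutive genes (m drawn from a
length mixture over 1..5 genes) at uniformly random positions of the
re-ligated chromosome until the observed number of deletions is reached.
Because the chromosome is ligated after every event, independent events can
land next to each other and *apparent* runs in the original gene order are
often longer than any single event.  The published comparison plots the
observed run histogram against the median and 95% envelope of 1,000 such
replicates; this module reproduces that machinery.

The retained-run variant simulates both homeologs at once with a deletion
bias and the mutual-exclusion constraint: once a gene is lost from one
homeolog, its ortholog on the other homeolog is never deleted (losing both
copies of an essential gene is lethal, so such events are purged).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import _engine
from .run_analysis import RunDistribution

__all__ = [
    "DeletionMixture",
    "SimulationEnvelope",
    "SINGLE_GENE",
    "BEST_FIT_MIXTURE",
    "simulate_deletion_runs",
    "simulate_retained_runs",
    "compare_to_envelope",
]

MAX_DELETION_LENGTH = 5
DEFAULT_REPLICATES = 1000


@dataclass(frozen=True)
class DeletionMixture:
    """Probability weights over deletion lengths (in genes, 1..5)."""

    weights: Mapping[int, float]

    def __post_init__(self) -> None:
        w = dict(self.weights)
        if not w:
            raise ValueError("empty deletion mixture")
        if any(not (1 <= k <= MAX_DELETION_LENGTH) for k in w):
            raise ValueError(f"deletion lengths must be in 1..{MAX_DELETION_LENGTH}")
        if any(v < 0 for v in w.values()):
            raise ValueError("mixture weights must be non-negative")
        total = sum(w.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1 (got {total})")
        object.__setattr__(self, "weights", w)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(lengths, cumulative weights) sorted by length, for the sampler."""
        items = sorted((k, v) for k, v in self.weights.items() if v > 0)
        lengths = np.array([k for k, _ in items], dtype=np.int64)
        cdf = np.cumsum([v for _, v in items])
        cdf[-1] = 1.0  # guard against float round-off
        return lengths, cdf

    @property
    def mean_length(self) -> float:
        return sum(k * v for k, v in self.weights.items())


#: One-gene-at-a-time null mechanism.
SINGLE_GENE = DeletionMixture({1: 1.0})
#: The best-fit mechanism for the over-fractionated maize homeolog:
#: 80% single-gene, 15% two-gene, 5% three-gene deletions.
BEST_FIT_MIXTURE = DeletionMixture({1: 0.80, 2: 0.15, 3: 0.05})


@dataclass(frozen=True)
class SimulationEnvelope:
    """Per-run-length median and 95% interval over Monte Carlo replicates."""

    kind: str
    medians: dict[int, float]
    lower: dict[int, int]
    upper: dict[int, int]
    replicates: int
    seed: int
    counts: np.ndarray = field(repr=False, compare=False, default=None)  # (reps, maxlen+1)

    def __post_init__(self) -> None:
        for length in self.medians:
            if not (self.lower[length] <= self.medians[length] <= self.upper[length]):
                raise AssertionError("envelope ordering violated")

    def lengths(self) -> list[int]:
        return sorted(self.medians)

    def mean_counts(self) -> dict[int, float]:
        """Replicate-mean run count per length (used by enumeration oracles)."""
        means = self.counts.mean(axis=0)
        return {i: float(means[i]) for i in range(1, means.shape[0]) if means[i] > 0}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "length": self.lengths(),
                "median": [self.medians[k] for k in self.lengths()],
                "lo95": [self.lower[k] for k in self.lengths()],
                "hi95": [self.upper[k] for k in self.lengths()],
            }
        )


def _replicate_seeds(seed: int, replicates: int) -> np.ndarray:
    ss = np.random.SeedSequence(seed)
    return (ss.generate_state(replicates).astype(np.int64)) & 0x7FFFFFFF


def _summarize(counts: np.ndarray, kind: str, seed: int) -> SimulationEnvelope:
    reps = counts.shape[0]
    # nearest-rank 2.5th / 97.5th percentiles on sorted replicate counts
    lo_idx = max(ceil(0.025 * reps) - 1, 0)
    hi_idx = max(ceil(0.975 * reps) - 1, 0)
    nonzero = np.flatnonzero(counts.any(axis=0))
    nonzero = nonzero[nonzero >= 1]
    medians, lower, upper = {}, {}, {}
    for length in nonzero:
        col = np.sort(counts[:, length])
        medians[int(length)] = float(np.median(col))
        lower[int(length)] = int(col[lo_idx])
        upper[int(length)] = int(col[hi_idx])
    maxlen = int(nonzero.max()) if nonzero.size else 0
    return SimulationEnvelope(
        kind=kind,
        medians=medians,
        lower=lower,
        upper=upper,
        replicates=reps,
        seed=seed,
        counts=counts[:, : maxlen + 1].copy(),
    )


def simulate_deletion_runs(
    n_genes: int,
    n_deleted: int,
    mixture: DeletionMixture = SINGLE_GENE,
    replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
    kind: str = "deleted_over",
) -> SimulationEnvelope:
    """Envelope of apparent deletion-run counts under the ligated-deletion model.

    Each replicate deletes blocks (lengths from *mixture*, uniform start
    among survivors, truncated at the array end, final event trimmed) until
    exactly ``n_deleted`` genes are gone, then tallies maximal runs of
    deleted genes in the original gene order.
    """
    if not (0 < n_deleted <= n_genes):
        raise ValueError("need 0 < n_deleted <= n_genes")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    lengths, cdf = mixture.arrays()
    seeds = _replicate_seeds(seed, replicates)
    counts = _engine.deletion_replicates(n_genes, n_deleted, lengths, cdf, seeds)
    return _summarize(counts, kind, seed)


def simulate_retained_runs(
    n_genes: int,
    n_retained_target: int,
    bias: float,
    replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
    mixture: Optional[DeletionMixture] = None,
) -> SimulationEnvelope:
    """Envelope of both-retained run counts under biased two-copy deletion.

    Each replicate deletes genes from one or the other homeolog (homeolog 1
    with probability *bias*) under mutual exclusion until the number of
    genes retained on both copies equals the target.  Multi-gene deletions
    (optional *mixture*) span consecutive genes in the hit copy's ligated
    coordinates, skipping genes protected by the constraint.
    """
    if not (0 < n_retained_target <= n_genes):
        raise ValueError("retained target unreachable: need 0 < target <= n_genes")
    if not (0 < bias < 1):
        raise ValueError("bias must be strictly between 0 and 1")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    lengths, cdf = (mixture or SINGLE_GENE).arrays()
    seeds = _replicate_seeds(seed, replicates)
    counts = _engine.two_copy_replicates(
        n_genes, n_retained_target, bias, lengths, cdf, seeds
    )
    return _summarize(counts, "retained", seed)


def compare_to_envelope(
    observed: RunDistribution, envelope: SimulationEnvelope
) -> pd.DataFrame:
    """Per run length: observed count vs simulated median and 95% interval.

    ``outside`` flags lengths whose observed count falls outside the
    envelope (lengths absent from one side count as 0 there).
    """
    obs_family = "retained" if observed.kind == "retained" else "deleted"
    env_family = "retained" if envelope.kind == "retained" else "deleted"
    if obs_family != env_family:
        raise ValueError(
            f"run kinds disagree: observed {observed.kind!r} vs envelope {envelope.kind!r}"
        )
    lengths = sorted(set(observed.counts) | set(envelope.medians))
    rows = []
    for length in lengths:
        obs = observed.counts.get(length, 0)
        med = envelope.medians.get(length, 0.0)
        lo = envelope.lower.get(length, 0)
        hi = envelope.upper.get(length, 0)
        rows.append(
            {
                "length": length,
                "observed": obs,
                "median": med,
                "lo95": lo,
                "hi95": hi,
                "outside": not (lo <= obs <= hi),
            }
        )
    return pd.DataFrame(rows)
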