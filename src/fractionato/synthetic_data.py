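"""Synthetic fractionation data with known ground truth.

Two generators, matching the two observable layers of the pipeline:

* :func:`generate_region` — a gene-level region fractionated by biased,
  mutually exclusive deletion events with a deletion-length mixture.  It
  runs the exact same compiled event engine as the Monte Carlo simulators
  (one source of truth), records the full event log, and emits the
  resulting retention code string.  Defaults are the study conditions: a
  2.3:1 deletion bias (events hit homeolog 1 with probability 0.70), 57%
  of genes losing one copy (43% retained as pairs), and the 80/15/5
  one/two/three-gene length mixture.

* :func:`generate_sequence_pair` — a nucleotide precursor/product pair in
  which the deleted segment was flanked by a planted direct repeat,
  leaving one copy behind (the illegitimate-recombination footprint).
  Accidental junction matches that would lengthen the apparent repeat are
  rejected during construction, so the planted repeat length is exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _engine
from .fractionation_sim import BEST_FIT_MIXTURE, DeletionMixture
from .region_io import GeneRecord, RegionCode

__all__ = [
    "SyntheticRegionTruth",
    "SyntheticPairTruth",
    "generate_region",
    "generate_sequence_pair",
]

_STATE_TO_CODE = {
    _engine.BOTH_RETAINED: "B",
    _engine.DELETED_ON_H1: "2",  # survives only on homeolog 2
    _engine.DELETED_ON_H2: "1",
}


@dataclass(frozen=True)
class SyntheticRegionTruth:
    """Ground truth for one generated region.

    ``events`` is the ordered log of deletion events as (homeolog, start
    position in original coordinates, genes spanned on that homeolog,
    genes actually removed) tuples; replaying it on the all-retained state
    reproduces the emitted code exactly.
    """

    n_genes: int
    bias: float
    mixture: DeletionMixture
    deletion_fraction: float
    seed: int
    events: tuple[tuple[int, int, int, int], ...]
    codes: str

    @property
    def n_events(self) -> int:
        return len(self.events)

    def replay(self) -> str:
        """Re-derive the code string from the event log (determinism check)."""
        state = [0] * self.n_genes
        for copy, start, span, removed in self.events:
            spanned = 0
            done = 0
            q = start
            while q < self.n_genes and spanned < span:
                if state[q] == copy:
                    q += 1
                    continue
                spanned += 1
                if state[q] == 0 and done < removed:
                    state[q] = copy
                    done += 1
                q += 1
        return "".join(_STATE_TO_CODE[s] for s in state)


def generate_region(
    n_genes: int = 2943,
    bias: float = 0.70,
    mixture: DeletionMixture = BEST_FIT_MIXTURE,
    deletion_fraction: float = 0.57,
    seed: int = 0,
    region_id: str = "synthetic",
) -> tuple[RegionCode, SyntheticRegionTruth]:
    """Generate one fractionated region with known ground truth.

    Starts from an all-``B`` array and applies ligated-coordinate deletion
    events — homeolog 1 hit with probability *bias*, lengths drawn from
    *mixture*, a gene already lost on one homeolog never deleted on the
    other — until ``deletion_fraction`` of the genes have lost one copy.
    """
    if not (0 <= deletion_fraction < 1):
        raise ValueError("deletion_fraction must be in [0, 1)")
    if not (0 < bias < 1):
        raise ValueError("bias must be strictly between 0 and 1")
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    target_both = n_genes - int(round(deletion_fraction * n_genes))
    if target_both < 1:
        raise ValueError("infeasible deletion_fraction: no gene would remain retained")
    lengths, cdf = mixture.arrays()
    state, n_events, ev_copy, ev_start, ev_span, ev_removed = _engine.two_copy_generate(
        n_genes, target_both, bias, lengths, cdf, seed & 0x7FFFFFFF
    )
    codes = "".join(_STATE_TO_CODE[int(s)] for s in state)
    events = tuple(
        (int(ev_copy[i]), int(ev_start[i]), int(ev_span[i]), int(ev_removed[i]))
        for i in range(n_events)
    )
    genes = tuple(
        GeneRecord(gene_id=f"{region_id}_g{i:05d}", position=i, code=c)
        for i, c in enumerate(codes)
    )
    region = RegionCode(region_id=region_id, genes=genes)
    truth = SyntheticRegionTruth(
        n_genes=n_genes,
        bias=bias,
        mixture=mixture,
        deletion_fraction=deletion_fraction,
        seed=seed,
        events=events,
        codes=codes,
    )
    assert truth.replay() == codes, "event-log replay failed to reproduce the region"
    return region, truth


@dataclass(frozen=True)
class SyntheticPairTruth:
    """Ground truth for one precursor/product sequence pair."""

    flank_a: str
    flank_b: str
    insert: str
    repeat: str
    seed: int

    @property
    def precursor(self) -> str:
        return self.flank_a + self.repeat + self.insert + self.repeat + self.flank_b

    @property
    def product(self) -> str:
        return self.flank_a + self.repeat + self.flank_b

    @property
    def gap_size(self) -> int:
        return len(self.insert) + len(self.repeat)


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def generate_sequence_pair(
    flank_len: int = 200,
    insert_len: int = 20,
    repeat_len: int = 8,
    seed: int = 0,
    gc: float = 0.5,
    max_tries: int = 100,
) -> tuple[str, str, SyntheticPairTruth]:
    """Generate a deletion flanked by a planted direct repeat.

    Builds precursor ``A + R + X + R + B`` and product ``A + R + B`` from
    random flanks A/B, insert X and repeat R of exactly ``repeat_len`` bp.
    The apparent repeat would exceed the planted one iff the first insert
    base equals the first base of B, or the last insert base equals the
    last base of A; such draws are rejected (up to ``max_tries`` insert
    resamples) so the ground-truth repeat length is exact.
    """
    if repeat_len < 0 or insert_len < 1 or flank_len < 1:
        raise ValueError("need repeat_len >= 0, insert_len >= 1, flank_len >= 1")
    rng = np.random.default_rng(seed)
    a = _random_seq(rng, flank_len, gc)
    b = _random_seq(rng, flank_len, gc)
    repeat = _random_seq(rng, repeat_len, gc)
    for _ in range(max_tries):
        insert = _random_seq(rng, insert_len, gc)
        if insert[0] != b[0] and insert[-1] != a[-1]:
            break
    else:
        raise RuntimeError(
            f"could not avoid accidental junction repeats in {max_tries} tries"
        )
    truth = SyntheticPairTruth(
        flank_a=a, flank_b=b, insert=insert, repeat=repeat, seed=seed
    )
    return truth.precursor, truth.product, truth
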