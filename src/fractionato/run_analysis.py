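"""Maximal-run length distributions from reduced code strings.

A *run* is a maximal stretch of consecutive outgroup genes with the same
fate: all deleted from one homeolog (consecutive ``1``s or ``2``s) or all
retained on both (consecutive ``B``s).  The run-length histogram is the
observable the deletion-length model is fitted against: single-gene
deletion mechanisms still produce apparent multi-gene runs whenever
independent events land next to each other.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from .bias_stats import DELETION_SYMBOL_FOR_HOMEOLOG
from .region_io import RegionCode

__all__ = ["RunDistribution", "deletion_runs", "retained_runs", "pool_runs", "runs_of"]

RUN_KINDS = {"deleted_on_h1", "deleted_on_h2", "deleted_over", "deleted_under", "retained"}


@dataclass(frozen=True)
class RunDistribution:
    """Histogram of maximal run lengths: ``counts[length] = number of runs``."""

    kind: str
    counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in RUN_KINDS:
            raise ValueError(f"unknown run kind {self.kind!r}")
        if any(length < 1 or n < 0 for length, n in self.counts.items()):
            raise ValueError("run lengths must be >= 1 and counts >= 0")

    @property
    def total_genes(self) -> int:
        """Sum of length x count — the number of genes covered by the runs."""
        return sum(length * n for length, n in self.counts.items())

    @property
    def total_runs(self) -> int:
        return sum(self.counts.values())


def runs_of(code: str, symbol: str) -> Counter[int]:
    """Lengths of maximal runs of *symbol* in *code* (any other symbol breaks a run)."""
    runs: Counter[int] = Counter()
    n = 0
    for ch in code:
        if ch == symbol:
            n += 1
        elif n:
            runs[n] += 1
            n = 0
    if n:
        runs[n] += 1
    return runs


def deletion_runs(region: RegionCode, homeolog: int) -> RunDistribution:
    """Runs of genes deleted from the chosen homeolog (1 or 2).

    A deletion on homeolog 1 is marked by symbol ``2`` (the gene survives
    only on homeolog 2), so runs for homeolog 1 scan for ``2``s.
    """
    if not region.reduced:
        raise ValueError("deletion_runs requires a reduced region")
    if homeolog not in (1, 2):
        raise ValueError("homeolog must be 1 or 2")
    symbol = DELETION_SYMBOL_FOR_HOMEOLOG[homeolog]
    counts = runs_of(region.code_string, symbol)
    return RunDistribution(kind=f"deleted_on_h{homeolog}", counts=dict(counts))


def retained_runs(region: RegionCode) -> RunDistribution:
    """Runs of genes retained on both homeologs (``B``); any deletion breaks a run."""
    if not region.reduced:
        raise ValueError("retained_runs requires a reduced region")
    counts = runs_of(region.code_string, "B")
    return RunDistribution(kind="retained", counts=dict(counts))


def pool_runs(distributions: Iterable[RunDistribution], kind: str | None = None) -> RunDistribution:
    """Element-wise sum of same-kind run histograms (regions are independent;
    runs never span region boundaries)."""
    dists = list(distributions)
    if not dists:
        return RunDistribution(kind=kind or "retained", counts={})
    kinds = {d.kind for d in dists}
    if len(kinds) > 1:
        raise ValueError(f"cannot pool mixed run kinds: {sorted(kinds)}")
    if kind is not None and kinds != {kind}:
        raise ValueError(f"expected kind {kind!r}, got {kinds.pop()!r}")
    total: Counter[int] = Counter()
    for d in dists:
        total.update(d.counts)
    return RunDistribution(kind=dists[0].kind, counts=dict(total))


def relabel(dist: RunDistribution, kind: str) -> RunDistribution:
    """Return the same histogram under another kind label (e.g. after
    assigning which homeolog is the over-fractionated one)."""
    return RunDistribution(kind=kind, counts=dict(dist.counts))
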