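"""Direct-repeat footprints of illegitimate recombination at deletion sites.

When a deletion is caused by intra-chromosomal recombination between two
short direct repeats, the excised circle carries one repeat copy and the
chromosome keeps a single (solo) copy.  Comparing the precursor sequence
(intact homeolog or outgroup-inferred ancestor) to the deleted product, the
solo repeat makes the deletion breakpoint ambiguous: the deleted interval
can be slid by exactly the repeat length and still explain the product.

That identity is how detection works here: the set of valid deletion start
offsets ``s`` (those with ``product == precursor[:s] + precursor[s+gap:]``)
always forms one contiguous range, and its width equals the length of the
flanking direct repeat.  This replaces visual alignment inspection with an
exact, alignment-free criterion.  Matching is exact; ``N`` never matches
anything, so unknown bases cannot create spurious repeats.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DeletionEvent",
    "FootprintReport",
    "infer_deletion_interval",
    "classify_footprint",
    "summarize_footprints",
    "split_by_anchors",
    "read_sequence_pairs",
]

VALID_BASES = frozenset("ACGTN")
DEFAULT_MIN_REPEAT = 3

FOOTPRINT = "direct-repeat footprint"
NO_FOOTPRINT = "none"


class NotSingleDeletionError(ValueError):
    """The product cannot be explained by one contiguous deletion."""


@dataclass(frozen=True)
class DeletionEvent:
    """One inferred deletion with its placement ambiguity.

    The deletion of ``gap_size`` bases may start at any offset in
    ``[placement_min, placement_max]`` (inclusive); the width of that range
    is the flanking direct-repeat length, and ``repeat`` is the repeat
    itself (precursor bases at ``placement_min..placement_min+repeat_length``).
    """

    precursor_id: str
    product_id: str
    gap_size: int
    placement_min: int
    placement_max: int
    repeat: str

    @property
    def repeat_length(self) -> int:
        return self.placement_max - self.placement_min

    def __post_init__(self) -> None:
        if self.gap_size < 1:
            raise ValueError("gap_size must be >= 1")
        if self.placement_min > self.placement_max:
            raise ValueError("placement_min must be <= placement_max")
        if len(self.repeat) != self.placement_max - self.placement_min:
            raise ValueError("repeat string length must equal placement range width")


def _clean(seq: str, label: str) -> str:
    s = seq.upper()
    bad = set(s) - VALID_BASES
    if bad:
        raise ValueError(f"{label}: invalid nucleotide characters {sorted(bad)}")
    return s


def _match(a: str, b: str) -> bool:
    # N is an unknown base: it never matches, not even another N.
    return a == b and a != "N"


def infer_deletion_interval(
    precursor: str, product: str, precursor_id: str = "precursor", product_id: str = "product"
) -> DeletionEvent:
    """Locate the single deletion turning *precursor* into *product*.

    Finds every start offset ``s`` such that removing
    ``precursor[s : s+gap]`` yields the product, verifies (by construction)
    that they form one contiguous range, and reports the range together
    with the implied flanking direct repeat.

    >>> ev = infer_deletion_interval("AACGATXXXXCGATTT".replace("X", "G"), "AACGATTT")
    >>> (ev.gap_size, ev.placement_min, ev.placement_max, ev.repeat)
    (8, 2, 6, 'CGAT')
    """
    pre = _clean(precursor, precursor_id)
    prod = _clean(product, product_id)
    gap = len(pre) - len(prod)
    if gap < 1:
        raise NotSingleDeletionError(
            f"precursor ({len(pre)} bp) is not longer than product ({len(prod)} bp)"
        )
    L = len(prod)
    # Longest matching prefix and suffix between precursor and product;
    # valid placements are exactly s in [L - suffix, prefix] (intersected
    # with [0, L]), hence always one contiguous range.
    prefix = 0
    while prefix < L and _match(pre[prefix], prod[prefix]):
        prefix += 1
    suffix = 0
    while suffix < L and _match(pre[len(pre) - 1 - suffix], prod[L - 1 - suffix]):
        suffix += 1
    s_min = max(L - suffix, 0)
    s_max = min(prefix, L)
    if s_min > s_max:
        raise NotSingleDeletionError(
            f"{product_id!r} is not {precursor_id!r} minus one contiguous deletion"
        )
    repeat = pre[s_min : s_max]
    return DeletionEvent(
        precursor_id=precursor_id,
        product_id=product_id,
        gap_size=gap,
        placement_min=s_min,
        placement_max=s_max,
        repeat=repeat,
    )


def classify_footprint(event: DeletionEvent, min_repeat_len: int = DEFAULT_MIN_REPEAT) -> str:
    """Label an event a direct-repeat footprint if its flanking repeat is
    at least ``min_repeat_len`` bp (default 3)."""
    return FOOTPRINT if event.repeat_length >= min_repeat_len else NO_FOOTPRINT


@dataclass(frozen=True)
class FootprintReport:
    """Summary over a set of deletion events."""

    events: tuple[DeletionEvent, ...]
    footprint_positive: int
    gap_min: int
    gap_max: int
    gap_mean: float
    min_repeat_len: int

    @property
    def n_events(self) -> int:
        return len(self.events)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "precursor_id": [e.precursor_id for e in self.events],
                "product_id": [e.product_id for e in self.events],
                "gap_size": [e.gap_size for e in self.events],
                "repeat": [e.repeat for e in self.events],
                "repeat_length": [e.repeat_length for e in self.events],
                "classification": [
                    classify_footprint(e, self.min_repeat_len) for e in self.events
                ],
            }
        )


def summarize_footprints(
    events: Sequence[DeletionEvent], min_repeat_len: int = DEFAULT_MIN_REPEAT
) -> FootprintReport:
    """Count footprint-positive events and summarize gap sizes."""
    if not events:
        raise ValueError("no deletion events to summarize")
    gaps = np.array([e.gap_size for e in events])
    positive = sum(
        1 for e in events if classify_footprint(e, min_repeat_len) == FOOTPRINT
    )
    return FootprintReport(
        events=tuple(events),
        footprint_positive=positive,
        gap_min=int(gaps.min()),
        gap_max=int(gaps.max()),
        gap_mean=float(gaps.mean()),
        min_repeat_len=min_repeat_len,
    )


def split_by_anchors(
    precursor: str,
    product: str,
    anchors: Sequence[tuple[tuple[int, int], tuple[int, int]]],
) -> list[tuple[str, str]]:
    """Split a multi-gap pair into one window pair per gap.

    ``anchors`` are ((precursor_start, precursor_end), (product_start,
    product_end)) half-open windows, one per gap, supplied by the caller
    from outgroup-anchored flanks.  Each returned pair isolates one gap for
    :func:`infer_deletion_interval`.
    """
    out = []
    for (ps, pe), (qs, qe) in anchors:
        if not (0 <= ps < pe <= len(precursor) and 0 <= qs < qe <= len(product)):
            raise ValueError("anchor window out of bounds")
        out.append((precursor[ps:pe], product[qs:qe]))
    return out


def read_sequence_pairs(path) -> list[tuple[str, str, str, str]]:
    """Read precursor/product pairs from FASTA.

    Records are matched by shared id stem with ``_precursor`` / ``_product``
    suffixes.  Returns (pair_id, precursor_seq, product_seq, source_id)
    tuples in file order of the precursor records.
    """
    from Bio import SeqIO

    pre: dict[str, str] = {}
    prod: dict[str, str] = {}
    order: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id.endswith("_precursor"):
            stem = rec.id[: -len("_precursor")]
            pre[stem] = str(rec.seq)
            order.append(stem)
        elif rec.id.endswith("_product"):
            prod[rec.id[: -len("_product")]] = str(rec.seq)
        else:
            raise ValueError(
                f"record {rec.id!r}: ids must end in _precursor or _product"
            )
    missing = set(pre) ^ set(prod)
    if missing:
        raise ValueError(f"unpaired sequence ids: {sorted(missing)}")
    return [(stem, pre[stem], prod[stem], stem) for stem in order]
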