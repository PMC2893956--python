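"""Compiled Monte Carlo kernels shared by the simulators and the synthetic
generator (single event engine, so simulated expectations and generated data
come from the same process).

Gene arrays are modelled as chromosomes that re-ligate after every deletion:
an event samples a length m from the deletion-length mixture, picks a
uniform start among *surviving* genes, and removes m consecutive survivors
(truncating at the array end; the final event is trimmed so the target
deletion count is hit exactly).  Apparent runs are then measured in the
ORIGINAL gene order, which is what makes independent events able to fuse
into longer apparent runs.

Survivors are indexed with a Fenwick (binary indexed) tree supporting
O(log n) rank->position selection, so a replicate costs O(events * log n).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "deletion_replicates",
    "two_copy_replicates",
    "BOTH_RETAINED",
    "DELETED_ON_H1",
    "DELETED_ON_H2",
]

# Per-gene states in the two-copy (homeolog) engine.
BOTH_RETAINED = 0
DELETED_ON_H1 = 1  # gene survives only on homeolog 2 -> code "2"
DELETED_ON_H2 = 2  # gene survives only on homeolog 1 -> code "1"


@njit(cache=True)
def _bit_build(n):
    """Fenwick tree over n positions, all initially alive (value 1)."""
    tree = np.zeros(n + 1, dtype=np.int64)
    for i in range(1, n + 1):
        tree[i] = i & (-i)
    return tree


@njit(cache=True)
def _bit_add(tree, i, delta):
    # i is 1-based
    n = tree.shape[0] - 1
    while i <= n:
        tree[i] += delta
        i += i & (-i)


@njit(cache=True)
def _bit_select(tree, k, log2n):
    """0-based position of the (k+1)-th alive element (k is a 0-based rank)."""
    pos = 0
    rem = k + 1
    pw = 1 << log2n
    n = tree.shape[0] - 1
    while pw > 0:
        npos = pos + pw
        if npos <= n and tree[npos] < rem:
            pos = npos
            rem -= tree[npos]
        pw >>= 1
    return pos  # pos is the count of elements strictly before; 0-based index


@njit(cache=True)
def _sample_length(lengths, cdf):
    u = np.random.random()
    for i in range(cdf.shape[0]):
        if u <= cdf[i]:
            return lengths[i]
    return lengths[cdf.shape[0] - 1]


@njit(cache=True)
def _count_runs(flags, match, out):
    """Accumulate maximal-run lengths of flags == match into out[length]."""
    n = flags.shape[0]
    run = 0
    for i in range(n):
        if flags[i] == match:
            run += 1
        elif run > 0:
            out[run] += 1
            run = 0
    if run > 0:
        out[run] += 1


@njit(cache=True)
def _deletion_replicate(n_genes, n_deleted, lengths, cdf, log2n, deleted, runs_out):
    """One ligated-coordinate deletion replicate; fills `deleted` flags and
    accumulates apparent run counts (original gene order) into runs_out."""
    tree = _bit_build(n_genes)
    n_alive = n_genes
    remaining = n_deleted
    for i in range(n_genes):
        deleted[i] = 0
    while remaining > 0:
        m = _sample_length(lengths, cdf)
        if m > remaining:
            m = remaining  # final event trimmed to hit the target exactly
        s = np.random.randint(0, n_alive)
        if s + m > n_alive:
            m = n_alive - s  # truncate at the array end
        for _ in range(m):
            pos = _bit_select(tree, s, log2n)  # rank s is always the next survivor
            deleted[pos] = 1
            _bit_add(tree, pos + 1, -1)
        n_alive -= m
        remaining -= m
    _count_runs(deleted, 1, runs_out)


@njit(cache=True)
def deletion_replicates(n_genes, n_deleted, lengths, cdf, seeds):
    """Run one deletion replicate per seed; returns (replicates, n_genes+1)
    matrix of apparent-run counts by length."""
    reps = seeds.shape[0]
    counts = np.zeros((reps, n_genes + 1), dtype=np.int64)
    deleted = np.zeros(n_genes, dtype=np.uint8)
    log2n = 0
    while (1 << (log2n + 1)) <= n_genes:
        log2n += 1
    for r in range(reps):
        np.random.seed(seeds[r])
        _deletion_replicate(n_genes, n_deleted, lengths, cdf, log2n, deleted, counts[r])
    return counts


@njit(cache=True)
def _two_copy_replicate(
    n_genes,
    target_both,
    bias,
    lengths,
    cdf,
    log2n,
    state,
    runs_out,
    ev_copy,
    ev_start,
    ev_span,
    ev_removed,
    record,
):
    """One two-copy replicate with the mutual-exclusion constraint.

    Events choose homeolog 1 with probability `bias`, start at a uniformly
    chosen both-retained gene, and span m consecutive genes in the chosen
    copy's ligated coordinates; genes protected by the constraint (already
    deleted on the other copy) are spanned but skipped.  Stops the moment
    the number of both-retained genes reaches `target_both` (final event
    trimmed).  Returns the number of events.
    """
    tree = _bit_build(n_genes)  # indexes both-retained genes
    for i in range(n_genes):
        state[i] = BOTH_RETAINED
    n_both = n_genes
    n_events = 0
    while n_both > target_both:
        m = _sample_length(lengths, cdf)
        k = np.random.randint(0, n_both)
        start = _bit_select(tree, k, log2n)
        copy = 1 if np.random.random() < bias else 2
        spanned = 0
        removed = 0
        q = start
        while q < n_genes and spanned < m and n_both > target_both:
            if state[q] == copy:
                q += 1  # already gone from this copy: not part of its chromosome
                continue
            spanned += 1
            if state[q] == BOTH_RETAINED:
                state[q] = copy
                _bit_add(tree, q + 1, -1)
                n_both -= 1
                removed += 1
            # else: protected (ortholog already lost on the other copy) - skipped
            q += 1
        if record:
            ev_copy[n_events] = copy
            ev_start[n_events] = start
            ev_span[n_events] = spanned
            ev_removed[n_events] = removed
        n_events += 1
    _count_runs(state, BOTH_RETAINED, runs_out)
    return n_events


@njit(cache=True)
def two_copy_replicates(n_genes, target_both, bias, lengths, cdf, seeds):
    """Run one two-copy replicate per seed; returns the (replicates,
    n_genes+1) matrix of both-retained run counts."""
    reps = seeds.shape[0]
    counts = np.zeros((reps, n_genes + 1), dtype=np.int64)
    state = np.zeros(n_genes, dtype=np.uint8)
    dummy = np.zeros(1, dtype=np.int64)
    log2n = 0
    while (1 << (log2n + 1)) <= n_genes:
        log2n += 1
    for r in range(reps):
        np.random.seed(seeds[r])
        _two_copy_replicate(
            n_genes, target_both, bias, lengths, cdf, log2n,
            state, counts[r], dummy, dummy, dummy, dummy, False,
        )
    return counts


@njit(cache=True)
def two_copy_generate(n_genes, target_both, bias, lengths, cdf, seed):
    """One recorded two-copy realization for the synthetic generator.

    Returns (state, n_events, ev_copy, ev_start, ev_span, ev_removed):
    the final per-gene states plus the ordered event log.
    """
    state = np.zeros(n_genes, dtype=np.uint8)
    runs = np.zeros(n_genes + 1, dtype=np.int64)
    max_events = n_genes + 1
    ev_copy = np.zeros(max_events, dtype=np.int64)
    ev_start = np.zeros(max_events, dtype=np.int64)
    ev_span = np.zeros(max_events, dtype=np.int64)
    ev_removed = np.zeros(max_events, dtype=np.int64)
    log2n = 0
    while (1 << (log2n + 1)) <= n_genes:
        log2n += 1
    np.random.seed(seed)
    n_events = _two_copy_replicate(
        n_genes, target_both, bias, lengths, cdf, log2n,
        state, runs, ev_copy, ev_start, ev_span, ev_removed, True,
    )
    return state, n_events, ev_copy, ev_start, ev_span, ev_removed
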