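"""Monte Carlo simulators vs exhaustive enumeration oracles."""

from itertools import combinations

import numpy as np
import pytest

from fractionato.fractionation_sim import (
    SINGLE_GENE,
    DeletionMixture,
    compare_to_envelope,
    simulate_deletion_runs,
    simulate_retained_runs,
)
from fractionato.run_analysis import RunDistribution


def run_lengths(deleted_positions, n):
    """Maximal runs of a position set, as {length: count}."""
    flags = np.zeros(n, dtype=bool)
    flags[list(deleted_positions)] = True
    out = {}
    run = 0
    for v in list(flags) + [False]:
        if v:
            run += 1
        elif run:
            out[run] = out.get(run, 0) + 1
            run = 0
    return out


def subset_oracle_means(n, k):
    """Mean run counts over all C(n, k) equally likely deletion subsets —
    the exact distribution for the single-gene mechanism."""
    totals = {}
    subsets = list(combinations(range(n), k))
    for sub in subsets:
        for length, c in run_lengths(sub, n).items():
            totals[length] = totals.get(length, 0) + c
    return {length: t / len(subsets) for length, t in totals.items()}


class TestDeletionSim:
    def test_full_deletion_single_run(self):
        env = simulate_deletion_runs(5, 5, SINGLE_GENE, replicates=50, seed=1)
        assert env.medians == {5: 1.0}
        assert (env.counts[:, 5] == 1).all()

    def test_conservation_per_replicate(self):
        env = simulate_deletion_runs(60, 23, DeletionMixture({1: 0.5, 3: 0.5}), replicates=200, seed=2)
        weights = np.arange(env.counts.shape[1])
        assert (env.counts @ weights == 23).all()

    @pytest.mark.parametrize("n,k", [(4, 2), (6, 3), (8, 4)])
    def test_single_gene_matches_subset_enumeration(self, n, k):
        reps = 30000
        env = simulate_deletion_runs(n, k, SINGLE_GENE, replicates=reps, seed=3)
        oracle = subset_oracle_means(n, k)
        means = env.mean_counts()
        for length in sorted(set(oracle) | set(means)):
            col = env.counts[:, length] if length < env.counts.shape[1] else np.zeros(reps)
            se = col.std(ddof=1) / np.sqrt(reps)
            assert means.get(length, 0.0) == pytest.approx(
                oracle.get(length, 0.0), abs=max(3 * se, 1e-9)
            )

    def test_known_small_case_expectations(self):
        # n=4, k=2: E[len-1 runs] = 1.0 and E[len-2 runs] = 0.5 by enumeration
        oracle = subset_oracle_means(4, 2)
        assert oracle == {1: 1.0, 2: 0.5}

    def test_ligation_fuses_two_gene_events(self):
        env = simulate_deletion_runs(100, 50, DeletionMixture({2: 1.0}), replicates=300, seed=4)
        assert max(env.medians) > 2  # apparent runs longer than any single event

    def test_single_gene_mixture_gives_more_singletons(self):
        env1 = simulate_deletion_runs(100, 50, SINGLE_GENE, replicates=400, seed=5)
        env2 = simulate_deletion_runs(100, 50, DeletionMixture({2: 1.0}), replicates=400, seed=5)
        assert env1.counts[:, 1].mean() > env2.counts[:, 1].mean()

    def test_deterministic_under_seed(self):
        a = simulate_deletion_runs(80, 30, DeletionMixture({1: 0.8, 2: 0.2}), replicates=100, seed=9)
        b = simulate_deletion_runs(80, 30, DeletionMixture({1: 0.8, 2: 0.2}), replicates=100, seed=9)
        assert a.medians == b.medians and (a.counts == b.counts).all()

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            simulate_deletion_runs(5, 6, SINGLE_GENE)
        with pytest.raises(ValueError):
            DeletionMixture({})
        with pytest.raises(ValueError):
            DeletionMixture({7: 1.0})


def retained_oracle_medians(n, target):
    """Exhaustive oracle for single-gene two-copy loss: the surviving
    both-retained set is a uniform (target)-subset of n positions; median
    run counts follow from enumerating all subsets."""
    per_subset = [run_lengths(sub, n) for sub in combinations(range(n), target)]
    lengths = sorted({length for d in per_subset for length in d})
    medians = {}
    for length in lengths:
        # replicate counts are iid draws from this finite distribution;
        # the envelope median converges to the distribution median
        vals = np.array([d.get(length, 0) for d in per_subset])
        medians[length] = float(np.median(vals))
    return medians


class TestRetainedSim:
    def test_no_deletions(self):
        env = simulate_retained_runs(10, 10, bias=0.5, replicates=20, seed=1)
        assert env.medians == {10: 1.0}

    def test_two_genes_one_loss(self):
        env = simulate_retained_runs(2, 1, bias=0.3, replicates=100, seed=2)
        assert env.medians == {1: 1.0}

    def test_conservation_per_replicate(self):
        env = simulate_retained_runs(40, 17, bias=0.7, replicates=200, seed=3)
        weights = np.arange(env.counts.shape[1])
        assert (env.counts @ weights == 17).all()

    def test_matches_subset_enumeration_oracle(self):
        env = simulate_retained_runs(6, 2, bias=0.5, replicates=4001, seed=4)
        assert env.medians == retained_oracle_medians(6, 2)

    def test_bias_realized_in_loss_fractions(self):
        # with many events the per-copy deletion split converges to the bias
        from fractionato.synthetic_data import generate_region

        _, truth = generate_region(n_genes=4000, bias=0.7, mixture=SINGLE_GENE,
                                   deletion_fraction=0.6, seed=5)
        on_h1 = sum(e[3] for e in truth.events if e[0] == 1)
        total = sum(e[3] for e in truth.events)
        assert on_h1 / total == pytest.approx(0.7, abs=0.03)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            simulate_retained_runs(10, 0, bias=0.5)
        with pytest.raises(ValueError):
            simulate_retained_runs(10, 5, bias=1.5)


class TestCompare:
    def test_observed_at_medians_no_flags(self):
        env = simulate_deletion_runs(50, 20, SINGLE_GENE, replicates=500, seed=6)
        obs = RunDistribution(
            kind="deleted_over",
            counts={k: int(round(v)) for k, v in env.medians.items() if round(v) > 0},
        )
        report = compare_to_envelope(obs, env)
        flagged = report[report["outside"]]
        assert flagged.empty

    def test_impossible_long_run_flagged(self):
        env = simulate_deletion_runs(50, 12, SINGLE_GENE, replicates=500, seed=7)
        obs = RunDistribution(kind="deleted_over", counts={12: 1})
        report = compare_to_envelope(obs, env).set_index("length")
        assert report.loc[12, "outside"]

    def test_single_replicate_self_comparison(self):
        env = simulate_deletion_runs(30, 10, SINGLE_GENE, replicates=1, seed=8)
        obs = RunDistribution(
            kind="deleted_over",
            counts={k: int(env.counts[0, k]) for k in range(1, env.counts.shape[1]) if env.counts[0, k]},
        )
        assert not compare_to_envelope(obs, env)["outside"].any()

    def test_kind_mismatch(self):
        env = simulate_retained_runs(10, 5, bias=0.5, replicates=10, seed=9)
        obs = RunDistribution(kind="deleted_over", counts={1: 1})
        with pytest.raises(ValueError, match="kinds disagree"):
            compare_to_envelope(obs, env)
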