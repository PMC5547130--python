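"""Fisher over-representation, B-H adjustment, activation z-scores, GMT I/O."""

import math
from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from plexde.enrich import (
    GeneSet,
    GeneSetCollection,
    activation_zscore,
    bh_adjust,
    direction_fractions,
    fisher_enrichment,
    fisher_right_tail,
    read_gmt,
    run_enrichment,
    write_gmt,
)
from plexde.synthetic import generate_genesets, generate_cohort

from conftest import analyze_cohort, small_config


def hypergeom_tail_by_enumeration(k, K, n, N):
    """Exhaustive right tail: sum of C(K,j) C(N-K,n-j) / C(N,n) for j >= k."""
    total = math.comb(N, n)
    acc = 0
    for j in range(max(k, 0, n - (N - K)), min(K, n) + 1):
        acc += math.comb(K, j) * math.comb(N - K, n - j)
    return acc / total


class TestFisher:
    def test_zero_overlap_gives_one(self):
        universe = {f"G{i}" for i in range(20)}
        k, K, n, N, p = fisher_enrichment({"G0", "G1"}, {"G10", "G11"}, universe)
        assert k == 0
        assert p == 1.0

    def test_worked_example_n20(self):
        # N=20, K=4, n=5, k=3 -> (C(5,3)C(15,1)+C(5,4)C(15,0))/C(20,4)
        p = fisher_right_tail(3, 4, 5, 20)
        assert p == pytest.approx(hypergeom_tail_by_enumeration(3, 4, 5, 20), rel=1e-12)
        assert p == pytest.approx(0.0320, abs=5e-5)

    def test_set_fully_within_de_list(self):
        universe = {f"G{i}" for i in range(12)}
        members = {"G0", "G1", "G2"}
        k, K, n, N, p = fisher_enrichment(members, members, universe)
        assert (k, K, n) == (3, 3, 3)
        assert p == pytest.approx(hypergeom_tail_by_enumeration(3, 3, 3, 12), rel=1e-12)
        assert p == pytest.approx(1 / math.comb(12, 3), rel=1e-12)

    def test_matches_enumeration_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            N = int(rng.integers(1, 26))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            assert fisher_right_tail(k, K, n, N) == pytest.approx(
                hypergeom_tail_by_enumeration(k, K, n, N), rel=1e-9, abs=1e-12
            )

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment({"A"}, {"A"}, set())


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.037])[0] == pytest.approx(0.037)

    def test_hand_step_up_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_all_equal_stay_equal(self):
        out = bh_adjust([0.2, 0.2, 0.2, 0.2])
        assert np.allclose(out, 0.2)

    def test_order_invariant_and_monotone(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=30)
        once = bh_adjust(p)
        perm = rng.permutation(30)
        assert np.allclose(bh_adjust(p[perm]), once[perm])
        order = np.argsort(p)
        assert np.all(np.diff(once[order]) >= -1e-15)
        assert np.all(once >= p)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.2])


class TestActivationZ:
    def test_all_concordant_ten_genes(self):
        z, n_con, n_dis = activation_zscore([(+1, +1)] * 10)
        assert z == pytest.approx(10 / math.sqrt(10), rel=1e-12)
        assert round(z, 3) == 3.162
        assert (n_con, n_dis) == (10, 0)

    def test_three_concordant_two_discordant(self):
        pairs = [(+1, +1)] * 3 + [(-1, +1)] * 2
        z, n_con, n_dis = activation_zscore(pairs)
        assert z == pytest.approx(1 / math.sqrt(5), rel=1e-12)
        assert round(z, 3) == 0.447

    def test_balanced_gives_zero(self):
        z, *_ = activation_zscore([(+1, +1), (-1, +1)])
        assert z == 0.0

    def test_unannotated_genes_yield_missing(self):
        z, n_con, n_dis = activation_zscore([(+1, 0), (-1, 0)])
        assert math.isnan(z)
        assert (n_con, n_dis) == (0, 0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.sampled_from([-1, 1]), st.sampled_from([-1, 0, 1])),
                    min_size=1, max_size=30))
    def test_bounded_and_antisymmetric(self, pairs):
        z, n_con, n_dis = activation_zscore(pairs)
        annotated = n_con + n_dis
        if annotated == 0:
            assert math.isnan(z)
            return
        assert abs(z) <= math.sqrt(annotated) + 1e-12
        z_flip, *_ = activation_zscore([(-o, e) for o, e in pairs])
        assert z_flip == pytest.approx(-z, rel=1e-12)


def _diff_frame(consensus, direction):
    return pd.DataFrame(
        {"consensus": consensus, "direction": direction},
        index=[f"G{i}" for i in range(len(consensus))],
    )


class TestRunEnrichment:
    def test_planted_sets_flagged_significant(self, planted_run):
        _, _, truth, _, _, diff = planted_run
        sets = generate_genesets(truth, n_sets=8, set_size_range=(6, 10),
                                 enrichment_fraction=1.0, seed=1, n_enriched=3)
        res = run_enrichment(diff, sets)
        enriched = res.set_index("set_name").loc[truth.enriched_set_names]
        assert enriched["significant"].all()
        assert (enriched["z"] > 0).all()  # planted direction agrees with observed

    def test_empty_de_list_all_null(self):
        diff = _diff_frame([False] * 10, [0] * 10)
        sets = GeneSetCollection([GeneSet("S1", {"G0": 0, "G1": 0})])
        res = run_enrichment(diff, sets)
        assert (res["p_fisher"] == 1.0).all()
        assert not res["significant"].any()

    def test_neglog_threshold_equivalent_to_corrected_p(self, planted_run):
        *_, diff = planted_run
        _, _, truth, *_ = planted_run
        sets = generate_genesets(truth, n_sets=10, set_size_range=(5, 12),
                                 enrichment_fraction=0.8, seed=3, n_enriched=4)
        res = run_enrichment(diff, sets, neglog_threshold=1.3)
        assert res["significant"].equals(res["p_bh"] <= 0.05)

    def test_results_sorted_by_significance(self, planted_run):
        _, _, truth, _, _, diff = planted_run
        sets = generate_genesets(truth, n_sets=6, set_size_range=(5, 10),
                                 enrichment_fraction=0.9, seed=2, n_enriched=2)
        res = run_enrichment(diff, sets)
        assert list(res["neg_log10_bh"]) == sorted(res["neg_log10_bh"], reverse=True)

    def test_no_overlap_warns_and_returns_empty(self):
        diff = _diff_frame([True] * 4, [1] * 4)
        sets = GeneSetCollection([GeneSet("S1", {"X1": 0, "X2": 0})])
        with pytest.warns(UserWarning, match="no overlap"):
            res = run_enrichment(diff, sets)
        assert res.empty

    def test_direction_fractions_partition(self, planted_run):
        _, _, truth, _, _, diff = planted_run
        sets = generate_genesets(truth, n_sets=5, set_size_range=(6, 10),
                                 enrichment_fraction=0.7, seed=4, n_enriched=2)
        frac = direction_fractions(diff, sets)
        total = frac[["frac_up", "frac_down", "frac_absent"]].sum(axis=1)
        assert np.allclose(total, 1.0)


class TestGmtIO:
    def test_direction_annotated_round_trip(self, tmp_path):
        coll = GeneSetCollection(
            [
                GeneSet("SET_A", {"G1": 1, "G2": -1, "G3": 0}, description="planted"),
                GeneSet("SET_B", {"G4": 0}),
            ]
        )
        write_gmt(coll, tmp_path / "sets.gmt")
        back = read_gmt(tmp_path / "sets.gmt")
        assert [s.name for s in back] == ["SET_A", "SET_B"]
        assert dict(back.sets[0].members) == {"G1": 1, "G2": -1, "G3": 0}
        assert dict(back.sets[1].members) == {"G4": 0}

    def test_plain_gmt_reads_with_zero_directions(self, tmp_path):
        (tmp_path / "plain.gmt").write_text("PATH1\tdesc\tG1\tG2\tG3\n")
        coll = read_gmt(tmp_path / "plain.gmt")
        assert dict(coll.sets[0].members) == {"G1": 0, "G2": 0, "G3": 0}
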