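"""Seed-match targets, correlation filters, sponge test and network build."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from circsponge import cerna
from circsponge.bsj import quantify_rpm
from circsponge.cerna import (
    build_network,
    find_seed_sites,
    overrepresentation,
    pearson,
    predict_targets,
    seed_site_patterns,
    spearman,
    sponge_test,
)
from circsponge.genome import revcomp
from oracles import hypergeom_enumeration


MIR = "TAGCTTATCAGACTGATGTTG"  # 21 nt


class TestSeedMatching:
    def test_site_patterns(self):
        pats = seed_site_patterns(MIR)
        assert pats["7mer-m8"] == revcomp(MIR[1:8])
        assert pats["7mer-A1"] == revcomp(MIR[1:7]) + "A"
        assert all(len(p) == 7 for p in pats.values())

    def test_single_m8_site_gives_edge_with_one_site(self):
        site = seed_site_patterns(MIR)["7mer-m8"]
        tx = "C" * 30 + site + "C" * 30
        edges = predict_targets({"m": MIR}, {"t": tx})
        assert len(edges) == 1
        assert edges[0].site_count == 1
        assert edges[0].site_positions == (30,)

    def test_junction_crossing_site_needs_circular_scan(self):
        site = seed_site_patterns(MIR)["7mer-m8"]
        tx = site[3:] + "C" * 60 + site[:3]  # wraps the junction
        assert find_seed_sites(MIR, tx, circular=False) == []
        assert find_seed_sites(MIR, tx, circular=True) == [len(tx) - 3]

    def test_siteless_transcript_gives_no_edge(self):
        assert predict_targets({"m": MIR}, {"t": "C" * 100}) == []

    def test_short_transcript_no_sites_no_error(self):
        assert find_seed_sites(MIR, "ACG") == []

    def test_short_mirna_rejected(self):
        with pytest.raises(ValueError):
            seed_site_patterns("ACGTAizz"[:6])

    def test_rna_alphabet_accepted(self):
        site = seed_site_patterns(MIR)["7mer-m8"]
        mir_rna = MIR.replace("T", "U")
        # the trailing A also completes a 7mer-A1 match one base downstream
        assert find_seed_sites(mir_rna, "A" * 10 + site + "A" * 10) == [10, 11]


class TestCorrelations:
    def test_perfect_linear_relation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson(x, 2 * x + 3) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_strictly_decreasing_spearman_is_minus_one(self):
        x = np.array([1.0, 5.0, 2.0, 9.0, 4.0])
        y = -np.exp(x)
        assert spearman(x, y) == pytest.approx(-1.0)

    def test_spearman_equals_rank_then_pearson_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0])
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        oracle = stats.pearsonr(rx, ry).statistic
        assert spearman(x, y) == pytest.approx(oracle, abs=1e-12)

    def test_pearson_equals_longhand_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 5.0])
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        oracle = cov / (x.std() * y.std())
        assert pearson(x, y) == pytest.approx(oracle, abs=1e-12)

    def test_matches_scipy_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(4, 30))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            assert pearson(x, y) == pytest.approx(
                stats.pearsonr(x, y).statistic, abs=1e-12)
            assert spearman(x, y) == pytest.approx(
                stats.spearmanr(x, y).statistic, abs=1e-12)

    def test_spearman_handles_ties_with_midranks(self):
        x = np.array([1.0, 1.0, 2.0, 3.0, 3.0, 4.0])
        y = np.array([2.0, 4.0, 4.0, 1.0, 5.0, 5.0])
        assert spearman(x, y) == pytest.approx(
            stats.spearmanr(x, y).statistic, abs=1e-12)

    def test_joint_permutation_invariance(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=12), rng.normal(size=12)
        perm = rng.permutation(12)
        assert spearman(x[perm], y[perm]) == pytest.approx(spearman(x, y), abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.integers(-10000, 10000), min_size=4, max_size=20, unique=True))
    def test_spearman_invariant_under_monotone_transform(self, xs):
        rng = np.random.default_rng(abs(hash(tuple(xs))) % 2**31)
        x = np.array(xs, dtype=float) / 100.0
        y = rng.normal(size=len(x))
        if np.ptp(y) == 0:
            return
        assert spearman(np.exp(x / 50), y) == pytest.approx(spearman(x, y), abs=1e-9)
        assert abs(spearman(x, y)) <= 1 + 1e-12
        assert abs(pearson(x, y)) <= 1 + 1e-12

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            spearman([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3"):
            pearson([1.0, 2.0], [3.0, 4.0])


class TestSpongeTest:
    def test_zero_overlap_gives_one(self):
        assert sponge_test(30, 10, 5, 0) == 1.0

    def test_full_marking_forces_overlap(self):
        assert sponge_test(20, 20, 6, 6) == 1.0

    @pytest.mark.parametrize("N,K,n,x", [
        (20, 5, 6, 3), (10, 4, 4, 2), (15, 7, 5, 1), (12, 6, 6, 6), (9, 3, 5, 0),
    ])
    def test_matches_brute_force_enumeration(self, N, K, n, x):
        assert sponge_test(N, K, n, x) == pytest.approx(
            hypergeom_enumeration(N, K, n, x), abs=1e-12)

    def test_matches_scipy_survival_function(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            N = int(rng.integers(5, 200))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            x = int(rng.integers(0, min(K, n) + 1))
            assert sponge_test(N, K, n, x) == pytest.approx(
                stats.hypergeom.sf(x - 1, N, K, n), rel=1e-10)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.data())
    def test_monotone_in_overlap_and_symmetric_in_set_sizes(self, data):
        N = data.draw(st.integers(2, 40))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        ps = [sponge_test(N, K, n, x) for x in range(min(K, n) + 1)]
        assert all(0 <= p <= 1 for p in ps)
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))
        x = data.draw(st.integers(0, min(K, n)))
        assert sponge_test(N, K, n, x) == pytest.approx(sponge_test(N, n, K, x), rel=1e-12)

    def test_invalid_overlap_rejected(self):
        with pytest.raises(ValueError):
            sponge_test(10, 3, 4, 5)


class TestNetwork:
    def _setup(self, expression):
        rpm = {o: quantify_rpm(expression.counts[o], expression.counts[o].sum(axis=0))
               for o in expression.counts}
        edges = predict_targets(expression.mirna_seqs, expression.transcript_seqs,
                                expression.circular_ids)
        return rpm, edges

    def test_planted_triplets_recovered(self, expression):
        rpm, edges = self._setup(expression)
        trip = build_network(rpm, edges)
        truth = set(map(tuple, expression.triplets[["circ_id", "mirna_id", "mrna_id"]].values))
        called = set(map(tuple, trip.loc[trip.passes, ["circ_id", "mirna_id", "mrna_id"]].values))
        assert len(called & truth) >= 8
        assert len(called - truth) == 0

    def test_relaxed_thresholds_give_superset(self, expression):
        rpm, edges = self._setup(expression)
        strict = build_network(rpm, edges)
        loose = build_network(rpm, edges, scc_max=0.0, pcc_min=0.0, sponge_alpha=1.01)
        s = set(map(tuple, strict.loc[strict.passes, ["circ_id", "mirna_id", "mrna_id"]].values))
        l = set(map(tuple, loose.loc[loose.passes, ["circ_id", "mirna_id", "mrna_id"]].values))
        assert s <= l

    def test_triplet_requires_both_edges(self, expression):
        rpm, edges = self._setup(expression)
        kept = [e for e in edges if e.transcript_kind == "circ"]  # drop mRNA edges
        trip = build_network(rpm, kept)
        assert trip.empty

    def test_passes_flag_consistent_with_thresholds(self, expression):
        rpm, edges = self._setup(expression)
        trip = build_network(rpm, edges)
        manual = ((trip.scc_circ_mir < -0.7) & (trip.scc_mrna_mir < -0.7)
                  & (trip.pcc_circ_mrna > 0.9) & (trip.sponge_p < 0.05))
        assert (trip.passes == manual).all()

    def test_de_restriction_filters_candidates(self, expression):
        rpm, edges = self._setup(expression)
        none_de = {"circ": set(), "mir": set(), "mrna": set()}
        assert build_network(rpm, edges, de_features=none_de).empty

    def test_sif_and_graphml_export(self, expression, tmp_path):
        rpm, edges = self._setup(expression)
        trip = build_network(rpm, edges)
        cerna.write_sif(trip, tmp_path / "net.sif")
        cerna.write_graphml(trip, tmp_path / "net.graphml")
        sif = (tmp_path / "net.sif").read_text().splitlines()
        n_pass = trip.passes.sum()
        assert len(sif) == 2 * n_pass  # unique circ-mir + mir-mrna pairs here
        import networkx as nx
        g = nx.read_graphml(tmp_path / "net.graphml")
        kinds = {d["kind"] for _, d in g.nodes(data=True)}
        assert kinds == {"circ", "mir", "mrna"}


class TestOverrepresentation:
    def test_study_drawn_from_one_set_has_smallest_p(self):
        background = {f"g{i}" for i in range(100)}
        sets = {
            "hit": {f"g{i}" for i in range(10)},
            "other": {f"g{i}" for i in range(50, 80)},
        }
        study = {f"g{i}" for i in range(8)}
        res = overrepresentation(study, sets, background)
        assert res["p_value"].idxmin() == "hit"

    def test_study_equals_background_gives_p_one(self):
        background = {f"g{i}" for i in range(30)}
        sets = {"a": {f"g{i}" for i in range(5)}, "b": {f"g{i}" for i in range(10, 20)}}
        res = overrepresentation(set(background), sets, background)
        assert (res["p_value"] == 1.0).all()

    def test_three_set_toy_matches_enumeration(self):
        background = {f"g{i}" for i in range(100)}
        sets = {
            "s5": {f"g{i}" for i in range(5)},
            "s10": {f"g{i}" for i in range(20, 30)},
            "s20": {f"g{i}" for i in range(40, 60)},
        }
        study = ({f"g{i}" for i in range(4)}          # 4 hits in s5
                 | {f"g{i}" for i in range(20, 22)}   # 2 hits in s10
                 | {f"g{i}" for i in range(40, 42)}   # 2 hits in s20
                 | {"g98", "g99"})
        res = overrepresentation(study, sets, background)
        for name, K in [("s5", 5), ("s10", 10), ("s20", 20)]:
            x = len(sets[name] & study)
            expected = stats.hypergeom.sf(x - 1, 100, K, len(study))
            assert res.loc[name, "p_value"] == pytest.approx(expected, rel=1e-10)
# small enough to enumerate every draw exhaustively
        small_bg = {f"g{i}" for i in range(20)}
        small_sets = {"s": {f"g{i}" for i in range(5)}}
        small_study = {"g0", "g1", "g2", "g10", "g11", "g12"}
        res_small = overrepresentation(small_study, small_sets, small_bg)
        assert res_small.loc["s", "p_value"] == pytest.approx(
            hypergeom_enumeration(20, 5, 6, 3), abs=1e-12)

    def test_bh_fdr_never_below_raw_p_for_smallest(self):
        background = {f"g{i}" for i in range(50)}
        sets = {f"set{j}": {f"g{i}" for i in range(j, j + 10)} for j in range(5)}
        study = {f"g{i}" for i in range(6)}
        res = overrepresentation(study, sets, background)
        smallest = res["p_value"].idxmin()
        assert res.loc[smallest, "fdr"] >= res.loc[smallest, "p_value"] - 1e-15

    def test_study_outside_background_rejected(self):
        with pytest.raises(ValueError):
            overrepresentation({"x"}, {"a": {"x"}}, {"y"})

    def test_empty_study_gives_empty_result(self):
        assert overrepresentation(set(), {"a": {"x"}}, {"x"}).empty
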