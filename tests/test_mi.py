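import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from episcan import (MIParams, SampleClassification, WindowingParams, bh_adjust,
                     default_spec, filter_significant, generate,
                     mutual_information, permutation_pvalue, results_to_frame,
                     scan, truth_eval)
from episcan.mi import _window_rng
from episcan.windowing import Window

from conftest import (bh_bruteforce, exact_permutation_p, make_classification,
                      make_profile, mi_bruteforce)

STATES = ("Tx", "Enh", "Het", "Quies")


class TestMutualInformation:
    def test_perfect_split_5_vs_6(self):
        """A profile exactly mirroring a 5/6 grouping scores H(G) =
        -(5/11)log2(5/11) - (6/11)log2(6/11) ~ 0.994 bits."""
        cls = make_classification(["A"] * 5 + ["B"] * 6)
        profile = make_profile(["Tx"] * 5 + ["Het"] * 6)
        mi = mutual_information(profile, cls)
        expected = -(5 / 11) * math.log2(5 / 11) - (6 / 11) * math.log2(6 / 11)
        assert mi == pytest.approx(expected, abs=1e-12)
        assert round(mi, 3) == 0.994

    def test_symmetric_perfect_split_is_one_bit(self):
        cls = make_classification(["A"] * 4 + ["B"] * 4)
        profile = make_profile(["Tx"] * 4 + ["Het"] * 4)
        assert mutual_information(profile, cls) == pytest.approx(1.0)

    def test_single_shared_state_scores_zero(self):
        cls = make_classification(["A", "A", "B", "B"])
        assert mutual_information(make_profile(["Tx"] * 4), cls) == 0.0

    def test_undefined_samples_excluded_before_frequencies(self):
        """Marginals are recomputed on retained samples only: dropping one
        group entirely leaves a degenerate marginal and MI 0."""
        cls = make_classification(["A", "A", "B", "B"])
        profile = make_profile(["undefined", "undefined", "Het", "Tx"])
        assert mutual_information(profile, cls) == 0.0
        # and a clean 1-vs-1 after exclusion gives exactly 1 bit
        profile2 = make_profile(["undefined", "Tx", "undefined", "Het"])
        assert mutual_information(profile2, cls) == pytest.approx(1.0)

    def test_fewer_than_two_retained_samples(self):
        cls = make_classification(["A", "A", "B"])
        profile = make_profile(["undefined", "undefined", "Tx"])
        assert mutual_information(profile, cls) == 0.0

    def test_empty_profile_rejected(self):
        cls = make_classification(["A", "B"])
        with pytest.raises((ValueError, KeyError)):
            mutual_information(make_profile([]), cls)

    def test_agrees_with_bruteforce_double_sum(self):
        """1,000 random profiles (<=12 samples, <=4 states, <=3 groups) vs
        the definition-level oracle."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(2, 13))
            n_states = int(rng.integers(1, 5))
            n_groups = int(rng.integers(2, 4))
            states = [STATES[i] if i < n_states else "undefined"
                      for i in rng.integers(0, n_states + 1, size=n)]
            groups = [f"g{i}" for i in rng.integers(0, n_groups, size=n)]
            if len(set(groups)) < 2:
                groups[0], groups[1] = "g0", "g1"
            got = mutual_information(make_profile(states),
                                     make_classification(groups))
            assert got == pytest.approx(mi_bruteforce(states, groups),
                                        abs=1e-12)

    @given(st.lists(st.tuples(st.sampled_from(STATES + ("undefined",)),
                              st.sampled_from("AB")),
                    min_size=2, max_size=10))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_entropy_bound_and_label_invariance(self, pairs):
        states = [p[0] for p in pairs]
        groups = [p[1] for p in pairs]
        if len(set(groups)) < 2:
            groups[0] = "A" if groups[0] != "A" else "B"
        cls = make_classification(groups)
        mi = mutual_information(make_profile(states), cls)
        # 0 <= MI <= min(H(G), log2 m) on the retained samples
        kept = [(g, s) for g, s in zip(groups, states) if s != "undefined"]
        assert mi >= 0.0
        if kept:
            gk = [g for g, _ in kept]
            hg = -sum((gk.count(g) / len(gk)) * math.log2(gk.count(g) / len(gk))
                      for g in set(gk))
            m = len({s for _, s in kept})
            assert mi <= min(hg, math.log2(max(m, 1))) + 1e-9
        # invariance under relabelling of states and of groups
        state_map = {"Tx": "x1", "Enh": "x2", "Het": "x3", "Quies": "x4",
                     "undefined": "undefined"}
        relabeled = mutual_information(
            make_profile([state_map[s] for s in states]),
            make_classification([{"A": "Z", "B": "Y"}[g] for g in groups]))
        assert relabeled == pytest.approx(mi, abs=1e-12)

    def test_symmetry_profile_vs_classification(self):
        """MI(G:S) equals MI(S:G): swap the roles of states and groups."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(4, 10))
            states = [STATES[i] for i in rng.integers(0, 3, size=n)]
            groups = [f"g{i}" for i in rng.integers(0, 2, size=n)]
            if len(set(groups)) < 2:
                groups[0], groups[1] = "g0", "g1"
            if len(set(states)) < 2:
                states[0], states[1] = STATES[0], STATES[1]
            a = mutual_information(make_profile(states),
                                   make_classification(groups))
            b = mutual_information(make_profile(groups),
                                   make_classification(states))
            assert a == pytest.approx(b, abs=1e-12)


class TestPermutationPvalue:
    def test_constant_profile_p_is_one(self):
        cls = make_classification(["A", "A", "B", "B"])
        p, mi = permutation_pvalue(make_profile(["Tx"] * 4), cls,
                                   MIParams(n_permutations=200, seed=0))
        assert (p, mi) == (1.0, 0.0)

    @pytest.mark.parametrize("states,groups", [
        (["Tx", "Tx", "Tx", "Het", "Het", "Het"], "AAABBB"),
        (["Tx", "Tx", "Het", "Het", "Enh", "Enh"], "AAABBB"),
        (["Tx", "undefined", "Het", "Het", "Tx", "Tx"], "ABABAB"),
        (["Tx", "Tx", "Tx", "Tx", "Het", "Het", "Het"], "AAAABBB"),
        (["Tx", "Het", "Enh", "Tx", "Het"], "AABBB"),
    ])
    def test_matches_exact_enumeration_within_3se(self, states, groups):
        """Empirical p at 10,000 shuffles vs the exact p over all n!
        arrangements, within 3 binomial standard errors."""
        cls = make_classification(list(groups))
        p_exact = exact_permutation_p(states, list(groups))
        p_emp, _ = permutation_pvalue(make_profile(states), cls,
                                      MIParams(n_permutations=10_000, seed=11))
        se = math.sqrt(p_exact * (1 - p_exact) / 10_000)
        assert abs(p_emp - p_exact) <= 3 * se + 1e-12

    def test_group_aligned_profile_has_tiny_p(self):
        cls = make_classification(["A"] * 8 + ["B"] * 8)
        profile = make_profile(["Tx"] * 8 + ["Het"] * 8)
        for seed in range(3):
            p, mi = permutation_pvalue(profile, cls,
                                       MIParams(n_permutations=10_000,
                                                seed=seed))
            assert mi == pytest.approx(1.0)
            assert p <= 10 / 10_000

    def test_p_can_be_exactly_zero_and_pseudocount_variant(self):
        cls = make_classification(["A"] * 10 + ["B"] * 10)
        profile = make_profile(["Tx"] * 10 + ["Het"] * 10)
        p, _ = permutation_pvalue(profile, cls,
                                  MIParams(n_permutations=2000, seed=5))
        assert p == 0.0
        p1, _ = permutation_pvalue(profile, cls,
                                   MIParams(n_permutations=2000, seed=5,
                                            pseudocount=True))
        assert p1 == pytest.approx(1 / 2001)

    def test_reproducible_given_seed(self):
        cls = make_classification(["A", "B"] * 4)
        profile = make_profile(["Tx", "Het", "Tx", "Tx",
                                "Het", "Het", "Tx", "Het"])
        params = MIParams(n_permutations=500, seed=123)
        runs = {permutation_pvalue(profile, cls, params,
                                   np.random.default_rng(9))[0]
                for _ in range(3)}
        assert len(runs) == 1


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_and_tied_values(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        assert bh_adjust([0.5, 0.5, 0.5]) == pytest.approx([0.5] * 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(1, 101))
            p = rng.random(n)
            assert bh_adjust(p) == pytest.approx(bh_bruteforce(p), abs=1e-12)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(1)
        p = rng.random(200)
        assert np.all(bh_adjust(p) >= p)


class TestScan:
    def test_planted_window_tops_scan(self):
        # 10 samples/group: the exact null probability of a perfect split is
        # 2/C(20,10) ~ 1e-5, small enough to clear the 1e-4 FDR threshold
        spec = default_spec(seed=2, n_planted=1, samples_per_group=10)
        tracks, truth = generate(spec)
        params = MIParams(n_permutations=2000, seed=2)
        results = scan(tracks, spec.classification(), spec.layout,
                       WindowingParams(), params)
        assert len(results) == 400
        best = max(results, key=lambda r: r.mi)
        assert (best.window.chrom, best.window.start) == \
            (truth.chrom[0], truth.start[0])
        sig = filter_significant(results, params)
        ev = truth_eval(sig, truth, results)
        assert ev["sensitivity"] == 1.0 and ev["false_positives"] == 0.0

    def test_single_group_classification_rejected(self):
        with pytest.raises(ValueError, match="2 distinct groups"):
            SampleClassification({"a": "g", "b": "g"})

    def test_deterministic_given_seed_and_order_independent(self):
        spec = default_spec(seed=4, n_planted=2, samples_per_group=4)
        tracks, _ = generate(spec)
        cls = spec.classification()
        params = MIParams(n_permutations=500, seed=7)
        r1 = scan(tracks, cls, spec.layout, WindowingParams(), params)
        r2 = scan(tracks, cls, spec.layout, WindowingParams(), params)
        f1 = results_to_frame(r1, cls.samples)
        f2 = results_to_frame(r2, cls.samples)
        assert f1.equals(f2)
        # the per-window generator depends only on (seed, chrom, start)
        a = _window_rng(7, Window("chr1", 5000, 10000)).integers(0, 1 << 30)
        b = _window_rng(7, Window("chr1", 5000, 10000)).integers(0, 1 << 30)
        c = _window_rng(7, Window("chr2", 5000, 10000)).integers(0, 1 << 30)
        assert a == b and a != c

    def test_all_undefined_windows_kept_in_family(self):
        spec = default_spec(seed=3, n_planted=1, samples_per_group=3,
                            undefined_rate=1.0)
        tracks, truth = generate(spec)
        params = MIParams(n_permutations=200, seed=3)
        results = scan(tracks, spec.classification(), spec.layout,
                       WindowingParams(), params)
        by_window = {(r.window.chrom, r.window.start): r for r in results}
        planted = by_window[(truth.chrom[0], truth.start[0])]
        assert planted.mi == 0.0 and planted.p_raw == 1.0
        assert len(results) == 400  # family size includes every window

    def test_detection_monotone_in_association_strength(self):
        rates = []
        for strength in (1.0, 0.8, 0.6):
            hits = 0
            for seed in (0, 1):
                spec = default_spec(seed=seed, n_planted=4,
                                    samples_per_group=10, strength=strength)
                tracks, truth = generate(spec)
                params = MIParams(n_permutations=2000, seed=seed)
                res = scan(tracks, spec.classification(), spec.layout,
                           WindowingParams(), params)
                ev = truth_eval(filter_significant(res, params), truth, res)
                hits += ev["true_positives"]
            rates.append(hits)
        assert rates[0] >= rates[1] >= rates[2]
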