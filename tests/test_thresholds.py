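import numpy as np
import pytest

from ontothresh import (
    LabeledDistributions,
    SimilarityThresholdModel,
    build_distributions,
    leave_one_out,
    scan_particularity_threshold,
    scan_similarity_threshold,
    welch_test,
    whiskers,
)
from ontothresh.errors import ConfigurationError, DegenerateInputError, WelchGateError

from oracles import exhaustive_par_scan, exhaustive_scan


def jaccard_of_names(a: str, b: str) -> float:
    sa, sb = set(a), set(b)
    return len(sa & sb) / len(sa | sb)


class TestBuildDistributions:
    def test_pair_counting_two_groups(self):
        dist = build_distributions(
            {"G1": ["ab", "ac"], "G2": ["xy", "xz"]}, jaccard_of_names
        )
        assert len(dist.s_values) == 2
        assert len(dist.n_values) == 4

    def test_single_group_rejected(self):
        with pytest.raises(ConfigurationError):
            build_distributions({"G1": ["a", "b", "c"]}, jaccard_of_names)

    def test_undersized_group_rejected(self):
        with pytest.raises(ConfigurationError):
            build_distributions({"G1": ["a", "b"], "G2": ["c"]}, jaccard_of_names)

    def test_six_group_pair_counts(self):
        sizes = [3, 4, 5, 2, 6, 3]
        groups = {
            f"G{i}": [f"g{i}_{j}" for j in range(n)] for i, n in enumerate(sizes)
        }
        dist = build_distributions(groups, lambda a, b: 0.5)
        assert len(dist.s_values) == sum(n * (n - 1) // 2 for n in sizes)
        expected_n = sum(
            sizes[i] * sizes[j]
            for i in range(len(sizes))
            for j in range(i + 1, len(sizes))
        )
        assert len(dist.n_values) == expected_n
        # fifteen group pairs contribute to N
        assert len({gp for gp, _ in dist.n_provenance}) == 15

    def test_failing_pairs_skipped_and_counted(self):
        def flaky(a, b):
            if "bad" in (a, b):
                raise ValueError("boom")
            return 0.5

        dist = build_distributions({"G1": ["a", "bad"], "G2": ["c", "d"]}, flaky)
        assert dist.failed_pairs == 3  # (a,bad), (bad,c), (bad,d)
        assert len(dist.s_values) == 1  # only (c,d) survives in S
        assert len(dist.n_values) == 2


class TestWelch:
    def test_identical_samples(self):
        res = welch_test([0.1, 0.4, 0.7], [0.1, 0.4, 0.7])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0)

    def test_clearly_separated_samples(self):
        res = welch_test([0.8, 0.9, 0.85, 0.95], [0.1, 0.2, 0.15, 0.25])
        assert res.pvalue < 0.001
        assert res.statistic > 0

    def test_zero_variance_both_sides_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            welch_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])

    def test_too_few_values(self):
        with pytest.raises(DegenerateInputError):
            welch_test([1.0], [0.0, 0.5])


class TestWhiskers:
    def test_singleton(self):
        assert whiskers([5.0]) == (5.0, 5.0)

    def test_no_outliers_gives_extremes(self):
        assert whiskers([1.0, 2.0, 3.0, 4.0]) == (1.0, 4.0)

    def test_high_outlier_excluded(self):
        lo, hi = whiskers([1.0, 2.0, 3.0, 4.0, 100.0])
        assert hi == 4.0

    def test_minmax_mode_keeps_outliers(self):
        assert whiskers([1.0, 2.0, 3.0, 4.0, 100.0], mode="minmax") == (1.0, 100.0)


class TestSimilarityScan:
    def test_disjoint_ranges_midpoint(self):
        dist = LabeledDistributions([0.6, 0.7, 0.8, 0.9], [0.1, 0.2, 0.3, 0.4])
        res = scan_similarity_threshold(dist)
        assert not res.overlap
        assert (res.tau_n, res.tau_s) == (0.4, 0.6)
        assert res.tau_opt == pytest.approx(0.5)
        assert res.objective_min == 0.0
        assert res.curve == []

    def test_overlapping_distributions(self):
        dist = LabeledDistributions([0.4, 0.6, 0.8], [0.3, 0.5, 0.7])
        res = scan_similarity_threshold(dist, step=0.005)
        assert res.overlap
        assert (res.tau_n, res.tau_s) == (0.4, 0.7)
        assert res.objective_min == pytest.approx(2 / 3, abs=1e-12)
        # the minimum is attained at the left endpoint (FN=0, FP=2/3) and
        # again on the plateau (0.5, 0.6]; the smallest minimizer wins
        assert res.tau_opt == pytest.approx(0.4)
        frame = res.curve_frame().set_index("threshold")
        plateau = frame.loc[0.505:0.6]
        assert np.allclose(
            plateau["fn_proportion"] + plateau["fp_proportion"], 2 / 3
        )

    def test_tied_minimum_takes_smallest_grid_point(self):
        dist = LabeledDistributions([0.5, 0.9], [0.1, 0.5])
        res = scan_similarity_threshold(dist)
        assert (res.tau_n, res.tau_s) == (0.5, 0.5)
        assert res.tau_opt == 0.5

    def test_curve_monotonicity_and_oracle_agreement(self):
        rng = np.random.default_rng(73)
        for _ in range(30):
            s = rng.beta(4, 2, size=int(rng.integers(5, 60))).tolist()
            n = rng.beta(2, 4, size=int(rng.integers(5, 60))).tolist()
            dist = LabeledDistributions(s, n)
            res = scan_similarity_threshold(dist, step=0.01)
            if not res.overlap:
                continue
            grid = [row[0] for row in res.curve]
            fn = [row[1] for row in res.curve]
            fp = [row[2] for row in res.curve]
            assert all(x <= y + 1e-12 for x, y in zip(fn, fn[1:]))
            assert all(x >= y - 1e-12 for x, y in zip(fp, fp[1:]))
            tau_star, obj_star, curve = exhaustive_scan(s, n, grid)
            assert res.tau_opt == pytest.approx(tau_star)
            assert res.objective_min == pytest.approx(obj_star)
            for (t1, a1, b1), (t2, a2, b2) in zip(res.curve, curve):
                assert (a1, b1) == pytest.approx((a2, b2))

    def test_shift_invariance_within_one_step(self):
        rng = np.random.default_rng(79)
        s = (0.25 + 0.2 * rng.random(40)).tolist()
        n = (0.05 + 0.2 * rng.random(40)).tolist()
        c = 0.3
        step = 0.005
        base = scan_similarity_threshold(LabeledDistributions(s, n), step=step)
        shifted = scan_similarity_threshold(
            LabeledDistributions([v + c for v in s], [v + c for v in n]), step=step
        )
        assert shifted.tau_n == pytest.approx(base.tau_n + c, abs=step)
        assert shifted.tau_s == pytest.approx(base.tau_s + c, abs=step)
        assert shifted.tau_opt == pytest.approx(base.tau_opt + c, abs=step + 1e-9)

    def test_empty_side_rejected(self):
        with pytest.raises(DegenerateInputError):
            scan_similarity_threshold(LabeledDistributions([], [0.1]))


class TestParticularityScan:
    def test_all_dissimilar_high_par_has_zero_objective_at_zero(self):
        triples = [(0.2, 1.0, 1.0), (0.3, 1.0, 1.0)]
        res = scan_particularity_threshold(triples, tau_sim=0.5)
        assert res.tau_opt == 0.0
        assert res.objective_min == 0.0

    def test_single_informative_triple(self):
        res = scan_particularity_threshold([(0.9, 0.2, 0.2)], tau_sim=0.5, step=0.005)
        assert res.tau_opt == pytest.approx(0.205)
        assert res.objective_min == 0.0

    def test_single_dissimilar_triple(self):
        res = scan_particularity_threshold([(0.1, 0.2, 0.2)], tau_sim=0.5, step=0.005)
        assert res.tau_opt == 0.0
        assert res.objective_min == 0.0

    def test_matches_bruteforce_pattern_count(self):
        rng = np.random.default_rng(83)
        triples = [tuple(rng.random(3)) for _ in range(100)]
        res = scan_particularity_threshold(triples, tau_sim=0.5, step=0.02)
        grid = [row[0] for row in res.curve]
        tau_star, obj_star, curve = exhaustive_par_scan(triples, 0.5, grid)
        assert res.tau_opt == pytest.approx(tau_star)
        assert res.objective_min == pytest.approx(obj_star)
        for (t1, ppp, mmm), (t2, obj) in zip(res.curve, curve):
            assert ppp + mmm == pytest.approx(obj)

    def test_empty_triples_rejected(self):
        with pytest.raises(DegenerateInputError):
            scan_particularity_threshold([], tau_sim=0.5)


class TestLeaveOneOut:
    def test_identical_groups_give_identical_thresholds(self):
        # three clone groups whose pair values depend only on member indexes,
        # so every omission leaves the same S/N multisets
        def const_fn(a, b):
            ga, ia = a.split("_")
            gb, ib = b.split("_")
            if ga == gb:
                return 0.7 + 0.03 * (int(ia) + int(ib))
            return 0.2 + 0.01 * (int(ia) + int(ib))

        groups = {g: [f"{g}_{i}" for i in range(3)] for g in "XYZ"}
        res = leave_one_out(groups, const_fn)
        taus = res.tau_opts
        assert len(taus) == 3
        assert max(taus) - min(taus) == pytest.approx(0.0)

    def test_adversarial_group_shifts_threshold_most(self):
        # group ADV's intra-group values sit near the inter-group range, so it
        # contributes the entire S/N overlap
        groups = {g: [f"{g}_{i}" for i in range(6)] for g in ["A", "B", "C", "ADV"]}
        rng = np.random.default_rng(17)
        table = {}
        members = [m for ms in groups.values() for m in ms]
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                ga, gb = a.split("_")[0], b.split("_")[0]
                if ga == gb:
                    loc = 0.45 if ga == "ADV" else 0.75
                else:
                    loc = 0.35
                table[(a, b)] = float(np.clip(rng.normal(loc, 0.05), 0, 1))

        def fn(a, b):
            return table[(a, b)] if (a, b) in table else table[(b, a)]

        res = leave_one_out(groups, fn)
        shifts = {gid: abs(r.tau_opt - res.full.tau_opt) for gid, r in res.omitted}
        assert shifts["ADV"] == max(shifts.values())
        assert shifts["ADV"] > max(v for k, v in shifts.items() if k != "ADV")

    def test_two_groups_rejected(self):
        with pytest.raises(ConfigurationError):
            leave_one_out({"A": ["a1", "a2"], "B": ["b1", "b2"]}, lambda a, b: 0.5)


class TestModelFrontend:
    def test_welch_gate_blocks_and_force_overrides(self):
        rng = np.random.default_rng(89)

        def noise(a, b):
            return float(rng.random())

        groups = {"G1": [f"a{i}" for i in range(8)], "G2": [f"b{i}" for i in range(8)]}
        model = SimilarityThresholdModel(groups, noise)
        with pytest.raises(WelchGateError):
            model.fit()
        res = model.fit(force=True)
        assert res.welch.pvalue >= model.alpha

    def test_fit_summary_mentions_thresholds(self):
        def fn(a, b):
            base = 0.8 if a[0] == b[0] else 0.2
            return base + 0.01 * (int(a[1]) + int(b[1]))

        groups = {"X": ["x1", "x2", "x3"], "Y": ["y1", "y2", "y3"]}
        res = SimilarityThresholdModel(groups, fn).fit()
        text = res.summary()
        assert "tau_opt" in text and "Welch" in text
        assert res.tau_n <= res.tau_opt <= res.tau_s
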