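"""Mann-Whitney U correctness and group reporting."""

import itertools

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from rcdprofiler import RcdError, group_report, mann_whitney_u
from rcdprofiler.io import read_species_manifest
from rcdprofiler.stats import group_summary


def brute_force_p(x, y):
    """Two-tailed p by literal enumeration of all rank assignments."""
    pooled = sorted(x) + sorted(y)
    n = len(x)
    ranks = {v: r + 1 for r, v in enumerate(sorted(pooled))}
    u_obs = sum(ranks[v] for v in x) - n * (n + 1) / 2
    us = []
    for combo in itertools.combinations(range(len(pooled)), n):
        r_sum = sum(c + 1 for c in combo)
        us.append(r_sum - n * (n + 1) / 2)
    us = np.array(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return min(1.0, 2 * min(p_le, p_ge))


class TestMannWhitney:
    def test_extreme_separation_exact_p(self):
        c = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert c.U == 0.0
        assert c.method == "exact"
        assert c.p_two_tailed == pytest.approx(0.1)

    def test_identical_samples_p_one(self):
        c = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert c.p_two_tailed == 1.0

    def test_label_symmetry(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            x = rng.integers(0, 12, size=6).tolist()
            y = rng.integers(0, 12, size=9).tolist()
            assert mann_whitney_u(x, y).p_two_tailed == pytest.approx(
                mann_whitney_u(y, x).p_two_tailed
            )

    def test_u_statistics_sum_to_product(self):
        rng = np.random.default_rng(15)
        for _ in range(20):
            x = rng.integers(0, 8, size=7).tolist()
            y = rng.integers(0, 8, size=5).tolist()
            ua = mann_whitney_u(x, y).U
            ub = mann_whitney_u(y, x).U
            assert ua + ub == pytest.approx(len(x) * len(y))

    def test_exact_matches_enumeration_all_3v3_splits(self):
        pool = [3, 7, 11, 18, 25, 40]
        for combo in itertools.combinations(range(6), 3):
            x = [pool[i] for i in combo]
            y = [pool[i] for i in range(6) if i not in combo]
            c = mann_whitney_u(x, y)
            assert c.method == "exact"
            assert c.p_two_tailed == pytest.approx(brute_force_p(x, y))

    def test_exact_matches_scipy(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            x = rng.permutation(100)[:8].tolist()
            y = rng.permutation(100)[50:][: 9].tolist()
            if len(set(x) | set(y)) < len(x) + len(y):
                continue
            ours = mann_whitney_u(x, y)
            ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert ours.p_two_tailed == pytest.approx(ref.pvalue)

    def test_approx_close_to_exact_at_crossover(self):
        rng = np.random.default_rng(33)
        from rcdprofiler.stats import approx_p_two_tailed, exact_p_two_tailed

        for _ in range(10):
            vals = rng.permutation(2000)[:40]
            x, y = vals[:20].astype(float), vals[20:].astype(float)
            c = mann_whitney_u(x, y)
            assert c.method == "exact"
            approx = approx_p_two_tailed(c.U, x, y)
            assert abs(approx - c.p_two_tailed) <= 0.01

    def test_ties_use_normal_approximation(self):
        c = mann_whitney_u([1, 1, 2], [2, 3, 3])
        assert c.method == "normal_approx"
        ref = mannwhitneyu([1, 1, 2], [2, 3, 3], alternative="two-sided",
                           method="asymptotic", use_continuity=True)
        assert c.p_two_tailed == pytest.approx(ref.pvalue, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(RcdError):
            mann_whitney_u([], [1, 2])

    def test_single_member_group_sd_flagged(self):
        c = mann_whitney_u([5], [1, 2, 3])
        assert c.sd_a == 0.0 and "sd_a undefined" in c.notes


class TestGroupReport:
    def test_toy_counts_match_hand_computation(self, toy_manifest_path):
        records = read_species_manifest(toy_manifest_path)
        # hand-built counts: aerobic species get 6, others get 2
        counts = {
            r.species_id: 6 if r.mito_class.value == "aerobic" else 2
            for r in records
        }
        summary, comps = group_report(counts, records, "mito_class")
        assert summary.loc["aerobic", "mean"] == pytest.approx(6.0)
        (c,) = comps
        assert (c.label_a, c.label_b) == ("diverged", "aerobic")
        assert c.mean_a == pytest.approx(2.0)
        assert c.n_a == 5 and c.n_b == 7

    def test_lifestyle_report_has_both_contrasts(self, toy_manifest_path):
        records = read_species_manifest(toy_manifest_path)
        rng = np.random.default_rng(2)
        counts = {r.species_id: int(rng.integers(0, 10)) for r in records}
        summary, comps = group_report(counts, records, "lifestyle")
        pairs = {(c.label_a, c.label_b) for c in comps}
        assert pairs == {
            ("parasitic", "non_parasitic"),
            ("multicellular", "free_living"),
        }

    def test_custom_partition_all_pairs(self, toy_manifest_path):
        records = read_species_manifest(toy_manifest_path)
        labels = {
            r.species_id: ("g1" if i % 2 else "g2")
            for i, r in enumerate(records)
        }
        counts = {r.species_id: i for i, r in enumerate(records)}
        _, comps = group_report(counts, records, labels)
        assert len(comps) == 1

    def test_empty_group_excluded_with_warning(self):
        counts = {"A": 1, "B": 2}
        labels = {"A": "g1", "B": "g1", "C": "g2"}
        with pytest.warns(UserWarning, match="g2"):
            summary = group_summary(counts, labels)
        assert list(summary.index) == ["g1"]

    def test_null_pvalues_roughly_uniform(self):
        """Type-I control: no group effect -> p approx Uniform(0,1)."""
        rng = np.random.default_rng(123)
        ps = []
        for _ in range(300):
            x = rng.binomial(10, 0.5, size=12).tolist()
            y = rng.binomial(10, 0.5, size=12).tolist()
            ps.append(mann_whitney_u(x, y).p_two_tailed)
        rej = np.mean(np.array(ps) < 0.05)
        assert 0.0 <= rej <= 0.1
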