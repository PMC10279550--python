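import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from protraj.subsets import (
    bh_adjust,
    cluster_proteins,
    driver_summary,
    kruskal_wallis,
    subset_patient_score,
)

from oracles import bh_stepup_brute, kruskal_h_brute, random_intercept_scores_closed_form


def _template_features(rng, n_patients=40, n_per_template=6, noise=0.1):
    """Proteins generated from 3 orthogonal patient-profile templates."""
    templates = rng.normal(size=(3, n_patients)) * 3.0
    cols, truth = {}, []
    for s in range(3):
        for j in range(n_per_template):
            cols[f"SQ{s}{j}"] = templates[s] + rng.normal(0, noise, n_patients)
            truth.append(s)
    df = pd.DataFrame(cols, index=[f"P{i}" for i in range(n_patients)])
    return df, np.array(truth)


class TestClusterProteins:
    def test_three_templates_recovered_exactly(self):
        rng = np.random.default_rng(0)
        df, truth = _template_features(rng)
        part = cluster_proteins(df, "intercept", k_range=(2, 6), seed=1)
        assert part.k == 3
        from protraj.synthetic import truth_alignment

        assert truth_alignment(part.labels.to_numpy(), truth) == 1.0
        # letters assigned by decreasing size then protein id
        assert set(part.sizes) == {"A", "B", "C"}

    def test_axes_are_isolated(self):
        rng = np.random.default_rng(1)
        icpt, _ = _template_features(rng)
        slope_a, _ = _template_features(np.random.default_rng(2))
        slope_b, _ = _template_features(np.random.default_rng(3))
        fa = pd.concat({"intercept": icpt, "slope": slope_a}, axis=1)
        fb = pd.concat({"intercept": icpt, "slope": slope_b}, axis=1)
        pa = cluster_proteins(fa, "intercept", seed=4)
        pb = cluster_proteins(fb, "intercept", seed=4)
        pd.testing.assert_series_equal(pa.labels, pb.labels)

    def test_partition_membership_invariant_to_protein_order(self):
        rng = np.random.default_rng(5)
        df, _ = _template_features(rng)
        shuffled = df[list(rng.permutation(df.columns))]
        a = cluster_proteins(df, "intercept", seed=6)
        b = cluster_proteins(shuffled, "intercept", seed=6)
        # same proteins grouped together, whatever the presentation order
        for letter in a.sizes:
            members = set(a.labels.index[a.labels == letter])
            assert any(members == set(b.labels.index[b.labels == l])
                       for l in b.sizes)


class TestKruskalWallis:
    def test_hand_example_h_7_2(self):
        values = [1, 2, 3, 4, 5, 6, 7, 8, 9]
        groups = [0, 0, 0, 1, 1, 1, 2, 2, 2]
        h, df, p = kruskal_wallis(values, groups)
        assert h == pytest.approx(7.2, abs=1e-12)
        assert df == 2
        assert p == pytest.approx(stats.chi2.sf(7.2, 2), abs=1e-12)

    def test_matches_rank_sum_oracle_with_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            values = rng.integers(0, 6, size=30).astype(float)  # heavy ties
            groups = rng.integers(0, 3, size=30)
            if len(np.unique(groups)) < 2 or np.ptp(values) == 0:
                continue
            h, _, _ = kruskal_wallis(values, groups)
            assert h == pytest.approx(kruskal_h_brute(values, groups), abs=1e-9)

    def test_identical_observations_give_h_zero_p_one(self):
        h, _, p = kruskal_wallis([5.0] * 9, [0, 0, 0, 1, 1, 1, 2, 2, 2])
        assert h == 0.0 and p == 1.0

    def test_two_groups_equal_wilcoxon_chi_square(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=12)
        g = np.array([0] * 6 + [1] * 6)
        h, _, p = kruskal_wallis(x, g)
        # two-group KW is the square of the normal-approx rank-sum statistic
        z = stats.ranksums(x[g == 0], x[g == 1]).statistic
        n1 = n2 = 6
        n = 12
        # exact variance correction: H = z'^2 with z' from the U statistic
        u = stats.mannwhitneyu(x[g == 0], x[g == 1],
                               alternative="two-sided", method="asymptotic")
        zexact = (u.statistic - n1 * n2 / 2) / np.sqrt(n1 * n2 * (n + 1) / 12)
        assert h == pytest.approx(zexact**2, abs=1e-9)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=24)
        g = rng.integers(0, 3, size=24)
        h1, _, _ = kruskal_wallis(x, g)
        h2, _, _ = kruskal_wallis(np.exp(2 * x) + 5, g)
        assert h1 == pytest.approx(h2, abs=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            kruskal_wallis([1.0, 2.0], [0, 0])


class TestBHAdjust:
    def test_stepup_hand_example(self):
        p = np.array([0.005, 0.011, 0.02, 0.04, 0.13])
        q, reject = bh_adjust(p)
        assert reject.tolist() == [True, True, True, True, False]
        np.testing.assert_array_equal(reject, bh_stepup_brute(p))

    def test_equal_pvalues_share_their_q(self):
        q, _ = bh_adjust(np.full(7, 0.03))
        np.testing.assert_allclose(q, 0.03)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=60))
    def test_matches_stepup_oracle_and_dominates_bonferroni(self, pvals):
        p = np.array(pvals)
        q, reject = bh_adjust(p)
        np.testing.assert_array_equal(reject, bh_stepup_brute(p))
        assert np.all(q >= p - 1e-15)
        bonf = p <= 0.05 / len(p)
        assert np.all(reject[bonf])  # BH rejections superset Bonferroni's

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError, match="p-values"):
            bh_adjust(np.array([0.2, 1.4]))

    def test_null_fdr_controlled(self):
        """Uniform null p-values: empirical FDR below 0.05 + 2 MC SE."""
        rng = np.random.default_rng(10)
        fdrs = []
        for _ in range(200):
            p = rng.uniform(size=2000)
            _, reject = bh_adjust(p)
            fdrs.append(reject.mean() if reject.any() else 0.0)
        mc_se = np.std(fdrs, ddof=1) / np.sqrt(len(fdrs))
        assert np.mean(fdrs) <= 0.05 + 2 * mc_se


class TestDriverSummary:
    def _setup(self, rng, contrast_subset=0):
        n = 60
        z = pd.Series(rng.integers(1, 4, size=n), index=[f"P{i}" for i in range(n)])
        cols, letters = {}, {}
        for s in range(3):
            for j in range(8):
                base = rng.normal(0, 1, n)
                if s == contrast_subset:
                    base += z.to_numpy() * 2.0  # subphenotype-driven
                cols[f"SQ{s}{j}"] = base
        df = pd.DataFrame(cols, index=z.index)
        part_labels = pd.Series(
            [chr(65 + int(c[2])) for c in df.columns], index=df.columns)
        from protraj.subsets import ProteinSubsetPartition

        part = ProteinSubsetPartition("intercept", part_labels, 3,
                                      {l: 8 for l in "ABC"}, pd.DataFrame())
        return df, z, part

    def test_contrast_subset_has_highest_significant_fraction(self):
        rng = np.random.default_rng(11)
        df, z, part = self._setup(rng)
        drv = driver_summary(part, df, z)
        frac = drv.per_subset.set_index("subset")["fraction_significant"]
        assert frac["A"] == 1.0
        assert frac["A"] > frac["B"] and frac["A"] > frac["C"]
        top = drv.top_drivers["A"]
        assert (top["q"].diff().dropna() >= -1e-15).all()

    def test_permuted_labels_collapse_fractions(self):
        rng = np.random.default_rng(12)
        df, z, part = self._setup(rng)
        zperm = pd.Series(rng.permutation(z.to_numpy()), index=z.index)
        drv = driver_summary(part, df, zperm)
        assert drv.per_protein["significant"].mean() <= 0.10


class TestSubsetPatientScore:
    def test_matches_balanced_closed_form_oracle(self):
        rng = np.random.default_rng(13)
        n, P = 30, 6
        x = rng.normal(0, 1, (n, 1)) + rng.normal(0, 0.7, (n, P))
        df = pd.DataFrame(x, index=[f"P{i}" for i in range(n)],
                          columns=[f"SQ{j}" for j in range(P)])
        scores, collapsed = subset_patient_score(df, df.columns)
        assert not collapsed
        oracle = random_intercept_scores_closed_form(x)
        np.testing.assert_allclose(scores.to_numpy(), oracle, atol=1e-8)

    def test_noiseless_scores_equal_patient_constants(self):
        c = np.linspace(-1, 1, 12)
        df = pd.DataFrame(np.tile(c[:, None], (1, 5)) + 1e-10,
                          index=[f"P{i}" for i in range(12)],
                          columns=list("abcde"))
        scores, _ = subset_patient_score(df, df.columns)
        np.testing.assert_allclose(scores.to_numpy(), c + 1e-10, atol=1e-6)

    def test_single_protein_subset_is_shrunken_column(self):
        rng = np.random.default_rng(14)
        df = pd.DataFrame({"SQ1": rng.normal(size=20)},
                          index=[f"P{i}" for i in range(20)])
        scores, collapsed = subset_patient_score(df, ["SQ1"])
        # with one observation per patient the model cannot separate
        # within from between variance; scores stay finite and centered
        assert np.isfinite(scores).all()

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            subset_patient_score(pd.DataFrame({"a": [1.0]}), [])
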