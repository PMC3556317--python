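import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as ss
from statsmodels.stats.multitest import multipletests

from triohet.de import (
    Contrast,
    adjust_fdr,
    call_degs,
    de_test,
    equalize_library_sizes,
    estimate_dispersion,
    exact_nb_test,
    exact_nb_test_single,
    partition_degs,
    trio_contrasts,
)
from triohet.simulate import SimulationConfig, simulate_trio_counts

from conftest import make_matrix


def oracle_exact_p(sum_a, sum_b, n_a, n_b, phi, mu=1.0):
    """Brute-force conditional two-sided p via scipy NB pmf products.

    Enumerates every split of the total; independent of the package's
    beta-binomial formula.  The result does not depend on mu.
    """
    total = sum_a + sum_b
    if total == 0:
        return 1.0
    a = np.arange(total + 1)
    if phi == 0:
        joint = ss.poisson.pmf(a, n_a * mu) * ss.poisson.pmf(total - a, n_b * mu)
    else:
        r = 1.0 / phi
        p_shared = r / (r + mu)
        joint = ss.nbinom.pmf(a, n_a * r, p_shared) * ss.nbinom.pmf(
            total - a, n_b * r, p_shared
        )
    cond = joint / joint.sum()
    obs = cond[sum_a]
    return float(min(1.0, cond[cond <= obs * (1.0 + 1e-9)].sum()))


class TestExactNbTest:
    def test_balanced_split_gives_p_one(self):
        assert exact_nb_test_single(10, 10, 2, 2, 0.1) == pytest.approx(1.0)

    def test_poisson_reduction_closed_form(self):
        # dispersion 0, sums (10, 0), equal groups -> 2 * (1/2)^10
        p = exact_nb_test_single(10, 0, 2, 2, 0.0)
        assert p == pytest.approx(2 * 0.5**10, rel=1e-9)

    @pytest.mark.parametrize("phi", [0.0, 0.05, 0.3, 1.0])
    def test_matches_enumeration_oracle(self, phi):
        rng = np.random.default_rng(4)
        for _ in range(40):
            total = int(rng.integers(1, 51))
            sum_a = int(rng.integers(0, total + 1))
            p = exact_nb_test_single(sum_a, total - sum_a, 2, 2, phi)
            assert p == pytest.approx(
                oracle_exact_p(sum_a, total - sum_a, 2, 2, phi), abs=1e-10
            )

    def test_group_swap_symmetry(self):
        for sa, sb, phi in [(3, 17, 0.2), (0, 9, 0.0), (25, 5, 0.5)]:
            assert exact_nb_test_single(sa, sb, 2, 2, phi) == pytest.approx(
                exact_nb_test_single(sb, sa, 2, 2, phi), rel=1e-12
            )

    def test_unequal_group_sizes(self):
        p = exact_nb_test_single(5, 30, 2, 3, 0.1)
        assert p == pytest.approx(oracle_exact_p(5, 30, 2, 3, 0.1), abs=1e-10)

    def test_zero_total(self):
        assert exact_nb_test_single(0, 0, 2, 2, 0.1) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            exact_nb_test(np.array([[-1, 2]]), np.array([[1, 1]]), np.array([0.1]))

    def test_null_pvalues_conservative(self):
        # small-count null: P(p <= alpha) should not exceed alpha (discreteness)
        rng = np.random.default_rng(8)
        phi = 0.1
        r = 1 / phi
        mu = 5.0
        counts_a = rng.negative_binomial(r, r / (r + mu), size=(2000, 2))
        counts_b = rng.negative_binomial(r, r / (r + mu), size=(2000, 2))
        p = exact_nb_test(counts_a, counts_b, np.full(2000, phi))
        for alpha in (0.01, 0.05, 0.1, 0.25, 0.5):
            frac = (p <= alpha).mean()
            assert frac <= alpha + 2.5 * np.sqrt(alpha * (1 - alpha) / 2000)

    def test_power_at_large_effect(self):
        # |log2FC| = 2, phi = 0.1, mean 100, n = 2/group -> detection > 0.5
        rng = np.random.default_rng(9)
        n_genes = 300
        r = 1 / 0.1

        def draw(mu, size):
            return rng.negative_binomial(r, r / (r + mu), size=size)

        ca = draw(100.0, (n_genes, 2))
        cb = draw(400.0, (n_genes, 2))
        p = exact_nb_test(ca, cb, np.full(n_genes, 0.1))
        lfc = np.log2((cb.mean(axis=1) + 0.5) / (ca.mean(axis=1) + 0.5))
        fdr = adjust_fdr(p)
        detected = ((fdr <= 0.05) & (np.abs(lfc) >= 1)).mean()
        assert detected > 0.5


class TestAdjustFdr:
    def test_forced_arithmetic(self):
        q = adjust_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_single_p(self):
        assert adjust_fdr([0.37])[0] == pytest.approx(0.37)

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            adjust_fdr([0.1, np.nan])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_matches_statsmodels(self, pvals):
        ours = adjust_fdr(pvals)
        theirs = multipletests(pvals, method="fdr_bh")[1]
        assert np.allclose(ours, theirs, atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_sorted_order(self, pvals):
        p = np.asarray(pvals)
        q = adjust_fdr(p)[np.argsort(p, kind="stable")]
        assert (np.diff(q) >= -1e-12).all()


class TestDispersion:
    def test_hand_computed_mom_before_shrinkage(self):
        # P1 counts [10, 20], F1 [30, 40] (gene 0); gene 1 balances columns
        counts = np.array(
            [
                [10, 20, 7, 7, 30, 40],
                [40, 30, 7, 7, 20, 10],
            ]
        )
        m = make_matrix(counts)
        contrast = trio_contrasts(m, "tillering")["R/F"]
        phi = estimate_dispersion(m, contrast, prior_df=0.0)
        expected = ((50 - 15) / 15**2 + (50 - 35) / 35**2) / 2.0
        assert phi.iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_poisson_data_low_dispersion(self):
        cfg = SimulationConfig(
            n_genes=2000, stages=("s1",), dispersion=0.0, frac_null=1.0, seed=21,
            replicate_effect_sd=0.0,
        )
        m, _ = simulate_trio_counts(cfg)
        contrast = trio_contrasts(m, "s1")["R/F"]
        phi = estimate_dispersion(m, contrast)
        assert phi.median() <= 0.05

    def test_all_zero_gene_gets_common_value(self):
        counts = np.array(
            [
                [0, 0, 0, 0, 0, 0],
                [10, 20, 7, 7, 30, 40],
                [40, 30, 7, 7, 20, 10],
            ]
        )
        m = make_matrix(counts)
        contrast = trio_contrasts(m, "tillering")["R/F"]
        phi = estimate_dispersion(m, contrast, prior_df=0.0)
        informative = phi.iloc[1:]
        assert phi.iloc[0] == pytest.approx(np.mean(informative))

    def test_single_replicate_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            Contrast("R/F", ["a"], ["b", "c"], "s1")


class TestCallDegs:
    def _frame(self, fdr, lfc):
        return pd.DataFrame({"log2fc": [lfc], "fdr": [fdr], "pvalue": [fdr]})

    def test_threshold_conjunction(self):
        assert not call_degs(self._frame(0.04, 0.9))["is_deg"].iloc[0]

    def test_boundary_inclusive(self):
        assert call_degs(self._frame(0.05, -1.0))["is_deg"].iloc[0]

    def test_custom_thresholds(self):
        assert call_degs(self._frame(0.09, 0.5), fdr_max=0.1, min_abs_log2fc=0.5)[
            "is_deg"
        ].iloc[0]


class TestPartition:
    def test_set_algebra_example(self):
        part = partition_degs(
            {"R/F": {"g1", "g2"}, "X/F": {"g2", "g3"}, "R/X": {"g3"}}, stage="s1"
        )
        assert part.dg_hp == {"g1", "g2", "g3"}
        assert part.dg_pp == {"g3"}
        assert part.total == 3
        assert part.venn["100"] == 1  # g1
        assert part.venn["110"] == 1  # g2
        assert part.venn["011"] == 1  # g3

    def test_empty_sets(self):
        part = partition_degs({"R/F": set(), "X/F": set(), "R/X": set()}, "s1")
        assert sum(part.venn.values()) == 0
        assert part.total == 0

    def test_missing_contrast_rejected(self):
        with pytest.raises(ValueError, match="missing contrast"):
            partition_degs({"R/F": set(), "X/F": set()}, "s1")

    @given(
        rf=st.sets(st.integers(0, 30)),
        xf=st.sets(st.integers(0, 30)),
        rx=st.sets(st.integers(0, 30)),
    )
    @settings(max_examples=100, deadline=None)
    def test_inclusion_exclusion(self, rf, xf, rx):
        part = partition_degs({"R/F": rf, "X/F": xf, "R/X": rx}, "s1")
        assert len(part.dg_hp) == len(rf) + len(xf) - len(rf & xf)
        assert sum(part.venn.values()) == len(rf | xf | rx)
        assert part.total == len(part.dg_hp | part.dg_pp)


class TestDeTest:
    def test_equalize_library_sizes(self):
        counts = pd.DataFrame({"a": [100, 100], "b": [400, 400]})
        eq = equalize_library_sizes(counts)
        assert eq["a"].sum() == eq["b"].sum() == 400  # geometric mean of 200, 800

    def test_null_false_positive_rate(self):
        cfg = SimulationConfig(n_genes=1500, stages=("s1",), frac_null=1.0, seed=31)
        m, _ = simulate_trio_counts(cfg)
        contrast = trio_contrasts(m, "s1")["R/F"]
        res = de_test(m, contrast)
        fp = res["is_deg"].mean()
        assert fp <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / len(res))

    def test_orientation_hybrid_over_parent(self):
        # hybrid (group B) higher -> positive log2fc; flat genes anchor the
        # library sizes so normalization cannot erase the difference
        counts = np.array(
            [
                [10, 10, 10, 10, 80, 80],
                [1000, 1000, 1000, 1000, 1000, 1000],
                [1000, 1000, 1000, 1000, 1000, 1000],
            ]
        )
        m = make_matrix(counts)
        contrast = trio_contrasts(m, "tillering")["R/F"]
        res = de_test(m, contrast)
        assert res["log2fc"].iloc[0] > 1.5
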