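"""Site-rate machinery: masking, discrete gamma, pruning likelihoods,
posterior means, normalization, classification, sequence mapping."""

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import gamma as gamma_dist
from scipy.stats import spearmanr

from stoichseq.jtt import AA_INDEX, AMINO_ACIDS, jtt_model
from stoichseq.nitrogen import Habitat
from stoichseq.simulate import simulate_alignment, simulate_yule_tree
from stoichseq.site_rates import (
    FAST,
    INTERMEDIATE,
    SLOW,
    Alignment,
    SiteRateModel,
    classify_sites,
    discretize_gamma,
    estimate_alpha,
    map_rates_to_sequence,
    mask_columns,
    normalize_scores,
    posterior_mean_rates,
    site_likelihood,
    site_log_likelihoods,
)
from stoichseq.trees import Tree, TreeNode


@pytest.fixture(scope="module")
def model():
    return jtt_model()


class TestMasking:
    def _aln(self, cols):
        rows = ["".join(col[i] for col in cols) for i in range(len(cols[0]))]
        return Alignment(ids=tuple(f"s{i}" for i in range(len(rows))), rows=tuple(rows))

    def test_below_ten_percent_excluded(self):
        col = ["A"] + ["-"] * 19        # 5% ungapped
        aln = self._aln([col])
        assert mask_columns(aln).tolist() == [False]

    def test_exactly_ten_percent_included(self):
        col = ["A", "A"] + ["-"] * 18   # 10% ungapped: strict "<" keeps it
        aln = self._aln([col])
        assert mask_columns(aln).tolist() == [True]

    def test_fully_ungapped_included(self):
        aln = self._aln([["A"] * 20])
        assert mask_columns(aln).tolist() == [True]


class TestDiscreteGamma:
    def test_single_category_is_unit_rate(self):
        rm = discretize_gamma(0.5, 1)
        assert rm.rates.tolist() == [1.0]

    def test_mean_one_and_increasing(self):
        for alpha in (0.2, 0.7, 1.0, 3.0):
            rm = discretize_gamma(alpha, 16)
            assert rm.rates @ rm.probabilities == pytest.approx(1.0, abs=1e-12)
            assert np.all(np.diff(rm.rates) > 0)

    def test_large_alpha_collapses_to_one(self):
        rm = discretize_gamma(100.0, 4)
        assert np.allclose(rm.rates, 1.0, atol=0.2)

    def test_exponential_case_against_quadrature(self):
        # alpha = 1: conditional means of Exp(1) within quantile slices
        alpha, k = 1.0, 4
        rm = discretize_gamma(alpha, k)
        edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a=alpha, scale=1.0)
        expected = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            hi_ = hi if np.isfinite(hi) else 60.0
            num, _ = integrate.quad(lambda x: x * np.exp(-x), lo, hi_)
            expected.append(num * k)
        expected = np.array(expected) / (np.mean(expected))
        assert np.allclose(rm.rates, expected, atol=1e-6)


def two_leaf_tree(t1: float, t2: float) -> Tree:
    return Tree(
        root=TreeNode(
            children=[TreeNode(name="a", length=t1), TreeNode(name="b", length=t2)]
        )
    )


def quartet_tree(lengths) -> Tree:
    t1, t2, t3, t4, t5 = lengths
    inner = TreeNode(
        length=t5,
        children=[TreeNode(name="c", length=t3), TreeNode(name="d", length=t4)],
    )
    return Tree(
        root=TreeNode(
            children=[TreeNode(name="a", length=t1), TreeNode(name="b", length=t2), inner]
        )
    )


def brute_force_quartet_likelihood(column, tree, model, rate):
    """Exhaustive sum over the two internal-node states."""
    pi = model.frequencies
    a, b, inner = tree.root.children
    c, d = inner.children
    obs = dict(zip(["a", "b", "c", "d"], column))

    def p_leaf(state, leaf, length):
        ch = obs[leaf]
        if ch == "-":
            return 1.0
        return model.transition(length, rate)[state, AA_INDEX[ch]]

    total = 0.0
    p_inner = model.transition(inner.length, rate)
    for root_state in range(20):
        for inner_state in range(20):
            total += (
                pi[root_state]
                * p_leaf(root_state, "a", a.length)
                * p_leaf(root_state, "b", b.length)
                * p_inner[root_state, inner_state]
                * p_leaf(inner_state, "c", c.length)
                * p_leaf(inner_state, "d", d.length)
            )
    return total


class TestPruning:
    def test_single_leaf_returns_equilibrium_frequency(self, model):
        tree = Tree(root=TreeNode(name="a"))
        assert site_likelihood(["R"], tree, model) == pytest.approx(
            model.frequencies[AA_INDEX["R"]], abs=1e-15
        )

    def test_two_leaf_closed_form(self, model):
        t1, t2, rate = 0.3, 0.7, 1.3
        tree = two_leaf_tree(t1, t2)
        pi = model.frequencies
        p1 = model.transition(t1, rate)
        p2 = model.transition(t2, rate)
        ia, ib = AA_INDEX["A"], AA_INDEX["W"]
        expected = float(np.sum(pi * p1[:, ia] * p2[:, ib]))
        assert site_likelihood(["A", "W"], tree, model, rate) == pytest.approx(
            expected, rel=1e-12
        )

    def test_gap_is_missing_data(self, model):
        tree = two_leaf_tree(0.2, 0.4)
        # a gap at one leaf marginalizes it out: likelihood = pi of the other
        assert site_likelihood(["R", "-"], tree, model) == pytest.approx(
            model.frequencies[AA_INDEX["R"]], rel=1e-12
        )

    def test_quartet_matches_exhaustive_enumeration(self, model):
        rng = np.random.default_rng(4)
        aa = list(AMINO_ACIDS)
        for _ in range(25):
            lengths = rng.uniform(0.05, 1.5, size=5)
            rate = float(rng.uniform(0.1, 3.0))
            column = list(rng.choice(aa + ["-"], size=4, p=[0.045] * 20 + [0.1]))
            if all(ch == "-" for ch in column):
                continue
            tree = quartet_tree(lengths)
            ours = site_likelihood(column, tree, model, rate)
            brute = brute_force_quartet_likelihood(column, tree, model, rate)
            assert ours == pytest.approx(brute, rel=1e-10, abs=1e-300)

    def test_scale_confounding(self, model):
        """Doubling branch lengths while halving the rate is a no-op."""
        rng = np.random.default_rng(9)
        lengths = rng.uniform(0.1, 1.0, size=5)
        tree1 = quartet_tree(lengths)
        tree2 = quartet_tree(lengths * 2)
        col = ["A", "R", "N", "D"]
        l1 = site_likelihood(col, tree1, model, rate=1.0)
        l2 = site_likelihood(col, tree2, model, rate=0.5)
        assert l1 == pytest.approx(l2, rel=1e-12)


class TestPosteriorRates:
    def test_single_category_gives_unit_rates(self, model):
        tree = simulate_yule_tree(8, seed=0)
        sim = simulate_alignment(tree, 50, alpha=1.0, seed=1)
        res = SiteRateModel(sim.alignment, n_categories=1, alpha=1.0).fit()
        assert np.allclose(res.rates, 1.0)

    def test_conserved_below_variable_column(self, model):
        tree = simulate_yule_tree(12, seed=2)
        names = tree.leaf_names
        conserved = "A" * len(names)
        rng = np.random.default_rng(0)
        variable = "".join(rng.choice(list(AMINO_ACIDS), size=len(names)))
        aln = Alignment(
            ids=tuple(names),
            rows=tuple(c + v for c, v in zip(conserved, variable)),
        )
        rm = discretize_gamma(0.7, 8)
        ll = site_log_likelihoods(aln.encoded(), names, tree, model, rm.rates)
        rates = posterior_mean_rates(ll, rm)
        assert rates[0] < rates[1]
        assert np.all(rates >= rm.rates.min() - 1e-12)
        assert np.all(rates <= rm.rates.max() + 1e-12)

    def test_alpha_recovery_within_broad_band(self, model):
        tree = simulate_yule_tree(40, seed=5)
        sim = simulate_alignment(tree, 400, alpha=0.5, seed=6)
        alpha, _ = estimate_alpha(
            sim.alignment.encoded(), sim.alignment.ids, tree, model
        )
        assert 0.3 <= alpha <= 0.8

    def test_boundary_alpha_warns(self, model):
        tree = simulate_yule_tree(6, seed=7)
        sim = simulate_alignment(tree, 40, alpha=1.0, seed=8)
        with pytest.warns(UserWarning, match="boundary"):
            estimate_alpha(
                sim.alignment.encoded(), sim.alignment.ids, tree, model,
                n_categories=4, grid=[5.0, 10.0],
            )


class TestNormalizationAndClasses:
    def test_constant_rates_all_zero(self):
        assert normalize_scores(np.ones(5)).tolist() == [0.0] * 5

    def test_two_point_standardization(self):
        assert normalize_scores(np.array([1.0, 3.0])).tolist() == [-1.0, 1.0]

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(1)
        z = normalize_scores(rng.gamma(0.7, size=500))
        assert abs(z.mean()) < 1e-12
        assert abs(z.std() - 1.0) < 1e-12

    def test_too_few_columns(self):
        with pytest.raises(ValueError):
            normalize_scores(np.array([1.0]))

    @pytest.mark.parametrize(
        "z,expected",
        [(-0.75, SLOW), (0.75, FAST), (0.0, INTERMEDIATE), (2.1, FAST), (-2.0, SLOW),
         (-0.74, INTERMEDIATE), (0.74, INTERMEDIATE)],
    )
    def test_cutoffs_inclusive(self, z, expected):
        assert classify_sites(np.array([z]))[0] == expected


class TestSequenceMapping:
    def test_gapless_row_fully_classified(self):
        aln = Alignment(ids=("a", "b"), rows=("ARN", "ARN"))
        included = np.array([True, True, True])
        classes = np.array([SLOW, FAST, INTERMEDIATE], dtype=object)
        assert map_rates_to_sequence(aln, "a", included, classes) == {
            1: SLOW, 2: FAST, 3: INTERMEDIATE,
        }

    def test_excluded_column_omitted(self):
        aln = Alignment(ids=("a", "b"), rows=("A-C", "AAC"))
        included = np.array([True, False, True])
        classes = np.array([SLOW, None, FAST], dtype=object)
        # row "a" has residues in columns 1 and 3 only
        assert map_rates_to_sequence(aln, "a", included, classes) == {1: SLOW, 2: FAST}
        # for row "b" the middle residue falls in an excluded column
        assert map_rates_to_sequence(aln, "b", included, classes) == {1: SLOW, 3: FAST}

    def test_unknown_id_raises(self):
        aln = Alignment(ids=("a", "b"), rows=("AA", "AA"))
        with pytest.raises(KeyError):
            map_rates_to_sequence(aln, "zz", np.array([True, True]),
                                  np.array([SLOW, SLOW], dtype=object))


class TestEndToEndFit:
    def test_rate_recovery_on_one_seed(self):
        tree = simulate_yule_tree(40, seed=11)
        sim = simulate_alignment(tree, 400, alpha=0.7, seed=12)
        res = SiteRateModel(sim.alignment, n_categories=16).fit()
        rho = spearmanr(sim.true_rates, res.rates).statistic
        assert rho >= 0.8

    def test_results_normalization_contract(self):
        tree = simulate_yule_tree(10, seed=13)
        sim = simulate_alignment(tree, 80, alpha=0.7, seed=14)
        res = SiteRateModel(sim.alignment, n_categories=8, alpha=0.7).fit()
        z = res.zscores[res.included]
        assert abs(z.mean()) < 1e-12 and abs(z.std() - 1.0) < 1e-12

    def test_summary_and_tsv_round_trip(self, tmp_path):
        import pandas as pd

        tree = simulate_yule_tree(6, seed=15)
        sim = simulate_alignment(tree, 40, alpha=1.0, seed=16)
        res = SiteRateModel(sim.alignment, n_categories=4, alpha=1.0).fit()
        assert "gamma shape alpha" in res.summary()
        out = tmp_path / "rates.tsv"
        res.to_tsv(out)
        df = pd.read_csv(out, sep="\t")
        assert list(df.columns) == ["column_index", "included", "rate", "z", "class"]
        assert len(df) == 40
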