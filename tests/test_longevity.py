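"""Lifespan correlation machinery: log-log Pearson, partial correlation,
independent contrasts, multilinear q shares and the median split."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from redoxusage._aa import AMINO_ACIDS
from redoxusage.errors import DataError
from redoxusage.longevity import (loglog_pearson, median_split,
                                  median_split_effect, multilinear_q,
                                  partial_correlation, pic_contrasts,
                                  pic_correlation)
from redoxusage.reference import species_table
from redoxusage.simulate import generate_tree, simulate_brownian


def newick(s: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=s, schema="newick")


class TestLogLogPearson:
    def test_power_law_perfect(self):
        x = np.array([1.0, 2.0, 5.0, 10.0, 30.0])
        res = loglog_pearson(x, x**2.7)
        assert res.r == pytest.approx(1.0)

    def test_reference_panel_mass_correlation(self):
        """Lifespan vs body mass across the 20-species panel: r = 0.933."""
        df = species_table()
        res = loglog_pearson(df.lifespan_years, df.body_mass_kg)
        assert round(res.r, 3) == 0.933
        assert res.p < 1e-8
        assert res.n == 20

    def test_log_base_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(0, 1, 30)
        y = rng.lognormal(0, 1, 30)
        r10 = loglog_pearson(x, y).r
        rn = np.corrcoef(np.log(x), np.log(y))[0, 1]
        assert r10 == pytest.approx(rn, abs=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(DataError):
            loglog_pearson([1.0, -1.0, 2.0], [1.0, 2.0, 3.0])

    def test_zero_variance_flagged(self):
        with pytest.raises(DataError):
            loglog_pearson([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestPartialCorrelation:
    def test_matches_closed_form(self, rng):
        """The result equals the first-order formula computed from the three
        pairwise Pearson correlations."""
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        z = rng.normal(size=25)
        r_xy = np.corrcoef(x, y)[0, 1]
        r_xz = np.corrcoef(x, z)[0, 1]
        r_yz = np.corrcoef(y, z)[0, 1]
        expect = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        assert partial_correlation(x, y, z).r == pytest.approx(expect)

    def test_formula_arithmetic(self):
        """r_xy = r_xz = r_yz = 0.9 gives (0.9 - 0.81)/(1 - 0.81) = 0.4737."""
        r = (0.9 - 0.9 * 0.9) / np.sqrt((1 - 0.81) * (1 - 0.81))
        assert r == pytest.approx(0.4737, abs=1e-4)

    def test_equals_residual_on_residual(self, rng):
        x = rng.normal(size=40)
        z = rng.normal(size=40)
        y = 0.5 * x + 0.7 * z + rng.normal(size=40)
        res = partial_correlation(x, y, z)
        bx = np.polyfit(z, x, 1)
        by = np.polyfit(z, y, 1)
        rx = x - np.polyval(bx, z)
        ry = y - np.polyval(by, z)
        assert res.r == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-10)

    def test_partial_of_x_with_y_given_y_is_zero(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        res = partial_correlation(x, y, y + 0.0)
        assert res.r == pytest.approx(0.0, abs=1e-8)

    def test_minimum_n(self):
        with pytest.raises(DataError):
            partial_correlation([1, 2, 3], [1, 2, 3], [3, 2, 1])


class TestPicContrasts:
    def test_cherry_equal_values_zero(self):
        cs = pic_contrasts(newick("(A:1,B:1);"), {"A": 2.0, "B": 2.0})
        assert cs.contrasts == pytest.approx([0.0])

    def test_cherry_closed_form(self):
        cs = pic_contrasts(newick("(A:1,B:1);"), {"A": 3.0, "B": 1.0})
        assert abs(cs.contrasts[0]) == pytest.approx(2 / np.sqrt(2))

    def test_three_tip_augmented_branch(self):
        """After pruning a cherry with branches 1 and 1, its parent branch is
        lengthened by 1*1/2 = 0.5, so the second contrast variance is
        (1 + 0.5) + 2 = 3.5."""
        cs = pic_contrasts(newick("((A:1,B:1):1,C:2);"),
                           {"A": 3.0, "B": 1.0, "C": 0.0})
        assert cs.variances[1] == pytest.approx(3.5)
        # ancestral value of the cherry is the weighted mean (equal weights)
        assert abs(cs.contrasts[1]) == pytest.approx(2.0 / np.sqrt(3.5))

    def test_contrast_count(self):
        tree = generate_tree([f"s{i}" for i in range(12)], seed=4)
        vals = {f"s{i}": float(i) for i in range(12)}
        cs = pic_contrasts(tree, vals)
        assert len(cs.contrasts) == 11

    def test_all_equal_tips_all_zero(self):
        tree = generate_tree([f"s{i}" for i in range(8)], seed=2)
        cs = pic_contrasts(tree, {f"s{i}": 5.0 for i in range(8)})
        np.testing.assert_allclose(cs.contrasts, 0.0, atol=1e-12)

    def test_missing_tip_value(self):
        with pytest.raises(DataError):
            pic_contrasts(newick("(A:1,B:1);"), {"A": 1.0})


class TestPicCorrelation:
    def test_proportional_traits(self):
        tree = generate_tree([f"s{i}" for i in range(10)], seed=9)
        x = {f"s{i}": float(i) * 1.3 + 1 for i in range(10)}
        y = {k: 2.0 * v for k, v in x.items()}
        res = pic_correlation(tree, x, y)
        assert res.r == pytest.approx(1.0)

    def test_star_limit_matches_plain_correlation(self):
        """On a star-like tree (equal branches) contrasts reduce to scaled
        tip differences, so the PIC correlation approaches the ordinary
        correlation of independent data."""
        labels = [f"s{i}" for i in range(40)]
        star = "(" + ",".join(f"{l}:1" for l in labels) + ");"
        tree = newick(star)
        rng = np.random.default_rng(5)
        xv = rng.normal(size=40)
        yv = 0.7 * xv + rng.normal(size=40) * np.sqrt(1 - 0.49)
        res = pic_correlation(tree, dict(zip(labels, xv)),
                              dict(zip(labels, yv)))
        plain = np.corrcoef(xv, yv)[0, 1]
        assert res.r == pytest.approx(plain, abs=0.15)

    def test_brownian_recovery(self):
        """Correlated Brownian traits (rho = 0.7) on a 100-tip tree: the
        mean recovered contrast correlation over 200 replicates is within
        0.05 of the generating value."""
        tree = generate_tree([f"s{i}" for i in range(100)], seed=7)
        rng = np.random.default_rng(21)
        rs = []
        for _ in range(200):
            x, y = simulate_brownian(tree, rho=0.7, rng=rng)
            rs.append(pic_correlation(tree, x, y).r)
        assert np.mean(rs) == pytest.approx(0.7, abs=0.05)


class TestMultilinearQ:
    def test_shares_sum_to_100(self, rng):
        X = pd.DataFrame(rng.dirichlet(np.ones(20), 30),
                         columns=list(AMINO_ACIDS))
        q = multilinear_q(X, rng.lognormal(1, 1, 30))
        assert q.sum() == pytest.approx(100.0, abs=1e-6)
        assert (q >= 0).all()

    def test_single_informative_predictor_dominates(self):
        """With independent predictor columns, a lifespan driven by one
        amino acid alone concentrates the q share on it."""
        rng = np.random.default_rng(3)
        n = 200
        X = pd.DataFrame(rng.uniform(0.01, 0.09, (n, 20)),
                         columns=list(AMINO_ACIDS))
        lifespan = 10 ** (20.0 * X["C"] + rng.normal(0, 0.02, n))
        q = multilinear_q(X, lifespan)
        assert q["C"] > 80

    def test_compositional_signal_still_ranks_first(self):
        """On compositional (simplex) frequencies the minimum-norm fit
        spreads the coefficient mass, but the driving amino acid still
        carries the largest share."""
        rng = np.random.default_rng(4)
        n = 200
        X = pd.DataFrame(rng.dirichlet(np.ones(20) * 50, n),
                         columns=list(AMINO_ACIDS))
        lifespan = 10 ** (50.0 * X["C"] + rng.normal(0, 0.02, n))
        q = multilinear_q(X, lifespan)
        assert q.idxmax() == "C"

    def test_row_permutation_invariance(self, rng):
        X = pd.DataFrame(rng.dirichlet(np.ones(20), 25),
                         columns=list(AMINO_ACIDS))
        y = rng.lognormal(0, 1, 25)
        q1 = multilinear_q(X, y)
        perm = rng.permutation(25)
        q2 = multilinear_q(X.iloc[perm], y[perm])
        pd.testing.assert_series_equal(q1, q2, atol=1e-8)

    def test_r2_share_mode(self, rng):
        X = pd.DataFrame(rng.dirichlet(np.ones(20), 30),
                         columns=list(AMINO_ACIDS))
        q = multilinear_q(X, rng.lognormal(0, 1, 30), mode="r2-share",
                          n_orderings=20, seed=1)
        assert q.sum() == pytest.approx(100.0, abs=1e-6)


class TestMedianSplit:
    def test_reference_panel_split_sizes(self):
        """Median-longevity split of the 20-animal panel: 10 long, 10 short,
        with the boundary between 6 and 15 years."""
        df = species_table()
        long_ids, short_ids = median_split(df.lifespan_years)
        assert len(long_ids) == 10 and len(short_ids) == 10
        assert df.loc[long_ids, "lifespan_years"].min() == 15
        assert df.loc[short_ids, "lifespan_years"].max() == 6

    def test_identical_groups_unity(self):
        lifespans = pd.Series([1, 2, 10, 20.0], index=list("abcd"))
        freqs = pd.DataFrame(np.full((4, 20), 0.05), index=list("abcd"),
                             columns=list(AMINO_ACIDS))
        eff = median_split_effect(freqs, lifespans)
        np.testing.assert_allclose(eff["ratio"], 1.0)

    def test_arithmetic_example(self):
        lifespans = pd.Series([30, 20, 1, 2.0], index=list("abcd"))
        freqs = pd.DataFrame(
            {"C": [0.02, 0.02, 0.04, 0.04]}, index=list("abcd"))
        eff = median_split_effect(freqs, lifespans)
        assert eff["ratio"]["C"] == pytest.approx(0.5)
        assert set(eff.attrs["long_ids"]) == {"a", "b"}

    def test_minimum_n(self):
        with pytest.raises(DataError):
            median_split(pd.Series([1.0, 2.0]))
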