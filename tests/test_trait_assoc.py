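"""Mass residuals, ME-trait correlation, jack-knife screen, multiple R, GS."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import coexphys.simulate as sim
from coexphys.network import eigengene
from coexphys.trait_assoc import (
    ModuleTraitAssociation,
    association_summary,
    correlate_me_traits,
    gene_significance,
    hub_gs,
    jackknife_support,
    mass_residuals,
    multiple_correlation,
    range_spread,
)

S = lambda v, idx=None: pd.Series(
    v, index=idx or [f"s{i}" for i in range(len(v))])


class TestMassResiduals:
    def test_exact_linear_trait_gives_zero_residuals(self):
        mass = S([1.0, 2.0, 3.0, 4.0])
        assert np.allclose(mass_residuals(2 * mass, mass), 0.0)

    def test_mass_independent_trait_is_centered(self):
        mass = S([1.0, 2.0, 3.0, 4.0])
        trait = S([5.0, 5.0, 5.0, 5.0])
        assert np.allclose(mass_residuals(trait, mass), 0.0)
        trait2 = S([1.0, -1.0, 1.0, -1.0])
        resid = mass_residuals(trait2, mass)
        assert resid.mean() == pytest.approx(0.0, abs=1e-12)

    def test_matches_ols_oracle(self):
        mass = S([1.0, 2.0, 3.0])
        trait = S([2.0, 4.0, 7.0])
        slope, intercept, *_ = stats.linregress(mass, trait)
        want = trait - (intercept + slope * mass)
        assert np.allclose(mass_residuals(trait, mass), want)

    def test_zero_mass_variance_raises(self):
        with pytest.raises(ValueError):
            mass_residuals(S([1.0, 2.0, 3.0]), S([5.0, 5.0, 5.0]))


class TestCorrelateMETraits:
    def test_self_and_reversed_correlations(self):
        me = pd.DataFrame({"ME1": [1.0, 2, 3, 4, 5],
                           "ME2": [5.0, 4, 3, 2, 1]})
        traits = pd.DataFrame({"t": [1.0, 2, 3, 4, 5]})
        res = correlate_me_traits(me, traits).set_index("module")
        assert res.loc["ME1", "r"] == pytest.approx(1.0)
        assert res.loc["ME2", "r"] == pytest.approx(-1.0)

    def test_five_point_toy_matches_t_distribution_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.2, 1.9, 3.4, 4.1, 4.6])
        me = pd.DataFrame({"ME1": x})
        res = correlate_me_traits(me, pd.DataFrame({"t": y}))
        r = np.corrcoef(x, y)[0, 1]
        tstat = r * np.sqrt(3 / (1 - r ** 2))
        p = 2 * stats.t.sf(abs(tstat), 3)
        assert res.loc[0, "r"] == pytest.approx(r)
        assert res.loc[0, "p"] == pytest.approx(p)

    def test_bh_is_within_trait(self):
        rng = np.random.default_rng(0)
        me = pd.DataFrame(rng.normal(size=(30, 4)),
                          columns=[f"ME{i}" for i in range(4)])
        traits = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        res = correlate_me_traits(me, traits)
        from coexphys.diffexp import bh_adjust
        for t in ("a", "b"):
            sub = res[res["trait"] == t]
            assert np.allclose(sub["q"], bh_adjust(sub["p"].to_numpy()))


class TestJackknife:
    def test_deterministic_relation_has_full_support(self):
        x = S(np.linspace(0, 1, 40))
        support, ok = jackknife_support(x, 2 * x + 1, seed=0)
        assert support == 100 and ok

    def test_null_false_pass_rate_small(self):
        passes = 0
        rng = np.random.default_rng(1)
        for _ in range(100):
            x = S(rng.normal(size=40))
            y = S(rng.normal(size=40))
            _, ok = jackknife_support(x, y, seed=rng)
            passes += ok
        assert passes / 100 < 0.05

    def test_power_at_strong_correlation(self):
        rng = np.random.default_rng(2)
        passes = 0
        for _ in range(50):
            x = rng.normal(size=20)
            y = 0.7 * x + np.sqrt(1 - 0.49) * rng.normal(size=20)
            _, ok = jackknife_support(S(x), S(y), seed=rng)
            passes += ok
        assert passes / 50 > 0.8

    def test_small_n_raises(self):
        x = S(np.arange(8.0))
        with pytest.raises(ValueError):
            jackknife_support(x, x)


def fabricate_outlier_correlation(seed, trait_name="WAM", p_target=0.045):
    """Build a dataset whose only significant ME-trait correlation is
    fabricated by one outlier sample.

    A zero-coupling dataset is simulated; the sample with the most extreme
    eigengene score gets the smallest trait shift that drags the full-sample
    correlation to nominal significance (binary search on the shift, applied
    through inject_outlier). Returns (ME, shifted trait) or None when the
    unshifted data are already significant (a chance correlation, not an
    outlier artifact) or the target is not reached.
    """
    from coexphys.preprocess import normalize

    cfg = sim.SimulationConfig(
        n_genes=60, module_sizes=(30,), trait_weights={},
        design=(("TE", 12, 20),), dispersion=0.2,
        de_acclim_fraction=0.0, de_pop_fraction=0.0, seed=seed)
    ds = sim.simulate_dataset(cfg)
    expr = normalize(ds.counts).log_values
    me, _ = eigengene(expr, expr.index[:30])
    trait = ds.traits[trait_name]
    if stats.pearsonr(me, trait)[1] < 0.05:
        return None
    jstar = int(np.argmax(np.abs(me.to_numpy())))
    sign = np.sign(me.iloc[jstar])
    lo, hi = 0.0, 20.0 * trait.std()
    for _ in range(40):
        mid = (lo + hi) / 2
        t = trait.copy()
        t.iloc[jstar] += sign * mid
        if stats.pearsonr(me, t)[1] < p_target:
            hi = mid
        else:
            lo = mid
    shifted = sim.inject_outlier(ds, jstar, trait_shift=sign * hi,
                                 expression_logshift=0.0)
    t = shifted.traits[trait_name]
    if stats.pearsonr(me, t)[1] >= 0.05:
        return None
    return me, t


class TestOutlierScreen:
    """A single high-leverage sample can fabricate a nominally significant
    module-trait correlation; the jack-knife screen should reject it."""

    def test_fabricated_correlations_are_rejected(self):
        created = rejected = 0
        for seed in range(40):
            case = fabricate_outlier_correlation(seed)
            if case is None:
                continue
            me, trait = case
            created += 1
            _, ok = jackknife_support(me, trait, seed=seed)
            rejected += not ok
        assert created >= 20
        assert rejected / created >= 0.9


class TestMultipleCorrelation:
    def test_single_regressor_equals_abs_r(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=25)
        y = -0.6 * x + rng.normal(size=25)
        R = multiple_correlation(pd.Series(y), pd.DataFrame({"ME1": x}))
        assert R == pytest.approx(abs(np.corrcoef(x, y)[0, 1]))

    def test_exact_linear_combination_gives_one(self):
        rng = np.random.default_rng(4)
        mes = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        y = 2 * mes["a"] - 3 * mes["b"] + 1
        assert multiple_correlation(y, mes) == pytest.approx(1.0)

    def test_r_squared_matches_ols_oracle(self):
        rng = np.random.default_rng(5)
        mes = pd.DataFrame(rng.normal(size=(40, 3)),
                           columns=["a", "b", "c"])
        y = S(rng.normal(size=40), idx=list(mes.index))
        import statsmodels.api as smod
        ols = smod.OLS(y.to_numpy(),
                       smod.add_constant(mes.to_numpy())).fit()
        R = multiple_correlation(y, mes)
        assert R ** 2 == pytest.approx(ols.rsquared, abs=1e-12)

    def test_monotone_in_added_regressors(self):
        rng = np.random.default_rng(6)
        mes = pd.DataFrame(rng.normal(size=(40, 3)),
                           columns=["a", "b", "c"])
        y = S(0.5 * mes["a"] + rng.normal(size=40), idx=list(mes.index))
        rs = [multiple_correlation(y, mes[cols])
              for cols in (["a"], ["a", "b"], ["a", "b", "c"])]
        assert rs[0] <= rs[1] + 1e-12 <= rs[2] + 2e-12

    def test_too_many_regressors_raise(self):
        rng = np.random.default_rng(7)
        mes = pd.DataFrame(rng.normal(size=(5, 4)))
        with pytest.raises(ValueError):
            multiple_correlation(pd.Series(rng.normal(size=5)), mes)


class TestGeneSignificance:
    def test_trait_equal_to_gene_profile(self):
        rng = np.random.default_rng(8)
        expr = pd.DataFrame(rng.normal(size=(5, 20)),
                            index=list("abcde"),
                            columns=[f"s{i}" for i in range(20)])
        trait = expr.loc["c"]
        gs = gene_significance(expr, trait)
        assert gs["c"] == pytest.approx(1.0)

    def test_sign_flip_of_trait_flips_gs(self):
        rng = np.random.default_rng(9)
        expr = pd.DataFrame(rng.normal(size=(4, 15)),
                            columns=[f"s{i}" for i in range(15)])
        trait = S(rng.normal(size=15))
        assert np.allclose(gene_significance(expr, trait),
                           -gene_significance(expr, -trait))

    def test_matches_direct_pearson(self):
        rng = np.random.default_rng(10)
        expr = pd.DataFrame(rng.normal(size=(6, 12)),
                            columns=[f"s{i}" for i in range(12)])
        trait = S(rng.normal(size=12))
        gs = gene_significance(expr, trait)
        for g in expr.index:
            assert gs[g] == pytest.approx(
                stats.pearsonr(expr.loc[g], trait)[0])

    def test_hub_gs_reports_max_and_positive_fraction(self):
        gs = pd.Series([0.9, -0.95, 0.2], index=["a", "b", "c"])
        gene, value, pos_frac = hub_gs(gs, pd.Index(["a", "b", "c"]))
        assert gene == "b" and value == pytest.approx(-0.95)
        assert pos_frac == pytest.approx(2 / 3)


class TestSummaryAndRangeSpread:
    HEART_R = [0.49, -0.53, 0.50, 0.53, 0.55, -0.57,
               -0.65, -0.56, -0.56, -0.55, -0.54, -0.56]
    BRAIN_R = [-0.60, 0.58, -0.60, -0.57, -0.67, -0.70]

    @pytest.mark.parametrize("rs,expected", [(HEART_R, 0.55),
                                             (BRAIN_R, 0.62)])
    def test_average_row_from_reported_coefficients(self, rs, expected):
        df = pd.DataFrame({"trait": [f"t{i}" for i in range(len(rs))],
                           "module": [f"ME{i}" for i in range(len(rs))],
                           "r": rs})
        out = association_summary(df)
        avg = out[out["trait"] == "AVERAGE"]["r"].iloc[0]
        assert avg == pytest.approx(expected)

    def test_single_row_average_is_abs(self):
        df = pd.DataFrame({"trait": ["t"], "module": ["ME1"], "r": [-0.4]})
        out = association_summary(df)
        assert out[out["trait"] == "AVERAGE"]["r"].iloc[0] == 0.40

    def test_range_spread_values(self):
        assert range_spread([3.0, 3.0, 3.0]) == 0.0
        assert range_spread([1.0, 15.0]) == 14.0
        with pytest.raises(ValueError):
            range_spread([-1.0, 5.0])


class TestEstimator:
    def test_planted_weights_found_with_correct_sign(self):
        """Coupled modules pass the screen with sign-correct correlations."""
        rng = np.random.default_rng(11)
        n = 60
        hits = 0
        for seed in range(10):
            r2 = np.random.default_rng(seed + 100)
            e = r2.normal(size=(2, n))
            mes = pd.DataFrame({"ME1": e[0], "ME2": e[1]},
                               index=[f"s{i}" for i in range(n)])
            traits = pd.DataFrame(
                {"WAM": 1.0 * e[0] + r2.normal(size=n),
                 "CT_max": -1.0 * e[1] + r2.normal(size=n)},
                index=mes.index)
            assoc = ModuleTraitAssociation(seed=seed).fit(mes, traits)
            res = assoc.results_.set_index(["module", "trait"])
            ok = (res.loc[("ME1", "WAM"), "pass"]
                  and res.loc[("ME1", "WAM"), "r"] > 0
                  and res.loc[("ME2", "CT_max"), "pass"]
                  and res.loc[("ME2", "CT_max"), "r"] < 0)
            hits += ok
        assert hits >= 9

    def test_mass_covariate_defaults_apply(self):
        rng = np.random.default_rng(12)
        n = 40
        mes = pd.DataFrame({"ME1": rng.normal(size=n)},
                           index=[f"s{i}" for i in range(n)])
        mass = pd.Series(rng.lognormal(2.3, 0.3, size=n), index=mes.index)
        # trait is purely mass-driven: residual should decorrelate it
        traits = pd.DataFrame({"WAM": 3.0 * mass}, index=mes.index)
        samples = pd.DataFrame({"body_mass": mass, "heart_mass": mass / 500},
                               index=mes.index)
        assoc = ModuleTraitAssociation().fit(mes, traits, samples)
        assert np.allclose(assoc.residual_traits_["WAM"], 0.0, atol=1e-9)
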