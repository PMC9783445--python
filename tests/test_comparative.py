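import numpy as np
import pandas as pd
import pytest

from osteophylo.comparative import (
    PGLSFit,
    match_species,
    nagelkerke_pseudo_r2,
    pgls_fit,
    phylo_ancova,
    predict_body_mass,
    size_correct,
)
from osteophylo.synthetic import (
    TraitSimConfig,
    paint_regimes,
    simulate_traits,
    simulate_tree,
)
from osteophylo.trees import read_tree

from ._oracles import ols_fit


def star_tree(n, height=1.0):
    # effectively a star: binary caterpillar whose internal branches are
    # negligible (1e-9) and whose tip heights are all equal
    eps = 1e-9
    s = (
        f"(t{n - 1}:{height - (n - 2) * eps:.12g},"
        f"t{n}:{height - (n - 2) * eps:.12g})"
    )
    for i in range(n - 2, 0, -1):
        s = f"(t{i}:{height - (i - 1) * eps:.12g},{s}:{eps:.12g})"
    return read_tree(s + ";")


def bm_tip_vector(tree, sigma2, seed):
    traits = simulate_traits(
        tree, TraitSimConfig(model="BM", sigma2=sigma2, seed=seed)
    )
    return np.array([traits[nm] for nm in tree.tip_names()])


class TestPglsFit:
    def test_star_tree_equals_ols(self):
        tree = star_tree(30)
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(30), rng.normal(size=30)])
        y = 1.0 + 2.0 * X[:, 1] + rng.normal(size=30)
        fit = pgls_fit(y, X, tree)
        assert np.allclose(fit.beta, ols_fit(y, X), atol=1e-8)

    def test_lambda_recovered_high_under_bm(self):
        lams = []
        for rep in range(20):
            tree = simulate_tree(100, seed=200 + rep)
            y = bm_tip_vector(tree, 0.1, seed=rep)
            fit = pgls_fit(y, np.ones((100, 1)), tree)
            lams.append(fit.lambda_hat)
        assert np.mean(lams) >= 0.9

    def test_lambda_recovered_low_for_iid_noise(self):
        lams = []
        for rep in range(20):
            tree = simulate_tree(100, seed=300 + rep)
            rng = np.random.default_rng(rep)
            fit = pgls_fit(rng.normal(size=100), np.ones((100, 1)), tree)
            lams.append(fit.lambda_hat)
        assert np.mean(lams) <= 0.1

    def test_profile_likelihood_maximized_at_lambda_hat(self):
        tree = simulate_tree(60, seed=17)
        y = bm_tip_vector(tree, 0.05, seed=4)
        X = np.ones((60, 1))
        fit = pgls_fit(y, X, tree)
        for lam in (0.0, 0.25, 0.5, 0.75, 1.0):
            alt = pgls_fit(y, X, tree, lam=lam)
            assert fit.loglik >= alt.loglik - 1e-6

    def test_rank_deficient_design_rejected(self):
        tree = simulate_tree(20, seed=0)
        X = np.ones((20, 2))
        with pytest.raises(ValueError, match="rank-deficient"):
            pgls_fit(np.zeros(20), X, tree)


class TestPhyloAncova:
    @staticmethod
    def _grouped_data(seed, offset=0.0, n_tips=100):
        tree = simulate_tree(n_tips, seed=seed)
        rt = paint_regimes(tree, 6, seed=seed + 1, talpid_like=False)
        y = simulate_traits(
            tree, TraitSimConfig(model="BM", sigma2=0.02, seed=seed + 2)
        )
        names = tree.tip_names()
        group = pd.Series(
            [
                "subterranean"
                if rt.regime_of_tip[s] != "background"
                else "non_subterranean"
                for s in names
            ],
            index=names,
        )
        trait = pd.Series(
            [y[s] + (offset if group[s] == "subterranean" else 0.0)
             for s in names],
            index=names,
        )
        return tree, trait, group

    def test_strong_offset_detected(self):
        tree, trait, group = self._grouped_data(seed=21, offset=10.0)
        fit = phylo_ancova(trait, group, tree)
        assert fit.group_test["p"] < 1e-4

    def test_permuted_labels_uniform_p(self):
        ps = []
        for rep in range(60):
            tree, trait, group = self._grouped_data(seed=500 + rep)
            rng = np.random.default_rng(rep)
            permuted = pd.Series(
                rng.permutation(group.to_numpy()), index=group.index
            )
            if permuted.value_counts().min() < 3:
                continue
            fit = phylo_ancova(trait, permuted, tree)
            ps.append(fit.group_test["p"])
        ps = np.asarray(ps)
        # roughly uniform: unbiased mean and sensible spread
        assert abs(ps.mean() - 0.5) < 0.12
        assert (ps < 0.05).mean() < 0.15

    def test_covariate_coefficient_recovered(self):
        tree = simulate_tree(100, seed=33)
        names = tree.tip_names()
        rng = np.random.default_rng(3)
        log_mass = pd.Series(rng.normal(1.5, 0.6, 100), index=names)
        noise = bm_tip_vector(tree, 0.01, seed=9)
        trait = pd.Series(0.3 * log_mass.to_numpy() + noise, index=names)
        group = pd.Series(
            ["a"] * 50 + ["b"] * 50, index=names
        )
        fit = phylo_ancova(trait, group, tree, covariate=log_mass)
        slope, se = fit.beta[-1], fit.se[-1]
        assert abs(slope - 0.3) < 2 * se

    def test_small_group_refused(self):
        tree = simulate_tree(20, seed=1)
        names = tree.tip_names()
        trait = pd.Series(np.arange(20.0), index=names)
        group = pd.Series(["a"] * 18 + ["b"] * 2, index=names)
        with pytest.raises(ValueError, match="fewer than 3"):
            phylo_ancova(trait, group, tree)


class TestPseudoR2:
    @staticmethod
    def _fit_pair(n=40, signal=1.0, noise=1.0, seed=0):
        tree = star_tree(n)
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = signal * x + noise * rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        full = pgls_fit(y, X, tree)
        null = pgls_fit(y, np.ones((n, 1)), tree)
        return full, null

    def test_null_vs_itself_is_zero(self):
        _, null = self._fit_pair()
        assert nagelkerke_pseudo_r2(null, null) == 0.0

    def test_monotone_in_full_loglik(self):
        full, null = self._fit_pair()
        r2 = nagelkerke_pseudo_r2(full, null)
        boosted = PGLSFit(
            **{**full.__dict__, "loglik_ml": full.loglik_ml + 5.0}
        )
        assert nagelkerke_pseudo_r2(boosted, null) > r2

    def test_approaches_one_as_noise_vanishes(self):
        r2s = [
            nagelkerke_pseudo_r2(*self._fit_pair(noise=s, seed=2))
            for s in (1.0, 0.1, 1e-4)
        ]
        assert r2s[0] < r2s[1] < r2s[2]
        assert r2s[2] > 0.999

    def test_bounded(self):
        for seed in range(5):
            full, null = self._fit_pair(seed=seed)
            assert 0.0 <= nagelkerke_pseudo_r2(full, null) <= 1.0


class TestBodyMass:
    @staticmethod
    def _table(tree, noise_sd=0.0, seed=0, n_missing_mass=3):
        names = tree.tip_names()
        rng = np.random.default_rng(seed)
        log_csa = rng.normal(0.5, 0.5, len(names))
        log_mass = 1.0 + 1.5 * log_csa + rng.normal(0, noise_sd, len(names))
        table = pd.DataFrame(
            {"body_mass_g": 10.0**log_mass, "csa_mm2": 10.0**log_csa},
            index=pd.Index(names, name="species"),
        )
        table.iloc[:n_missing_mass, 0] = np.nan  # fossils: no database mass
        return table

    def test_noiseless_power_law_recovered(self):
        tree = simulate_tree(30, seed=8)
        table = self._table(tree, noise_sd=0.0)
        out, fit = predict_body_mass(table, tree)
        assert fit.beta[1] == pytest.approx(1.5, abs=1e-6)
        assert fit.pseudo_r2 > 0.999

    def test_noisy_slope_within_two_se(self):
        tree = simulate_tree(80, seed=9)
        table = self._table(tree, noise_sd=0.1, seed=1)
        _, fit = predict_body_mass(table, tree)
        assert abs(fit.beta[1] - 1.5) < 2 * fit.se[1]

    def test_fossil_rows_imputed_and_flagged(self):
        tree = simulate_tree(30, seed=8)
        table = self._table(tree, noise_sd=0.05, seed=2)
        out, _ = predict_body_mass(table, tree)
        fossils = table.index[table["body_mass_g"].isna()]
        assert out.loc[fossils, "body_mass_pred_g"].notna().all()
        assert out.loc[fossils, "body_mass_imputed"].all()

    def test_missing_csa_keeps_database_mass(self):
        tree = simulate_tree(30, seed=8)
        table = self._table(tree, noise_sd=0.05, seed=2, n_missing_mass=0)
        table.loc[table.index[5], "csa_mm2"] = np.nan
        out, _ = predict_body_mass(table, tree)
        sp = table.index[5]
        assert out.loc[sp, "body_mass_pred_g"] == table.loc[sp, "body_mass_g"]
        assert not out.loc[sp, "body_mass_imputed"]

    def test_too_few_knowns_rejected(self):
        tree = simulate_tree(12, seed=8)
        table = self._table(tree, n_missing_mass=8)
        with pytest.raises(ValueError, match=">= 10"):
            predict_body_mass(table, tree)


class TestSizeCorrect:
    def test_mass_independent_trait_residuals_centered(self):
        tree = simulate_tree(50, seed=12)
        names = tree.tip_names()
        rng = np.random.default_rng(0)
        trait = pd.Series(rng.normal(size=50), index=names)
        mass = pd.Series(10.0 ** rng.normal(1.5, 0.5, 50), index=names)
        resid, fit = size_correct(trait, mass, tree)
        centered = trait - trait.mean()
        assert np.corrcoef(resid, centered.loc[resid.index])[0, 1] > 0.95

    def test_exact_allometry_gives_zero_residuals(self):
        tree = simulate_tree(50, seed=12)
        names = tree.tip_names()
        rng = np.random.default_rng(1)
        mass = pd.Series(10.0 ** rng.normal(1.5, 0.5, 50), index=names)
        trait = 0.7 * np.log10(mass)
        resid, _ = size_correct(trait, mass, tree)
        assert np.allclose(resid, 0.0, atol=1e-8)

    def test_unit_rescaling_invariance(self):
        tree = simulate_tree(50, seed=12)
        names = tree.tip_names()
        rng = np.random.default_rng(2)
        mass_g = pd.Series(10.0 ** rng.normal(1.5, 0.5, 50), index=names)
        trait = pd.Series(
            0.4 * np.log10(mass_g) + rng.normal(0, 0.1, 50), index=names
        )
        r_g, _ = size_correct(trait, mass_g, tree)
        r_kg, _ = size_correct(trait, mass_g / 1000.0, tree)
        assert np.allclose(r_g, r_kg, atol=1e-6)


def test_match_species_report():
    tree = read_tree("((A:1,B:1):1,C:2);")
    report = match_species(tree, pd.Index(["A", "B", "X"]))
    assert report["matched"] == ["A", "B"]
    assert report["tree_only"] == ["C"]
    assert report["table_only"] == ["X"]
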