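"""Mixed-model estimation and inference, checked against independent oracles.

The REML fitter is validated against R's lme4 on a small cohort; slope
derivation is validated by the releveling identity; F-test machinery by a
power simulation against the package's own generator.
"""

import subprocess
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import taskspace as ts
from taskspace.mixed_model import ModelSpec

R_ORACLE = """
suppressMessages(library(lme4))
d <- read.delim(commandArgs(trailingOnly=TRUE)[1])
d$condition <- factor(d$condition)
contrasts(d$condition) <- contr.sum(nlevels(d$condition))
for (v in c("neuroticism","openness","conscientiousness","extraversion",
            "agreeableness","age","gender","mean_fd")) d[[v]] <- d[[v]] - mean(d[[v]])
m <- lmer(location ~ condition*(neuroticism+openness+conscientiousness+
          extraversion+agreeableness) + age + gender + mean_fd +
          (1|subject_id) + (1|family_id), data=d, REML=TRUE)
vc <- as.data.frame(VarCorr(m))
fe <- fixef(m)
vals <- c(vc$vcov[vc$grp=="subject_id"], vc$vcov[vc$grp=="family_id"],
          vc$vcov[vc$grp=="Residual"], as.numeric(logLik(m)),
          fe["(Intercept)"], fe["neuroticism"], fe["openness"], fe["conscientiousness"],
          fe["extraversion"], fe["agreeableness"], fe["age"], fe["gender"], fe["mean_fd"])
cat(sprintf("%.14g", vals), sep="\\n")
"""


@pytest.fixture(scope="module")
def planted_fit():
    cohort = ts.generate_cohort(200, seed=51)
    rng = np.random.default_rng(52)
    eff = ts.EffectSpec(trait_slopes=rng.normal(0, 0.01, size=(5, 13, 3)))
    table = ts.generate_coordinates(cohort, eff, seed=53)
    fit = ts.fit_state_space_model(table, "D2")
    return table, fit


class TestFitAgainstLme4:
    def test_matches_lme4_reml(self, tmp_path):
        """Variance components, fixed effects and REML loglik agree with lme4."""
        cohort = ts.generate_cohort(100, seed=61)
        eff = ts.EffectSpec.null().with_slope("agreeableness", "wm-2back", "D2", 0.03)
        table = ts.generate_coordinates(cohort, eff, seed=62)
        fit = ts.fit_state_space_model(table, "D2")

        tsv = tmp_path / "d2.tsv"
        table[table.dimension == "D2"].to_csv(tsv, sep="\t", index=False)
        rfile = tmp_path / "oracle.R"
        rfile.write_text(R_ORACLE)
        out = subprocess.run(
            ["Rscript", str(rfile), str(tsv)], capture_output=True, text=True, check=True
        )
        vals = [float(x) for x in out.stdout.split()]
        r_sub, r_fam, r_res, r_ll = vals[:4]
        r_fixed = vals[4:]

        assert fit.varcomps["subject"] == pytest.approx(r_sub, abs=1e-6)
        assert fit.varcomps["family"] == pytest.approx(r_fam, abs=1e-6)
        assert fit.varcomps["residual"] == pytest.approx(r_res, abs=1e-6)
        assert fit.loglik_reml == pytest.approx(r_ll, abs=1e-4)
        py = [fit.params["(Intercept)"]] + [fit.params[t] for t in ts.TRAITS] + [
            fit.params["age"], fit.params["gender"], fit.params["mean_fd"]
        ]
        assert np.allclose(py, r_fixed, atol=1e-6)


class TestFitBehaviour:
    def test_zero_family_variance_boundary(self):
        """sd_family=0 data: family varcomp hits the boundary, fixed effects match
        a fit in which the family factor duplicates the subject factor."""
        cohort = ts.generate_cohort(150, seed=71)
        eff = ts.EffectSpec.null(sd_family=0.0)
        table = ts.generate_coordinates(cohort, eff, seed=72)
        fit = ts.fit_state_space_model(table, "D1")
        assert fit.varcomps["family"] < 1e-5
        assert "family" in fit.boundary
        solo = table.copy()
        solo["family_id"] = solo["subject_id"]  # subject-only structure
        fit2 = ts.fit_state_space_model(solo, "D1")
        assert np.allclose(fit.params, fit2.params, atol=1e-6)

    def test_row_order_invariance(self, planted_fit):
        table, fit = planted_fit
        shuffled = table.sample(frac=1.0, random_state=0)
        fit2 = ts.fit_state_space_model(shuffled, "D2")
        # summation order differs, so agreement is to optimizer precision
        assert np.allclose(fit.params, fit2.params, atol=1e-7)
        assert fit.varcomps == pytest.approx(fit2.varcomps, rel=1e-4)

    def test_unbalanced_rows_dropped_not_padded(self, planted_fit):
        table, _ = planted_fit
        drop_subject = table["subject_id"].iloc[0]
        mask = ~((table.subject_id == drop_subject) & (table.condition == "motor-avg"))
        fit = ts.fit_state_space_model(table[mask], "D2")
        assert fit.n_obs == (table.dimension == "D2").sum() - 1

    def test_rank_deficient_design_names_columns(self, planted_fit):
        table, _ = planted_fit
        bad = table.copy()
        bad["gender"] = 1.0  # constant covariate -> zero column after centering
        with pytest.raises(ValueError, match="gender"):
            ts.fit_state_space_model(bad, "D2")

    def test_missing_columns_rejected(self, planted_fit):
        table, _ = planted_fit
        with pytest.raises(ValueError, match="openness"):
            ts.fit_state_space_model(table.drop(columns=["openness"]), "D2")

    def test_interaction_power_on_planted_slope(self):
        """A planted openness-by-condition slope (-0.02 rho per trait sd on
        the story condition, n=400) is detected at p<0.05 in most replicates;
        theoretical noncentral-F power at this design is ~0.92."""
        hits = 0
        n_reps = 50
        for rep in range(n_reps):
            cohort = ts.generate_cohort(400, seed=8000 + rep)
            eff = ts.EffectSpec.null().with_slope("openness", "language-story", "D3", -0.02)
            table = ts.generate_coordinates(cohort, eff, conditions=ts.CONDITIONS, seed=rep)
            fit = ts.fit_state_space_model(table, "D3")
            p = fit.ftests.set_index("term").loc["openness:condition", "p"]
            hits += p < 0.05
        assert hits / n_reps > 0.8


class TestTraitSlopes:
    def test_zero_interactions_give_constant_slopes(self, planted_fit):
        import dataclasses

        _, fit = planted_fit
        params = fit.params.copy()
        params[[c for c in params.index if ":condition[" in c]] = 0.0
        neutered = dataclasses.replace(fit, params=params)
        slopes = ts.trait_slopes_by_condition(neutered)
        for t in ts.TRAITS:
            est = slopes[slopes.trait == t]["estimate"]
            assert est.nunique() == 1
            assert est.iloc[0] == pytest.approx(params[t], abs=1e-12)

    def test_releveling_identity_spot_check(self, planted_fit):
        table, fit = planted_fit
        slopes = ts.trait_slopes_by_condition(fit)
        for c in ("motor-avg", "wm-2back"):
            refit = ts.fit_state_space_model(
                table, "D2", ModelSpec(coding="treatment", reference_condition=c)
            )
            for t in ts.TRAITS:
                s = slopes[(slopes.trait == t) & (slopes.condition == c)].iloc[0]
                assert s["estimate"] == pytest.approx(refit.params[t], abs=1e-8)

    def test_ci_contains_estimate_and_table_shape(self, planted_fit):
        _, fit = planted_fit
        slopes = ts.trait_slopes_by_condition(fit)
        assert len(slopes) == 5 * 13
        assert ((slopes.ci_lower <= slopes.estimate) & (slopes.estimate <= slopes.ci_upper)).all()
        assert (slopes.df >= 1).all()


class TestBonferroni:
    def test_headline_family_size(self):
        n, alpha = ts.bonferroni_alpha(13, 5, 3, 0.05)
        assert n == 1170
        assert alpha == pytest.approx(0.05 / 1170)

    def test_pair_enumeration_oracle(self):
        pairs = {(a, b) for i, a in enumerate(ts.CONDITIONS) for b in ts.CONDITIONS[i + 1:]}
        assert len(pairs) == 78
        n, _ = ts.bonferroni_alpha(len(ts.CONDITIONS), 5, 3)
        assert n == len(pairs) * 5 * 3

    def test_single_comparison(self):
        assert ts.bonferroni_alpha(2, 1, 1, 0.05) == (1, 0.05)

    @pytest.mark.parametrize("args", [(1, 5, 3, 0.05), (13, 5, 3, 0.0), (13, 5, 3, 1.0)])
    def test_preconditions(self, args):
        with pytest.raises(ValueError):
            ts.bonferroni_alpha(*args)


class TestFlagging:
    def test_alpha_boundaries(self, planted_fit):
        _, fit = planted_fit
        none = ts.flag_significant_interactions({"D2": fit}, alpha=1e-300)
        assert not none["significant"].any()
        every = ts.flag_significant_interactions({"D2": fit}, alpha=1.0)
        assert every["significant"].all()
        assert len(every) == 5

    def test_deterministic_given_fits(self, planted_fit):
        _, fit = planted_fit
        a = ts.flag_significant_interactions({"D2": fit}, alpha=0.01)
        b = ts.flag_significant_interactions({"D2": fit}, alpha=0.01)
        pd.testing.assert_frame_equal(a, b)


class TestStrongestDivergentPair:
    @staticmethod
    def _slope_table(tvals: dict) -> pd.DataFrame:
        rows = [
            {"trait": "agreeableness", "condition": c, "dimension": "D2", "t": t}
            for c, t in tvals.items()
        ]
        return pd.DataFrame(rows)

    def test_headline_example(self):
        tvals = {c: 0.0 for c in ts.CONDITIONS}
        tvals["wm-2back"] = 2.17
        tvals["motor-avg"] = -3.35
        pair = ts.strongest_divergent_pair(self._slope_table(tvals), "agreeableness", "D2")
        assert pair == ("wm-2back", "motor-avg")

    def test_tie_broken_by_catalogue_order(self, caplog):
        tvals = {c: 1.0 for c in ts.CONDITIONS}
        with caplog.at_level("WARNING"):
            pair = ts.strongest_divergent_pair(self._slope_table(tvals), "agreeableness", "D2")
        assert pair == (ts.CONDITIONS[0], ts.CONDITIONS[0])
        assert any("tie" in r.message.lower() for r in caplog.records)

    def test_matches_brute_force_scan(self, rng):
        for _ in range(20):
            tvals = dict(zip(ts.CONDITIONS, rng.normal(size=13)))
            pair = ts.strongest_divergent_pair(
                self._slope_table(tvals), "agreeableness", "D2"
            )
            assert pair == (max(tvals, key=tvals.get), min(tvals, key=tvals.get))
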