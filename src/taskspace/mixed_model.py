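"""Linear mixed models for state-space locations.

Per dimension of brain variation, the model is

    location ~ condition + trait_1..5 + trait:condition interactions
               + age + gender + meanFD + (1 | subject) + (1 | family) + eps

estimated by REML. Because every subject belongs to exactly one family the
two random-intercept factors are nested, which makes the marginal
covariance block-diagonal by family; the fitter exploits that structure, so
models with thousands of observations fit in well under a second.

Inference follows the lmerTest/emmeans conventions without depending on
them: the condition factor is deviation (sum-to-zero) coded and continuous
predictors are mean-centered, so Wald F-tests on coefficient blocks are
Type-III tests; denominator degrees of freedom use the Satterthwaite
approximation computed from finite differences of the REML criterion; and
per-condition trait slopes (simple slopes / estimated marginal trends) are
linear combinations of fixed effects with Satterthwaite t intervals, hence
invariant to the factor coding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats
from scipy.optimize import minimize

from .conditions import CONDITIONS, TRAITS, UnknownConditionError

__all__ = [
    "ModelSpec",
    "ModelFit",
    "fit_state_space_model",
    "trait_slopes_by_condition",
    "bonferroni_alpha",
    "flag_significant_interactions",
    "strongest_divergent_pair",
]

logger = logging.getLogger(__name__)

_DF_CAP = 1e7  # effectively-infinite denominator df


@dataclass(frozen=True)
class ModelSpec:
    """Fixed- and random-effect layout of the per-dimension model."""

    traits: tuple[str, ...] = TRAITS
    covariates: tuple[str, ...] = ("age", "gender", "mean_fd")
    coding: str = "deviation"  # or "treatment" (used by the releveling oracle)
    reference_condition: str | None = None
    reml: bool = True

    def __post_init__(self):
        if len(self.traits) != 5:
            raise ValueError("the model uses exactly five trait predictors")
        if self.coding not in ("deviation", "treatment"):
            raise ValueError("coding must be 'deviation' or 'treatment'")


def _ordered_levels(observed) -> list[str]:
    cat = [c for c in CONDITIONS if c in observed]
    extra = sorted(set(observed) - set(CONDITIONS))
    return cat + extra


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def _build_design(df: pd.DataFrame, spec: ModelSpec):
    """Design matrix with named columns; factor coding per spec."""
    levels = _ordered_levels(df["condition"].unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 observed conditions")
    ref = spec.reference_condition if spec.reference_condition is not None else levels[-1]
    if ref not in levels:
        raise UnknownConditionError(f"reference condition {ref!r} not observed")
    nonref = [l for l in levels if l != ref]

    n = len(df)
    cond = df["condition"].to_numpy()
    cols: dict[str, np.ndarray] = {"(Intercept)": np.ones(n)}
    cond_cols = {}
    for l in nonref:
        col = (cond == l).astype(float)
        if spec.coding == "deviation":
            col = col - (cond == ref).astype(float)
        cond_cols[l] = col
        cols[f"condition[{l}]"] = col
    trait_c = {}
    for t in spec.traits:
        v = df[t].to_numpy(dtype=float)
        trait_c[t] = v - v.mean()
        cols[t] = trait_c[t]
    for t in spec.traits:
        for l in nonref:
            cols[f"{t}:condition[{l}]"] = trait_c[t] * cond_cols[l]
    for k in spec.covariates:
        v = df[k].to_numpy(dtype=float)
        cols[k] = v - v.mean()

    names = list(cols)
    X = np.column_stack([cols[c] for c in names])
    # rank check, naming offending columns
    _, R = np.linalg.qr(X)
    d = np.abs(np.diag(R))
    bad = [names[i] for i in np.flatnonzero(d < 1e-8 * d.max())]
    if bad:
        raise ValueError(f"rank-deficient fixed-effect design; collinear columns: {bad}")

    terms: dict[str, list[int]] = {"condition": [names.index(f"condition[{l}]") for l in nonref]}
    for t in spec.traits:
        terms[t] = [names.index(t)]
        terms[f"{t}:condition"] = [names.index(f"{t}:condition[{l}]") for l in nonref]
    for k in spec.covariates:
        terms[k] = [names.index(k)]
    return X, names, terms, levels, ref, nonref


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------

class _REMLProblem:
    """Profiled REML for y = Xb + u_subject + u_family + eps.

    Variance ratios gamma = (sd_subject^2, sd_family^2) / sd_noise^2 are
    optimized; sd_noise^2 and the fixed effects are profiled out. The
    marginal covariance is block-diagonal by family; blocks of equal size
    are batched through vectorized Cholesky factorizations.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, subject: np.ndarray, family: np.ndarray):
        self.n, self.p = X.shape
        self.n_subjects = len(pd.unique(subject))
        self.n_families = len(pd.unique(family))
        order = np.argsort(family, kind="stable")
        Xo, yo, so, fo = X[order], y[order], subject[order], family[order]
        # split into family blocks; families sharing the same within-block
        # subject pattern share one covariance factorization per evaluation
        # (balanced designs collapse to two patterns: singletons and pairs)
        bounds = np.flatnonzero(np.r_[True, fo[1:] != fo[:-1], True])
        by_pattern: dict[bytes, list] = {}
        patterns: dict[bytes, np.ndarray] = {}
        for a, b in zip(bounds[:-1], bounds[1:]):
            S = (so[a:b, None] == so[None, a:b]).astype(float)
            key = S.tobytes()
            patterns[key] = S
            by_pattern.setdefault(key, []).append((Xo[a:b], np.r_[yo[a:b]]))
        self.batches = []
        for key, items in by_pattern.items():
            # rhs = [X | y] per block, pre-stacked as (n_block, m*(p+1))
            rhs = np.stack(
                [np.column_stack([Xb, yb]) for Xb, yb in items], axis=1
            )  # (nb, m, p+1)
            m = rhs.shape[1]
            self.batches.append((patterns[key], m, rhs.reshape(rhs.shape[0], -1)))

    def _assemble(self, gs: float, gf: float):
        """Accumulate logdet(Vt), X'Vt^-1 X, X'Vt^-1 y, y'Vt^-1 y."""
        p = self.p
        G = np.zeros((p + 1, p + 1))
        logdetV = 0.0
        for S, m, rhs in self.batches:
            nb = S.shape[0]
            Vt = np.eye(nb) + gs * S + gf
            L = np.linalg.cholesky(Vt)
            logdetV += 2.0 * m * np.sum(np.log(np.diag(L)))
            w = sla.solve_triangular(L, rhs, lower=True)  # whitened rows
            W = w.reshape(nb * m, p + 1)
            G += W.T @ W
        A = G[:p, :p]
        bvec = G[:p, p]
        q = G[p, p]
        return logdetV, A, bvec, q

    def profiled(self, gamma) -> dict:
        gs, gf = max(float(gamma[0]), 0.0), max(float(gamma[1]), 0.0)
        logdetV, A, bvec, q = self._assemble(gs, gf)
        cf = sla.cho_factor(A, lower=True)
        logdetA = 2.0 * np.sum(np.log(np.diag(cf[0])))
        beta = sla.cho_solve(cf, bvec)
        rss = max(q - bvec @ beta, 1e-300)
        npf = self.n - self.p
        s2 = rss / npf
        crit = npf * (np.log(2 * np.pi) + np.log(s2) + 1.0) + logdetV + logdetA
        return {
            "crit": crit, "beta": beta, "s2": s2, "A": A, "cho": cf,
            "logdetV": logdetV, "logdetA": logdetA, "gs": gs, "gf": gf,
        }

    def neg2_reml(self, theta) -> float:
        """Unprofiled -2 restricted log-likelihood at theta = (s2e, s2s, s2f)."""
        s2, ss, sf_ = theta
        if s2 <= 0:
            return np.inf
        try:
            logdetV, A, bvec, q = self._assemble(ss / s2, sf_ / s2)
            cf = sla.cho_factor(A, lower=True)
        except np.linalg.LinAlgError:
            return np.inf
        logdetA = 2.0 * np.sum(np.log(np.diag(cf[0])))
        beta = sla.cho_solve(cf, bvec)
        rss = q - bvec @ beta
        npf = self.n - self.p
        return npf * (np.log(2 * np.pi) + np.log(s2)) + logdetV + logdetA + rss / s2

    def beta_cov(self, theta) -> np.ndarray:
        """Covariance of the GLS fixed effects at theta: s2e * A(gamma)^-1."""
        s2, ss, sf_ = theta
        _, A, _, _ = self._assemble(ss / s2, sf_ / s2)
        return s2 * sla.cho_solve(sla.cho_factor(A, lower=True), np.eye(self.p))

    def fit(self, x0=(0.5, 0.25)):
        obj = lambda g: self.profiled(g)["crit"]
        res = minimize(
            obj, np.asarray(x0, dtype=float), method="L-BFGS-B",
            bounds=[(0.0, None), (0.0, None)],
            options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 300},
        )
        res2 = minimize(
            obj, res.x, method="Nelder-Mead",
            bounds=[(0.0, None), (0.0, None)],
            options={"xatol": 1e-12, "fatol": 1e-13, "maxiter": 600, "maxfev": 1200},
        )
        best = res2 if res2.fun <= res.fun else res
        return self.profiled(best.x), bool(res.success or res2.success)


@dataclass
class ModelFit:
    """REML fit of the per-dimension state-space model."""

    dimension: str
    params: pd.Series
    vcov: pd.DataFrame
    varcomps: dict[str, float]
    ftests: pd.DataFrame
    n_obs: int
    n_subjects: int
    n_families: int
    converged: bool
    boundary: list[str]
    loglik_reml: float
    spec: ModelSpec
    condition_levels: tuple[str, ...]
    reference_condition: str
    # private inference state
    _problem: _REMLProblem = field(repr=False, default=None)
    _theta: np.ndarray = field(repr=False, default=None)
    _acov: np.ndarray = field(repr=False, default=None)
    _C0: np.ndarray = field(repr=False, default=None)
    _Cplus: list = field(repr=False, default=None)
    _Cminus: list = field(repr=False, default=None)
    _steps: np.ndarray = field(repr=False, default=None)

    # -- Satterthwaite helpers -------------------------------------------
    def _grad_quadform(self, ell: np.ndarray) -> np.ndarray:
        return np.array(
            [
                (ell @ self._Cplus[j] @ ell - ell @ self._Cminus[j] @ ell) / (2 * self._steps[j])
                for j in range(3)
            ]
        )

    def satterthwaite_df(self, ell: np.ndarray) -> float:
        """Denominator df for the scalar contrast ell' beta."""
        f = float(ell @ self._C0 @ ell)
        g = self._grad_quadform(ell)
        denom = float(g @ self._acov @ g)
        if denom <= 0 or not np.isfinite(denom):
            return _DF_CAP
        return float(np.clip(2.0 * f * f / denom, 1.0, _DF_CAP))

    def contrast(self, ell: np.ndarray):
        """(estimate, se, t, df, p) for a single contrast of fixed effects."""
        est = float(ell @ self.params.to_numpy())
        se = float(np.sqrt(ell @ self._C0 @ ell))
        df = self.satterthwaite_df(ell)
        t = est / se if se > 0 else np.nan
        p = 2.0 * stats.t.sf(abs(t), df)
        return est, se, t, df, p

    def ftest(self, idx: list[int]):
        """Type-III Wald F with Satterthwaite denominator df for a block."""
        beta = self.params.to_numpy()[idx]
        Csub = self._C0[np.ix_(idx, idx)]
        q = len(idx)
        Fstat = float(beta @ np.linalg.solve(Csub, beta)) / q
        w, U = np.linalg.eigh(Csub)
        nus = []
        for i in range(q):
            ell = np.zeros(len(self.params))
            ell[idx] = U[:, i]
            f = float(w[i])
            g = self._grad_quadform(ell)
            denom = float(g @ self._acov @ g)
            nu = _DF_CAP if denom <= 0 else np.clip(2 * f * f / denom, 1.0, _DF_CAP)
            nus.append(float(nu))
        contrib = [nu / (nu - 2.0) for nu in nus if nu > 2.0]
        E = sum(contrib)
        if E > q and len(contrib) == q:
            df_den = float(np.clip(2.0 * E / (E - q), 1.0, _DF_CAP))
        else:
            df_den = float(np.mean(nus)) if nus else _DF_CAP
        pval = float(stats.f.sf(Fstat, q, df_den))
        return Fstat, q, df_den, pval

    def to_dict(self) -> dict:
        return {
            "dimension": self.dimension,
            "params": self.params.to_dict(),
            "varcomps": self.varcomps,
            "ftests": self.ftests.to_dict(orient="records"),
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
            "n_families": self.n_families,
            "converged": self.converged,
            "boundary": self.boundary,
            "loglik_reml": self.loglik_reml,
            "reference_condition": self.reference_condition,
        }


def fit_state_space_model(
    table: pd.DataFrame,
    dimension: str,
    spec: ModelSpec | None = None,
) -> ModelFit:
    """Fit the state-space mixed model for one dimension of brain variation.

    Rows of other dimensions are ignored; rows with missing values in any
    used column are dropped (unbalanced designs pass through). Variance
    components at the zero boundary are tolerated with a logged warning.
    """
    spec = spec or ModelSpec()
    df = table[table["dimension"] == dimension]
    needed = ["location", "condition", "subject_id", "family_id", *spec.traits, *spec.covariates]
    df = df.dropna(subset=[c for c in needed if c in df.columns])
    if len(df) == 0:
        raise ValueError(f"no rows for dimension {dimension!r}")
    missing_cols = [c for c in needed if c not in df.columns]
    if missing_cols:
        raise ValueError(f"state-space table lacks columns {missing_cols}")
    vals = df[["location", *spec.traits, *spec.covariates]].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite values in outcome or fixed-effect columns")

    X, names, terms, levels, ref, _ = _build_design(df, spec)
    y = df["location"].to_numpy(dtype=float)
    prob = _REMLProblem(X, y, df["subject_id"].to_numpy(), df["family_id"].to_numpy())
    sol, converged = prob.fit()

    s2 = sol["s2"]
    theta = np.array([s2, sol["gs"] * s2, sol["gf"] * s2])
    boundary = []
    if sol["gs"] < 1e-7:
        boundary.append("subject")
    if sol["gf"] < 1e-7:
        boundary.append("family")
    if boundary:
        logger.warning(
            "variance component(s) %s at the zero boundary for dimension %s",
            boundary, dimension,
        )

    # Satterthwaite state: numerical Hessian of -2 REML loglik and finite-
    # difference evaluations of the beta covariance around theta-hat.
    steps = 1e-4 * np.maximum(theta, 0.01 * s2)
    H = np.zeros((3, 3))
    f0 = prob.neg2_reml(theta)
    for j in range(3):
        ej = np.zeros(3)
        ej[j] = steps[j]
        fp, fm = prob.neg2_reml(theta + ej), prob.neg2_reml(theta - ej)
        H[j, j] = (fp + fm - 2 * f0) / steps[j] ** 2
    for j in range(3):
        for k in range(j + 1, 3):
            ej = np.zeros(3); ej[j] = steps[j]
            ek = np.zeros(3); ek[k] = steps[k]
            H[j, k] = H[k, j] = (
                prob.neg2_reml(theta + ej + ek)
                - prob.neg2_reml(theta + ej - ek)
                - prob.neg2_reml(theta - ej + ek)
                + prob.neg2_reml(theta - ej - ek)
            ) / (4 * steps[j] * steps[k])
    try:
        acov = 2.0 * sla.pinvh(H)
    except np.linalg.LinAlgError:
        acov = np.zeros((3, 3))
    C0 = s2 * sla.cho_solve(sol["cho"], np.eye(prob.p))
    Cplus, Cminus = [], []
    for j in range(3):
        ej = np.zeros(3)
        ej[j] = steps[j]
        Cplus.append(prob.beta_cov(theta + ej))
        Cminus.append(prob.beta_cov(theta - ej))

    params = pd.Series(sol["beta"], index=names)
    fit = ModelFit(
        dimension=dimension,
        params=params,
        vcov=pd.DataFrame(C0, index=names, columns=names),
        varcomps={"subject": float(theta[1]), "family": float(theta[2]), "residual": float(s2)},
        ftests=pd.DataFrame(),
        n_obs=prob.n,
        n_subjects=prob.n_subjects,
        n_families=prob.n_families,
        converged=converged,
        boundary=boundary,
        loglik_reml=-0.5 * float(f0),
        spec=spec,
        condition_levels=tuple(levels),
        reference_condition=ref,
        _problem=prob,
        _theta=theta,
        _acov=acov,
        _C0=C0,
        _Cplus=Cplus,
        _Cminus=Cminus,
        _steps=steps,
    )
    rows = []
    for term, idx in terms.items():
        F, qn, dfd, p = fit.ftest(idx)
        rows.append({"term": term, "F": F, "df_num": qn, "df_den": dfd, "p": p})
    fit.ftests = pd.DataFrame(rows)
    return fit


# ---------------------------------------------------------------------------
# simple slopes (estimated marginal trends)
# ---------------------------------------------------------------------------

def trait_slopes_by_condition(fit: ModelFit, conf_level: float = 0.95) -> pd.DataFrame:
    """Per-condition trait slopes as linear combinations of fixed effects.

    slope(trait, condition) is d(location)/d(trait) evaluated at that
    condition; under deviation coding that is the trait main effect plus the
    condition's interaction contrast, so the result does not depend on the
    factor coding. One row per trait x observed condition.
    """
    if not fit.converged:
        raise RuntimeError("model fit did not converge; slopes unavailable")
    spec = fit.spec
    names = list(fit.params.index)
    ref = fit.reference_condition
    nonref = [l for l in fit.condition_levels if l != ref]
    qa = stats.t.ppf
    rows = []
    for t in spec.traits:
        for c in fit.condition_levels:
            ell = np.zeros(len(names))
            ell[names.index(t)] = 1.0
            if spec.coding == "deviation":
                if c == ref:
                    for l in nonref:
                        ell[names.index(f"{t}:condition[{l}]")] = -1.0
                else:
                    ell[names.index(f"{t}:condition[{c}]")] = 1.0
            else:  # treatment
                if c != ref:
                    ell[names.index(f"{t}:condition[{c}]")] = 1.0
            est, se, tval, df, p = fit.contrast(ell)
            half = qa(0.5 + conf_level / 2.0, df) * se
            rows.append(
                {
                    "trait": t,
                    "condition": c,
                    "dimension": fit.dimension,
                    "estimate": est,
                    "se": se,
                    "t": tval,
                    "df": df,
                    "ci_lower": est - half,
                    "ci_upper": est + half,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# multiplicity and follow-up selection
# ---------------------------------------------------------------------------

def bonferroni_alpha(
    n_conditions: int, n_traits: int, n_dims: int, fwer: float = 0.05
) -> tuple[int, float]:
    """Family-wise comparison count and Bonferroni threshold.

    The family counts every unordered pair of conditions crossed with
    traits and dimensions: C(n_conditions, 2) * n_traits * n_dims.
    """
    if n_conditions < 2:
        raise ValueError("n_conditions must be >= 2")
    if not 0 < fwer < 1:
        raise ValueError("fwer must be in (0, 1)")
    if n_traits < 1 or n_dims < 1:
        raise ValueError("n_traits and n_dims must be >= 1")
    n_comparisons = comb(n_conditions, 2) * n_traits * n_dims
    return n_comparisons, fwer / n_comparisons


def flag_significant_interactions(
    fits: dict[str, ModelFit], alpha: float
) -> pd.DataFrame:
    """Compare each trait-by-condition interaction F-test to alpha.

    One row per (dimension, trait); deterministic given the fits.
    """
    rows = []
    for dim, fit in fits.items():
        ft = fit.ftests.set_index("term")
        for t in fit.spec.traits:
            r = ft.loc[f"{t}:condition"]
            rows.append(
                {
                    "dimension": dim,
                    "trait": t,
                    "F": float(r["F"]),
                    "df_num": float(r["df_num"]),
                    "df_den": float(r["df_den"]),
                    "p": float(r["p"]),
                    "significant": bool(r["p"] < alpha),
                }
            )
    return pd.DataFrame(rows)


def strongest_divergent_pair(
    slopes: pd.DataFrame, trait: str, dimension: str
) -> tuple[str, str]:
    """Conditions with the most positive and most negative trait slope t.

    Ties are broken by catalogue order (first occurrence) with a logged
    warning.
    """
    sub = slopes[(slopes["trait"] == trait) & (slopes["dimension"] == dimension)]
    if sub["condition"].nunique() < 2:
        raise ValueError("need slopes for at least two conditions")
    order = _ordered_levels(sub["condition"].unique())
    sub = sub.set_index("condition").loc[order]
    tvals = sub["t"].to_numpy()
    imax, imin = int(np.argmax(tvals)), int(np.argmin(tvals))
    if (tvals == tvals[imax]).sum() > 1 or (tvals == tvals[imin]).sum() > 1:
        logger.warning(
            "tied extreme t-values for trait %s on %s; catalogue order breaks the tie",
            trait, dimension,
        )
    return order[imax], order[imin]
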