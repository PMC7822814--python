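"""Nested mixed-effects inference for the placental oximetry outcomes.

Placentas are sampled within mothers, and mothers are the statistically
independent unit, so every outcome (PO2, T1, SNR at each TR, S0) is
modelled with a linear mixed model:

* full model — fixed effects genotype + oxygen + genotype x oxygen, random
  intercepts for mother and for placenta-within-mother (oxygen is the
  within-subject factor);
* post-hoc model at one oxygen level — fixed effect genotype, random
  intercept for mother.

Estimation is REML via statsmodels ``MixedLM``.  Fixed-effect terms are
tested with Wald F statistics on type-III-style contrasts (main effects are
differences of cell means weighted equally over the other factor).
Denominator degrees of freedom use the Satterthwaite approximation — the
convention of repeated-measures software — computed from the REML
likelihood of the nested variance structure; if the variance estimates sit
on the boundary and the approximation degenerates, a containment
(between/within) df is used instead and recorded in the result metadata.
Estimated marginal means carry t-based 95% CIs on their own Satterthwaite
df.  Outcomes are modelled independently with no cross-outcome multiplicity
correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

__all__ = [
    "OUTCOME_COLUMNS",
    "MixedModelResult",
    "fit_full_model",
    "fit_posthoc_model",
    "descriptive_summary",
    "unpaired_ttest",
    "fit_all_outcomes",
    "posthoc_all_outcomes",
]

OUTCOME_COLUMNS = ["po2_mmhg", "t1_s", "snr_tr1", "snr_tr2", "snr_tr3", "snr_tr4", "s0"]

ALPHA = 0.05


@dataclass
class MixedModelResult:
    """Fixed-effect tests, estimated marginal means and variance components."""

    outcome: str
    anova: pd.DataFrame            # source, num_df, den_df, F, p
    emmeans: pd.DataFrame          # group columns, estimate, se, df, ci_lo, ci_hi
    varcomps: dict
    converged: bool
    singular: bool
    degenerate: bool
    method: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# REML engine for the nested variance structure (mother / placenta / residual)
#
# statsmodels maximizes the REML criterion; this engine evaluates the same
# criterion and its derivatives at the estimate to obtain the Satterthwaite
# denominator df, which statsmodels does not provide.


class _NestedREML:
    """y = X beta + b_mother (+ b_placenta) + e with independent Normal terms.

    ``theta`` is the variance vector (sigma2_mother[, sigma2_placenta],
    sigma2_residual) on the response scale.
    """

    def __init__(self, X, y, mother_ids, placenta_ids=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self.k = X.shape[1]
        self.n = X.shape[0]
        self.groups = []
        for m in pd.unique(mother_ids):
            idx = np.asarray(mother_ids) == m
            Xi, yi = X[idx], y[idx]
            if placenta_ids is not None:
                pi = np.asarray(placenta_ids)[idx]
                Zi = (pi[:, None] == pd.unique(pi)[None, :]).astype(float)
            else:
                Zi = None
            self.groups.append((Xi, yi, Zi))
        self.n_theta = 3 if placenta_ids is not None else 2

    def _vinv_blocks(self, theta):
        if self.n_theta == 3:
            s2m, s2p, s2e = theta
        else:
            (s2m, s2e), s2p = theta, 0.0
        out = []
        for Xi, yi, Zi in self.groups:
            ni = len(yi)
            V = s2m * np.ones((ni, ni)) + s2e * np.eye(ni)
            if Zi is not None:
                V += s2p * (Zi @ Zi.T)
            out.append((Xi, yi, np.linalg.inv(V), np.linalg.slogdet(V)[1]))
        return out

    def beta_cov(self, theta):
        """GLS fixed effects and their covariance at the given variances."""
        XtVX = np.zeros((self.k, self.k))
        XtVy = np.zeros(self.k)
        blocks = self._vinv_blocks(theta)
        for Xi, yi, Vinv, _ in blocks:
            XtVX += Xi.T @ Vinv @ Xi
            XtVy += Xi.T @ Vinv @ yi
        Vb = np.linalg.inv(XtVX)
        return Vb @ XtVy, Vb

    def loglike(self, theta):
        """Restricted (REML) log-likelihood."""
        blocks = self._vinv_blocks(theta)
        XtVX = np.zeros((self.k, self.k))
        XtVy = np.zeros(self.k)
        ll = 0.0
        for Xi, yi, Vinv, logdet in blocks:
            XtVX += Xi.T @ Vinv @ Xi
            XtVy += Xi.T @ Vinv @ yi
            ll -= 0.5 * logdet
        beta = np.linalg.solve(XtVX, XtVy)
        quad = sum(
            (yi - Xi @ beta) @ Vinv @ (yi - Xi @ beta)
            for Xi, yi, Vinv, _ in blocks
        )
        ll -= 0.5 * (np.linalg.slogdet(XtVX)[1] + quad)
        ll -= 0.5 * (self.n - self.k) * np.log(2 * np.pi)
        return ll

    def optimize(self, theta0):
        """Polish the REML estimate (statsmodels may stop near, not at, a
        variance boundary, which would corrupt the observed information)."""
        from scipy.optimize import minimize

        t0 = np.maximum(np.asarray(theta0, dtype=float), 0.0)
        scale = max(t0.max(), 1e-12)

        def neg(th):
            return -self.loglike(np.maximum(th, 0.0))

        sol = minimize(
            neg, x0=t0, method="L-BFGS-B",
            bounds=[(0.0, None)] * (self.n_theta - 1) + [(1e-12 * scale, None)],
            options={"ftol": 1e-14, "gtol": 1e-10},
        )
        th = np.maximum(sol.x, 0.0)
        return th if sol.fun <= neg(t0) + 1e-9 else t0

    def active_mask(self, theta, rel_tol: float = 1e-3):
        """Variance components treated as free parameters for Satterthwaite:
        boundary components (relative size < rel_tol) are held fixed at
        zero, matching how a fit without them would behave."""
        t = np.asarray(theta, dtype=float)
        mask = t > rel_tol * t.sum()
        mask[-1] = True  # residual variance is always free
        return mask

    def _steps(self, theta, mask):
        h = np.zeros(len(theta))
        ref = max(np.asarray(theta).max(), 1e-12)
        h[mask] = np.maximum(1e-4 * np.abs(np.asarray(theta)[mask]), 1e-6 * ref)
        return h

    def theta_cov(self, theta, mask):
        """Asymptotic covariance of the active variance estimates: inverse
        observed REML information by central finite differences."""
        t = np.asarray(theta, dtype=float)
        h = self._steps(t, mask)
        act = np.flatnonzero(mask)
        m = len(act)
        H = np.zeros((m, m))
        f0 = self.loglike(t)
        for a, i in enumerate(act):
            ei = np.zeros(len(t)); ei[i] = h[i]
            H[a, a] = (self.loglike(t + ei) - 2 * f0 + self.loglike(np.maximum(t - ei, 0))) / h[i] ** 2
            for b, j in enumerate(act[:a]):
                ej = np.zeros(len(t)); ej[j] = h[j]
                H[a, b] = H[b, a] = (
                    self.loglike(t + ei + ej) - self.loglike(np.maximum(t + ei - ej, 0))
                    - self.loglike(np.maximum(t - ei + ej, 0))
                    + self.loglike(np.maximum(t - ei - ej, 0))
                ) / (4 * h[i] * h[j])
        info = -H
        try:
            return np.linalg.inv(info)
        except np.linalg.LinAlgError:
            return np.linalg.pinv(info)

    def satterthwaite_df(self, ell, theta, theta_cov, mask):
        """Satterthwaite df of the scalar contrast ell' beta:
        df = 2 f^2 / Var(f) with f(theta) = ell' Cov(beta; theta) ell."""
        t = np.asarray(theta, dtype=float)
        h = self._steps(t, mask)
        act = np.flatnonzero(mask)

        def f(th):
            return float(ell @ self.beta_cov(np.maximum(th, 0))[1] @ ell)

        grad = np.zeros(len(act))
        for a, i in enumerate(act):
            ei = np.zeros(len(t)); ei[i] = h[i]
            grad[a] = (f(t + ei) - f(t - ei)) / (2 * h[i])
        var_f = float(grad @ theta_cov @ grad)
        if var_f <= 0:
            return np.nan
        return 2.0 * f(t) ** 2 / var_f

    def f_test(self, L, theta, theta_cov, mask, fallback_df):
        """Wald F test of L beta = 0 with a Satterthwaite denominator df.

        Multi-row contrasts combine per-eigencontrast dfs the way
        repeated-measures software does; a degenerate approximation falls
        back to ``fallback_df``.
        """
        beta, Vb = self.beta_cov(theta)
        L = np.atleast_2d(np.asarray(L, dtype=float))
        q = L.shape[0]
        M = L @ Vb @ L.T
        b = L @ beta
        F = float(b @ np.linalg.solve(M, b)) / q

        evals, evecs = np.linalg.eigh(M)
        dfs = []
        for i in range(q):
            if evals[i] <= 0:
                continue
            ell = evecs[:, i] @ L
            nu = self.satterthwaite_df(ell, theta, theta_cov, mask)
            if np.isfinite(nu) and nu > 0:
                dfs.append(nu)
        ddf = np.nan
        if len(dfs) == q:
            if q == 1:
                ddf = dfs[0]
            else:
                terms = [nu / (nu - 2.0) for nu in dfs if nu > 2.0]
                if len(terms) == q:
                    E = sum(terms)
                    if E > q:
                        ddf = 2.0 * E / (E - q)
        used_fallback = not (np.isfinite(ddf) and ddf > 0)
        if used_fallback:
            ddf = float(fallback_df)
        p = float(sps.f.sf(F, q, ddf))
        return F, q, float(ddf), p, used_fallback


# ---------------------------------------------------------------------------
# Model fitting


def _clean(records: pd.DataFrame, outcome: str) -> pd.DataFrame:
    df = records.copy()
    for col in ("qc_unusable", "qc_nonconverged"):
        if col in df.columns:
            df = df[~df[col].astype(bool)]
    df = df.dropna(subset=[outcome])
    if df.empty:
        raise ValueError(f"no usable rows for outcome {outcome!r}")
    df["genotype"] = pd.Categorical(df["genotype"], categories=["WT", "KO"])
    return df


def _degenerate_result(outcome: str, note: str) -> MixedModelResult:
    return MixedModelResult(
        outcome=outcome,
        anova=pd.DataFrame(columns=["source", "num_df", "den_df", "F", "p"]),
        emmeans=pd.DataFrame(),
        varcomps={},
        converged=False,
        singular=True,
        degenerate=True,
        method={"note": note},
    )


def _fit_mixedlm(formula, data, groups, vc_formula=None, re_formula="1"):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            formula, data=data, groups=data[groups],
            re_formula=re_formula, vc_formula=vc_formula,
        )
        try:
            res = model.fit(reml=True, method="lbfgs")
            if not res.converged:
                raise RuntimeError("lbfgs did not converge")
        except Exception:
            res = model.fit(reml=True, method="powell", maxiter=500)
    return model, res


def _cell_rows(result, genotypes, oxy_levels=None) -> dict:
    """Fixed-effects design row for each factor-level cell."""
    from patsy import build_design_matrices

    design_info = result.model.data.design_info
    cells = {}
    for g in genotypes:
        if oxy_levels is None:
            X = build_design_matrices([design_info], pd.DataFrame({"genotype": [g]}))[0]
            cells[g] = np.asarray(X)[0]
        else:
            for o in oxy_levels:
                X = build_design_matrices(
                    [design_info],
                    pd.DataFrame({"genotype": [g], "oxygen_percent": [o]}),
                )[0]
                cells[(g, o)] = np.asarray(X)[0]
    return cells


def _emm_row(engine, ell, theta, theta_cov, mask, beta, Vb, fallback_df):
    est = float(ell @ beta)
    se = float(np.sqrt(ell @ Vb @ ell))
    nu = engine.satterthwaite_df(ell, theta, theta_cov, mask)
    if not (np.isfinite(nu) and nu > 0):
        nu = float(fallback_df)
    tcrit = sps.t.ppf(1 - ALPHA / 2, nu)
    return dict(estimate=est, se=se, df=nu, ci_lo=est - tcrit * se, ci_hi=est + tcrit * se)


def fit_full_model(records: pd.DataFrame, outcome: str) -> MixedModelResult:
    """Full repeated-measures mixed model for one outcome.

    Fixed: genotype * oxygen; random: mother intercept and
    placenta-within-mother intercept.  Requires >= 2 mothers per genotype
    and >= 2 oxygen levels.  A constant outcome yields a degenerate-fit
    diagnostic rather than an exception; near-zero variance components are
    reported with a ``singular`` flag.
    """
    df = _clean(records, outcome)
    n_per_geno = df.groupby("genotype", observed=True)["mother_id"].nunique()
    if (n_per_geno < 2).any() or len(n_per_geno) < 2:
        raise ValueError("need >= 2 mothers in each genotype")
    oxy_levels = sorted(df["oxygen_percent"].unique())
    if len(oxy_levels) < 2:
        raise ValueError("need >= 2 oxygen levels for the within-subject factor")
    if np.var(df[outcome].values) < 1e-12:
        return _degenerate_result(outcome, "outcome constant across all rows")

    formula = f"{outcome} ~ C(genotype, Treatment('WT')) * C(oxygen_percent)"
    model, res = _fit_mixedlm(
        formula, df, groups="mother_id",
        vc_formula={"placenta": "0 + C(placenta_id)"},
    )

    engine = _NestedREML(
        model.exog, model.endog, df["mother_id"].values, df["placenta_id"].values
    )
    theta = engine.optimize(
        [float(np.asarray(res.cov_re)[0, 0]), float(res.vcomp[0]), float(res.scale)]
    )
    mask = engine.active_mask(theta)
    theta_cov = engine.theta_cov(theta, mask)
    beta, Vb = engine.beta_cov(theta)

    # type-III-style contrasts from equally weighted cell means
    cells = _cell_rows(res, ("WT", "KO"), oxy_levels)
    mean_ko = np.mean([cells[("KO", o)] for o in oxy_levels], axis=0)
    mean_wt = np.mean([cells[("WT", o)] for o in oxy_levels], axis=0)
    o_ref = oxy_levels[0]
    oxy_L, int_L = [], []
    for o in oxy_levels[1:]:
        mean_o = np.mean([cells[(g, o)] for g in ("WT", "KO")], axis=0)
        mean_ref = np.mean([cells[(g, o_ref)] for g in ("WT", "KO")], axis=0)
        oxy_L.append(mean_o - mean_ref)
        int_L.append(
            (cells[("KO", o)] - cells[("WT", o)])
            - (cells[("KO", o_ref)] - cells[("WT", o_ref)])
        )
    n_mothers = df["mother_id"].nunique()
    n_plac = df["placenta_id"].nunique()
    n_within = len(oxy_L) + len(int_L)
    fallback = {
        "genotype": n_mothers - 2,
        "oxygen": len(df) - n_plac - n_within,
        "genotype_x_oxygen": len(df) - n_plac - n_within,
    }
    contrasts = {
        "genotype": np.atleast_2d(mean_ko - mean_wt),
        "oxygen": np.asarray(oxy_L),
        "genotype_x_oxygen": np.asarray(int_L),
    }
    rows, any_fallback = [], False
    for source in ("genotype", "oxygen", "genotype_x_oxygen"):
        F, q, ddf, p, used_fb = engine.f_test(
            contrasts[source], theta, theta_cov, mask, fallback[source]
        )
        any_fallback |= used_fb
        rows.append({"source": source, "num_df": q, "den_df": ddf, "F": F, "p": p})
    anova = pd.DataFrame(rows)

    emm_rows = []
    for g in ("WT", "KO"):
        ell = np.mean([cells[(g, o)] for o in oxy_levels], axis=0)
        emm_rows.append(
            {"genotype": g, "oxygen_percent": None,
             **_emm_row(engine, ell, theta, theta_cov, mask, beta, Vb,
                        fallback["genotype"])}
        )
        for o in oxy_levels:
            emm_rows.append(
                {"genotype": g, "oxygen_percent": o,
                 **_emm_row(engine, cells[(g, o)], theta, theta_cov, mask, beta, Vb,
                            fallback["genotype"])}
            )
    emmeans = pd.DataFrame(emm_rows)

    varcomps = {
        "mother_var": float(theta[0]), "placenta_var": float(theta[1]),
        "residual_var": float(theta[2]),
    }
    singular = not bool(mask.all())

    return MixedModelResult(
        outcome=outcome,
        anova=anova,
        emmeans=emmeans,
        varcomps=varcomps,
        converged=bool(res.converged),
        singular=bool(singular),
        degenerate=False,
        method={
            "estimation": "REML",
            "df_method": "satterthwaite" + (" (containment fallback)" if any_fallback else ""),
            "formula": formula,
            "random": "mother intercept + placenta-within-mother intercept",
            "n_obs": len(df), "n_mothers": n_mothers, "n_placentas": n_plac,
        },
    )


def fit_posthoc_model(records: pd.DataFrame, outcome: str) -> MixedModelResult:
    """Genotype-only mixed model at a single oxygen level.

    Fixed effect genotype, random intercept for mother; estimated marginal
    means with 95% CI per genotype; Satterthwaite denominator df.
    """
    df = _clean(records, outcome)
    oxy = df["oxygen_percent"].unique()
    if len(oxy) != 1:
        raise ValueError("post-hoc model requires records at a single oxygen level")
    if df.groupby("genotype", observed=True).size().size < 2:
        raise ValueError("both genotypes must be present")
    if np.var(df[outcome].values) < 1e-12:
        return _degenerate_result(outcome, "outcome constant across all rows")

    group_means = df.groupby("genotype", observed=True)[outcome].mean()
    within_var = float(
        df.groupby("genotype", observed=True)[outcome].var(ddof=0).max()
    )
    if within_var < 1e-12 * max(float(np.var(df[outcome].values)), 1.0):
        # no within-group variation: the group means are exact
        emmeans = pd.DataFrame(
            [
                {"genotype": g, "oxygen_percent": float(oxy[0]),
                 "estimate": float(group_means[g]), "se": 0.0, "df": np.nan,
                 "ci_lo": float(group_means[g]), "ci_hi": float(group_means[g])}
                for g in ("WT", "KO")
            ]
        )
        return MixedModelResult(
            outcome=outcome,
            anova=pd.DataFrame(
                [{"source": "genotype", "num_df": 1, "den_df": np.nan,
                  "F": np.inf, "p": 0.0}]
            ),
            emmeans=emmeans,
            varcomps={"mother_var": 0.0, "residual_var": 0.0},
            converged=True,
            singular=True,
            degenerate=False,
            method={"note": "zero within-genotype variance; exact group means"},
        )

    formula = f"{outcome} ~ C(genotype, Treatment('WT'))"
    model, res = _fit_mixedlm(formula, df, groups="mother_id")

    engine = _NestedREML(model.exog, model.endog, df["mother_id"].values)
    theta = engine.optimize([float(np.asarray(res.cov_re)[0, 0]), float(res.scale)])
    mask = engine.active_mask(theta)
    theta_cov = engine.theta_cov(theta, mask)
    beta, Vb = engine.beta_cov(theta)

    cells = _cell_rows(res, ("WT", "KO"))
    n_mothers = df["mother_id"].nunique()
    fallback_df = n_mothers - 2
    L = np.atleast_2d(cells["KO"] - cells["WT"])
    F, q, ddf, p, used_fb = engine.f_test(L, theta, theta_cov, mask, fallback_df)
    anova = pd.DataFrame(
        [{"source": "genotype", "num_df": q, "den_df": ddf, "F": F, "p": p}]
    )

    emm_rows = []
    for g in ("WT", "KO"):
        emm_rows.append(
            {"genotype": g, "oxygen_percent": float(oxy[0]),
             **_emm_row(engine, cells[g], theta, theta_cov, mask, beta, Vb,
                        fallback_df)}
        )
    emmeans = pd.DataFrame(emm_rows)

    varcomps = {"mother_var": float(theta[0]), "residual_var": float(theta[1])}
    return MixedModelResult(
        outcome=outcome,
        anova=anova,
        emmeans=emmeans,
        varcomps=varcomps,
        converged=bool(res.converged),
        singular=not bool(mask.all()),
        degenerate=False,
        method={
            "estimation": "REML",
            "df_method": "satterthwaite" + (" (containment fallback)" if used_fb else ""),
            "formula": formula,
            "random": "mother intercept",
            "oxygen_percent": float(oxy[0]),
            "n_obs": len(df), "n_mothers": n_mothers,
        },
    )


def descriptive_summary(records: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """Plain per genotype x oxygen summaries (mean, SD, 95% CI), not model-based.

    SD and CI are reported as missing for singleton groups.
    """
    df = _clean(records, outcome)
    rows = []
    for (g, o), grp in df.groupby(["genotype", "oxygen_percent"], observed=True):
        vals = grp[outcome].values
        n = len(vals)
        mean = float(np.mean(vals))
        if n > 1:
            sd = float(np.std(vals, ddof=1))
            half = sps.t.ppf(1 - ALPHA / 2, n - 1) * sd / np.sqrt(n)
            ci_lo, ci_hi = mean - half, mean + half
        else:
            sd = ci_lo = ci_hi = np.nan
        rows.append(
            {
                "genotype": g, "oxygen_percent": o, "n": n,
                "mean": mean, "sd": sd, "ci_lo": ci_lo, "ci_hi": ci_hi,
            }
        )
    return pd.DataFrame(rows)


def unpaired_ttest(records: pd.DataFrame, outcome: str) -> dict:
    """Unpaired two-tailed t-test between genotypes at placenta level.

    Supplementary to the mixed models (it ignores the nesting); reported as
    an optional column, never the primary inference.
    """
    df = _clean(records, outcome)
    wt = df.loc[df["genotype"] == "WT", outcome].values
    ko = df.loc[df["genotype"] == "KO", outcome].values
    t, p = sps.ttest_ind(wt, ko, equal_var=True)
    return {"t": float(t), "df": len(wt) + len(ko) - 2, "p": float(p)}


def fit_all_outcomes(
    records: pd.DataFrame, outcomes=OUTCOME_COLUMNS
) -> tuple[pd.DataFrame, dict[str, MixedModelResult]]:
    """Full model for every outcome; returns a stacked fixed-effects table."""
    results, tables = {}, []
    for outcome in outcomes:
        r = fit_full_model(records, outcome)
        results[outcome] = r
        t = r.anova.copy()
        t.insert(0, "outcome", outcome)
        tables.append(t)
    return pd.concat(tables, ignore_index=True), results


def posthoc_all_outcomes(
    records: pd.DataFrame, oxygen_percent: float, outcomes=OUTCOME_COLUMNS
) -> tuple[pd.DataFrame, dict[str, MixedModelResult]]:
    """Post-hoc genotype models at one oxygen level for every outcome."""
    sub = records[records["oxygen_percent"] == oxygen_percent]
    results, tables = {}, []
    for outcome in outcomes:
        r = fit_posthoc_model(sub, outcome)
        results[outcome] = r
        t = r.anova.copy()
        t.insert(0, "outcome", outcome)
        tables.append(t)
    return pd.concat(tables, ignore_index=True), results
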