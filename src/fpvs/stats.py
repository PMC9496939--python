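"""Statistical layer for the cross-over study.

Linear mixed models with treatment, stimulus type and ROI as fixed effects
(sum-to-zero coding, type-III Wald F tests), session order as a nuisance
covariate, and a per-participant random intercept plus diagonal variance
components for each fixed factor. Post-hoc contrasts are Z tests on
estimated marginal means with Holm correction. Evidence for the null is
quantified by a BIC-approximated Bayes factor (full vs. same model without
the treatment terms) and by posterior OT-PL differences per cell with 95%
highest-density intervals.

Denominator degrees of freedom use the residual (nobs - rank) count — a
deliberate, documented approximation; see the methods note.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

MAD_SCALE = 1.4826  # consistency constant for normal data


# --------------------------------------------------------------------------
# outliers
# --------------------------------------------------------------------------

def mad_outliers(values: np.ndarray, k: float = 3.0) -> np.ndarray:
    """Keep-mask: False where |x - median| > k * 1.4826 * MAD.

    With MAD = 0 (a majority of identical values) the robust z is infinite
    for any value off the median: constant vectors drop nothing, otherwise
    the deviating values are dropped; both cases warn.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        dev = x != med
        if dev.any():
            warnings.warn(
                "MAD is zero with non-identical values: dropping values off the median",
                stacklevel=2,
            )
            return ~dev
        warnings.warn("MAD is zero (constant values): nothing dropped", stacklevel=2)
        return np.ones_like(x, dtype=bool)
    return np.abs(x - med) <= k * MAD_SCALE * mad


def holm(pvals: list[float] | np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, >= raw)."""
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


# --------------------------------------------------------------------------
# mixed models
# --------------------------------------------------------------------------

NEURAL_FORMULA = (
    "{y} ~ C(treatment, Sum) * C(stimulus, Sum) * C(roi, Sum) + C(session_order, Sum)"
)
BEHAVIOR_FORMULA = "{y} ~ C(treatment, Sum) + C(session_order, Sum)"

_EFFECT_LABELS = {
    "C(treatment, Sum)": "treatment",
    "C(stimulus, Sum)": "stimulus",
    "C(roi, Sum)": "roi",
    "C(session_order, Sum)": "session_order",
    "C(treatment, Sum):C(stimulus, Sum)": "treatment:stimulus",
    "C(treatment, Sum):C(roi, Sum)": "treatment:roi",
    "C(stimulus, Sum):C(roi, Sum)": "stimulus:roi",
    "C(treatment, Sum):C(stimulus, Sum):C(roi, Sum)": "treatment:stimulus:roi",
}


@dataclass
class TestReport:
    """Container for the model outputs of one response variable."""

    anova: pd.DataFrame  # effect, F, df1, df2, p
    posthoc: pd.DataFrame | None = None
    bf_treatment: float | None = None
    bf_label: str | None = None
    posterior: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def effect(self, name: str) -> pd.Series:
        m = self.anova[self.anova.effect == name]
        if m.empty:
            raise KeyError(name)
        return m.iloc[0]

    def to_json(self, path=None) -> str:
        payload = dict(
            anova=self.anova.to_dict(orient="records"),
            posthoc=None if self.posthoc is None else self.posthoc.to_dict(orient="records"),
            bf_treatment=self.bf_treatment,
            bf_label=self.bf_label,
            posterior=None if self.posterior is None else self.posterior.to_dict(orient="records"),
            meta=self.meta,
        )
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "TestReport":
        d = json.loads(text)
        return cls(
            anova=pd.DataFrame(d["anova"]),
            posthoc=None if d.get("posthoc") is None else pd.DataFrame(d["posthoc"]),
            bf_treatment=d.get("bf_treatment"),
            bf_label=d.get("bf_label"),
            posterior=None if d.get("posterior") is None else pd.DataFrame(d["posterior"]),
            meta=d.get("meta", {}),
        )


def _check_full_rank(exog: np.ndarray) -> None:
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise ValueError("fixed-effects design is rank deficient (duplicate predictors?)")


def _fit_mixedlm(formula: str, data: pd.DataFrame, vc: dict | None, reml: bool):
    md = smf.mixedlm(
        formula, data, groups="participant", re_formula="1", vc_formula=vc or None
    )
    _check_full_rank(np.asarray(md.exog))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # Powell handles the boundary-prone variance surface much more
        # reliably than the gradient methods here
        res = md.fit(reml=reml, method="powell", maxiter=2000)
        if not res.converged:
            res = md.fit(reml=reml, method="lbfgs", maxiter=2000)
    if not np.all(np.isfinite(np.asarray(res.bse_fe))):
        raise RuntimeError("mixed model produced non-finite standard errors")
    return res


def fit_lmm(
    table: pd.DataFrame,
    response: str = "amp_uv",
    formula: str | None = None,
    random_slopes: bool = True,
    reml: bool = True,
) -> TestReport:
    """Type-III Wald F tests for all fixed effects of the cross-over model.

    Random structure: per-participant intercept plus, with
    ``random_slopes``, a diagonal variance component per fixed factor (the
    treatment component is what absorbs session-level noise — each session
    carries exactly one treatment). Variance components estimated at the
    boundary (zero) are flagged as singular, not refitted — the fixed-effect
    inference remains valid there. A failed fit (non-finite standard errors)
    escalates to progressively simpler random structures with warnings.
    """
    data = table.copy()
    has_factors = {"stimulus", "roi"}.issubset(data.columns)
    if formula is None:
        formula = (NEURAL_FORMULA if has_factors else BEHAVIOR_FORMULA).format(y=response)
    if np.var(data[response].to_numpy(dtype=float)) == 0:
        # perfectly constant response: every effect is exactly null
        labels = list(_EFFECT_LABELS.values()) if has_factors else [
            "treatment", "session_order"
        ]
        anova = pd.DataFrame(
            [dict(effect=lab, F=0.0, df1=1, df2=float(len(data)), p=1.0) for lab in labels]
        )
        return TestReport(anova=anova, meta=dict(formula=formula, degenerate=True))
    structures: list[tuple[str, dict | None]] = []
    if random_slopes:
        vc = {"vc_treatment": "0 + C(treatment)"}
        if has_factors:
            vc["vc_stimulus"] = "0 + C(stimulus)"
            vc["vc_roi"] = "0 + C(roi)"
        structures.append(("intercept+diagonal-slopes", vc))
        if has_factors:
            structures.append(("intercept+treatment-slope", {"vc_treatment": "0 + C(treatment)"}))
    structures.append(("intercept-only", None))
    res = None
    structure_used = structures[-1][0]
    for i, (name, vc) in enumerate(structures):
        try:
            res = _fit_mixedlm(formula, data, vc, reml)
            structure_used = name
            break
        except (RuntimeError, np.linalg.LinAlgError) as exc:
            if i == len(structures) - 1:
                raise
            warnings.warn(
                f"mixed-model fit failed with {name} random structure ({exc}); "
                "simplifying",
                stacklevel=2,
            )

    design_info = res.model.data.design_info
    k_fe = len(res.fe_params)
    k_total = len(res.params)
    rows = []
    for term, label in _EFFECT_LABELS.items():
        if term not in design_info.term_name_slices:
            continue
        sl = design_info.term_name_slices[term]
        cols = range(sl.start, sl.stop)
        R = np.zeros((len(list(cols)), k_total))
        for i, c in enumerate(cols):
            R[i, c] = 1.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            wt = res.wald_test(R, use_f=True, scalar=False)
        rows.append(
            dict(
                effect=label,
                F=float(np.squeeze(wt.statistic)),
                df1=int(wt.df_num),
                df2=float(wt.df_denom),
                p=float(np.squeeze(wt.pvalue)),
            )
        )
    anova = pd.DataFrame(rows)
    report = TestReport(
        anova=anova,
        meta=dict(
            formula=formula, reml=reml, nobs=int(res.nobs),
            df_method="residual", random_structure=structure_used,
            converged=bool(res.converged),
            singular=bool(res.vcomp.size and np.any(res.vcomp < 1e-8)),
        ),
    )
    if has_factors:
        report.posthoc = _posthoc_emm(res, data)
    return report


def _emm_vector(design_info, factors: dict, data: pd.DataFrame) -> np.ndarray:
    """Row vector whose dot with the fixed effects gives the estimated
    marginal mean of a factor cell, averaging over the other factors."""
    from patsy import build_design_matrices

    levels = {
        "treatment": sorted(data["treatment"].unique()),
        "stimulus": sorted(data["stimulus"].unique()) if "stimulus" in data else [None],
        "roi": sorted(data["roi"].unique()) if "roi" in data else [None],
        "session_order": sorted(data["session_order"].unique()),
    }
    grid = []
    for t in [factors.get("treatment")] if "treatment" in factors else levels["treatment"]:
        for s in [factors.get("stimulus")] if "stimulus" in factors else levels["stimulus"]:
            for r in [factors.get("roi")] if "roi" in factors else levels["roi"]:
                for o in levels["session_order"]:
                    row = dict(treatment=t, session_order=o)
                    if s is not None:
                        row["stimulus"] = s
                    if r is not None:
                        row["roi"] = r
                    grid.append(row)
    gx = build_design_matrices([design_info], pd.DataFrame(grid))[0]
    return np.asarray(gx).mean(axis=0)


def _posthoc_emm(res, data: pd.DataFrame) -> pd.DataFrame:
    """Post-hoc Z tests on estimated marginal means, Holm-corrected within
    each contrast family (ROI main effect; stimulus-by-ROI cells)."""
    design_info = res.model.data.design_info
    k_fe = len(res.fe_params)
    cov = np.asarray(res.cov_params())[:k_fe, :k_fe]
    beta = np.asarray(res.fe_params)

    def contrast(fa: dict, fb: dict) -> tuple[float, float]:
        c = _emm_vector(design_info, fa, data) - _emm_vector(design_info, fb, data)
        est = float(c @ beta)
        se = float(np.sqrt(c @ cov @ c))
        return est, se

    rois = sorted(data["roi"].unique())
    rows = []
    fam = []
    for i, a in enumerate(rois):
        for b in rois[i + 1:]:
            est, se = contrast({"roi": a}, {"roi": b})
            z = est / se
            fam.append(dict(family="roi", contrast=f"{a} - {b}", estimate=est,
                            se=se, z=z, p=2 * sps.norm.sf(abs(z))))
    rows.extend(_holm_family(fam))
    fam = []
    for roi in rois:
        est, se = contrast({"stimulus": "face", "roi": roi}, {"stimulus": "house", "roi": roi})
        z = est / se
        fam.append(dict(family="stimulus|roi", contrast=f"face - house | {roi}",
                        estimate=est, se=se, z=z, p=2 * sps.norm.sf(abs(z))))
    for stim in sorted(data["stimulus"].unique()):
        for i, a in enumerate(rois):
            for b in rois[i + 1:]:
                est, se = contrast({"stimulus": stim, "roi": a}, {"stimulus": stim, "roi": b})
                z = est / se
                fam.append(dict(family="stimulus|roi", contrast=f"{a} - {b} | {stim}",
                                estimate=est, se=se, z=z, p=2 * sps.norm.sf(abs(z))))
    rows.extend(_holm_family(fam))
    return pd.DataFrame(rows)


def _holm_family(fam: list[dict]) -> list[dict]:
    if not fam:
        return fam
    adj = holm([f["p"] for f in fam])
    for f, a in zip(fam, adj):
        f["p_holm"] = float(a)
    return fam


# --------------------------------------------------------------------------
# Bayes factors and posteriors
# --------------------------------------------------------------------------

def _bic(res) -> float:
    # fixed effects + variance parameters + residual variance
    k = len(res.params) + 1
    return float(-2 * res.llf + k * np.log(res.nobs))


def bayes_factor_treatment(
    table: pd.DataFrame,
    response: str = "amp_uv",
    random_slopes: bool = True,
) -> float:
    """BF10 for the treatment factor via the BIC approximation
    exp((BIC_reduced - BIC_full)/2); the reduced model drops every fixed
    term containing treatment, keeping the random structure."""
    data = table.copy()
    has_factors = {"stimulus", "roi"}.issubset(data.columns)
    full = (NEURAL_FORMULA if has_factors else BEHAVIOR_FORMULA).format(y=response)
    if has_factors:
        reduced = f"{response} ~ C(stimulus, Sum) * C(roi, Sum) + C(session_order, Sum)"
    else:
        reduced = f"{response} ~ C(session_order, Sum)"
    vc = None
    if random_slopes:
        vc = {"vc_treatment": "0 + C(treatment)"}
        if has_factors:
            vc["vc_stimulus"] = "0 + C(stimulus)"
            vc["vc_roi"] = "0 + C(roi)"
    res_full = _fit_mixedlm(full, data, vc, reml=False)
    res_red = _fit_mixedlm(reduced, data, vc, reml=False)
    if not (np.isfinite(res_full.llf) and np.isfinite(res_red.llf)):
        raise RuntimeError("model log-likelihood not finite; BF unavailable")
    return float(np.exp((_bic(res_red) - _bic(res_full)) / 2.0))


def bf_label(bf: float) -> str:
    """Evidence band per the conventional classification scheme (3-10
    moderate, 10-30 strong, 30-100 very strong; inverses favour the null)."""
    bands = [
        (100.0, "extreme evidence for treatment effect"),
        (30.0, "very strong evidence for treatment effect"),
        (10.0, "strong evidence for treatment effect"),
        (3.0, "moderate evidence for treatment effect"),
        (1.0, "anecdotal evidence for treatment effect"),
        (1 / 3, "anecdotal evidence for no treatment effect"),
        (1 / 10, "moderate evidence for no treatment effect"),
        (1 / 30, "strong evidence for no treatment effect"),
        (1 / 100, "very strong evidence for no treatment effect"),
    ]
    for cut, label in bands:
        if bf >= cut:
            return label
    return "extreme evidence for no treatment effect"


def paired_posterior(
    diffs: np.ndarray,
    seed: int = 0,
    n_draws: int = 20000,
    hdi_prob: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Posterior of the mean of paired differences under a normal likelihood
    with the Jeffreys prior: mean ~ location-scale Student-t(n-1). Returns
    (posterior mean, HDI); a point mass yields a zero-width interval."""
    import arviz as az

    d = np.asarray(diffs, dtype=float)
    d = d[np.isfinite(d)]
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 paired differences")
    m, s = d.mean(), d.std(ddof=1)
    if s <= 1e-12 * max(1.0, abs(m)):  # point mass up to float rounding
        return float(m), (float(m), float(m))
    rng = np.random.default_rng(seed)
    draws = m + (s / np.sqrt(n)) * rng.standard_t(df=n - 1, size=n_draws)
    lo, hi = az.hdi(draws, hdi_prob=hdi_prob)
    return float(draws.mean()), (float(lo), float(hi))


def posterior_difference(
    table: pd.DataFrame,
    stimulus: str,
    roi: str,
    seed: int = 0,
    n_draws: int = 20000,
) -> tuple[float, tuple[float, float]]:
    """Posterior mean OT-PL difference and 95% HDI within one
    stimulus x ROI cell (per-participant paired differences, averaged over
    presentation rates)."""
    cell = table[(table.stimulus == stimulus) & (table.roi == roi)]
    piv = cell.groupby(["participant", "treatment"])["amp_uv"].mean().unstack()
    if not {"OT", "PL"}.issubset(piv.columns):
        raise ValueError("cell lacks one of the treatment conditions")
    diffs = (piv["OT"] - piv["PL"]).dropna().to_numpy()
    return paired_posterior(diffs, seed=seed, n_draws=n_draws)


# --------------------------------------------------------------------------
# reliability and power
# --------------------------------------------------------------------------

def test_retest(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between session-1 and session-2 mean responses
    per stimulus type, paired by participant."""
    rows = []
    for stim, sub in table.groupby("stimulus"):
        piv = sub.groupby(["participant", "session"])["amp_uv"].mean().unstack()
        piv = piv.dropna()
        if len(piv) < 3:
            raise ValueError("need at least 3 paired participants")
        r, p = sps.pearsonr(piv[1], piv[2])
        rows.append(dict(stimulus=stim, r=float(r), p=float(p), n=len(piv)))
    return pd.DataFrame(rows)


def rm_power(
    n: int, d: float, rho: float, alpha: float = 0.05, m: int = 2
) -> float:
    """Power of the within-factor repeated-measures F test.

    With ``m`` repeated measurements correlated at ``rho``, effect size
    f = d/2 and noncentrality lambda = n*m*f^2/(1-rho); power is the upper
    tail of the noncentral F(1, n-1; lambda) beyond the central critical
    value at ``alpha``.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0 <= rho < 1:
        raise ValueError("rho must be in [0, 1)")
    f = d / 2.0
    lam = n * m * f**2 / (1.0 - rho)
    fcrit = sps.f.isf(alpha, 1, n - 1)
    if lam == 0:  # central case (scipy's ncf is numerically unstable at 0)
        return float(sps.f.sf(fcrit, 1, n - 1))
    return float(sps.ncf.sf(fcrit, 1, n - 1, lam))


def treatment_rejection_rate(
    config,
    n_replicates: int,
    seed: int,
    alpha: float = 0.05,
    mad_k: float = 3.0,
) -> float:
    """Fraction of replicate simulated studies whose treatment main effect
    rejects at ``alpha`` (outlier screening + mixed model per replicate).
    Under the generator's null (zero treatment effect) this estimates the
    type-I error of the full analysis chain."""
    from .simulate import simulate_response_table

    seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    rej = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in seeds:
            t = simulate_response_table(config, int(s))
            keep = mad_outliers(t["amp_uv"].to_numpy(), k=mad_k)
            rep = fit_lmm(t[keep])
            rej += rep.effect("treatment")["p"] < alpha
    return rej / n_replicates


# --------------------------------------------------------------------------
# study-level driver
# --------------------------------------------------------------------------

def run_stats(
    table: pd.DataFrame,
    behavior: pd.DataFrame | None = None,
    mad_k: float = 3.0,
    alpha: float = 0.05,
    seed: int = 0,
    n_draws: int = 20000,
) -> dict:
    """Outlier screening, mixed models, BF and posteriors for a study.

    Returns {"neural": TestReport, "behavior_accuracy": ..., "behavior_rt":
    ..., "test_retest": DataFrame}; the BF and posterior differences are
    computed when the treatment effect is non-significant, mirroring the
    null-validation workflow.
    """
    keep = mad_outliers(table["amp_uv"].to_numpy(), k=mad_k)
    clean = table[keep].reset_index(drop=True)
    neural = fit_lmm(clean)
    neural.meta["n_outliers_removed"] = int((~keep).sum())
    neural.meta["n_rows_total"] = int(len(table))
    p_treat = neural.effect("treatment")["p"]
    if p_treat > alpha:
        neural.bf_treatment = bayes_factor_treatment(clean)
        neural.bf_label = bf_label(neural.bf_treatment)
        rows = []
        for stim in sorted(clean["stimulus"].unique()):
            for roi in sorted(clean["roi"].unique()):
                mdiff, (lo, hi) = posterior_difference(
                    clean, stim, roi, seed=seed, n_draws=n_draws
                )
                rows.append(dict(stimulus=stim, roi=roi, mean_diff=mdiff,
                                 hdi_low=lo, hdi_high=hi))
        neural.posterior = pd.DataFrame(rows)
    try:
        retest = test_retest(clean)
    except ValueError:
        retest = None  # fewer than 3 paired participants
    out = dict(neural=neural, test_retest=retest)
    if behavior is not None and len(behavior):
        for col, key in (("accuracy", "behavior_accuracy"), ("mean_rt", "behavior_rt")):
            sub = behavior.dropna(subset=[col]).copy()
            rep = fit_lmm(sub, response=col)
            if rep.effect("treatment")["p"] > alpha:
                rep.bf_treatment = bayes_factor_treatment(sub, response=col)
                rep.bf_label = bf_label(rep.bf_treatment)
                piv = sub.groupby(["participant", "treatment"])[col].mean().unstack()
                if {"OT", "PL"}.issubset(piv.columns):
                    diffs = (piv["OT"] - piv["PL"]).dropna().to_numpy()
                    mdiff, (lo, hi) = paired_posterior(diffs, seed=seed, n_draws=n_draws)
                    rep.posterior = pd.DataFrame(
                        [dict(measure=col, mean_diff=mdiff, hdi_low=lo, hdi_high=hi)]
                    )
            out[key] = rep
    return out


def render_report(reports: dict) -> str:
    """Human-readable text report mirroring the F-table layout."""
    lines = []
    neural: TestReport = reports["neural"]
    lines.append("Neural responses — linear mixed model (type-III Wald F)")
    lines.append("-" * 60)
    for _, row in neural.anova.iterrows():
        lines.append(
            f"{row['effect']:<28s} F({row['df1']:.0f}, {row['df2']:.0f}) = "
            f"{row['F']:6.2f}   p = {row['p']:.3f}"
        )
    if neural.meta.get("n_outliers_removed") is not None:
        lines.append(
            f"outliers removed: {neural.meta['n_outliers_removed']} of "
            f"{neural.meta.get('n_rows_total', '?')}"
        )
    if neural.posthoc is not None:
        lines.append("")
        lines.append("Post-hoc contrasts (Z tests, Holm-corrected)")
        for _, row in neural.posthoc.iterrows():
            lines.append(
                f"  {row['contrast']:<24s} est = {row['estimate']:+.3f} µV  "
                f"z = {row['z']:+6.2f}  p_holm = {row['p_holm']:.4f}"
            )
    if neural.bf_treatment is not None:
        lines.append("")
        lines.append(
            f"BF10 (treatment, BIC approximation) = {neural.bf_treatment:.3g} "
            f"[{neural.bf_label}]"
        )
    if neural.posterior is not None:
        lines.append("Posterior OT−PL differences (95% HDI):")
        for _, row in neural.posterior.iterrows():
            lines.append(
                f"  {row['stimulus']:<6s} {row['roi']:<4s} {row['mean_diff']:+.3f} µV "
                f"[{row['hdi_low']:+.3f}, {row['hdi_high']:+.3f}]"
            )
    tr = reports.get("test_retest")
    if tr is not None:
        lines.append("")
        lines.append("Test-retest reliability (Pearson r between sessions):")
        for _, row in tr.iterrows():
            lines.append(f"  {row['stimulus']:<6s} r = {row['r']:.2f} (n = {row['n']:.0f})")
    for key, title in (("behavior_accuracy", "Accuracy"), ("behavior_rt", "Reaction time")):
        rep = reports.get(key)
        if rep is None:
            continue
        lines.append("")
        lines.append(f"{title} — treatment LMM")
        for _, row in rep.anova.iterrows():
            lines.append(
                f"  {row['effect']:<16s} F({row['df1']:.0f}, {row['df2']:.0f}) = "
                f"{row['F']:6.2f}   p = {row['p']:.3f}"
            )
        if rep.bf_treatment is not None:
            lines.append(f"  BF10 = {rep.bf_treatment:.3g} [{rep.bf_label}]")
    return "\n".join(lines)
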