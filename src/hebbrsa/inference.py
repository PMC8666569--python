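"""Group-level inference on RSA effects and behavior.

Implements the study's statistical endpoints on any effects table produced
by the RSA pipeline:

* phase x sequence-type linear mixed models (REML, random subject intercept,
  optional random slopes) with Wald F-tests for the interaction and
  model-based marginal means;
* the learning test — does the repeat-minus-novel effect grow over runs —
  as the sequence-type x run interaction with run as a linear covariate;
* per-ROI contrasts of the repeat effect against zero with BH-FDR across
  ROIs within each phase;
* signal-detection sensitivity d' = Phi^-1(hit rate) - Phi^-1(false-alarm
  rate) for the match/mismatch recognition behavior, with the log-linear
  (add 0.5 to counts / 1 to totals) correction engaged only at 0/1 rates.

Wald tests use the residual degrees of freedom of the fixed-effects design
(any recognized df approximation is acceptable here; the method is recorded
in the result metadata).  A two-stage summary-statistics engine (per-subject
cell means -> repeated-measures ANOVA) is provided as a clearly labelled
approximation for the interaction tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.anova import AnovaRM

from .exceptions import InvalidInputError, UndefinedStatisticError
from .roisel import bh_fdr, one_sample_t


@dataclass(frozen=True)
class MixedModelSpec:
    """Contract for a mixed model: fixed factors, random structure, contrasts."""

    response: str = "value"
    fixed: tuple[str, ...] = ("phase", "seq_type")
    random: str = "intercept"          # "intercept" or a re_formula like "~run_c"
    contrasts: tuple[str, ...] = ()


@dataclass
class FitResult:
    params: pd.DataFrame
    interaction_tests: dict
    marginal_means: pd.DataFrame | None
    converged: bool
    engine: str
    df_method: str
    formula: str


def d_prime(hits: int, misses: int, false_alarms: int,
            correct_rejections: int) -> float:
    """Sensitivity d'; log-linear correction only when a rate hits 0 or 1."""
    for v in (hits, misses, false_alarms, correct_rejections):
        if v < 0:
            raise InvalidInputError("counts must be non-negative")
    n_sig = hits + misses
    n_noise = false_alarms + correct_rejections
    if n_sig == 0 or n_noise == 0:
        raise UndefinedStatisticError("need at least one signal and one noise trial")

    def rate(k, n):
        r = k / n
        if r in (0.0, 1.0):
            r = (k + 0.5) / (n + 1.0)
        return r

    return float(stats.norm.ppf(rate(hits, n_sig)) - stats.norm.ppf(rate(false_alarms, n_noise)))


def behavioral_summary(behav: pd.DataFrame,
                       by=("subject", "delay_s", "seq_type")) -> pd.DataFrame:
    """Per-cell hit/false-alarm rates, d', and proportion correct.

    Mismatch probes are the signal class: a hit is a "mismatch" response on
    a mismatch trial, a false alarm a "mismatch" response on a match trial.
    """
    rows = []
    for key, grp in behav.groupby(list(by)):
        sig = grp[grp["probe_type"] == "mismatch"]
        noi = grp[grp["probe_type"] == "match"]
        hits = int((sig["response"] == "mismatch").sum())
        fas = int((noi["response"] == "mismatch").sum())
        d = d_prime(hits, len(sig) - hits, fas, len(noi) - fas)
        row = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        row.update(
            hit_rate=hits / len(sig) if len(sig) else np.nan,
            fa_rate=fas / len(noi) if len(noi) else np.nan,
            d_prime=d,
            proportion_correct=float(grp["correct"].mean()),
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _wald_f(res, names) -> dict:
    """Wald F-test that the named fixed-effect coefficients are jointly zero."""
    fe = res.fe_params
    idx = [list(fe.index).index(n) for n in names]
    b = fe.to_numpy()[idx]
    C = np.asarray(res.cov_params())[np.ix_(idx, idx)]
    q = len(idx)
    F = float(b @ np.linalg.solve(C, b) / q)
    df_denom = int(res.nobs - len(fe))
    p = float(stats.f.sf(F, q, df_denom))
    return {"F": F, "df_num": q, "df_denom": df_denom, "p": p, "terms": list(names)}


def _marginal_means(res, data: pd.DataFrame, factors) -> pd.DataFrame:
    """Model-based cell means with normal-approximation 95% CIs."""
    from patsy import dmatrix

    cells = data[list(factors)].drop_duplicates().sort_values(list(factors))
    design_info = res.model.data.design_info
    X = np.asarray(dmatrix(design_info, cells))
    fe = res.fe_params.to_numpy()
    C = np.asarray(res.cov_params())[: len(fe), : len(fe)]
    mean = X @ fe
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, C, X))
    out = cells.reset_index(drop=True)
    out["mean"] = mean
    out["se"] = se
    out["ci_low"] = mean - 1.96 * se
    out["ci_high"] = mean + 1.96 * se
    return out


def _fit_mixedlm(model):
    """REML fit with an optimizer fallback chain (bfgs -> powell -> nm)."""
    last = None
    for method in ("bfgs", "powell", "nm"):
        try:
            res = model.fit(reml=True, method=method)
        except np.linalg.LinAlgError as err:
            last = err
            continue
        if res.converged:
            return res
        last = res
    if last is None or isinstance(last, np.linalg.LinAlgError):
        raise RuntimeError(f"mixed model failed to fit: {last}")
    return last        # best-effort non-converged fit; caller checks .converged


def _check_subjects(df: pd.DataFrame):
    if df["subject"].nunique() < 2:
        raise InvalidInputError(
            "random subject intercept is unidentifiable with a single subject"
        )


def fit_effects_model(effects: pd.DataFrame,
                      spec: MixedModelSpec = MixedModelSpec(),
                      engine: str = "mixed") -> FitResult:
    """Phase x sequence-type (etc.) model on an RSA effects table.

    ``engine='mixed'`` fits a REML linear mixed model with a random subject
    intercept (plus ``spec.random`` slopes); ``engine='two-stage'`` is the
    summary-statistics approximation: per-subject cell means followed by a
    repeated-measures ANOVA (valid for balanced within-subject factors).
    """
    df = effects.dropna(subset=[spec.response]).copy()
    _check_subjects(df)
    factors = list(spec.fixed)
    fixed_formula = " * ".join(f"C({f})" for f in factors)
    formula = f"{spec.response} ~ {fixed_formula}"

    if engine == "two-stage":
        agg = df.groupby(["subject", *factors], as_index=False)[spec.response].mean()
        res = AnovaRM(agg, depvar=spec.response, subject="subject",
                      within=factors).fit()
        tab = res.anova_table
        tests = {}
        for term in tab.index:
            tests[term] = {
                "F": float(tab.loc[term, "F Value"]),
                "df_num": float(tab.loc[term, "Num DF"]),
                "df_denom": float(tab.loc[term, "Den DF"]),
                "p": float(tab.loc[term, "Pr > F"]),
                "terms": [term],
            }
        mm = agg.groupby(factors, as_index=False)[spec.response].mean().rename(
            columns={spec.response: "mean"})
        return FitResult(params=tab.reset_index(), interaction_tests=tests,
                         marginal_means=mm, converged=True, engine="two-stage",
                         df_method="repeated-measures ANOVA",
                         formula=f"{spec.response} ~ {' * '.join(factors)} | subject")

    re_formula = None if spec.random == "intercept" else spec.random
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM.from_formula(formula, groups="subject",
                                     re_formula=re_formula, data=df)
        res = _fit_mixedlm(model)
        if not res.converged and re_formula is not None:
            warnings.warn("singular/non-converged random-slope fit; "
                          "refitting with random intercept only")
            model = MixedLM.from_formula(formula, groups="subject", data=df)
            res = _fit_mixedlm(model)
    if not res.converged:
        raise RuntimeError(f"mixed model failed to converge: {res.summary()}")

    fe = res.fe_params
    params = pd.DataFrame({
        "term": fe.index,
        "estimate": fe.to_numpy(),
        "se": res.bse_fe.to_numpy(),
        "p": res.pvalues[: len(fe)].to_numpy(),
    })
    tests = {}
    if len(factors) >= 2:
        inter = [n for n in fe.index if ":" in n]
        if inter:
            tests["interaction"] = _wald_f(res, inter)
    for f in factors:
        main = [n for n in fe.index if f"C({f})" in n and ":" not in n]
        if main:
            tests[f] = _wald_f(res, main)
    mm = _marginal_means(res, df, factors)
    return FitResult(params=params, interaction_tests=tests, marginal_means=mm,
                     converged=bool(res.converged), engine="mixed",
                     df_method="Wald F with fixed-effects residual df",
                     formula=formula)


def run_slope_test(per_run_effects: pd.DataFrame,
                   random: str = "intercept") -> dict:
    """Sequence-type x run interaction on per-run RSA effects.

    Run enters as a linear covariate (centered); a positive estimate means
    the repeat-trial effect grows faster over runs than the novel-trial
    effect.  Returns the slope-difference estimate with its t and p.
    """
    df = per_run_effects.dropna(subset=["value"]).copy()
    _check_subjects(df)
    runs = pd.to_numeric(df["run"], errors="coerce")
    if runs.nunique() < 3:
        raise InvalidInputError("need at least 3 runs for a run-slope test")
    df["run_c"] = runs - runs.mean()
    has_phase = df["phase"].nunique() > 1
    base = "C(phase) * C(seq_type)" if has_phase else "C(seq_type)"
    formula = f"value ~ {base} + run_c + run_c:C(seq_type)"
    re_formula = None if random == "intercept" else random
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM.from_formula(formula, groups="subject",
                                     re_formula=re_formula, data=df)
        res = _fit_mixedlm(model)
    name = [n for n in res.fe_params.index if "run_c" in n and "seq_type" in n]
    if len(name) != 1:
        raise RuntimeError(f"unexpected slope terms: {name}")
    est = float(res.fe_params[name[0]])
    se = float(res.bse_fe[name[0]])
    t = est / se
    df_denom = int(res.nobs - len(res.fe_params))
    p = float(2 * stats.t.sf(abs(t), df_denom))
    return {"term": name[0], "estimate": est, "se": se, "t": t,
            "df": df_denom, "p": p, "formula": formula}


def per_roi_contrasts(effects: pd.DataFrame, phases=("encoding", "delay", "probe"),
                      seq_type: str = "repeat", alpha: float = 0.05) -> pd.DataFrame:
    """Contrast each (ROI, phase) repeat effect against zero, BH-FDR within phase.

    Expects pooled per-subject effects (one row per subject x roi x phase of
    the requested sequence type); two-sided p with the sign carried by t.
    """
    df = effects[(effects["seq_type"] == seq_type)]
    if "run" in df.columns:
        df = df[df["run"] == "pooled"]
    missing = []
    out = []
    for phase in phases:
        sub = df[df["phase"] == phase]
        rows = []
        for roi, grp in sub.groupby("roi", dropna=False):
            vals = grp["value"].dropna()
            if len(vals) < 2:
                missing.append((roi, phase))
                continue
            t, p = one_sample_t(vals)
            rows.append(dict(roi=roi, phase=phase, mean=float(vals.mean()),
                             t_stat=t, p_value=max(p, np.nextafter(0, 1))))
        if rows:
            dfp = pd.DataFrame(rows)
            dfp["p_fdr"] = bh_fdr(dfp["p_value"])
            dfp["significant"] = (dfp["p_fdr"] < alpha) & (dfp["t_stat"] > 0)
            out.append(dfp)
    result = pd.concat(out, ignore_index=True) if out else pd.DataFrame(
        columns=["roi", "phase", "mean", "t_stat", "p_value", "p_fdr", "significant"])
    result.attrs["excluded_cells"] = missing
    return result
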