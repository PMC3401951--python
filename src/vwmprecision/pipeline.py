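"""Cohort-level statistical analysis of delayed-reproduction precision data.

Stages, mirroring the study's analysis plan:

1. Per-participant measures: circular SD of response error per condition
   and serial position; chance-corrected, sensorimotor-corrected precision;
   precision differences by variance subtraction; a mixture-model fit to
   the three-item data.
2. Per-measure outlier exclusion (|z| > 2.5 from the sample mean, strict,
   single pass, per dependent variable only), with a complete exclusion log.
3. Developmental statistics: OLS regressions of each measure on age
   (continuous), partial correlations controlling for estimated IQ,
   one-sample t-tests against zero (chance) per year group, a
   repeated-measures serial-position ANOVA with Greenhouse-Geisser
   correction plus pairwise t-tests, and per-parameter age regressions for
   the mixture fit.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
from scipy import stats

from . import circular
from .circular import (
    angular_error,
    chance_precision,
    circular_sd,
    precision_difference,
    sensorimotor_corrected_precision,
)
from .io import AnalysisConfig, RunConfig, build_geometries
from .mixture import FitConfig, MixtureFit, fit_em
from .simulate import TrialRecord

__all__ = [
    "PRECISION_MEASURES",
    "RegressionResult",
    "CohortResult",
    "exclude_outliers",
    "compute_measures",
    "age_regression",
    "partial_correlation",
    "serial_position_anova",
    "response_histograms",
    "parameter_age_regressions",
    "run_pipeline",
]

#: Chance-corrected precision measures tested against zero and regressed on age.
PRECISION_MEASURES = [
    "precision_sm",
    "precision_vwm1",
    "precision_vwm3",
    "precision_sp1",
    "precision_sp2",
    "precision_sp3",
]

#: All per-participant dependent variables entering the age analyses.
ALL_MEASURES = PRECISION_MEASURES + ["precision_diff_load", "precision_diff_recency"]

MIXTURE_PARAMS = ["kappa", "p_target", "p_nontarget", "p_uniform"]


@dataclass(frozen=True)
class RegressionResult:
    """OLS of a measure on age: slope, adjusted r^2, p-value of the slope."""

    slope: float
    r2_adj: float
    p: float
    n: int


@dataclass
class CohortResult:
    """All tabular outputs of the cohort pipeline."""

    measures: pd.DataFrame
    regressions: pd.DataFrame
    partials: pd.DataFrame
    group_ttests: pd.DataFrame
    sp_anova: dict
    sp_pairwise: pd.DataFrame
    param_regressions: pd.DataFrame
    histograms: dict
    exclusion_log: pd.DataFrame

    def to_csvs(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.measures.to_csv(outdir / "measures.csv", index=False)
        self.regressions.to_csv(outdir / "age_regressions.csv", index=False)
        self.partials.to_csv(outdir / "partial_correlations.csv", index=False)
        self.group_ttests.to_csv(outdir / "group_ttests.csv", index=False)
        pd.DataFrame([self.sp_anova]).to_csv(outdir / "sp_anova.csv", index=False)
        self.sp_pairwise.to_csv(outdir / "sp_pairwise.csv", index=False)
        self.param_regressions.to_csv(outdir / "parameter_regressions.csv", index=False)
        self.exclusion_log.to_csv(outdir / "exclusion_log.csv", index=False)
        hist = pd.DataFrame(
            {
                "bin_left": self.histograms["bin_edges"][:-1],
                "bin_right": self.histograms["bin_edges"][1:],
                "target": self.histograms["target"],
                "nontarget": self.histograms["nontarget"],
            }
        )
        hist.to_csv(outdir / "response_histograms.csv", index=False)


@functools.lru_cache(maxsize=256)
def _chance(n: int, replicates: int, seed: int) -> float:
    return chance_precision(n, replicates, seed)


def exclude_outliers(values: pd.Series, z_threshold: float = 2.5):
    """Drop values with |z| > threshold from the full-sample mean/SD.

    Single pass, strict inequality; a zero-variance sample excludes
    nothing. Returns the retained series and a log of exclusions.
    NaNs are ignored (never counted as outliers, never retained).
    """
    clean = values.dropna()
    if len(clean) < 5:
        raise ValueError(f"need >= 5 values for outlier screening, got {len(clean)}")
    sd = clean.std(ddof=1)
    log = []
    if sd == 0 or not np.isfinite(sd):
        return clean, log
    z = (clean - clean.mean()) / sd
    mask = z.abs() > z_threshold
    for idx in clean.index[mask]:
        log.append(
            {
                "stage": "outlier",
                "measure": values.name,
                "participant_id": idx,
                "value": float(clean[idx]),
                "reason": f"|z|={abs(z[idx]):.3f} > {z_threshold}",
            }
        )
    return clean[~mask], log


def compute_measures(
    records: list[TrialRecord],
    analysis: AnalysisConfig | None = None,
    fit_config: FitConfig | None = None,
    fit_mixture: bool = True,
):
    """Per-participant measures from one participant's trial records.

    Returns ``(measures_dict, log_entries)``. Undefined variance
    differences yield NaN and are logged, never silently dropped.
    """
    analysis = analysis or AnalysisConfig()
    fit_config = fit_config or FitConfig()
    pid = records[0].participant_id if records else "?"
    log: list[dict] = []
    by_cond: dict[str, list[TrialRecord]] = {"sensorimotor": [], "vwm1": [], "vwm3": []}
    for t in records:
        by_cond[t.condition].append(t)

    def errors_of(trials):
        return np.array(
            [
                angular_error(
                    t.response_orientation,
                    t.stimulus_orientations[t.probed_index],
                    math.pi,
                )
                for t in trials
            ]
        )

    def note(measure, reason):
        log.append(
            {
                "stage": "measure",
                "measure": measure,
                "participant_id": pid,
                "value": math.nan,
                "reason": reason,
            }
        )

    out: dict = {"participant_id": pid}
    floor = analysis.sd_floor
    reps, cseed = analysis.chance_replicates, analysis.chance_seed

    def sd_or_nan(trials, label):
        if len(trials) < max(2, analysis.min_trials_per_cell):
            note(label, f"only {len(trials)} trials")
            return math.nan, len(trials)
        return circular_sd(errors_of(trials)), len(trials)

    sd_sm, n_sm = sd_or_nan(by_cond["sensorimotor"], "precision_sm")
    sd_1, n_1 = sd_or_nan(by_cond["vwm1"], "precision_vwm1")
    out["sd_sm"], out["sd_vwm1"] = sd_sm, sd_1
    out["n_sm"], out["n_vwm1"] = n_sm, n_1

    out["precision_sm"] = (
        1.0 / max(sd_sm, floor) - _chance(n_sm, reps, cseed)
        if np.isfinite(sd_sm)
        else math.nan
    )

    def corrected(sd_task, n_task, label):
        if not (np.isfinite(sd_task) and np.isfinite(sd_sm)):
            return math.nan
        raw = sensorimotor_corrected_precision(sd_task, sd_sm)
        if math.isnan(raw):
            note(label, f"non-positive variance difference (sd={sd_task:.3f} <= sd_sm={sd_sm:.3f})")
            return math.nan
        return raw - _chance(n_task, reps, cseed)

    out["precision_vwm1"] = corrected(sd_1, n_1, "precision_vwm1")

    # three-item task: per serial position, then mean via variance averaging
    sp_sds, sp_ns = [], []
    for sp in range(3):
        sub = [t for t in by_cond["vwm3"] if t.probed_index == sp]
        sd_sp, n_sp = sd_or_nan(sub, f"precision_sp{sp + 1}")
        sp_sds.append(sd_sp)
        sp_ns.append(n_sp)
        out[f"sd_sp{sp + 1}"] = sd_sp
        out[f"n_sp{sp + 1}"] = n_sp
        out[f"precision_sp{sp + 1}"] = corrected(sd_sp, n_sp, f"precision_sp{sp + 1}")

    n_3 = len(by_cond["vwm3"])
    out["n_vwm3"] = n_3
    if all(np.isfinite(s) for s in sp_sds):
        sd_3 = math.sqrt(sum(s * s for s in sp_sds) / 3.0)
        out["sd_vwm3"] = sd_3
        out["precision_vwm3"] = corrected(sd_3, n_3, "precision_vwm3")
        # load difference: raw three-item variance minus raw one-item variance
        if np.isfinite(sd_1):
            diff = precision_difference(sd_3, sd_1)
            if math.isnan(diff):
                note("precision_diff_load", "non-positive variance difference")
            out["precision_diff_load"] = diff
        else:
            out["precision_diff_load"] = math.nan
        # recency difference: pooled SP1/2 variance minus SP3 variance
        pooled_12 = math.sqrt((sp_sds[0] ** 2 + sp_sds[1] ** 2) / 2.0)
        rec = precision_difference(pooled_12, sp_sds[2])
        if math.isnan(rec):
            note("precision_diff_recency", "non-positive variance difference")
        out["precision_diff_recency"] = rec
    else:
        out["sd_vwm3"] = math.nan
        out["precision_vwm3"] = math.nan
        out["precision_diff_load"] = math.nan
        out["precision_diff_recency"] = math.nan

    for key in MIXTURE_PARAMS + ["loglik", "converged", "kappa_identifiable"]:
        out[key] = math.nan
    if fit_mixture and n_3 >= fit_config.min_trials:
        fit = fit_em(build_geometries(by_cond["vwm3"]), fit_config)
        out["kappa"] = fit.params.kappa
        out["p_target"] = fit.params.p_target
        out["p_nontarget"] = fit.params.p_nontarget
        out["p_uniform"] = fit.params.p_uniform
        out["loglik"] = fit.log_likelihood
        out["converged"] = bool(fit.converged)
        out["kappa_identifiable"] = bool(fit.kappa_identifiable)
        if not fit.converged:
            note("mixture_fit", "EM did not converge")
    elif fit_mixture:
        note("mixture_fit", f"only {n_3} three-item trials (< {fit_config.min_trials})")
    return out, log


def age_regression(measure, ages) -> RegressionResult:
    """OLS of a dependent measure on age (continuous predictor)."""
    y = np.asarray(measure, dtype=float)
    x = np.asarray(ages, dtype=float)
    keep = np.isfinite(y) & np.isfinite(x)
    y, x = y[keep], x[keep]
    if y.size < 10:
        raise ValueError(f"need >= 10 retained participants, got {y.size}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) age predictor")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        r2_adj=float(model.rsquared_adj),
        p=float(model.pvalues[1]),
        n=int(y.size),
    )


def partial_correlation(measure, ages, covariate, method: str = "pearson"):
    """Correlation between a measure and age, controlling for a covariate.

    Pearson on residuals by default (rank-based via ``method='spearman'``).
    A constant covariate degrades gracefully to the plain correlation with
    a warning. Returns ``(rho, p)``.
    """
    df = pd.DataFrame(
        {
            "y": np.asarray(measure, dtype=float),
            "age": np.asarray(ages, dtype=float),
            "cov": np.asarray(covariate, dtype=float),
        }
    ).dropna()
    if len(df) < 10:
        raise ValueError(f"need >= 10 complete cases, got {len(df)}")
    if df["cov"].nunique() == 1:
        import warnings

        warnings.warn("constant covariate; falling back to plain correlation")
        if method == "spearman":
            rho, p = stats.spearmanr(df["y"], df["age"])
        else:
            rho, p = stats.pearsonr(df["y"], df["age"])
        return float(rho), float(p)
    res = pg.partial_corr(data=df, x="age", y="y", covar="cov", method=method)
    return float(res["r"].iloc[0]), float(res["p_val"].iloc[0])


def serial_position_anova(sp_frame: pd.DataFrame):
    """Within-subject one-way ANOVA over the three serial positions.

    ``sp_frame`` has one row per participant and columns
    ``precision_sp1..3``; incomplete rows are dropped listwise. Returns
    ``(anova_dict, pairwise_frame)`` where the ANOVA p-value and degrees of
    freedom carry the Greenhouse-Geisser correction.
    """
    cols = ["precision_sp1", "precision_sp2", "precision_sp3"]
    complete = sp_frame[cols].dropna()
    if len(complete) < 3:
        raise ValueError(f"need >= 3 complete serial-position triples, got {len(complete)}")
    long = complete.rename_axis("subject").reset_index().melt(
        id_vars="subject", value_vars=cols, var_name="sp", value_name="precision"
    )
    aov = pg.rm_anova(
        data=long, dv="precision", within="sp", subject="subject", correction=True
    )
    row = aov.iloc[0]
    eps = float(row["eps"]) if "eps" in aov.columns and np.isfinite(row.get("eps", np.nan)) else 1.0
    p = (
        row["p_GG_corr"]
        if "p_GG_corr" in aov.columns and np.isfinite(row.get("p_GG_corr", np.nan))
        else row["p_unc"]
    )
    anova = {
        "F": float(row["F"]),
        "ddof1": float(row["ddof1"]) * eps,
        "ddof2": float(row["ddof2"]) * eps,
        "eps_gg": eps,
        "p": float(p),
        "n": int(len(complete)),
    }
    pairs = [("precision_sp3", "precision_sp2"), ("precision_sp3", "precision_sp1"),
             ("precision_sp1", "precision_sp2")]
    rows = []
    for a, b in pairs:
        sub = sp_frame[[a, b]].dropna()
        t, p_t = stats.ttest_rel(sub[a], sub[b])
        rows.append(
            {
                "contrast": f"{a.replace('precision_', '')} vs {b.replace('precision_', '')}",
                "t": float(t),
                "dof": int(len(sub) - 1),
                "p": float(p_t),
                "mean_diff": float((sub[a] - sub[b]).mean()),
                "n": int(len(sub)),
            }
        )
    return anova, pd.DataFrame(rows)


def response_histograms(records: list[TrialRecord], n_bins: int = 9):
    """Response frequencies in equal orientation bins across pi rad.

    Errors are re-centred on the target (and, separately, on each
    non-target) and binned into ``n_bins`` equal bins spanning
    ``(-pi/2, pi/2]``. The target histogram sums to the number of trials;
    the non-target histogram pools both non-targets per trial.
    """
    vwm3 = [t for t in records if t.condition == "vwm3"]
    edges = np.linspace(-math.pi / 2, math.pi / 2, n_bins + 1)
    t_err, nt_err = [], []
    for t in vwm3:
        resp = t.response_orientation
        t_err.append(angular_error(resp, t.stimulus_orientations[t.probed_index], math.pi))
        for i, o in enumerate(t.stimulus_orientations):
            if i != t.probed_index:
                nt_err.append(angular_error(resp, o, math.pi))
    target_counts, _ = np.histogram(t_err, bins=edges)
    nontarget_counts, _ = np.histogram(nt_err, bins=edges)
    return {
        "bin_edges": edges,
        "target": target_counts,
        "nontarget": nontarget_counts,
        "n_trials": len(vwm3),
    }


def parameter_age_regressions(
    fits: pd.DataFrame,
    ages,
    covariate,
    analysis: AnalysisConfig | None = None,
):
    """Age regressions and partial correlations for each mixture parameter.

    Non-converged fits are excluded (and logged); the outlier rule is then
    applied per parameter. Returns ``(results_frame, log_entries)``.
    """
    analysis = analysis or AnalysisConfig()
    df = fits.copy()
    df["age"] = np.asarray(ages, dtype=float)
    df["cov"] = np.asarray(covariate, dtype=float)
    log = []
    conv = df["converged"].astype(bool) if "converged" in df else pd.Series(True, index=df.index)
    for idx in df.index[~conv]:
        log.append(
            {
                "stage": "fit",
                "measure": "mixture_fit",
                "participant_id": df.loc[idx].get("participant_id", idx),
                "value": math.nan,
                "reason": "non-converged fit excluded from parameter regressions",
            }
        )
    df = df[conv]
    if "participant_id" in df:
        df = df.set_index("participant_id")
    rows = []
    for param in MIXTURE_PARAMS:
        retained, excl = exclude_outliers(df[param].rename(param), analysis.outlier_z)
        log.extend(excl)
        sub = df.loc[retained.index]
        reg = age_regression(sub[param], sub["age"])
        rho, p_rho = partial_correlation(
            sub[param], sub["age"], sub["cov"], analysis.corr_method
        )
        rows.append(
            {
                "parameter": param,
                "n": reg.n,
                "slope": reg.slope,
                "r2_adj": reg.r2_adj,
                "p": reg.p,
                "partial_rho": rho,
                "partial_p": p_rho,
            }
        )
    return pd.DataFrame(rows), log


def _assign_groups(measures: pd.DataFrame, analysis: AnalysisConfig) -> pd.Series:
    if analysis.grouping == "quintile":
        return pd.qcut(measures["age"], 5, labels=[1, 2, 3, 4, 5]).astype(int)
    groups = measures["year_group"].astype(int)
    if analysis.collapse_years:
        groups = groups.replace({3: 4})
    return groups


def run_pipeline(
    trials: list[TrialRecord],
    participants: pd.DataFrame,
    config: RunConfig | None = None,
) -> CohortResult:
    """Run the full cohort analysis on trial and participant tables.

    Deterministic given the inputs and configuration; every exclusion
    (outlier, undefined variance difference, non-converged fit) appears in
    the exclusion log.
    """
    config = config or RunConfig()
    analysis, fit_cfg = config.analysis, config.fit
    log: list[dict] = []

    by_pid: dict[str, list[TrialRecord]] = {}
    for t in trials:
        by_pid.setdefault(t.participant_id, []).append(t)

    rows = []
    for pid, recs in by_pid.items():
        row, part_log = compute_measures(recs, analysis, fit_cfg)
        rows.append(row)
        log.extend(part_log)
    measures = pd.DataFrame(rows)
    part = participants.rename(columns={"id": "participant_id"})
    measures = measures.merge(
        part[["participant_id", "age", "year_group", "fsiq_e"]],
        on="participant_id",
        how="inner",
    )
    measures["group"] = _assign_groups(measures, analysis)

    # per-measure outlier exclusion, then age regression + partial correlation
    reg_rows, partial_rows = [], []
    retained_masks: dict[str, pd.Series] = {}
    indexed = measures.set_index("participant_id")
    for name in ALL_MEASURES:
        retained, excl = exclude_outliers(indexed[name], analysis.outlier_z)
        log.extend(excl)
        mask = indexed.index.isin(retained.index) & indexed[name].notna()
        retained_masks[name] = pd.Series(mask, index=indexed.index)
        sub = indexed[mask]
        reg = age_regression(sub[name], sub["age"])
        reg_rows.append(
            {
                "measure": name,
                "n": reg.n,
                "slope": reg.slope,
                "r2_adj": reg.r2_adj,
                "p": reg.p,
            }
        )
        rho, p_rho = partial_correlation(
            sub[name], sub["age"], sub["fsiq_e"], analysis.corr_method
        )
        partial_rows.append(
            {"measure": name, "n": len(sub), "rho": rho, "p": p_rho}
        )
    regressions = pd.DataFrame(reg_rows)
    partials = pd.DataFrame(partial_rows)
    if analysis.multiple_testing == "holm":
        from statsmodels.stats.multitest import multipletests

        regressions["p_holm"] = multipletests(regressions["p"], method="holm")[1]
        partials["p_holm"] = multipletests(partials["p"], method="holm")[1]

    # one-sample t-tests vs 0 (chance) per year group on corrected precision
    tt_rows = []
    for group, sub in indexed.groupby("group"):
        for name in PRECISION_MEASURES:
            vals = sub.loc[retained_masks[name][sub.index], name].dropna()
            if len(vals) < 2:
                continue
            t, p = stats.ttest_1samp(vals, 0.0)
            tt_rows.append(
                {
                    "group": group,
                    "measure": name,
                    "n": int(len(vals)),
                    "mean": float(vals.mean()),
                    "t": float(t),
                    "p": float(p),
                }
            )
    group_ttests = pd.DataFrame(tt_rows)

    # serial-position ANOVA on outlier-screened SP precisions
    sp_frame = indexed[["precision_sp1", "precision_sp2", "precision_sp3"]].copy()
    for name in ("precision_sp1", "precision_sp2", "precision_sp3"):
        sp_frame.loc[~retained_masks[name], name] = np.nan
    sp_anova, sp_pairwise = serial_position_anova(sp_frame)

    histograms = response_histograms(trials)

    fits = measures[
        ["participant_id", "age", "fsiq_e", "converged"] + MIXTURE_PARAMS
    ].dropna(subset=MIXTURE_PARAMS)
    param_reg, fit_log = parameter_age_regressions(
        fits.reset_index(drop=True),
        fits["age"].to_numpy(),
        fits["fsiq_e"].to_numpy(),
        analysis,
    )
    log.extend(fit_log)

    exclusion_log = pd.DataFrame(
        log, columns=["stage", "measure", "participant_id", "value", "reason"]
    )
    return CohortResult(
        measures=measures,
        regressions=regressions,
        partials=partials,
        group_ttests=group_ttests,
        sp_anova=sp_anova,
        sp_pairwise=sp_pairwise,
        param_regressions=param_reg,
        histograms=histograms,
        exclusion_log=exclusion_log,
    )
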