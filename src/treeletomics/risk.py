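"""Matched case-control risk contrasts for metabolite-pattern scores.

All models are 1:1 conditional logistic regressions (matching factors
are conditioned out by design and never entered as covariates).
Exposures enter either per one standard deviation of a reference
population (default: controls, the pattern-fitting population) or as
quintile indicators with control-based cutpoints.  Subtype analyses
refit on the matched sets whose case carries the subtype;
likelihood-ratio heterogeneity tests compare subtype-specific exposure
effects against a shared one while keeping covariate coefficients
subtype-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .clogit import CLogitFit, ConditionalLogit, NoInformationError
from .synthetic import MatchedCohort

__all__ = [
    "ExposureSpec",
    "AdjustmentSet",
    "HeterogeneityResult",
    "adjustment_design",
    "clogit_fit",
    "or_per_sd",
    "quintile_analysis",
    "subtype_analysis",
    "heterogeneity_lrt",
    "followup_strata",
    "mutual_adjust",
    "death_analysis",
]


@dataclass
class ExposureSpec:
    """Participant-level exposure and its scaling.

    ``values`` is indexed by participant id.  ``scale='per_sd'`` divides
    by the exposure SD in the reference population (``'controls'`` or
    ``'all'``), so the fitted coefficient is a log OR per 1 SD;
    ``'raw'`` leaves the unit untouched.
    """

    values: pd.Series
    scale: str = "per_sd"
    reference: str = "controls"
    name: str = "exposure"

    def __post_init__(self):
        if self.scale not in ("per_sd", "raw"):
            raise ValueError(f"scale must be 'per_sd' or 'raw', got {self.scale!r}")
        if self.reference not in ("controls", "all"):
            raise ValueError("reference must be 'controls' or 'all'")

    def reference_sd(self, cohort: MatchedCohort) -> float:
        part = cohort.participants
        ids = (part.loc[part["role"] == "control", "participant_id"]
               if self.reference == "controls" else part["participant_id"])
        sd = float(self.values.loc[ids].std(ddof=1))
        if not sd > 0:
            raise ValueError("exposure SD in the reference population is not positive")
        return sd

    def scaled(self, cohort: MatchedCohort) -> pd.Series:
        if self.scale == "raw":
            return self.values
        return self.values / self.reference_sd(cohort)


_CATEGORICALS = {
    "smoking": "never",
    "alcohol": "<10",
    "education": "primary",
    "marital": "married",
}


@dataclass
class AdjustmentSet:
    """Covariate design: exact age plus categorical sets with explicit
    reference levels; 'unknown' is always its own level."""

    include_age: bool = True
    include_bmi_quartiles: bool = True
    categoricals: dict = field(default_factory=lambda: dict(_CATEGORICALS))

    @classmethod
    def none(cls) -> "AdjustmentSet":
        return cls(include_age=False, include_bmi_quartiles=False, categoricals={})


def adjustment_design(cohort: MatchedCohort, adjust: AdjustmentSet) -> pd.DataFrame:
    """Covariate design matrix indexed by participant id."""
    part = cohort.participants.set_index("participant_id")
    cols = {}
    if adjust.include_age:
        cols["age_blood"] = part["age_blood"].astype(float)
    if adjust.include_bmi_quartiles:
        bmi = part["bmi"]
        known = bmi.dropna()
        qs = np.percentile(known, [25, 50, 75])
        cat = pd.Series("bmi_unknown", index=part.index, dtype=object)
        labels = ["bmi_q1", "bmi_q2", "bmi_q3", "bmi_q4"]
        cat.loc[known.index] = np.asarray(labels)[
            np.searchsorted(qs, known.to_numpy(), side="left")]
        for level in ("bmi_q2", "bmi_q3", "bmi_q4", "bmi_unknown"):  # q1 reference
            cols[level] = (cat == level).astype(float)
    for var, ref in adjust.categoricals.items():
        levels = [l for l in pd.unique(part[var]) if l != ref]
        for level in sorted(levels):
            cols[f"{var}_{level}"] = (part[var] == level).astype(float)
    return pd.DataFrame(cols, index=part.index)


def _pair_differences(part: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Case-minus-control difference rows (one per set) for a design."""
    y = part["role"].eq("case").to_numpy(int)
    gs = part["set_id"].to_numpy()
    _, counts = np.unique(gs, return_counts=True)
    if np.any(counts != 2):
        raise ValueError("every matched set must have exactly two participants")
    order = np.lexsort((1 - y, gs))
    if not np.all(y[order][0::2] == 1) or np.any(y[order][1::2] == 1):
        raise ValueError("every matched set must have exactly one case")
    Xs = design.loc[part["participant_id"]].to_numpy(dtype=float)[order]
    return pd.DataFrame(Xs[0::2] - Xs[1::2], columns=list(design.columns))


def _assemble(cohort, exposure: ExposureSpec, adjust: AdjustmentSet,
              extra: pd.DataFrame | None = None) -> pd.DataFrame:
    design = pd.DataFrame({exposure.name: exposure.scaled(cohort)})
    adj = adjustment_design(cohort, adjust)
    design = design.join(adj)
    if extra is not None:
        design = design.join(extra)
    return design


def clogit_fit(
    cohort: MatchedCohort,
    exposure: ExposureSpec,
    adjust: AdjustmentSet | None = None,
    set_ids=None,
) -> CLogitFit:
    """Conditional-logistic fit; returns the exposure-coefficient summary."""
    adjust = adjust or AdjustmentSet()
    design = _assemble(cohort, exposure, adjust)
    part = cohort.participants
    if set_ids is not None:
        part = part[part["set_id"].isin(set_ids)]
    model = ConditionalLogit()
    model.fit_differences(_pair_differences(part, design))
    if exposure.name not in model.feature_names_:
        raise NoInformationError(
            f"exposure {exposure.name!r} has no within-pair variation")
    return model.summary_for(exposure.name)


def or_per_sd(fit: CLogitFit, sd_ref: float = 1.0) -> CLogitFit:
    """Rescale a per-unit fit to a per-``sd_ref``-units contrast."""
    if sd_ref <= 0:
        raise ValueError("reference SD must be positive")
    return CLogitFit(
        beta=fit.beta * sd_ref,
        se=fit.se * sd_ref,
        ci_low=fit.ci_low * sd_ref,
        ci_high=fit.ci_high * sd_ref,
        p_value=fit.p_value,
        loglik=fit.loglik,
        n_sets=fit.n_sets,
        n_informative=fit.n_informative,
        converged=fit.converged,
    )


def quintile_analysis(
    cohort: MatchedCohort,
    scores: pd.Series,
    adjust: AdjustmentSet | None = None,
    reference: str = "controls",
) -> pd.DataFrame:
    """ORs for quintiles Q2-Q5 versus Q1 of a component score.

    Cutpoints are the 20/40/60/80th percentiles (linear interpolation)
    of the reference population, default controls.
    """
    adjust = adjust or AdjustmentSet()
    part = cohort.participants
    ref_ids = (part.loc[part["role"] == "control", "participant_id"]
               if reference == "controls" else part["participant_id"])
    ref_scores = scores.loc[ref_ids]
    if ref_scores.nunique() < 5:
        raise ValueError("need at least 5 distinct score values in the reference")
    cuts = np.percentile(ref_scores, [20, 40, 60, 80])
    if len(np.unique(cuts)) < 4:
        raise ValueError(f"degenerate quintile cutpoints (ties): {cuts}")
    q = np.searchsorted(cuts, scores.to_numpy(), side="left")  # 0..4
    indicators = pd.DataFrame(
        {f"Q{k + 1}": (q == k).astype(float) for k in range(1, 5)},
        index=scores.index)
    design = indicators.join(adjustment_design(cohort, adjust))
    model = ConditionalLogit().fit_differences(_pair_differences(part, design))
    rows = [{"quintile": "Q1", "odds_ratio": 1.0, "ci_low": np.nan,
             "ci_high": np.nan, "p_value": np.nan}]
    for k in range(2, 6):
        s = model.summary_for(f"Q{k}")
        lo, hi = s.or_ci
        rows.append({"quintile": f"Q{k}", "odds_ratio": s.odds_ratio,
                     "ci_low": lo, "ci_high": hi, "p_value": s.p_value})
    out = pd.DataFrame(rows)
    out.attrs["cutpoints"] = cuts
    out.attrs["n_informative"] = model.n_informative_
    return out


def _case_labels(cohort: MatchedCohort, column: str) -> pd.Series:
    """Per-set label taken from the case row."""
    cases = cohort.cases()
    return pd.Series(cases[column].to_numpy(), index=cases["set_id"].to_numpy())


def subtype_analysis(
    cohort: MatchedCohort,
    exposure: ExposureSpec,
    adjust: AdjustmentSet | None = None,
    labels: pd.Series | None = None,
    label_column: str = "stage",
) -> dict[str, CLogitFit]:
    """Per-subtype fits on the sets whose case carries each label.

    ``labels`` maps set id to subtype (NaN/'unknown' sets excluded);
    by default taken from the cases' ``stage`` column.
    """
    if labels is None:
        labels = _case_labels(cohort, label_column)
    labels = labels.dropna()
    labels = labels[~labels.isin(["unknown", "None"])]
    out: dict[str, CLogitFit] = {}
    for subtype in sorted(pd.unique(labels)):
        sets = labels.index[labels == subtype]
        if len(sets) == 0:
            raise ValueError(f"empty subtype {subtype!r}")
        out[str(subtype)] = clogit_fit(cohort, exposure, adjust, set_ids=sets)
    if not out:
        raise ValueError("no labeled subtypes to analyse")
    return out


@dataclass(frozen=True)
class HeterogeneityResult:
    """Likelihood-ratio test of a common exposure effect across subtypes."""

    chi2: float
    df: int
    p_value: float
    subtypes: tuple[str, ...]


def heterogeneity_lrt(
    cohort: MatchedCohort,
    exposure: ExposureSpec,
    adjust: AdjustmentSet | None = None,
    labels: pd.Series | None = None,
    label_column: str = "stage",
) -> HeterogeneityResult:
    """LRT comparing subtype-specific exposure effects to a shared one.

    The unconstrained log-likelihood is the sum of the subtype-specific
    fits (every parameter subtype-specific).  The constrained model
    shares the exposure coefficient across subtypes while covariate
    coefficients stay subtype-specific (covariate columns interacted
    with subtype indicators).  chi2 = 2(l_u - l_c), df = S - 1.
    """
    adjust = adjust or AdjustmentSet()
    if labels is None:
        labels = _case_labels(cohort, label_column)
    labels = labels.dropna()
    labels = labels[~labels.isin(["unknown", "None"])]
    subtypes = sorted(pd.unique(labels))
    if len(subtypes) < 2:
        raise ValueError("heterogeneity test needs at least 2 non-empty subtypes")

    fits = subtype_analysis(cohort, exposure, adjust, labels=labels)
    ll_u = sum(f.loglik for f in fits.values())

    # constrained: shared exposure, subtype-specific covariates
    design = _assemble(cohort, exposure, adjust)
    part = cohort.participants
    blocks, names = [], None
    for s in subtypes:
        sets = labels.index[labels == s]
        sub = part[part["set_id"].isin(sets)]
        D = _pair_differences(sub, design).to_numpy()
        cov = D[:, 1:]
        expo = D[:, :1]
        wide = np.zeros((D.shape[0], 1 + cov.shape[1] * len(subtypes)))
        wide[:, 0] = expo[:, 0]
        j = subtypes.index(s)
        wide[:, 1 + j * cov.shape[1]: 1 + (j + 1) * cov.shape[1]] = cov
        blocks.append(wide)
    if names is None:
        cov_names = list(design.columns[1:])
        names = [exposure.name] + [
            f"{c}@{s}" for s in subtypes for c in cov_names]
    Dall = np.vstack(blocks)
    model = ConditionalLogit().fit_differences(pd.DataFrame(Dall, columns=names))
    ll_c = model.loglik_

    stat = max(0.0, 2.0 * (ll_u - ll_c))
    df = len(subtypes) - 1
    return HeterogeneityResult(
        chi2=stat, df=df, p_value=float(chi2.sf(stat, df)),
        subtypes=tuple(str(s) for s in subtypes))


def followup_strata(
    cohort: MatchedCohort,
    exposure: ExposureSpec,
    adjust: AdjustmentSet | None = None,
    cutoff: float = 10.0,
    set_ids=None,
) -> dict[str, CLogitFit | None]:
    """Fits stratified by case time to diagnosis (<= cutoff vs > cutoff).

    An empty stratum is reported as ``None`` rather than an error.
    """
    t = _case_labels(cohort, "time_to_dx").astype(float)
    if set_ids is not None:
        t = t.loc[t.index.intersection(pd.Index(set_ids))]
    out: dict[str, CLogitFit | None] = {}
    for name, sets in ((f"<={cutoff:g}y", t.index[t <= cutoff]),
                       (f">{cutoff:g}y", t.index[t > cutoff])):
        out[name] = (clogit_fit(cohort, exposure, adjust, set_ids=sets)
                     if len(sets) else None)
    return out


def mutual_adjust(
    cohort: MatchedCohort,
    target: str,
    scores: pd.DataFrame,
    adjust: AdjustmentSet | None = None,
    threshold: float = 0.2,
    reference: str = "controls",
    set_ids=None,
) -> CLogitFit:
    """Fit the target component co-adjusted for correlated components.

    Components other than the target whose absolute Pearson correlation
    with it exceeds ``threshold`` in the reference population enter the
    model as continuous covariates.
    """
    adjust = adjust or AdjustmentSet()
    part = cohort.participants
    ref_ids = (part.loc[part["role"] == "control", "participant_id"]
               if reference == "controls" else part["participant_id"])
    corr = scores.loc[ref_ids].corr()
    others = [c for c in scores.columns
              if c != target and abs(corr.loc[target, c]) > threshold]
    exposure = ExposureSpec(scores[target], name=target)
    extra = scores[others] if others else None
    design = _assemble(cohort, exposure, adjust, extra=extra)
    if set_ids is not None:
        part = part[part["set_id"].isin(set_ids)]
    model = ConditionalLogit().fit_differences(_pair_differences(part, design))
    return model.summary_for(target)


def death_analysis(
    cohort: MatchedCohort,
    exposure: ExposureSpec,
    adjust: AdjustmentSet | None = None,
) -> tuple[CLogitFit, dict]:
    """Disease-death contrast with censored-control set exclusion.

    Restricts to sets whose case died of the disease and whose control
    was still under observation at that death; sets with a control that
    died, emigrated or was lost beforehand are excluded and counted.
    """
    death = _case_labels(cohort, "death").astype(bool)
    death_sets = set(death.index[death])
    ctrl = cohort.controls()
    censored_sets = set(ctrl.loc[ctrl["censored_before_case_death"], "set_id"])
    eligible = sorted(death_sets - censored_sets)
    counts = {
        "n_death_sets": len(death_sets),
        "n_censored_excluded": len(death_sets & censored_sets),
        "n_analyzed": len(eligible),
    }
    if not eligible:
        raise ValueError("no eligible sets for the death analysis")
    fit = clogit_fit(cohort, exposure, adjust, set_ids=eligible)
    return fit, counts
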