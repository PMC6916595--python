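"""End-to-end orchestration: simulate/load -> QC -> treelet -> risk -> report.

A run is described by a :class:`RunConfig`; every stage writes TSV
outputs into the run directory and records row counts, exclusions and
seeds in a JSON manifest, so that re-running an identical config
reproduces identical numbers.  All randomness flows from one top-level
seed expanded into named per-stage substreams.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import comparators, model_selection, risk, synthetic, treelet
from .clogit import NoInformationError, SeparationError
from .preprocess import QCConfig, log_transform, qc_filter
from .synthetic import EffectSpec, MatchedCohort, OutcomeMix, PanelSpec

__all__ = ["RunConfig", "run_pipeline", "make_report", "load_cohort"]


def _substream(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the top-level one."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class RunConfig:
    """Resolved configuration of a full pipeline run (all fields defaulted)."""

    outdir: str = "treeletomics_run"
    seed: int = 0
    # simulate block (ignored when input paths are given)
    n_sets: int = 600
    sim_outcome: str = "overall"
    sim_effects: dict = field(default_factory=lambda: {("block1", "overall"): 0.85})
    # input tables (TSV); all three required to skip simulation
    concentrations_path: str | None = None
    sets_path: str | None = None
    outcomes_path: str | None = None
    # preprocessing
    max_cv_fraction: float = 0.25
    max_missing_fraction: float = 0.05
    lod_policy: str = "floor"
    # treelet
    n_components: int = 3
    cut_level: int | None = None       # None -> cross-validate
    cv_folds: int = 5
    candidate_cuts: list | None = None
    # risk models
    sd_reference: str = "controls"
    mutual_adjust_threshold: float = 0.2
    followup_cutoff: float = 10.0
    # comparators
    pca_components: int = 9
    run_screen: bool = True
    screen_method: str = "bh"

    def as_dict(self) -> dict:
        d = asdict(self)
        d["sim_effects"] = {
            (k if isinstance(k, str) else ":".join(k)): v
            for k, v in self.sim_effects.items()}
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.as_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_cohort(concentrations_path, sets_path, outcomes_path) -> MatchedCohort:
    """Reassemble a MatchedCohort from the three study TSV tables."""
    conc = pd.read_csv(concentrations_path, sep="\t", index_col="participant_id")
    sets = pd.read_csv(sets_path, sep="\t")
    outcomes = pd.read_csv(outcomes_path, sep="\t")
    part = sets.merge(
        outcomes.drop(columns=[c for c in ("set_id", "role") if c in outcomes]),
        on="participant_id", how="left")
    panel = pd.DataFrame({"name": conc.columns, "metabolite_class": "unknown",
                          "block": None, "mean_log_conc": np.nan, "log_sd": np.nan})
    with np.errstate(divide="ignore"):
        logc = np.log(conc)
    return MatchedCohort(part, logc, panel, {"loaded_from": str(concentrations_path)})


def run_pipeline(config: RunConfig, simulate_only: bool = False) -> dict:
    """Execute the full analysis; returns the manifest dict.

    Stages: simulate (or load) -> QC + log transform -> treelet fitted on
    controls with cross-validated cut-level -> component scores ->
    conditional-logistic risk contrasts (overall, stage subtypes with
    heterogeneity LRT, follow-up strata, mutual adjustment, death
    analysis) -> PCA comparison and per-metabolite screen -> report
    tables.  Any stage failure raises with the stage name attached.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.as_dict(),
        "config_hash": config.config_hash(),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }
    # keys in sim_effects may arrive as "block1:overall" strings from YAML
    effects_map = {}
    for k, v in config.sim_effects.items():
        if isinstance(k, str):
            block, outcome = k.split(":")
            effects_map[(block, outcome)] = float(v)
        else:
            effects_map[tuple(k)] = float(v)

    stage = "simulate"
    try:
        if config.concentrations_path:
            cohort = load_cohort(config.concentrations_path, config.sets_path,
                                 config.outcomes_path)
        else:
            panel = synthetic.build_panel(PanelSpec())
            cohort = synthetic.simulate_matched_pairs(
                panel, EffectSpec(or_per_sd=effects_map), config.n_sets,
                outcome=config.sim_outcome, seed=_substream(config.seed, "simulate"))
            cohort = synthetic.assign_outcomes(
                cohort, OutcomeMix(), seed=_substream(config.seed, "outcomes"))
            synthetic.write_cohort(cohort, out)
        manifest["stages"]["simulate"] = {
            "n_sets": int(cohort.n_sets),
            "n_metabolites": int(cohort.log_concentrations.shape[1]),
        }
        if simulate_only:
            _write_manifest(out, manifest)
            return manifest

        stage = "preprocess"
        qc = QCConfig(config.max_cv_fraction, config.max_missing_fraction,
                      config.lod_policy)
        raw = cohort.concentrations()
        filtered, report = qc_filter(raw, qc, sets=cohort.participants[
            ["participant_id", "set_id"]])
        matrix = log_transform(filtered, qc)
        report.to_csv(out / "exclusions.tsv", sep="\t", index=False)
        manifest["stages"]["preprocess"] = {
            "kept_metabolites": int(matrix.values.shape[1]),
            "kept_participants": int(matrix.values.shape[0]),
            "exclusions": int(len(report)),
        }

        stage = "treelet"
        ctrl_ids = cohort.controls()["participant_id"]
        X_ctrl = matrix.values.loc[ctrl_ids]
        if config.cut_level is None:
            cut, cv_table = model_selection.cross_validate_cut(
                X_ctrl, config.n_components, folds=config.cv_folds,
                candidates=config.candidate_cuts,
                seed=_substream(config.seed, "cv"))
            cv_table.to_csv(out / "cv_cut_level.tsv", sep="\t", index=False)
        else:
            cut = config.cut_level
        tt = treelet.TreeletTransform(config.n_components, cut).fit(X_ctrl)
        tt.tree_.merge_table().to_csv(out / "merge_history.tsv", sep="\t", index=False)
        loadings = tt.component_set_.to_frame()
        if cohort.panel is not None:
            loadings.insert(0, "metabolite_class", cohort.panel.set_index("name")
                            .reindex(loadings.index)["metabolite_class"].to_numpy())
        loadings.to_csv(out / "loadings.tsv", sep="\t")
        scores = tt.transform(matrix.values)
        scores.to_csv(out / "scores.tsv", sep="\t")
        fracs, total = tt.variance_explained()
        manifest["stages"]["treelet"] = {
            "cut_level": int(cut),
            "variance_explained": [float(f) for f in fracs],
            "total_variance_explained": float(total),
        }

        stage = "risk"
        results = _risk_results(cohort, scores, config)
        results.to_csv(out / "risk_results.tsv", sep="\t", index=False)
        manifest["stages"]["risk"] = {"n_rows": int(len(results))}

        stage = "comparators"
        pca = comparators.fit_pca(matrix.values, config.pca_components)
        pc_scores = pca.transform(matrix.values)
        corr = comparators.correlate_scores(scores, pc_scores)
        corr.to_csv(out / "tt_pc_correlations.tsv", sep="\t")
        manifest["stages"]["pca"] = {
            "n_components": int(config.pca_components),
            "variance_explained": [float(v) for v in pca.explained_variance_ratio_],
        }
        if config.run_screen:
            screen = comparators.screen_metabolites(
                cohort, matrix.values, outcome="overall",
                method=config.screen_method)
            screen.to_csv(out / "metabolite_screen.tsv", sep="\t", index=False)
            manifest["stages"]["screen"] = {
                "n_metabolites": int(len(screen)),
                "n_failed": int((screen["error"] != "").sum()),
            }
    except Exception as err:
        manifest["failed_stage"] = stage
        manifest["error"] = str(err)
        _write_manifest(out, manifest)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    _write_manifest(out, manifest)
    make_report(out)
    return manifest


def _risk_results(cohort: MatchedCohort, scores: pd.DataFrame,
                  config: RunConfig) -> pd.DataFrame:
    """Per-SD conditional-logistic contrasts for every component."""
    rows = []
    adjust = risk.AdjustmentSet()

    def add(component, outcome, stratum, fit, model_tag):
        lo, hi = fit.or_ci
        rows.append({
            "exposure": component, "outcome": outcome, "stratum": stratum,
            "n_sets": fit.n_sets, "n_informative": fit.n_informative,
            "OR_1SD": fit.odds_ratio, "ci_low": lo, "ci_high": hi,
            "p": fit.p_value, "model": model_tag,
        })

    def guarded(component, outcome, stratum, model_tag, thunk):
        # a separated or uninformative contrast is reported, not fatal
        try:
            result = thunk()
        except (SeparationError, NoInformationError, ValueError) as err:
            rows.append({
                "exposure": component, "outcome": outcome, "stratum": stratum,
                "n_sets": np.nan, "n_informative": np.nan, "OR_1SD": np.nan,
                "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                "model": f"{model_tag}_failed:{type(err).__name__}",
            })
            return None
        add(component, outcome, stratum, result, model_tag)
        return result

    stage_labels = risk._case_labels(cohort, "stage")
    have_stages = stage_labels.isin(["localized", "advanced"]).any()
    death_flags = risk._case_labels(cohort, "death").astype(bool)
    for comp in scores.columns:
        expo = risk.ExposureSpec(scores[comp], reference=config.sd_reference,
                                 name=comp)
        guarded(comp, "overall", "all", "adjusted",
                lambda: risk.clogit_fit(cohort, expo, adjust))
        if have_stages:
            try:
                for subtype, fit in risk.subtype_analysis(
                        cohort, expo, adjust, label_column="stage").items():
                    add(comp, subtype, "all", fit, "adjusted")
                het = risk.heterogeneity_lrt(cohort, expo, adjust,
                                             label_column="stage")
                rows.append({
                    "exposure": comp, "outcome": "stage_heterogeneity",
                    "stratum": "all", "n_sets": int(stage_labels.notna().sum()),
                    "n_informative": np.nan, "OR_1SD": np.nan,
                    "ci_low": np.nan, "ci_high": np.nan, "p": het.p_value,
                    "model": f"LRT_chi2={het.chi2:.3f}_df={het.df}",
                })
            except (SeparationError, NoInformationError, ValueError) as err:
                rows.append({
                    "exposure": comp, "outcome": "stage", "stratum": "all",
                    "n_sets": np.nan, "n_informative": np.nan,
                    "OR_1SD": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                    "p": np.nan, "model": f"failed:{type(err).__name__}"})
            adv_sets = stage_labels.index[stage_labels == "advanced"]
            for stratum in (f"<={config.followup_cutoff:g}y",
                            f">{config.followup_cutoff:g}y"):
                def strat_fit(stratum=stratum):
                    fits = risk.followup_strata(
                        cohort, expo, adjust, cutoff=config.followup_cutoff,
                        set_ids=adv_sets)
                    if fits[stratum] is None:
                        raise NoInformationError("empty stratum")
                    return fits[stratum]
                guarded(comp, "advanced", stratum, "adjusted", strat_fit)
        if death_flags.any():
            guarded(comp, "death", "all", "adjusted_death",
                    lambda: risk.death_analysis(cohort, expo, adjust)[0])
        # mutual_adjust scales the target per SD internally
        guarded(comp, "overall", "all", "mutually_adjusted",
                lambda: risk.mutual_adjust(
                    cohort, comp, scores, adjust,
                    threshold=config.mutual_adjust_threshold,
                    reference=config.sd_reference))
    return pd.DataFrame(rows)


def _write_manifest(out: Path, manifest: dict) -> None:
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str))


def make_report(outdir: str | Path) -> Path:
    """Render a human-readable summary of a completed run directory."""
    out = Path(outdir)
    lines = ["# Metabolite-pattern analysis report", ""]
    missing = []
    for title, fname, n in (
            ("Cluster-tree merge history (last 10 merges)", "merge_history.tsv", 10),
            ("Component loadings (first 15 metabolites)", "loadings.tsv", 15),
            ("Risk contrasts (forest table)", "risk_results.tsv", None),
            ("Treelet vs PCA score correlations", "tt_pc_correlations.tsv", None)):
        path = out / fname
        if not path.exists():
            missing.append(fname)
            continue
        df = pd.read_csv(path, sep="\t")
        if n is not None:
            df = df.tail(n) if "merge" in fname else df.head(n)
        lines += [f"## {title}", "", df.to_string(index=False), ""]
    if missing:
        lines += ["## Missing stage outputs", ""] + [f"- {m}" for m in missing]
    if not (out / "risk_results.tsv").exists():
        lines += ["", "No risk-model fits were produced in this run."]
    report = out / "report.md"
    report.write_text("\n".join(lines))
    return report
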