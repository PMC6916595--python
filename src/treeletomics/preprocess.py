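"""QC filtering and log transformation of raw concentration tables.

Metabolites are dropped when their replicate-QC coefficient of
variation or their missingness fraction exceeds the configured
thresholds.  Remaining missing or zero values are either floor-imputed
at half the minimum observed concentration of that metabolite or the
participant is dropped -- always together with their matched partner so
the 1:1 set structure stays intact for conditional-logistic analysis.
Every exclusion is itemised in a report table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["QCConfig", "MetaboliteMatrix", "qc_filter", "log_transform"]


@dataclass
class QCConfig:
    """Thresholds for metabolite/participant exclusion.

    ``max_cv_fraction``: maximum coefficient of variation in replicate
    QC samples; ``max_missing_fraction``: maximum fraction of missing
    study samples per metabolite; ``lod_policy``: how residual missing
    or non-positive values are handled (``"floor"`` imputes half the
    minimum observed value, ``"drop"`` removes the participant and its
    matched partner).
    """

    max_cv_fraction: float = 0.25
    max_missing_fraction: float = 0.05
    lod_policy: str = "floor"

    def __post_init__(self):
        for name in ("max_cv_fraction", "max_missing_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.lod_policy not in ("floor", "drop"):
            raise ValueError(f"lod_policy must be 'floor' or 'drop', got {self.lod_policy!r}")


@dataclass
class MetaboliteMatrix:
    """Analysis-ready natural-log concentration matrix.

    ``values``: participants x metabolites, no missing cells;
    ``imputed``: same-shape boolean mask of floor-imputed cells;
    ``classes``: optional metabolite class annotation.
    """

    values: pd.DataFrame
    imputed: pd.DataFrame
    classes: pd.Series | None = None

    def __post_init__(self):
        if self.values.isna().any().any():
            raise ValueError("analysis matrix must have no missing cells")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("analysis matrix must be finite")
        if self.values.index.duplicated().any() or self.values.columns.duplicated().any():
            raise ValueError("participant ids and metabolite names must be unique")


def qc_filter(
    raw: pd.DataFrame,
    qc: QCConfig | None = None,
    qc_samples: pd.DataFrame | None = None,
    sets: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop failing metabolites, then incomplete participants with partners.

    ``raw``: participants x metabolites concentration table (>= 0 or
    NaN).  ``qc_samples``: replicate QC measurements (rows = replicates)
    used for the CV criterion; skipped when absent.  ``sets``: table
    with ``participant_id`` and ``set_id`` used to co-drop matched
    partners; without it participants are dropped individually.

    Returns ``(filtered, report)``; the report has one row per excluded
    entity with columns (entity, id, reason, value, threshold).
    """
    qc = qc or QCConfig()
    vals = raw.to_numpy(dtype=float)
    if vals.size and not np.isnan(vals).all() and np.nanmin(vals) < 0:
        raise ValueError("concentrations must be non-negative or missing")
    report_rows = []
    keep = raw.copy()

    if qc_samples is not None:
        mean = qc_samples.mean(axis=0)
        cv = qc_samples.std(axis=0, ddof=1) / mean.where(mean > 0)
        for m in keep.columns:
            if m in cv.index and np.isfinite(cv[m]) and cv[m] > qc.max_cv_fraction:
                report_rows.append(("metabolite", m, "qc_cv", float(cv[m]),
                                    qc.max_cv_fraction))
        bad = [r[1] for r in report_rows]
        keep = keep.drop(columns=bad)

    miss = keep.isna().mean(axis=0)
    for m in keep.columns[miss > qc.max_missing_fraction]:
        report_rows.append(("metabolite", m, "missingness", float(miss[m]),
                            qc.max_missing_fraction))
    keep = keep.loc[:, miss <= qc.max_missing_fraction]
    if keep.shape[1] == 0:
        raise ValueError("all metabolites excluded by QC thresholds")

    if qc.lod_policy == "drop":
        incomplete = keep.isna().any(axis=1)
        drop_ids = set(keep.index[incomplete])
        if sets is not None:
            sets = sets.set_index("participant_id") if "participant_id" in sets.columns else sets
            missing_ids = drop_ids - set(sets.index)
            if missing_ids:
                raise ValueError(
                    f"matched-set table lacks participants: {sorted(missing_ids)[:5]}")
            bad_sets = set(sets.loc[sorted(drop_ids), "set_id"])
            partners = set(sets.index[sets["set_id"].isin(bad_sets)]) & set(keep.index)
            for pid in sorted(partners):
                reason = "missingness" if pid in drop_ids else "partner_excluded"
                report_rows.append(("participant", pid, reason,
                                    float(keep.loc[pid].isna().mean()),
                                    qc.max_missing_fraction))
            keep = keep.drop(index=sorted(partners))
        else:
            for pid in sorted(drop_ids):
                report_rows.append(("participant", pid, "missingness",
                                    float(keep.loc[pid].isna().mean()),
                                    qc.max_missing_fraction))
            keep = keep.drop(index=sorted(drop_ids))

    report = pd.DataFrame(report_rows, columns=[
        "entity", "id", "reason", "value", "threshold"])
    return keep, report


def log_transform(
    filtered: pd.DataFrame,
    qc: QCConfig | None = None,
    classes: pd.Series | None = None,
) -> MetaboliteMatrix:
    """Natural-log transform with optional half-minimum floor imputation.

    Under the ``"floor"`` policy, missing and non-positive cells are set
    to half the minimum observed positive value of the metabolite before
    taking logs, and flagged in the imputation mask.  Under ``"drop"``
    any residual non-positive value is an error (participants should
    already have been removed by :func:`qc_filter`).
    """
    qc = qc or QCConfig()
    vals = filtered.astype(float).copy()
    needs = vals.isna() | (vals <= 0)
    if needs.any().any():
        if qc.lod_policy != "floor":
            bad = vals.columns[needs.any(axis=0)].tolist()
            raise ValueError(
                f"non-positive or missing values remain in {bad} with policy "
                "'drop'; no floor imputation allowed")
        for m in vals.columns[needs.any(axis=0)]:
            observed = vals.loc[~needs[m], m]
            if observed.empty:
                raise ValueError(f"metabolite {m!r} has no positive observations")
            vals.loc[needs[m], m] = observed.min() / 2.0
    return MetaboliteMatrix(values=np.log(vals), imputed=needs, classes=classes)
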