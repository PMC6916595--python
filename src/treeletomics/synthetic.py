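"""Synthetic matched case-control metabolomics cohorts with known structure.

Emulates a targeted plasma metabolomics panel of 119 metabolites
(8 acylcarnitines, 21 amino acids, 5 biogenic amines, 8 lysoPC,
31 diacyl PC, 33 acyl-alkyl PC, hexose, 5 SM(OH), 7 SM) measured in 1:1
incidence-density-matched case-control sets.  Three latent "pattern"
blocks drive correlated log-normal concentrations:

* block1 -- all diacyl and acyl-alkyl phosphatidylcholines plus three
  hydroxysphingomyelins (the dominant phospholipid pattern),
* block2 -- acylcarnitines C18:1 and C18:2, glutamate, ornithine and
  taurine,
* block3 -- all eight lysophosphatidylcholines.

Blocks 1 and 3 are correlated (default r = 0.46); the rest of the panel
is background noise with small random cross-loadings.  Case status is
assigned *within* each matched pair with probability
``exp(eta_1) / (exp(eta_1) + exp(eta_2))`` where ``eta = sum_b
log(OR_b) * s_b`` over the standardized latent block scores.  This is
exactly the 1:1 conditional-logistic likelihood, so downstream
conditional-logistic estimates of the latent-score effects are unbiased
in expectation -- the generator provides exact ground truth for
parameter-recovery checks.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "PanelSpec",
    "EffectSpec",
    "OutcomeMix",
    "CovariateModel",
    "MatchedCohort",
    "build_panel",
    "simulate_exposure_pairs",
    "simulate_matched_pairs",
    "assign_outcomes",
    "write_cohort",
]

CLASS_VOCAB = (
    "acylcarnitine", "amino_acid", "biogenic_amine", "lysoPC",
    "PC_aa", "PC_ae", "hexose", "SM_OH", "SM",
)

OUTCOME_VOCAB = (
    "overall", "localized", "advanced", "aggressive", "non_aggressive",
    "high_grade", "low_intermediate_grade", "death",
)

# class-defining member names; counts match the default panel composition
_ACYLCARNITINES = ["C0", "C2", "C3", "C10", "C14:2", "C16", "C18:1", "C18:2"]
_AMINO_ACIDS = [
    "Ala", "Arg", "Asn", "Asp", "Cit", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Orn", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
]
_BIOGENIC_AMINES = ["ADMA", "Kynurenine", "SDMA", "Serotonin", "Taurine"]
_LYSO_PC = [f"lysoPC.a.C{n}" for n in
            ("16:0", "16:1", "17:0", "18:0", "18:1", "18:2", "20:3", "20:4")]
_PC_AA = [f"PC.aa.C{c}:{d}" for c, d in
          [(28, 1), (30, 0), (32, 0), (32, 1), (32, 2), (32, 3), (34, 1),
           (34, 2), (34, 3), (34, 4), (36, 0), (36, 1), (36, 2), (36, 3),
           (36, 4), (36, 5), (36, 6), (38, 0), (38, 3), (38, 4), (38, 5),
           (38, 6), (40, 2), (40, 3), (40, 4), (40, 5), (40, 6), (42, 0),
           (42, 1), (42, 2), (42, 4)]]
_PC_AE = [f"PC.ae.C{c}:{d}" for c, d in
          [(30, 0), (32, 1), (32, 2), (34, 0), (34, 1), (34, 2), (34, 3),
           (36, 0), (36, 1), (36, 2), (36, 3), (36, 4), (36, 5), (38, 0),
           (38, 1), (38, 2), (38, 3), (38, 4), (38, 5), (38, 6), (40, 1),
           (40, 2), (40, 3), (40, 4), (40, 5), (40, 6), (42, 1), (42, 2),
           (42, 3), (42, 4), (42, 5), (44, 5), (44, 6)]]
_SM_OH = [f"SM.OH.C{n}" for n in ("14:1", "16:1", "22:1", "22:2", "24:1")]
_SM = [f"SM.C{n}" for n in ("16:0", "16:1", "18:0", "18:1", "20:2", "24:0", "24:1")]

_CLASS_NAMES = {
    "acylcarnitine": _ACYLCARNITINES,
    "amino_acid": _AMINO_ACIDS,
    "biogenic_amine": _BIOGENIC_AMINES,
    "lysoPC": _LYSO_PC,
    "PC_aa": _PC_AA,
    "PC_ae": _PC_AE,
    "hexose": ["H1"],
    "SM_OH": _SM_OH,
    "SM": _SM,
}

# typical plasma concentration scales (uM) and log-SDs per class
_CLASS_MEAN_UM = {
    "acylcarnitine": 0.15, "amino_acid": 80.0, "biogenic_amine": 1.5,
    "lysoPC": 80.0, "PC_aa": 30.0, "PC_ae": 3.0, "hexose": 5000.0,
    "SM_OH": 6.0, "SM": 100.0,
}
_CLASS_LOG_SD = {c: 0.35 for c in CLASS_VOCAB}

# members of the latent blocks
_BLOCK2_MEMBERS = {"C18:1", "C18:2", "Glu", "Orn", "Taurine"}
_BLOCK1_SM_OH = set(_SM_OH[:3])


@dataclass
class PanelSpec:
    """Composition of the metabolite panel and its latent block structure."""

    classes: list[tuple[str, int]] = field(default_factory=lambda: [
        ("acylcarnitine", 8), ("amino_acid", 21), ("biogenic_amine", 5),
        ("lysoPC", 8), ("PC_aa", 31), ("PC_ae", 33), ("hexose", 1),
        ("SM_OH", 5), ("SM", 7),
    ])
    class_mean_log_conc: dict = field(
        default_factory=lambda: {c: float(np.log(v)) for c, v in _CLASS_MEAN_UM.items()}
    )
    class_log_sd: dict = field(default_factory=lambda: dict(_CLASS_LOG_SD))

    def __post_init__(self):
        for name, count in self.classes:
            if name not in CLASS_VOCAB:
                raise ValueError(f"unknown metabolite class: {name!r}")
            if count < 0:
                raise ValueError(f"negative count for class {name!r}")

    @property
    def n_metabolites(self) -> int:
        return sum(c for _, c in self.classes)


def build_panel(spec: PanelSpec | None = None) -> pd.DataFrame:
    """One record per metabolite: name, class, latent block assignment.

    The default spec yields the 119-metabolite panel with block1 holding
    every PC aa/ae plus three SM(OH), block2 the two long-chain
    acylcarnitines with glutamate, ornithine and taurine, and block3 all
    lysoPC; everything else is background.
    """
    spec = spec or PanelSpec()
    records = []
    for cls, count in spec.classes:
        pool = _CLASS_NAMES[cls]
        if count <= len(pool):
            names = pool[:count]
        else:  # extend deterministically beyond the named members
            names = pool + [f"{cls}.x{i}" for i in range(count - len(pool))]
        for name in names:
            if cls in ("PC_aa", "PC_ae") or (cls == "SM_OH" and name in _BLOCK1_SM_OH):
                block = "block1"
            elif (cls in ("acylcarnitine", "amino_acid", "biogenic_amine")
                  and name in _BLOCK2_MEMBERS):
                block = "block2"
            elif cls == "lysoPC":
                block = "block3"
            else:
                block = None
            records.append(
                {
                    "name": name if cls != "acylcarnitine" else f"AC.{name}",
                    "metabolite_class": cls,
                    "block": block,
                    "mean_log_conc": spec.class_mean_log_conc[cls],
                    "log_sd": spec.class_log_sd[cls],
                }
            )
    panel = pd.DataFrame(records, columns=[
        "name", "metabolite_class", "block", "mean_log_conc", "log_sd"])
    if panel["name"].duplicated().any():
        dups = panel.loc[panel["name"].duplicated(), "name"].tolist()
        raise ValueError(f"duplicate metabolite names: {dups}")
    return panel


_BLOCKS = ("block1", "block2", "block3")


def _default_block_corr() -> np.ndarray:
    R = np.eye(3)
    R[0, 2] = R[2, 0] = 0.46
    return R


@dataclass
class EffectSpec:
    """Ground-truth per-1-SD odds ratios of the latent block scores.

    ``or_per_sd`` maps ``(block, outcome)`` to the true odds ratio per
    one SD of the standardized latent score; unlisted pairs have OR 1.
    ``block_corr`` is the 3x3 latent correlation matrix (unit diagonal,
    positive semi-definite), default corr(block1, block3) = 0.46.
    """

    or_per_sd: dict = field(default_factory=dict)
    block_corr: np.ndarray = field(default_factory=_default_block_corr)

    def __post_init__(self):
        for (block, outcome), or_ in self.or_per_sd.items():
            if block not in _BLOCKS:
                raise ValueError(f"unknown block: {block!r}")
            if outcome not in OUTCOME_VOCAB:
                raise ValueError(f"unknown outcome: {outcome!r}")
            if or_ <= 0:
                raise ValueError(f"odds ratio must be positive, got {or_}")
        R = np.asarray(self.block_corr, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R, R.T):
            raise ValueError("block_corr must be a symmetric 3x3 matrix")
        if not np.allclose(np.diag(R), 1.0):
            raise ValueError("block_corr must have unit diagonal")
        if np.linalg.eigvalsh(R).min() < -1e-10:
            raise ValueError("block_corr must be positive semi-definite")
        self.block_corr = R

    def log_or_vector(self, outcome: str) -> np.ndarray:
        return np.array([
            np.log(self.or_per_sd.get((b, outcome), 1.0)) for b in _BLOCKS
        ])


@dataclass
class OutcomeMix:
    """Marginal subtype composition of the cases (matched-study scale).

    Defaults reproduce a cohort of 3,057 cases in which 69.2% of staged
    cases are localized and 30.8% advanced, 19.5% are aggressive (a
    subset of advanced), 12.8% of graded cases are high grade, 326 cases
    die of the disease and 29 of those matched sets have a control
    censored before the case's death.
    """

    advanced: float = 0.308
    aggressive: float = 0.195
    high_grade: float = 0.128
    stage_known: float = 1886 / 3057
    grade_known: float = 2474 / 3057
    death: float = 326 / 3057
    censor_given_death: float = 29 / 326

    def __post_init__(self):
        for name, v in asdict(self).items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.aggressive > self.advanced:
            raise ValueError("aggressive cases are a subset of advanced cases")


@dataclass
class CovariateModel:
    """Baseline covariate frequencies (control-population scale)."""

    age_mean: float = 58.0
    age_sd: float = 7.3
    bmi_mean: float = 27.2
    bmi_sd: float = 3.5
    smoking: dict = field(default_factory=lambda: {
        "never": 0.311, "former": 0.436, "current": 0.253})
    alcohol: dict = field(default_factory=lambda: {
        "<10": 0.416, "10-19": 0.189, "20-39": 0.221, ">=40": 0.174})
    education: dict = field(default_factory=lambda: {
        "primary": 0.409, "secondary": 0.351, "degree": 0.241})
    marital: dict = field(default_factory=lambda: {
        "married": 0.889, "not_married": 0.111})
    unknown_rates: dict = field(default_factory=lambda: {
        "smoking": 0.015, "alcohol": 0.01, "education": 0.05,
        "marital": 0.242, "bmi": 0.01})


@dataclass
class MatchedCohort:
    """1:1 matched sets with covariates, outcomes and log concentrations.

    ``participants`` has one row per participant (two per set) holding
    set id, role, matching factors, covariates, latent block scores and
    outcome fields; ``log_concentrations`` is participants x metabolites
    (natural-log uM), indexed by participant id.
    """

    participants: pd.DataFrame
    log_concentrations: pd.DataFrame
    panel: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def n_sets(self) -> int:
        return self.participants["set_id"].nunique()

    @property
    def case_mask(self) -> pd.Series:
        return self.participants["role"].eq("case")

    def cases(self) -> pd.DataFrame:
        return self.participants[self.case_mask]

    def controls(self) -> pd.DataFrame:
        return self.participants[~self.case_mask]

    def concentrations(self) -> pd.DataFrame:
        """Concentrations on the measurement (uM) scale."""
        return np.exp(self.log_concentrations)


def simulate_exposure_pairs(
    n_sets: int,
    or_per_sd: float,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Minimal matched-pair recovery generator for a single exposure.

    Draws two independent standard-normal exposure scores per set and
    assigns the case label within the pair with probability
    ``exp(b x1) / (exp(b x1) + exp(b x2))``, ``b = ln(or_per_sd)`` --
    the exact 1:1 conditional-logistic model.  Returns one row per set
    with columns ``case_score`` and ``control_score``.
    """
    if n_sets < 1:
        raise ValueError("need at least one matched set")
    if or_per_sd <= 0:
        raise ValueError("odds ratio must be positive")
    rng = np.random.default_rng(rng)
    beta = np.log(or_per_sd)
    z = rng.standard_normal((n_sets, 2))
    p_first = expit(beta * (z[:, 0] - z[:, 1]))
    first_is_case = rng.random(n_sets) < p_first
    case = np.where(first_is_case, z[:, 0], z[:, 1])
    ctrl = np.where(first_is_case, z[:, 1], z[:, 0])
    return pd.DataFrame({
        "set_id": np.arange(n_sets), "case_score": case, "control_score": ctrl})


def _draw_categorical(rng, freqs: dict, unknown_rate: float, n: int) -> np.ndarray:
    cats = list(freqs) + ["unknown"]
    p = np.array(list(freqs.values()), dtype=float)
    p = p / p.sum() * (1.0 - unknown_rate)
    p = np.append(p, unknown_rate)
    return rng.choice(cats, size=n, p=p)


def simulate_matched_pairs(
    panel: pd.DataFrame,
    effects: EffectSpec,
    n_sets: int,
    outcome: str = "advanced",
    seed: int | None = None,
    *,
    block_loading: float = 0.3,
    noise_sd: float = 0.2,
    cross_loading_sd: float = 0.03,
    within_pair_latent_corr: float = 0.0,
    covariates: CovariateModel | None = None,
    n_centers: int = 8,
) -> MatchedCohort:
    """Simulate 1:1 matched sets with latent-pattern effects on case status.

    Log concentrations are ``class mean + loading * block score + noise``;
    block members carry loading ``block_loading`` on their block,
    background metabolites a small random cross-loading (SD
    ``cross_loading_sd``) on a random block, so the covariance is
    block-structured but not exactly block-diagonal.  Case status is
    assigned within each pair by the exact conditional-logistic rule on
    the standardized latent scores (see module docstring), making the
    generating per-1-SD odds ratios directly recoverable.  Matching
    factors (center, age +-6 months, blood-draw hour +-1, fasting
    category, follow-up length) are shared within set.  Deterministic
    for a fixed seed.
    """
    if n_sets < 1:
        raise ValueError("need at least one matched set")
    if outcome not in OUTCOME_VOCAB:
        raise ValueError(f"unknown outcome: {outcome!r}")
    cov_model = covariates or CovariateModel()
    rng = np.random.default_rng(seed)
    p = len(panel)
    n_people = 2 * n_sets

    # latent block scores, optionally correlated within pair
    R = effects.block_corr
    L = np.linalg.cholesky(R + 1e-12 * np.eye(3))
    if within_pair_latent_corr:
        rho = within_pair_latent_corr
        shared = rng.standard_normal((n_sets, 3))
        own = rng.standard_normal((n_people, 3))
        raw = (np.sqrt(rho) * np.repeat(shared, 2, axis=0)
               + np.sqrt(1 - rho) * own)
    else:
        raw = rng.standard_normal((n_people, 3))
    U = raw @ L.T  # standardized latent scores, corr = R

    beta = effects.log_or_vector(outcome)
    eta = U @ beta
    eta1, eta2 = eta[0::2], eta[1::2]
    p_first = expit(eta1 - eta2)
    first_is_case = rng.random(n_sets) < p_first
    is_case = np.zeros(n_people, dtype=bool)
    is_case[0::2] = first_is_case
    is_case[1::2] = ~first_is_case

    # loading matrix: p x 3
    block_idx = {b: i for i, b in enumerate(_BLOCKS)}
    Lam = np.zeros((p, 3))
    eps_sd = np.empty(p)
    for j, row in enumerate(panel.itertuples(index=False)):
        if row.block is not None and not (isinstance(row.block, float) and np.isnan(row.block)):
            Lam[j, block_idx[row.block]] = block_loading
            eps_sd[j] = noise_sd
        else:
            Lam[j, rng.integers(0, 3)] = rng.normal(0.0, cross_loading_sd)
            eps_sd[j] = row.log_sd
    means = panel["mean_log_conc"].to_numpy()
    X = means + U @ Lam.T + rng.standard_normal((n_people, p)) * eps_sd

    # matching factors, shared within set up to the stated tolerances
    center = rng.integers(1, n_centers + 1, n_sets)
    age_case = np.clip(rng.normal(cov_model.age_mean, cov_model.age_sd, n_sets), 40, 78)
    age_jitter = rng.uniform(-0.5, 0.5, n_sets)
    hour = rng.uniform(7.0, 17.0, n_sets)
    hour_jitter = rng.uniform(-1.0, 1.0, n_sets)
    fasting = rng.choice(["<3h", "3-6h", ">6h"], n_sets, p=[0.5, 0.25, 0.25])
    followup = rng.uniform(2.0, 20.0, n_sets)
    time_to_dx = np.clip(rng.normal(9.4, 4.2, n_sets), 0.1, None)

    ids = [f"P{i:06d}" for i in range(n_people)]
    set_ids = np.repeat([f"S{i:05d}" for i in range(n_sets)], 2)
    part = pd.DataFrame({
        "participant_id": ids,
        "set_id": set_ids,
        "role": np.where(is_case, "case", "control"),
        "center": np.repeat(center, 2),
        "fasting": np.repeat(fasting, 2),
        "followup_years": np.repeat(followup, 2),
    })
    # case keeps the drawn stratum value; control jittered within tolerance
    age = np.repeat(age_case, 2)
    blood_hour = np.repeat(hour, 2)
    age[~is_case] += np.repeat(age_jitter, 2)[~is_case]
    blood_hour[~is_case] += np.repeat(hour_jitter, 2)[~is_case]
    part["age_blood"] = age
    part["blood_hour"] = blood_hour

    bmi = np.clip(rng.normal(cov_model.bmi_mean, cov_model.bmi_sd, n_people), 17, 45)
    bmi[rng.random(n_people) < cov_model.unknown_rates["bmi"]] = np.nan
    part["bmi"] = bmi
    for name in ("smoking", "alcohol", "education", "marital"):
        part[name] = _draw_categorical(
            rng, getattr(cov_model, name), cov_model.unknown_rates[name], n_people)

    for i, b in enumerate(_BLOCKS):
        part[f"latent_{b}"] = U[:, i]

    # outcome fields; recovery simulations label every case with the
    # requested subtype, assign_outcomes() redraws a realistic mix
    part["stage"] = None
    part["aggressive"] = False
    part["grade"] = None
    part["death"] = False
    part["time_to_dx"] = np.repeat(time_to_dx, 2)
    part["censored_before_case_death"] = False
    if outcome in ("localized", "advanced"):
        part.loc[is_case, "stage"] = outcome
    elif outcome == "aggressive":
        part.loc[is_case, "stage"] = "advanced"
        part.loc[is_case, "aggressive"] = True
    elif outcome in ("high_grade", "low_intermediate_grade"):
        part.loc[is_case, "grade"] = outcome
    elif outcome == "death":
        part.loc[is_case, "death"] = True

    conc = pd.DataFrame(X, index=pd.Index(ids, name="participant_id"),
                        columns=panel["name"].tolist())
    meta = {
        "seed": seed, "n_sets": n_sets, "outcome": outcome,
        "block_loading": block_loading, "noise_sd": noise_sd,
        "cross_loading_sd": cross_loading_sd,
        "within_pair_latent_corr": within_pair_latent_corr,
    }
    return MatchedCohort(part, conc, panel.copy(), meta)


def assign_outcomes(
    cohort: MatchedCohort,
    mix: OutcomeMix | None = None,
    seed: int | None = None,
) -> MatchedCohort:
    """Attach subtype labels to cases at the configured expected mix.

    Stage and grade are drawn independently; aggressiveness only among
    advanced cases (subset constraint holds by construction).  A
    configurable fraction of sets whose case dies has the control
    flagged censored before the case's death (those sets are excluded
    from the death analysis downstream).
    """
    mix = mix or OutcomeMix()
    rng = np.random.default_rng(seed)
    part = cohort.participants.copy()
    case_idx = part.index[part["role"] == "case"]
    n = len(case_idx)

    staged = rng.random(n) < mix.stage_known
    adv_frac = mix.advanced  # of staged cases
    advanced = (rng.random(n) < adv_frac) & staged
    stage = np.where(staged, np.where(advanced, "advanced", "localized"), "unknown")
    p_agg_given_adv = (mix.aggressive / mix.advanced) if mix.advanced > 0 else 0.0
    aggressive = advanced & (rng.random(n) < p_agg_given_adv)

    graded = rng.random(n) < mix.grade_known
    high = (rng.random(n) < mix.high_grade) & graded
    grade = np.where(
        graded, np.where(high, "high_grade", "low_intermediate_grade"), "unknown")

    death = rng.random(n) < mix.death
    censored = death & (rng.random(n) < mix.censor_given_death)

    part.loc[case_idx, "stage"] = stage
    part.loc[case_idx, "aggressive"] = aggressive
    part.loc[case_idx, "grade"] = grade
    part.loc[case_idx, "death"] = death
    # flag sits on the control row of the affected set
    censored_sets = part.loc[case_idx[censored], "set_id"]
    ctrl_rows = part.index[part["role"].eq("control")
                           & part["set_id"].isin(censored_sets)]
    part["censored_before_case_death"] = False
    part.loc[ctrl_rows, "censored_before_case_death"] = True

    return MatchedCohort(part, cohort.log_concentrations, cohort.panel,
                         {**cohort.meta, "outcome_mix_seed": seed})


def write_cohort(cohort: MatchedCohort, outdir: str | Path) -> dict:
    """Write the three study tables as TSV plus a run manifest.

    ``concentrations.tsv`` (uM scale, participants x metabolites),
    ``sets.tsv`` (set structure, matching factors, covariates) and
    ``outcomes.tsv`` (case subtype fields and control censoring flags).
    Returns the manifest dict (also written as ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    conc = cohort.concentrations()
    conc.to_csv(outdir / "concentrations.tsv", sep="\t")
    set_cols = ["participant_id", "set_id", "role", "center", "age_blood",
                "blood_hour", "fasting", "followup_years", "bmi", "smoking",
                "alcohol", "education", "marital"]
    cohort.participants[set_cols].to_csv(outdir / "sets.tsv", sep="\t", index=False)
    out_cols = ["participant_id", "set_id", "role", "stage", "aggressive",
                "grade", "death", "time_to_dx", "censored_before_case_death"]
    cohort.participants[out_cols].to_csv(outdir / "outcomes.tsv", sep="\t", index=False)

    config_blob = json.dumps(cohort.meta, sort_keys=True, default=str).encode()
    manifest = {
        "config_hash": hashlib.sha256(config_blob).hexdigest()[:16],
        "meta": cohort.meta,
        "n_sets": int(cohort.n_sets),
        "n_metabolites": int(cohort.log_concentrations.shape[1]),
        "class_composition": cohort.panel["metabolite_class"]
            .value_counts().to_dict(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
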