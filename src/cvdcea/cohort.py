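"""Synthetic health-assessment cohorts.

The upstream data for this model are annual health assessments: one record
per participant per timepoint carrying the seven cardiovascular risk factors
(age, sex, diabetes, total cholesterol, systolic blood pressure,
antihypertensive-medication use, smoking).  Only stratum-level means and
proportions are published for the study population, so this module generates
individual-level cohorts whose stratum summaries match those targets, and
summarizes cohorts back into the stratum profiles the risk module consumes.

Cohort files are plain CSV with the column set in :data:`COHORT_COLUMNS`;
booleans are written as 0/1 and the timepoint is ``baseline`` or ``exit``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SEXES = ("male", "female")
TIMEPOINTS = ("baseline", "exit")

#: valid ranges for the continuous assessment variables
AGE_RANGE = (18.0, 110.0)
SBP_RANGE = (70.0, 260.0)
CHOL_RANGE = (80.0, 400.0)

COHORT_COLUMNS = [
    "participant_id",
    "timepoint",
    "age",
    "sex",
    "diabetes",
    "total_cholesterol",
    "sbp",
    "on_htn_medication",
    "smoker",
]

#: projected annual-assessment-to-assessment SBP rise (mmHg) used for the
#: no-intervention counterfactual when only baseline SBP is observed
COUNTERFACTUAL_SBP_DELTA = 12.0


class CohortValidationError(ValueError):
    """A cohort record or generator parameter failed validation."""


@dataclass(frozen=True)
class HealthAssessment:
    """One participant's risk-factor profile at a single timepoint."""

    participant_id: str
    timepoint: str
    age: float
    sex: str
    diabetes: bool
    total_cholesterol: float
    sbp: float
    on_htn_medication: bool
    smoker: bool

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise CohortValidationError(
                f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}"
            )
        if self.sex not in SEXES:
            raise CohortValidationError(
                f"sex must be one of {SEXES}, got {self.sex!r}"
            )
        for name, value, (lo, hi) in (
            ("age", self.age, AGE_RANGE),
            ("sbp", self.sbp, SBP_RANGE),
            ("total_cholesterol", self.total_cholesterol, CHOL_RANGE),
        ):
            if not (lo <= value <= hi):
                raise CohortValidationError(
                    f"{name}={value} outside valid range [{lo}, {hi}]"
                )


@dataclass(frozen=True)
class StratumProfile:
    """Aggregated risk-factor targets for one sex x diabetes stratum.

    Continuous fields are stratum means; ``prop_*`` fields are proportions in
    [0, 1].  ``mean_sbp_counterfactual`` is the projected no-intervention SBP
    (baseline mean plus :data:`COUNTERFACTUAL_SBP_DELTA` by default).
    """

    sex: str
    diabetes: bool
    n: int
    mean_entry_age: float
    mean_chol_baseline: float
    mean_chol_exit: float
    mean_sbp_baseline: float
    mean_sbp_counterfactual: float
    prop_htn_med_baseline: float
    prop_htn_med_exit: float
    prop_smoker_baseline: float
    prop_smoker_exit: float

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise CohortValidationError(f"sex must be one of {SEXES}")
        if self.n <= 0:
            raise CohortValidationError("stratum n must be positive")
        for name in (
            "prop_htn_med_baseline",
            "prop_htn_med_exit",
            "prop_smoker_baseline",
            "prop_smoker_exit",
        ):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise CohortValidationError(f"{name}={p} outside [0, 1]")

    @property
    def key(self) -> tuple[str, bool]:
        return (self.sex, self.diabetes)

    @property
    def label(self) -> str:
        return f"{self.sex}_{'diabetes' if self.diabetes else 'no_diabetes'}"


def reference_strata() -> list[StratumProfile]:
    """The four published sex x diabetes stratum profiles.

    Sample sizes 1395 / 581 / 3091 / 1087 (total 6154).  Counterfactual SBP is
    the published projection: baseline + 12 mmHg.
    """
    rows = [
        # sex, dm, n, age, chol_b, chol_e, sbp_b, med_b, med_e, smk_b, smk_e
        ("male", False, 1395, 66.2, 162.0, 160.0, 129.0, 0.06, 0.40, 0.27, 0.24),
        ("male", True, 581, 66.6, 180.0, 179.0, 141.0, 0.22, 0.60, 0.17, 0.15),
        ("female", False, 3091, 68.9, 195.0, 194.0, 130.0, 0.14, 0.41, 0.15, 0.13),
        ("female", True, 1087, 67.9, 173.0, 174.0, 131.0, 0.06, 0.68, 0.14, 0.12),
    ]
    return [
        StratumProfile(
            sex=sex,
            diabetes=dm,
            n=n,
            mean_entry_age=age,
            mean_chol_baseline=cb,
            mean_chol_exit=ce,
            mean_sbp_baseline=sbp,
            mean_sbp_counterfactual=sbp + COUNTERFACTUAL_SBP_DELTA,
            prop_htn_med_baseline=mb,
            prop_htn_med_exit=me,
            prop_smoker_baseline=sb,
            prop_smoker_exit=se,
        )
        for sex, dm, n, age, cb, ce, sbp, mb, me, sb, se in rows
    ]


@dataclass(frozen=True)
class CohortGenParams:
    """Generator settings: stratum targets plus continuous dispersions.

    Dispersions are standard deviations in the variable's own units; the
    published inputs carry no variance information, so these are generator
    settings, not data.  A fixed ``seed`` makes generation byte-reproducible;
    each stratum draws from its own substream keyed by (sex, diabetes) so
    adding or removing a stratum leaves the others unchanged.
    """

    strata: tuple[StratumProfile, ...]
    age_sd: float = 8.0
    sbp_sd: float = 15.0
    chol_sd: float = 35.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("age_sd", "sbp_sd", "chol_sd"):
            if getattr(self, name) < 0:
                raise CohortValidationError(f"{name} must be non-negative")
        keys = [s.key for s in self.strata]
        if len(set(keys)) != len(keys):
            raise CohortValidationError("duplicate sex x diabetes stratum")


def default_gen_params(seed: int = 0, **kwargs) -> CohortGenParams:
    """Generator parameters targeting the published stratum profiles."""
    return CohortGenParams(strata=tuple(reference_strata()), seed=seed, **kwargs)


def _stratum_rng(seed: int, profile: StratumProfile) -> np.random.Generator:
    # stable substream per stratum, independent of stratum ordering
    key = 2 * SEXES.index(profile.sex) + int(profile.diabetes)
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int
) -> np.ndarray:
    if not (lo <= mean <= hi):
        raise CohortValidationError(f"mean {mean} outside truncation range [{lo}, {hi}]")
    if sd == 0.0:
        return np.full(n, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _transition_binary(
    rng: np.random.Generator, base: np.ndarray, p_base: float, p_exit: float
) -> np.ndarray:
    """Exit binary state given baseline, with one-directional transitions.

    If the exit target is below the baseline target, positives may revert
    (smokers quit, non-smokers never start); otherwise negatives may convert
    (medication starts, never stops).  Expected exit proportion equals
    ``p_exit`` exactly in either regime.
    """
    out = base.copy()
    if p_exit < p_base:
        keep = p_exit / p_base if p_base > 0 else 0.0
        out &= rng.random(base.size) < keep
    elif p_exit > p_base:
        start = (p_exit - p_base) / (1.0 - p_base) if p_base < 1 else 0.0
        out |= (~base) & (rng.random(base.size) < start)
    return out


def _generate_stratum(
    profile: StratumProfile, params: CohortGenParams, n: int
) -> pd.DataFrame:
    rng = _stratum_rng(params.seed, profile)
    age = _truncated_normal(rng, profile.mean_entry_age, params.age_sd, *AGE_RANGE, n=n)
    sbp = _truncated_normal(rng, profile.mean_sbp_baseline, params.sbp_sd, *SBP_RANGE, n=n)
    chol = _truncated_normal(
        rng, profile.mean_chol_baseline, params.chol_sd, *CHOL_RANGE, n=n
    )
    med_b = rng.random(n) < profile.prop_htn_med_baseline
    smk_b = rng.random(n) < profile.prop_smoker_baseline
    med_e = _transition_binary(
        rng, med_b, profile.prop_htn_med_baseline, profile.prop_htn_med_exit
    )
    smk_e = _transition_binary(
        rng, smk_b, profile.prop_smoker_baseline, profile.prop_smoker_exit
    )
    # exit cholesterol: shift every participant by the stratum mean change so
    # within-person correlation is preserved; clip to the valid range
    chol_e = np.clip(
        chol + (profile.mean_chol_exit - profile.mean_chol_baseline), *CHOL_RANGE
    )
    pid = [f"{profile.label}-{i:06d}" for i in range(n)]
    base = pd.DataFrame(
        {
            "participant_id": pid,
            "timepoint": "baseline",
            "age": age,
            "sex": profile.sex,
            "diabetes": profile.diabetes,
            "total_cholesterol": chol,
            "sbp": sbp,
            "on_htn_medication": med_b,
            "smoker": smk_b,
        }
    )
    exit_ = base.assign(
        timepoint="exit",
        total_cholesterol=chol_e,
        on_htn_medication=med_e,
        smoker=smk_e,
    )
    return pd.concat([base, exit_], ignore_index=True)


def generate_cohort(params: CohortGenParams, n: int | None = None) -> pd.DataFrame:
    """Generate paired baseline/exit assessment records for every stratum.

    Parameters
    ----------
    params
        Stratum targets, dispersions and master seed.
    n
        If given, overrides every stratum's sample size (``n=0`` yields an
        empty cohort); otherwise each stratum uses its own ``n``.

    Returns
    -------
    pandas.DataFrame
        Long-format cohort with :data:`COHORT_COLUMNS`, two rows per
        participant (baseline and exit).
    """
    if n is not None and n < 0:
        raise CohortValidationError("n must be non-negative")
    frames = [
        _generate_stratum(p, params, p.n if n is None else n) for p in params.strata
    ]
    frames = [f for f in frames if len(f)]
    if not frames:
        return pd.DataFrame(columns=COHORT_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    return out[COHORT_COLUMNS]


def _records_to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([vars(r) for r in records])


def summarize_cohort(
    records,
    counterfactual_sbp_delta: float = COUNTERFACTUAL_SBP_DELTA,
) -> list[StratumProfile]:
    """Summarize assessment records into per-stratum profiles.

    Records missing a required field are excluded with a logged warning.
    Counterfactual SBP is projected as baseline mean plus
    ``counterfactual_sbp_delta``.
    """
    df = _records_to_frame(records)
    if df.empty:
        raise CohortValidationError("no records to summarize")
    missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise CohortValidationError(f"records missing columns: {missing_cols}")
    bad = df[COHORT_COLUMNS].isna().any(axis=1)
    if bad.any():
        for idx in df.index[bad]:
            fields = [c for c in COHORT_COLUMNS if pd.isna(df.loc[idx, c])]
            logger.warning(
                "excluding record %s: missing %s",
                df.loc[idx, "participant_id"],
                ", ".join(map(str, fields)),
            )
        df = df[~bad]
    base = df[df["timepoint"] == "baseline"]
    exit_ = df[df["timepoint"] == "exit"].set_index("participant_id")
    if base.empty:
        raise CohortValidationError("no baseline records present")
    profiles = []
    for (sex, dm), grp in base.groupby(["sex", "diabetes"], sort=True):
        ex = exit_.loc[exit_.index.intersection(grp["participant_id"])]
        sbp_b = float(grp["sbp"].mean())
        profiles.append(
            StratumProfile(
                sex=sex,
                diabetes=bool(dm),
                n=len(grp),
                mean_entry_age=float(grp["age"].mean()),
                mean_chol_baseline=float(grp["total_cholesterol"].mean()),
                mean_chol_exit=float(ex["total_cholesterol"].mean())
                if len(ex)
                else float(grp["total_cholesterol"].mean()),
                mean_sbp_baseline=sbp_b,
                mean_sbp_counterfactual=sbp_b + counterfactual_sbp_delta,
                prop_htn_med_baseline=float(grp["on_htn_medication"].mean()),
                prop_htn_med_exit=float(ex["on_htn_medication"].mean())
                if len(ex)
                else float(grp["on_htn_medication"].mean()),
                prop_smoker_baseline=float(grp["smoker"].mean()),
                prop_smoker_exit=float(ex["smoker"].mean())
                if len(ex)
                else float(grp["smoker"].mean()),
            )
        )
    return profiles


def write_cohort(records, path) -> None:
    """Write assessment records as the cohort CSV (booleans as 0/1)."""
    df = _records_to_frame(records).copy()
    for col in ("diabetes", "on_htn_medication", "smoker"):
        df[col] = df[col].astype(int)
    df[COHORT_COLUMNS].to_csv(path, index=False, float_format="%.6f")


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Raises
    ------
    CohortValidationError
        Naming the first offending line (1-based, counting the header) and
        field when a row fails schema validation.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"{path}: missing columns {missing}")
    checks = [
        ("timepoint", ~df["timepoint"].isin(TIMEPOINTS)),
        ("sex", ~df["sex"].isin(SEXES)),
        ("diabetes", ~df["diabetes"].isin([0, 1])),
        ("on_htn_medication", ~df["on_htn_medication"].isin([0, 1])),
        ("smoker", ~df["smoker"].isin([0, 1])),
        ("age", ~df["age"].between(*AGE_RANGE)),
        ("sbp", ~df["sbp"].between(*SBP_RANGE)),
        ("total_cholesterol", ~df["total_cholesterol"].between(*CHOL_RANGE)),
    ]
    for field_name, bad in checks:
        if bad.any():
            line = int(df.index[bad][0]) + 2  # header + 1-based
            raise CohortValidationError(
                f"{path}: line {line}: invalid value "
                f"{df.loc[df.index[bad][0], field_name]!r} for field {field_name!r}"
            )
    dup = df.duplicated(subset=["participant_id", "timepoint"])
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise CohortValidationError(
            f"{path}: line {line}: duplicate (participant_id, timepoint)"
        )
    for col in ("diabetes", "on_htn_medication", "smoker"):
        df[col] = df[col].astype(bool)
    return df[COHORT_COLUMNS]
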