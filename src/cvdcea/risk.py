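"""Risk-factor profiles to annual transition matrices.

Multi-year cardiovascular risk functions in the Framingham tradition map a
profile (age, sex, total cholesterol, diabetes, smoking, SBP,
antihypertensive-medication use) to a t-year probability of a first event.
This module evaluates such functions from pluggable coefficient tables,
converts the multi-year risk to an annual probability under a constant-hazard
assumption, and assembles full annual transition matrices over the five-state
set (healthy, stroke, MI, CHF, death) for the intervention and counterfactual
scenarios.

Printed post-event transition rows in the source material do not all sum to 1,
so matrices pass through an explicit validation step with a configurable
residual policy before the cohort engine will accept them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from .cohort import StratumProfile

logger = logging.getLogger(__name__)

STATES = ("healthy", "stroke", "mi", "chf", "death")
EVENT_TYPES = ("stroke", "mi", "chf", "death")
RISK_FACTORS = (
    "age",
    "male",
    "total_cholesterol",
    "diabetes",
    "smoker",
    "sbp",
    "on_htn_medication",
)

#: structurally forbidden transitions (from, to): no recovery to healthy, no
#: second event except stroke -> MI, which the published matrix permits
FORBIDDEN_EDGES = (
    ("stroke", "healthy"),
    ("mi", "healthy"),
    ("chf", "healthy"),
    ("death", "healthy"),
    ("mi", "stroke"),
    ("chf", "stroke"),
    ("chf", "mi"),
    ("death", "stroke"),
    ("death", "mi"),
    ("death", "chf"),
)


class RiskModelError(ValueError):
    """Invalid risk-model input (profile, coefficients or matrix)."""


class MatrixValidationError(RiskModelError):
    """A transition matrix failed validation under the active policy."""


def multi_year_to_annual(risk: float, t: float) -> float:
    """Convert a t-year event risk to an annual probability.

    Assumes a constant hazard over the risk horizon, so the annual
    probability ``p`` satisfies ``1 - (1 - p)**t = risk``:

        p = 1 - (1 - risk)**(1/t)

    Monotone increasing in ``risk`` and equal to ``risk`` at ``t = 1``.
    """
    if t <= 0:
        raise RiskModelError(f"risk horizon must be positive, got {t}")
    if not (0.0 <= risk <= 1.0):
        raise RiskModelError(f"risk {risk} outside [0, 1]")
    if risk == 1.0:
        return 1.0
    return 1.0 - (1.0 - risk) ** (1.0 / t)


@dataclass(frozen=True)
class RiskCoefficientSet:
    """Coefficients of one event's multi-year risk function.

    The t-year risk is ``1 - exp(-exp(intercept + sum_k beta_k x_k))`` — a
    proportional-hazards form with a complementary log-log link.  The
    coefficient table is treated as an opaque, versioned parameter set;
    alternative published functions can be dropped in via
    :func:`read_coefficient_file`.
    """

    event_type: str
    coefficients: Mapping[str, float]
    intercept: float
    horizon_years: float
    source: str = "unspecified"
    version: str = "0"

    def __post_init__(self) -> None:
        if self.horizon_years <= 0:
            raise RiskModelError("risk horizon must be positive")
        unknown = set(self.coefficients) - set(RISK_FACTORS)
        if unknown:
            raise RiskModelError(f"unknown risk factors in coefficients: {unknown}")

    def linear_predictor(self, profile: Mapping[str, float]) -> float:
        lp = self.intercept
        for factor, beta in self.coefficients.items():
            if factor not in profile:
                raise RiskModelError(
                    f"profile missing factor {factor!r} required by "
                    f"{self.event_type} coefficients"
                )
            lp += beta * float(profile[factor])
        return lp

    def multi_year_risk(self, profile: Mapping[str, float]) -> float:
        lp = self.linear_predictor(profile)
        risk = 1.0 - math.exp(-math.exp(lp))
        if not math.isfinite(risk):
            raise RiskModelError(
                f"non-finite {self.event_type} risk for profile {dict(profile)}"
            )
        return risk


def annual_event_probability(
    profile: Mapping[str, float], coeffs: RiskCoefficientSet
) -> float:
    """Annual probability of a first event for a risk-factor profile.

    Evaluates the multi-year risk function and annualizes it with
    :func:`multi_year_to_annual`.  Binary factors may be supplied as cohort
    proportions (values in [0, 1]) to evaluate a stratum-average profile.
    """
    risk = coeffs.multi_year_risk(profile)
    return multi_year_to_annual(risk, coeffs.horizon_years)


def read_coefficient_file(path) -> dict[str, RiskCoefficientSet]:
    """Read coefficient sets from a delimited text file.

    Format: ``#``-prefixed ``key: value`` metadata lines (``source``,
    ``version``, ``horizon_years``), then a tab-separated table with columns
    ``event_type``, ``factor``, ``coefficient``; the factor ``intercept``
    carries the baseline risk term.
    """
    meta: dict[str, str] = {}
    rows: list[tuple[str, str, float]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                if ":" in body:
                    k, v = body.split(":", 1)
                    if k.strip() != "note":
                        meta[k.strip()] = v.strip()
                continue
            parts = line.split("\t")
            if parts[0] == "event_type":
                continue
            if len(parts) != 3:
                raise RiskModelError(f"{path}: malformed coefficient row {line!r}")
            rows.append((parts[0], parts[1], float(parts[2])))
    horizon = float(meta.get("horizon_years", 10.0))
    out: dict[str, RiskCoefficientSet] = {}
    for event in sorted({r[0] for r in rows}):
        coefs = {f: c for e, f, c in rows if e == event and f != "intercept"}
        intercepts = [c for e, f, c in rows if e == event and f == "intercept"]
        if len(intercepts) != 1:
            raise RiskModelError(f"{path}: event {event!r} needs exactly one intercept")
        out[event] = RiskCoefficientSet(
            event_type=event,
            coefficients=coefs,
            intercept=intercepts[0],
            horizon_years=horizon,
            source=meta.get("source", str(path)),
            version=meta.get("version", "0"),
        )
    missing = set(EVENT_TYPES) - set(out)
    if missing:
        raise RiskModelError(f"{path}: missing coefficient sets for {missing}")
    return out


def default_coefficients() -> dict[str, RiskCoefficientSet]:
    """The packaged default coefficient table (see the file's header notes)."""
    ref = resources.files("cvdcea.data").joinpath("default_coefficients.tsv")
    with resources.as_file(ref) as path:
        return read_coefficient_file(path)


# ---------------------------------------------------------------------------
# scenarios

#: per-factor source rule: which stratum quantity feeds each risk factor
ScenarioRules = Mapping[str, str]


@dataclass(frozen=True)
class ScenarioSpec:
    """Maps each risk factor to the stratum quantity that feeds it.

    The intervention scenario uses observed exit medication/smoking status and
    observed (baseline, non-deteriorated) SBP; the counterfactual freezes all
    factors at baseline except SBP, which uses the projected no-intervention
    value.
    """

    name: str
    sources: ScenarioRules

    _VALID = {
        "total_cholesterol": ("baseline", "exit"),
        "sbp": ("baseline", "counterfactual"),
        "on_htn_medication": ("baseline", "exit"),
        "smoker": ("baseline", "exit"),
    }

    def __post_init__(self) -> None:
        for factor, valid in self._VALID.items():
            src = self.sources.get(factor)
            if src not in valid:
                raise RiskModelError(
                    f"scenario {self.name!r}: factor {factor!r} needs a source "
                    f"in {valid}, got {src!r}"
                )

    def profile_values(self, stratum: StratumProfile) -> dict[str, float]:
        """Resolve the stratum-average risk-factor profile for this scenario."""
        pick = {
            "total_cholesterol": {
                "baseline": stratum.mean_chol_baseline,
                "exit": stratum.mean_chol_exit,
            },
            "sbp": {
                "baseline": stratum.mean_sbp_baseline,
                "counterfactual": stratum.mean_sbp_counterfactual,
            },
            "on_htn_medication": {
                "baseline": stratum.prop_htn_med_baseline,
                "exit": stratum.prop_htn_med_exit,
            },
            "smoker": {
                "baseline": stratum.prop_smoker_baseline,
                "exit": stratum.prop_smoker_exit,
            },
        }
        values = {f: pick[f][self.sources[f]] for f in pick}
        values["age"] = stratum.mean_entry_age
        values["male"] = 1.0 if stratum.sex == "male" else 0.0
        values["diabetes"] = 1.0 if stratum.diabetes else 0.0
        return values


INTERVENTION = ScenarioSpec(
    "intervention",
    {
        "total_cholesterol": "exit",
        "sbp": "baseline",
        "on_htn_medication": "exit",
        "smoker": "exit",
    },
)
COUNTERFACTUAL = ScenarioSpec(
    "counterfactual",
    {
        "total_cholesterol": "baseline",
        "sbp": "counterfactual",
        "on_htn_medication": "baseline",
        "smoker": "baseline",
    },
)


# ---------------------------------------------------------------------------
# transition matrices

#: published post-event annual rows (stay/CHF/death and the permitted
#: stroke -> MI edge); stratum-independent defaults, configurable
DEFAULT_DOWNSTREAM_ROWS: dict[str, dict[str, float]] = {
    "stroke": {"stroke": 0.4053, "mi": 0.0392, "chf": 0.0488, "death": 0.1813},
    "mi": {"mi": 0.5078, "chf": 0.1230, "death": 0.3691},
    "chf": {"chf": 0.4873, "death": 0.5127},
}

VALIDATION_POLICIES = ("error", "renormalize", "residual_to_self", "residual_to_extra_state")


@dataclass(frozen=True)
class TransitionMatrix:
    """Annual state-to-state probabilities with validation metadata."""

    probs: np.ndarray
    states: tuple[str, ...] = STATES
    stratum: str = ""
    scenario: str = ""
    validated: bool = False
    policy: str | None = None
    row_residuals: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (len(self.states), len(self.states)):
            raise RiskModelError(
                f"matrix shape {p.shape} does not match states {self.states}"
            )
        object.__setattr__(self, "probs", p)

    def row(self, state: str) -> np.ndarray:
        return self.probs[self.states.index(state)]

    def entry(self, frm: str, to: str) -> float:
        return float(self.probs[self.states.index(frm), self.states.index(to)])


def _structural_check(probs: np.ndarray, states: Sequence[str]) -> None:
    idx = {s: i for i, s in enumerate(states)}
    for frm, to in FORBIDDEN_EDGES:
        if frm in idx and to in idx and probs[idx[frm], idx[to]] != 0.0:
            raise MatrixValidationError(
                f"structurally forbidden transition {frm} -> {to} has "
                f"probability {probs[idx[frm], idx[to]]}"
            )
    d = idx.get("death")
    if d is not None:
        expected = np.zeros(len(states))
        expected[d] = 1.0
        if not np.array_equal(probs[d], expected):
            raise MatrixValidationError("death row must be absorbing")


def validate_matrix(
    matrix: TransitionMatrix,
    policy: str = "renormalize",
    tolerance: float = 1e-9,
    extra_state: str = "post_stroke",
) -> tuple[TransitionMatrix, dict]:
    """Apply a row-sum residual policy and return the validated matrix.

    Policies
    --------
    ``error``
        Reject any row whose |1 - sum| exceeds ``tolerance``.
    ``renormalize``
        Divide each row by its sum (warning logged per affected row).
    ``residual_to_self``
        Add each row's residual to its diagonal entry, honouring printed
        stay-probabilities; rejected if that pushes an entry outside [0, 1].
    ``residual_to_extra_state``
        Route residual mass to a declared auxiliary absorbing-side state
        appended to the state set (e.g. an unprinted post-event state).

    Returns the validated matrix and a report with per-row residuals.
    """
    if policy not in VALIDATION_POLICIES:
        raise RiskModelError(
            f"unknown policy {policy!r}; valid: {VALIDATION_POLICIES}"
        )
    probs = np.array(matrix.probs, dtype=float)
    states = tuple(matrix.states)
    if (probs < 0).any() or (probs > 1).any():
        raise MatrixValidationError("matrix entries must lie in [0, 1]")
    _structural_check(probs, states)
    residuals = 1.0 - probs.sum(axis=1)
    report = {
        "states": states,
        "policy": policy,
        "row_residuals": {s: float(r) for s, r in zip(states, residuals)},
    }
    if policy == "error":
        bad = [s for s, r in zip(states, residuals) if abs(r) > tolerance]
        if bad:
            raise MatrixValidationError(
                f"rows {bad} have |residual| > {tolerance}: "
                f"{ {s: report['row_residuals'][s] for s in bad} }"
            )
        fixed = probs
    elif policy == "renormalize":
        sums = probs.sum(axis=1)
        if (sums <= 0).any():
            raise MatrixValidationError("cannot renormalize a zero row")
        for s, r in zip(states, residuals):
            if abs(r) > tolerance:
                logger.warning(
                    "renormalizing row %r with residual %.4f", s, float(r)
                )
        fixed = probs / sums[:, None]
    elif policy == "residual_to_self":
        fixed = probs.copy()
        fixed[np.arange(len(states)), np.arange(len(states))] += residuals
        if (fixed < -tolerance).any() or (fixed > 1 + tolerance).any():
            raise MatrixValidationError(
                "residual_to_self pushed a diagonal entry outside [0, 1]"
            )
        fixed = np.clip(fixed, 0.0, 1.0)
        for s, r in zip(states, residuals):
            if abs(r) > tolerance:
                logger.warning(
                    "routing residual %.4f of row %r to its diagonal", float(r), s
                )
    else:  # residual_to_extra_state
        if (residuals < -tolerance).any():
            raise MatrixValidationError(
                "negative residual cannot be routed to an extra state"
            )
        n = len(states)
        fixed = np.zeros((n + 1, n + 1))
        fixed[:n, :n] = probs
        fixed[:n, n] = np.clip(residuals, 0.0, None)
        fixed[n, n] = 1.0  # auxiliary state persists
        states = states + (extra_state,)
    sums = fixed.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-9):
        raise MatrixValidationError(f"row sums {sums} not 1 after {policy}")
    validated = TransitionMatrix(
        probs=fixed,
        states=states,
        stratum=matrix.stratum,
        scenario=matrix.scenario,
        validated=True,
        policy=policy,
        row_residuals=tuple(float(r) for r in residuals),
    )
    return validated, report


def build_transition_matrix(
    stratum: StratumProfile,
    scenario: ScenarioSpec,
    coefficients: Mapping[str, RiskCoefficientSet] | None = None,
    downstream_rows: Mapping[str, Mapping[str, float]] | None = None,
    event_probabilities: Mapping[str, float] | None = None,
    policy: str = "renormalize",
) -> TransitionMatrix:
    """Assemble and validate the annual matrix for one stratum and scenario.

    The healthy row is built from annual first-event probabilities (evaluated
    at the scenario's stratum-average profile, or injected directly via
    ``event_probabilities``), with the stay-probability as the complement.
    Post-event rows come from ``downstream_rows``; the death row is absorbing.
    The matrix is validated under ``policy`` before being returned.
    """
    if event_probabilities is None:
        coefficients = coefficients or default_coefficients()
        profile = scenario.profile_values(stratum)
        event_probabilities = {
            ev: annual_event_probability(profile, coefficients[ev])
            for ev in EVENT_TYPES
        }
    clamped = {ev: min(max(p, 0.0), 1.0) for ev, p in event_probabilities.items()}
    for ev in EVENT_TYPES:
        if clamped[ev] != event_probabilities[ev]:
            logger.warning(
                "clamped %s probability %.6f into [0, 1]", ev, event_probabilities[ev]
            )
    total = sum(clamped.values())
    if total > 1.0:
        raise RiskModelError(
            f"healthy-row event probabilities sum to {total:.4f} > 1 "
            f"(profile implies an impossible matrix)"
        )
    rows = downstream_rows or DEFAULT_DOWNSTREAM_ROWS
    probs = np.zeros((5, 5))
    idx = {s: i for i, s in enumerate(STATES)}
    probs[0, 0] = 1.0 - total
    for ev in EVENT_TYPES:
        probs[0, idx[ev]] = clamped[ev]
    for state in ("stroke", "mi", "chf"):
        if state not in rows:
            raise RiskModelError(f"downstream row missing for state {state!r}")
        for to, p in rows[state].items():
            probs[idx[state], idx[to]] = p
    probs[idx["death"], idx["death"]] = 1.0
    raw = TransitionMatrix(
        probs=probs,
        stratum=stratum.label,
        scenario=scenario.name,
    )
    validated, _ = validate_matrix(raw, policy=policy)
    return validated


def write_matrix(matrix: TransitionMatrix, path) -> None:
    """Write a matrix as a tab-delimited square table with state labels."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("from_state\t" + "\t".join(matrix.states) + "\n")
        for s, row in zip(matrix.states, matrix.probs):
            fh.write(s + "\t" + "\t".join(f"{p:.6f}" for p in row) + "\n")
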