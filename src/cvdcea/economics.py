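"""Program costs, healthcare costs, and cost-effectiveness ratios.

Three layers of cost accounting:

* a program-cost build-up from per-panel line items (wages, fringe loading,
  operating items, indirect overhead) to an average annual cost per
  participant;
* expected healthcare costs accumulated over a cohort trace: an annual
  maintenance cost for occupying each state, an acute-event cost on each
  transition, a mortality cost on transitions into death, and the program
  cost accrued per participant-year alive — all discounted under the
  engine's reward-timing convention;
* incremental cost-effectiveness ratios (cost per QALY and per life-year
  gained) between an intervention run and its counterfactual, with explicit
  dominance / cost-saving flags instead of raw division blow-ups.

All currency arithmetic is unrounded internally; display rounding is
round-half-up to the nearest dollar (fringe shown at two decimals).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import numpy as np

from .engine import CohortTrace, SimulationSettings, _reward_weights

logger = logging.getLogger(__name__)


class EconomicsError(ValueError):
    """Invalid cost input or inconsistent scenario pairing."""


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round half away from zero at ``decimals`` places (display rounding)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# program cost build-up


@dataclass(frozen=True)
class ProgramCostInputs:
    """Per-panel annual line items and loading rates.

    ``fringe_rate`` loads personnel wages with payroll benefits;
    ``indirect_rate`` loads total direct costs with overhead (space etc.).
    ``round_fringe_to_dollar`` applies payroll-style whole-dollar rounding to
    the fringe line before aggregation (the convention of the published
    build-up).
    """

    personnel: Mapping[str, float]
    operating: Mapping[str, float]
    fringe_rate: float = 0.33
    indirect_rate: float = 0.10
    panel_size: int = 100
    round_fringe_to_dollar: bool = True

    def __post_init__(self) -> None:
        for group in (self.personnel, self.operating):
            for item, value in group.items():
                if value < 0:
                    raise EconomicsError(f"line item {item!r} is negative: {value}")
        for name in ("fringe_rate", "indirect_rate"):
            r = getattr(self, name)
            if not (0.0 <= r <= 1.0):
                raise EconomicsError(f"{name}={r} outside [0, 1]")
        if self.panel_size < 1:
            raise EconomicsError("panel size must be at least 1 participant")


def default_program_cost_inputs() -> ProgramCostInputs:
    """The published per-panel annual line items (100 participants/panel)."""
    return ProgramCostInputs(
        personnel={
            "community_health_worker": 45760.0,
            "wellness_nurse": 16640.0,
            "supervisor_support": 3900.0,
            "admin_team_share": 9149.0,
        },
        operating={
            "travel": 1183.0,
            "laptops": 3000.0,
            "supplies_materials": 3775.0,
            "health_info_exchange": 102.0,
            "public_health_link": 1261.0,
            "training_licenses": 156.0,
            "phone_plan": 600.0,
        },
    )


@dataclass(frozen=True)
class ProgramCostBreakdown:
    """Every intermediate of the program-cost build-up, unrounded."""

    wages: float
    fringe: float
    total_personnel: float
    total_operating: float
    total_direct: float
    indirect: float
    total: float
    per_participant: float
    panel_size: int


def program_cost_per_participant(
    inputs: ProgramCostInputs,
) -> tuple[float, ProgramCostBreakdown]:
    """Annual program cost per participant with an itemized breakdown.

    fringe = fringe_rate x wages; total personnel = wages + fringe;
    total direct = personnel + operating; indirect = indirect_rate x direct;
    per-participant = (direct + indirect) / panel size.
    """
    wages = float(sum(inputs.personnel.values()))
    fringe = inputs.fringe_rate * wages
    if inputs.round_fringe_to_dollar:
        fringe = round_half_up(fringe)
    total_personnel = wages + fringe
    total_operating = float(sum(inputs.operating.values()))
    total_direct = total_personnel + total_operating
    indirect = inputs.indirect_rate * total_direct
    total = total_direct + indirect
    per_participant = total / inputs.panel_size
    breakdown = ProgramCostBreakdown(
        wages=wages,
        fringe=fringe,
        total_personnel=total_personnel,
        total_operating=total_operating,
        total_direct=total_direct,
        indirect=indirect,
        total=total,
        per_participant=per_participant,
        panel_size=inputs.panel_size,
    )
    return per_participant, breakdown


# ---------------------------------------------------------------------------
# healthcare + program costs over a trace

PROGRAM_ACCRUALS = ("per_year_alive", "one_time", "fixed_horizon")


@dataclass(frozen=True)
class CostSchedule:
    """Annual state maintenance costs, acute-event costs and program cost.

    ``state_costs`` is the annual cost of occupying each state; the death
    state must cost 0.  ``event_costs`` prices each allowed non-death
    transition (acute event); ``death_cost`` is applied once to mass
    transitioning into death.  ``placeholder`` marks schedules whose values
    are synthetic stand-ins rather than sourced estimates; pipelines refuse
    them unless explicitly confirmed.
    """

    state_costs: Mapping[str, float]
    event_costs: Mapping[tuple[str, str], float]
    death_cost: float = 0.0
    program_cost_per_participant_year: float = 0.0
    program_accrual: str = "per_year_alive"
    placeholder: bool = False

    def __post_init__(self) -> None:
        for state, c in self.state_costs.items():
            if c < 0:
                raise EconomicsError(f"state cost for {state!r} negative")
        if self.state_costs.get("death", 0.0) != 0.0:
            raise EconomicsError("death state maintenance cost must be 0")
        for edge, c in self.event_costs.items():
            if c < 0:
                raise EconomicsError(f"event cost for edge {edge} negative")
        if self.death_cost < 0 or self.program_cost_per_participant_year < 0:
            raise EconomicsError("costs must be non-negative")
        if self.program_accrual not in PROGRAM_ACCRUALS:
            raise EconomicsError(
                f"program_accrual must be one of {PROGRAM_ACCRUALS}"
            )


def placeholder_schedule(program_cost: float = 0.0) -> CostSchedule:
    """A synthetic stand-in schedule (values are NOT sourced estimates).

    The published analysis drew state and event costs from the literature
    without printing them; this schedule only exists so the pipeline can run
    end-to-end, and is flagged ``placeholder`` so reports carry a warning.
    """
    return CostSchedule(
        state_costs={
            "healthy": 6000.0,
            "stroke": 18000.0,
            "mi": 15000.0,
            "chf": 20000.0,
            "death": 0.0,
            "post_stroke": 12000.0,
        },
        event_costs={
            ("healthy", "stroke"): 20000.0,
            ("healthy", "mi"): 25000.0,
            ("healthy", "chf"): 15000.0,
            ("stroke", "mi"): 25000.0,
            ("stroke", "chf"): 15000.0,
            ("mi", "chf"): 15000.0,
            ("stroke", "post_stroke"): 0.0,
            ("healthy", "post_stroke"): 0.0,
            ("mi", "post_stroke"): 0.0,
            ("chf", "post_stroke"): 0.0,
        },
        death_cost=30000.0,
        program_cost_per_participant_year=program_cost,
        placeholder=True,
    )


def expected_costs(
    trace: CohortTrace,
    schedule: CostSchedule,
    settings: SimulationSettings | None = None,
) -> tuple[float, float]:
    """Discounted and undiscounted total cost per starting participant.

    Per cycle: occupancy x state maintenance + transition flows x event
    costs (+ death cost on flows into death) + alive mass x program cost,
    using the engine's reward-timing and discount conventions.

    Raises if a transition with nonzero flow has no price in the schedule.
    """
    settings = settings or trace.settings
    if schedule.placeholder:
        logger.warning(
            "cost schedule is a synthetic placeholder; totals are illustrative only"
        )
    states = trace.states
    n = len(states)
    state_cost = np.array([schedule.state_costs.get(s, 0.0) for s in states])
    for s in states:
        if s not in schedule.state_costs:
            raise EconomicsError(f"schedule missing maintenance cost for state {s!r}")
    edge_cost = np.zeros((n, n))
    for i, frm in enumerate(states):
        for j, to in enumerate(states):
            if i == j or frm == "death":
                continue
            if to == "death":
                edge_cost[i, j] = schedule.death_cost
            elif (frm, to) in schedule.event_costs:
                edge_cost[i, j] = schedule.event_costs[(frm, to)]
            elif trace.flows[:, i, j].any():
                raise EconomicsError(
                    f"schedule missing event cost for edge ({frm!r}, {to!r}) "
                    "with nonzero flow"
                )
    alive = np.array([0.0 if s == "death" else 1.0 for s in states])
    horizon = settings.horizon
    cl = settings.cycle_length

    def _totals(rate: float) -> float:
        s = SimulationSettings(
            horizon=horizon,
            cycle_length=cl,
            discount_rate=rate,
            reward_timing=settings.reward_timing,
            start_state=settings.start_state,
        )
        weighted, _ = _reward_weights(trace.occupancy, s)
        # event flows are discounted with the exponent the timing rule implies
        t = np.arange(horizon) * cl
        if settings.reward_timing == "cycle-end":
            t = t + cl
        elif settings.reward_timing == "half-cycle":
            t = t + 0.5 * cl
        df = (1.0 + rate) ** (-t)
        maintenance = float((weighted @ state_cost).sum()) * cl
        events = float((trace.flows * edge_cost[None, :, :]).sum(axis=(1, 2)) @ df)
        p = schedule.program_cost_per_participant_year
        if schedule.program_accrual == "one_time":
            program = p
        elif schedule.program_accrual == "fixed_horizon":
            program = p * cl * float(df.sum())
        else:  # per participant-year alive
            program = float((weighted @ alive).sum()) * cl * p
        return maintenance + events + program

    return _totals(settings.discount_rate), _totals(0.0)


# ---------------------------------------------------------------------------
# ICERs and scenario comparison


@dataclass(frozen=True)
class ICERResult:
    """An incremental cost-effectiveness ratio or its dominance flag.

    ``flag`` is ``ok`` (ratio defined), ``cost_saving`` (intervention is at
    least as effective and cheaper: no ratio, favourable), or
    ``dominated_or_undefined`` (no effect gain but positive extra cost).
    """

    incremental_cost: float
    delta_effect: float
    value: float | None
    flag: str

    @property
    def rounded(self) -> float | None:
        return None if self.value is None else round_half_up(self.value)


def icer(incremental_cost: float, delta_effect: float) -> ICERResult:
    """Incremental cost per unit of effect gained, with degenerate flags."""
    if delta_effect > 0:
        value = incremental_cost / delta_effect
        flag = "cost_saving" if incremental_cost < 0 else "ok"
        return ICERResult(incremental_cost, delta_effect, value, flag)
    if incremental_cost > 0:
        return ICERResult(incremental_cost, delta_effect, None, "dominated_or_undefined")
    return ICERResult(incremental_cost, delta_effect, None, "cost_saving")


@dataclass(frozen=True)
class ScenarioRun:
    """One scenario's completed trace with its cost totals."""

    label: str
    trace: CohortTrace
    discounted_cost: float
    undiscounted_cost: float

    @property
    def discounted_qalys(self) -> float:
        return self.trace.discounted_qalys

    @property
    def discounted_life_years(self) -> float:
        return self.trace.discounted_life_years


@dataclass(frozen=True)
class CEResult:
    """Paired intervention/counterfactual outcomes and ICERs."""

    stratum: str
    intervention: ScenarioRun
    counterfactual: ScenarioRun
    incremental_cost: float
    delta_qaly: float
    delta_ly: float
    cost_per_qaly: ICERResult
    cost_per_ly: ICERResult


def compare_scenarios(
    intervention: ScenarioRun, counterfactual: ScenarioRun, stratum: str = ""
) -> CEResult:
    """Assemble incremental outcomes and ICERs for a scenario pair."""
    si, sc = intervention.trace.settings, counterfactual.trace.settings
    if si != sc:
        raise EconomicsError(
            "intervention and counterfactual runs use different settings"
        )
    if intervention.trace.states != counterfactual.trace.states:
        raise EconomicsError("scenario runs use different state sets")
    inc_cost = intervention.discounted_cost - counterfactual.discounted_cost
    d_qaly = intervention.discounted_qalys - counterfactual.discounted_qalys
    d_ly = intervention.discounted_life_years - counterfactual.discounted_life_years
    return CEResult(
        stratum=stratum,
        intervention=intervention,
        counterfactual=counterfactual,
        incremental_cost=inc_cost,
        delta_qaly=d_qaly,
        delta_ly=d_ly,
        cost_per_qaly=icer(inc_cost, d_qaly),
        cost_per_ly=icer(inc_cost, d_ly),
    )


def ltc_breakeven(
    incremental_cost: float, ltc_monthly_cost: float, ltc_duration_months: float
) -> float:
    """Long-term-care utilization reduction at which avoided cost breaks even.

    Returns the proportion (percentage-point reduction / 100) of participants
    whose avoided LTC stay of ``ltc_duration_months`` at ``ltc_monthly_cost``
    per month offsets the intervention's incremental cost.
    """
    if ltc_monthly_cost <= 0 or ltc_duration_months <= 0:
        raise EconomicsError("LTC monthly cost and duration must be positive")
    return incremental_cost / (ltc_monthly_cost * ltc_duration_months)
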