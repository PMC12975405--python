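"""Configuration-driven orchestration and report tables.

One YAML config describes an end-to-end run: generate (or load) a cohort,
summarize it into sex x diabetes stratum profiles, build intervention and
counterfactual transition matrices per stratum, run the cohort engine, attach
costs and assemble incremental cost-effectiveness results, then emit the
input / matrix / cost / results tables.

Runs are deterministic: the same config and seed reproduce byte-identical
outputs, and every emitted file carries the config hash and seed in a
run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import cohort as cohort_mod
from . import economics as econ
from . import engine as engine_mod
from . import risk as risk_mod

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """The run configuration failed validation."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; message names the stage and stratum."""


DEFAULT_CONFIG: dict = {
    "schema_version": SCHEMA_VERSION,
    "seed": 0,
    "cohort": {
        "mode": "generate",  # generate | load
        "path": None,
        "n_per_stratum": None,
        "dispersions": {"age_sd": 8.0, "sbp_sd": 15.0, "chol_sd": 35.0},
        "counterfactual_sbp_delta": cohort_mod.COUNTERFACTUAL_SBP_DELTA,
    },
    "coefficients": None,  # path to a coefficient file; null = packaged default
    "downstream_rows": None,  # null = published post-event rows
    "validation_policy": "renormalize",
    "settings": {
        "horizon": 20,
        "cycle_length": 1.0,
        "discount_rate": 0.03,
        "reward_timing": "cycle-start",
    },
    "utilities": {
        "healthy": 0.85,
        "stroke": 0.65,
        "mi": 0.70,
        "chf": 0.60,
        "death": 0.0,
    },
    "costs": {
        "program": "default",  # 'default' | mapping of line items
        "schedule": "placeholder",  # 'placeholder' | mapping
        "allow_placeholder": False,
        "program_accrual": "per_year_alive",
    },
}


def _merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None, overrides: Mapping | None = None) -> dict:
    """Load a YAML run config, filling unset keys with documented defaults."""
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    validate_config(cfg)
    return cfg


def validate_config(cfg: Mapping) -> None:
    if cfg.get("schema_version") != SCHEMA_VERSION:
        raise ConfigError(
            f"unsupported schema_version {cfg.get('schema_version')!r}; "
            f"expected {SCHEMA_VERSION}"
        )
    mode = cfg["cohort"].get("mode")
    if mode not in ("generate", "load"):
        raise ConfigError(f"cohort.mode must be generate|load, got {mode!r}")
    if mode == "load":
        p = cfg["cohort"].get("path")
        if not p or not Path(p).exists():
            raise ConfigError(f"cohort.path {p!r} not resolvable")
    coeff = cfg.get("coefficients")
    if coeff is not None and not Path(coeff).exists():
        raise ConfigError(f"coefficients path {coeff!r} not resolvable")
    if cfg["validation_policy"] not in risk_mod.VALIDATION_POLICIES:
        raise ConfigError(
            f"validation_policy must be one of {risk_mod.VALIDATION_POLICIES}"
        )


def config_hash(cfg: Mapping) -> str:
    """Stable hash of the canonicalized config."""
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class ResultBundle:
    """Everything one pipeline run produced."""

    config: dict
    config_hash: str
    seed: int
    cohort: object  # pandas.DataFrame of assessment records
    profiles: list
    matrices: dict  # (stratum_label, scenario) -> TransitionMatrix
    traces: dict  # (stratum_label, scenario) -> CohortTrace
    results: dict  # stratum_label -> CEResult
    warnings: list[str] = field(default_factory=list)
    timings: dict = field(default_factory=dict)


class _WarningCollector(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record):
        self.messages.append(self.format(record))


def run_pipeline(config: Mapping, seed: int | None = None) -> ResultBundle:
    """Execute the full cohort -> risk -> engine -> economics pipeline.

    ``seed`` overrides the config's master seed.  Each of the four strata is
    run under both scenarios; failures are re-raised naming the stage and
    stratum.
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    validate_config(cfg)
    if seed is not None:
        cfg["seed"] = int(seed)
    collector = _WarningCollector()
    logging.getLogger("cvdcea").addHandler(collector)
    timings: dict[str, float] = {}
    try:
        # --- cohort stage
        t0 = time.perf_counter()
        try:
            ccfg = cfg["cohort"]
            if ccfg["mode"] == "load":
                records = cohort_mod.read_cohort(ccfg["path"])
            else:
                params = cohort_mod.default_gen_params(
                    seed=cfg["seed"], **{k: float(v) for k, v in ccfg["dispersions"].items()}
                )
                records = cohort_mod.generate_cohort(params, ccfg["n_per_stratum"])
            profiles = cohort_mod.summarize_cohort(
                records, counterfactual_sbp_delta=float(ccfg["counterfactual_sbp_delta"])
            )
            # canonical reporting order: male before female, non-diabetic first
            profiles.sort(key=lambda p: (p.sex != "male", p.diabetes))
        except Exception as exc:
            raise PipelineError(f"stage=cohort: {exc}") from exc
        timings["cohort"] = time.perf_counter() - t0

        # --- cost configuration
        t0 = time.perf_counter()
        try:
            costs = cfg["costs"]
            if costs["program"] == "default":
                program_inputs = econ.default_program_cost_inputs()
            else:
                program_inputs = econ.ProgramCostInputs(**costs["program"])
            per_participant, breakdown = econ.program_cost_per_participant(program_inputs)
            if costs["schedule"] == "placeholder":
                if not costs.get("allow_placeholder"):
                    raise ConfigError(
                        "cost schedule is a placeholder; set "
                        "costs.allow_placeholder: true to run with synthetic values"
                    )
                schedule = econ.placeholder_schedule(program_cost=per_participant)
            else:
                sched_cfg = dict(costs["schedule"])
                sched_cfg.setdefault(
                    "program_cost_per_participant_year", per_participant
                )
                if "event_costs" in sched_cfg:
                    sched_cfg["event_costs"] = {
                        tuple(k.split("->")): v
                        for k, v in sched_cfg["event_costs"].items()
                    }
                schedule = econ.CostSchedule(
                    program_accrual=costs["program_accrual"], **sched_cfg
                )
        except Exception as exc:
            raise PipelineError(f"stage=costs: {exc}") from exc
        timings["costs"] = time.perf_counter() - t0

        # --- risk + engine + economics per stratum x scenario
        coeffs = (
            risk_mod.read_coefficient_file(cfg["coefficients"])
            if cfg["coefficients"]
            else risk_mod.default_coefficients()
        )
        settings = engine_mod.SimulationSettings(**cfg["settings"])
        utilities = engine_mod.UtilityWeights(dict(cfg["utilities"]))
        downstream = cfg["downstream_rows"] or risk_mod.DEFAULT_DOWNSTREAM_ROWS
        matrices, traces, results = {}, {}, {}
        t0 = time.perf_counter()
        for profile in profiles:
            runs = {}
            for scenario in (risk_mod.INTERVENTION, risk_mod.COUNTERFACTUAL):
                try:
                    matrix = risk_mod.build_transition_matrix(
                        profile,
                        scenario,
                        coefficients=coeffs,
                        downstream_rows=downstream,
                        policy=cfg["validation_policy"],
                    )
                    trace = engine_mod.run_cohort(matrix, settings, utilities)
                    disc, undisc = econ.expected_costs(trace, schedule, settings)
                except Exception as exc:
                    raise PipelineError(
                        f"stage=model stratum={profile.label} "
                        f"scenario={scenario.name}: {exc}"
                    ) from exc
                matrices[(profile.label, scenario.name)] = matrix
                traces[(profile.label, scenario.name)] = trace
                runs[scenario.name] = econ.ScenarioRun(
                    label=scenario.name,
                    trace=trace,
                    discounted_cost=disc,
                    undiscounted_cost=undisc,
                )
            results[profile.label] = econ.compare_scenarios(
                runs["intervention"], runs["counterfactual"], stratum=profile.label
            )
        timings["model"] = time.perf_counter() - t0
    finally:
        logging.getLogger("cvdcea").removeHandler(collector)
    return ResultBundle(
        config=cfg,
        config_hash=config_hash(cfg),
        seed=int(cfg["seed"]),
        cohort=records,
        profiles=profiles,
        matrices=matrices,
        traces=traces,
        results=results,
        warnings=collector.messages,
        timings=timings,
    )


# ---------------------------------------------------------------------------
# report tables

REPORT_NAMES = ("inputs", "matrix", "costs", "results")

_INPUT_ROWS = [
    ("Age at entry (years)", "mean_entry_age", "{:.1f}"),
    ("Starting cholesterol (mg/dL)", "mean_chol_baseline", "{:.0f}"),
    ("Most recent cholesterol (mg/dL)", "mean_chol_exit", "{:.0f}"),
    ("Starting SBP (mmHg)", "mean_sbp_baseline", "{:.0f}"),
    ("Estimated SBP (mmHg)", "mean_sbp_counterfactual", "{:.0f}"),
    ("Using hypertension medication at baseline (%)", "prop_htn_med_baseline", "{:.0%}"),
    ("Using hypertension medication at exit (%)", "prop_htn_med_exit", "{:.0%}"),
    ("Smokers at baseline (%)", "prop_smoker_baseline", "{:.0%}"),
    ("Smokers at exit (%)", "prop_smoker_exit", "{:.0%}"),
    ("Sample size", "n", "{:d}"),
]

_STRATUM_DISPLAY = {
    "male_no_diabetes": "Base male",
    "male_diabetes": "Male diabetes",
    "female_no_diabetes": "Base female",
    "female_diabetes": "Female diabetes",
}


def _fmt_dollar(x: float) -> str:
    return f"${econ.round_half_up(x):,.0f}"


def report_tables(bundle: ResultBundle, which: str) -> str:
    """Render one of the standard tables as tab-separated text.

    ``which`` selects ``inputs`` (stratum risk-factor profiles), ``matrix``
    (one transition matrix per stratum/scenario), ``costs`` (the program-cost
    build-up), or ``results`` (QALY/life-year/cost/ICER summary, one column
    per stratum).  Warnings raised during the run are appended as a footer.
    """
    if which not in REPORT_NAMES:
        raise ConfigError(f"unknown table {which!r}; valid options: {REPORT_NAMES}")
    lines: list[str] = []
    order = [p.label for p in bundle.profiles]
    headers = [_STRATUM_DISPLAY.get(lbl, lbl) for lbl in order]
    if which == "inputs":
        lines.append("\t".join(["Risk factors"] + headers))
        for label, attr, fmt in _INPUT_ROWS:
            row = [label] + [
                fmt.format(getattr(p, attr)) for p in bundle.profiles
            ]
            lines.append("\t".join(row))
    elif which == "matrix":
        for (stratum, scenario), matrix in bundle.matrices.items():
            lines.append(f"# stratum={stratum} scenario={scenario} policy={matrix.policy}")
            pretty = {"healthy": "Healthy", "stroke": "Stroke", "mi": "MI",
                      "chf": "CHF", "death": "Death", "post_stroke": "Post-stroke"}
            names = [pretty.get(s, s) for s in matrix.states]
            lines.append("\t".join(["From (to)"] + names))
            for s, row in zip(names, matrix.probs):
                lines.append("\t".join([s] + [f"{p:.4f}" for p in row]))
            lines.append("")
    elif which == "costs":
        program = bundle.config["costs"]["program"]
        inputs = (
            econ.default_program_cost_inputs()
            if program == "default"
            else econ.ProgramCostInputs(**program)
        )
        _, b = econ.program_cost_per_participant(inputs)
        lines.append("Item\tAverage panel costs")
        for name, value in inputs.personnel.items():
            lines.append(f"{name}\t{_fmt_dollar(value)}")
        lines.append(f"Fringe ({inputs.fringe_rate:.0%})\t${b.fringe:,.2f}")
        lines.append(f"Total personnel cost\t{_fmt_dollar(b.total_personnel)}")
        for name, value in inputs.operating.items():
            lines.append(f"{name}\t{_fmt_dollar(value)}")
        lines.append(f"Total operating cost\t{_fmt_dollar(b.total_operating)}")
        lines.append(f"Total direct charges\t{_fmt_dollar(b.total_direct)}")
        lines.append(f"Total indirect charges\t${b.indirect:,.2f}")
        lines.append(f"Total costs\t{_fmt_dollar(b.total)}")
        lines.append(
            f"Average cost per participant ({b.panel_size} participants per panel)"
            f"\t{_fmt_dollar(b.per_participant)}"
        )
    else:  # results
        if not bundle.results:
            raise ConfigError("bundle holds no results")
        lines.append("\t".join([""] + headers))
        rows = [
            ("Discounted QALY with intervention",
             lambda r: f"{r.intervention.discounted_qalys:.1f}"),
            ("Discounted QALY without intervention",
             lambda r: f"{r.counterfactual.discounted_qalys:.1f}"),
            ("Discounted Life Years with intervention",
             lambda r: f"{r.intervention.discounted_life_years:.1f}"),
            ("Discounted Life Years without intervention",
             lambda r: f"{r.counterfactual.discounted_life_years:.1f}"),
            ("Cost with intervention",
             lambda r: _fmt_dollar(r.intervention.undiscounted_cost)),
            ("Total cost without intervention",
             lambda r: _fmt_dollar(r.counterfactual.undiscounted_cost)),
            ("Discounted cost with intervention",
             lambda r: _fmt_dollar(r.intervention.discounted_cost)),
            ("Discounted cost without intervention",
             lambda r: _fmt_dollar(r.counterfactual.discounted_cost)),
            ("Gain in discounted QALYs", lambda r: f"{r.delta_qaly:.1f}"),
            ("Gain in discounted Life Years", lambda r: f"{r.delta_ly:.1f}"),
            ("Incremental cost", lambda r: _fmt_dollar(r.incremental_cost)),
            ("Cost per QALY gained",
             lambda r: _fmt_dollar(r.cost_per_qaly.value)
             if r.cost_per_qaly.value is not None else r.cost_per_qaly.flag),
            ("Cost per Life Year gained",
             lambda r: _fmt_dollar(r.cost_per_ly.value)
             if r.cost_per_ly.value is not None else r.cost_per_ly.flag),
        ]
        for label, fn in rows:
            lines.append(
                "\t".join([label] + [fn(bundle.results[lbl]) for lbl in order])
            )
    if bundle.warnings:
        lines.append("")
        for msg in dict.fromkeys(bundle.warnings):  # de-duplicated, ordered
            lines.append(f"# warning: {msg}")
    return "\n".join(lines) + "\n"


def write_manifest(bundle: ResultBundle, path) -> None:
    """Write the run manifest (config hash, seed, version, stage timings)."""
    from . import __version__

    manifest = {
        "config_hash": bundle.config_hash,
        "seed": bundle.seed,
        "package_version": __version__,
        "timings_seconds": {k: round(v, 4) for k, v in bundle.timings.items()},
        "warnings": list(dict.fromkeys(bundle.warnings)),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
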