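"""Configuration, table serialization and the analysis pipeline.

All tabular inputs and outputs are plain CSV (UTF-8, comma separator,
``.`` decimal, no thousands separators); run configuration is YAML (JSON
accepted, being a YAML subset). Machine-readable results are JSON with a
metadata block (package version, seed, timestamp, input checksums);
human-readable summaries are aligned-text tables. In reports, currency is
rounded to 2 decimals, QALYs to 4 and ICERs to 2.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import BaseCaseResult, ModelBundle, run_base_case
from .bia import bia_report
from .econ_eval import StateValues, frontier_frame
from .errors import SchemaError
from .fixtures import (
    FixtureBundle,
    SynthSpec,
    default_bundle,
    generate_parameter_set,
    load_reference_fixture,
)
from .model_core import (
    AuxiliaryClinicalParams,
    CohortTrace,
    EventRateTable,
    LifeTable,
    ModelConfig,
)
from .sensitivity import (
    ce_probability,
    ceac,
    default_psa_distributions,
    run_psa,
    tornado,
    tornado_frame,
)
from .states import EVENTS, STRATEGIES

log = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "load_run_config",
    "run_pipeline",
    "write_trace_csv",
    "read_trace_csv",
    "write_fixture_dir",
    "load_bundle_dir",
]


# ---------------------------------------------------------------------------
# table round-trips
# ---------------------------------------------------------------------------

def write_trace_csv(trace: CohortTrace, path: str | Path) -> None:
    trace.to_frame().to_csv(path, index=False)


def read_trace_csv(path: str | Path) -> CohortTrace:
    frame = pd.read_csv(path)
    if "cycle" not in frame.columns or "time_years" not in frame.columns:
        raise SchemaError("trace CSV needs 'cycle' and 'time_years' columns")
    states = [c for c in frame.columns if c not in ("cycle", "time_years")]
    times = frame["time_years"].to_numpy()
    cl = float(times[1] - times[0]) if len(times) > 1 else 1.0 / 12.0
    return CohortTrace(states, frame[states].to_numpy(dtype=float), cl)


def _aux_to_frame(aux: AuxiliaryClinicalParams) -> pd.DataFrame:
    rows = []
    for e in EVENTS:
        rows.append({"param": "fatality", "event": e, "value": aux.case_fatality[e]})
        d = aux.destinations[e]
        for name, v in zip(("dest_af", "dest_af_no_ac", "dest_post_event"), d):
            rows.append({"param": name, "event": e, "value": v})
        rows.append({"param": "untreated_rate", "event": e, "value": aux.untreated_rates[e]})
    rows.append({"param": "disc_rate", "event": "", "value": aux.discontinuation_rate_per_100py})
    rows.append({"param": "post_event_mortality_multiplier", "event": "",
                 "value": aux.post_event_mortality_multiplier})
    return pd.DataFrame(rows)


def _aux_from_frame(frame: pd.DataFrame, life_table: LifeTable) -> AuxiliaryClinicalParams:
    frame = frame.fillna({"event": ""})
    def lookup(param: str, event: str = "") -> float:
        sel = frame[(frame["param"] == param) & (frame["event"] == event)]
        if len(sel) != 1:
            raise SchemaError(f"aux table: expected one row for ({param}, {event!r})")
        return float(sel["value"].iloc[0])

    return AuxiliaryClinicalParams(
        case_fatality={e: lookup("fatality", e) for e in EVENTS},
        destinations={
            e: (lookup("dest_af", e), lookup("dest_af_no_ac", e), lookup("dest_post_event", e))
            for e in EVENTS
        },
        discontinuation_rate_per_100py=lookup("disc_rate"),
        untreated_rates={e: lookup("untreated_rate", e) for e in EVENTS},
        life_table=life_table,
        post_event_mortality_multiplier=lookup("post_event_mortality_multiplier"),
    )


def write_fixture_dir(fixture: FixtureBundle, out_dir: str | Path) -> list[Path]:
    """Serialize a fixture bundle to a directory of CSV/YAML files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(frame: pd.DataFrame, name: str) -> None:
        p = out / name
        frame.to_csv(p, index=False)
        written.append(p)

    bundle = fixture.model
    emit(bundle.rates.to_frame(), "event_rates.csv")
    for strategy, sv in bundle.values.items():
        emit(sv.to_frame(), f"state_values_{strategy}.csv")
    emit(_aux_to_frame(bundle.aux), "aux_clinical.csv")
    emit(bundle.aux.life_table.to_frame(), "life_table.csv")

    cfg_path = out / "model_config.yaml"
    cfg_path.write_text(yaml.safe_dump(dataclasses.asdict(bundle.config)))
    written.append(cfg_path)

    bia = fixture.bia
    emit(
        pd.DataFrame(
            {
                "year": bia.projection.years,
                "national_population": [bia.projection.national[y] for y in bia.projection.years],
                "eligible_patients": [bia.projection.eligible[y] for y in bia.projection.years],
            }
        ),
        "bia_population.csv",
    )
    for sid, scenario in bia.scenarios.items():
        rows = [{"year": y, **scenario.shares[y]} for y in scenario.years]
        emit(pd.DataFrame(rows), f"bia_shares_{sid}.csv")
    emit(
        pd.DataFrame(
            [{"treatment": t, "annual_cost": c} for t, c in bia.treatment_costs.costs.items()]
        ),
        "bia_costs.csv",
    )
    prov_path = out / "provenance.yaml"
    prov_path.write_text(yaml.safe_dump(fixture.provenance))
    written.append(prov_path)
    return written


def load_bundle_dir(in_dir: str | Path) -> ModelBundle:
    """Load a model bundle from a directory written by :func:`write_fixture_dir`."""
    d = Path(in_dir)
    rates = EventRateTable.from_frame(pd.read_csv(d / "event_rates.csv"))
    life = LifeTable.from_frame(pd.read_csv(d / "life_table.csv"))
    aux = _aux_from_frame(pd.read_csv(d / "aux_clinical.csv", keep_default_na=False), life)
    config = ModelConfig(**yaml.safe_load((d / "model_config.yaml").read_text()))
    values = {}
    for p in sorted(d.glob("state_values_*.csv")):
        strategy = p.stem.removeprefix("state_values_")
        values[strategy] = StateValues.from_frame(pd.read_csv(p))
    if not values:
        raise SchemaError(f"no state_values_<strategy>.csv files in {d}")
    return ModelBundle(rates=rates, values=values, aux=aux, config=config)


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Pipeline settings: input location, analysis selection, outputs."""

    analysis: str = "base"            # base | dsa | psa | bia
    input_dir: str | None = None      # None = packaged fixture
    out_dir: str = "afecon_out"
    seed: int = 0
    threshold: float | None = None    # None = ModelConfig default
    n_iter: int = 5000                # PSA iterations
    dsa_comparison: tuple[str, str] = ("apixaban", "vka")
    dsa_top: int = 10
    log_level: str = "INFO"
    config_overrides: dict[str, Any] = field(default_factory=dict)


def load_run_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"unknown run-config keys: {sorted(unknown)}")
    if "dsa_comparison" in raw:
        raw["dsa_comparison"] = tuple(raw["dsa_comparison"])
    return RunConfig(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _metadata(config: RunConfig, input_files: Sequence[Path]) -> dict:
    return {
        "package": "afecon",
        "version": __version__,
        "seed": config.seed,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "analysis": config.analysis,
        "input_checksums": {p.name: _sha256(p) for p in input_files},
    }


def _round_floats(obj, ndigits=6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the selected analysis and write machine + human readable outputs.

    Returns a mapping of artifact name to written path. Raises (non-zero
    exit through the CLI) on any module error.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    input_files: list[Path] = []
    if config.input_dir is not None:
        input_files = sorted(Path(config.input_dir).glob("*.csv"))
        bundle = load_bundle_dir(config.input_dir)
    else:
        bundle = default_bundle()
    if config.config_overrides or config.threshold is not None or config.seed:
        over = dict(config.config_overrides)
        if config.threshold is not None:
            over["threshold"] = config.threshold
        over.setdefault("seed", config.seed)
        bundle = ModelBundle(bundle.rates, bundle.values, bundle.aux,
                             bundle.config.replace(**over))

    meta = _metadata(config, input_files)
    artifacts: dict[str, Path] = {}

    def write_json(name: str, payload: dict) -> None:
        p = out / name
        p.write_text(json.dumps({"metadata": meta, **_round_floats(payload)}, indent=2))
        artifacts[name] = p

    def write_csv(name: str, frame: pd.DataFrame, index: bool = False) -> None:
        p = out / name
        frame.to_csv(p, index=index)
        artifacts[name] = p

    threshold = config.threshold if config.threshold is not None else bundle.config.threshold

    if config.analysis == "base":
        result = run_base_case(bundle)
        ff = frontier_frame(result.frontier)
        write_csv("base_case.csv", ff)
        write_json(
            "base_case.json",
            {
                "threshold": threshold,
                "outcomes": {
                    s: {"total_cost": o.total_cost, "total_qaly": o.total_qaly}
                    for s, o in result.outcomes.items()
                },
                "frontier": ff.to_dict(orient="records"),
            },
        )
        (out / "base_case.txt").write_text(ff.to_string(index=False) + "\n")
        artifacts["base_case.txt"] = out / "base_case.txt"
    elif config.analysis == "dsa":
        entries = tornado(bundle, config.dsa_comparison, top=config.dsa_top)
        tf = tornado_frame(entries)
        write_csv("tornado.csv", tf)
        write_json("tornado.json", {"comparison": list(config.dsa_comparison),
                                    "entries": tf.to_dict(orient="records")})
    elif config.analysis == "psa":
        psa = run_psa(bundle, default_psa_distributions(bundle),
                      n_iter=config.n_iter, seed=config.seed)
        pairs = [(a, b) for i, a in enumerate(psa.strategies)
                 for b in psa.strategies[i + 1:]]
        scatter = pd.concat([psa.scatter_frame(p) for p in pairs], ignore_index=True)
        write_csv("psa_scatter.csv", scatter)
        grid = np.linspace(0, 3 * threshold, 61)
        curve = ceac(psa, grid)
        write_csv("ceac.csv", curve.to_frame())
        write_json(
            "psa_summary.json",
            {
                "n_iter": psa.n_iter,
                "threshold": threshold,
                "ce_probability": {
                    f"{a}_vs_{b}": ce_probability(psa, (a, b), threshold) for a, b in pairs
                },
            },
        )
    elif config.analysis == "bia":
        fixture = load_reference_fixture()
        bia = fixture.bia
        report = bia_report(
            bia.projection, bia.scenarios, bia.treatment_costs,
            impact_pairs=[("scenario2", "scenario1"), ("scenario2", "scenario3")],
        )
        write_csv("bia_report.csv", report, index=True)
        published = pd.DataFrame(bia.published_budgets)
        write_csv("bia_published.csv", published, index=True)
        write_json(
            "bia_summary.json",
            {
                "impact_with_vs_without_apixaban": {
                    str(y): bia.published_budgets["scenario2"][y] - bia.published_budgets["scenario1"][y]
                    for y in bia.projection.years
                },
                "impact_with_vs_without_rivaroxaban": {
                    str(y): bia.published_budgets["scenario2"][y] - bia.published_budgets["scenario3"][y]
                    for y in bia.projection.years
                },
            },
        )
    else:
        raise SchemaError(f"unknown analysis {config.analysis!r}")
    return artifacts
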