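"""File formats, fixtures, report rendering and the analysis pipeline.

Formats
-------
* Cost tables: comma-separated text with header ``code,descriptor,
  unit_cost_gbp``, one row per NHS reference-cost code.  Currency symbols
  and thousands separators are stripped on read ("£7,202.79" -> 7202.79)
  and en-dashes in code ranges are normalised to hyphens.  Codes must be
  unique within a table; where a published table reuses one code for two
  tariffs the fixture qualifies the token (e.g. ``LB09D:NEL``).
* Model configs: YAML documents (``schema: 1``) with ``parameters``,
  ``strategies`` (nested node records; YAML anchors/aliases may be used to
  share subtree *text*, each alias is expanded into an independent
  subtree), ``effects`` (scalar per-strategy effect expressions) and
  ``calibration_targets``.
* Cohorts: comma-separated text, one row per patient, booleans as 0/1.

The packaged fixtures under ``stonecea/data`` carry the published unit
costs, the reconstructed two-strategy tree, and the published cohort
comparison summaries.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Union

import pandas as pd
import yaml

from . import cea as _cea
from .calibrate import calibrate_free_parameters
from .parameters import Parameter, ParameterSet
from .simulate import COHORT_COLUMNS, OUTCOMES, estimate_parameters
from .stats import ProportionComparison, SummaryComparison
from .tree import Branch, EvaluationResult, StrategyTree, TreeNode, rollback, validate_tree

__all__ = [
    "CostItem",
    "CostTable",
    "ModelConfig",
    "RunConfig",
    "read_cost_table",
    "write_cost_table",
    "load_model",
    "read_cohort",
    "write_cohort",
    "read_comparisons",
    "packaged_path",
    "load_reference_model",
    "run_pipeline",
    "render_reports",
]

log = logging.getLogger("stonecea")

COST_HEADER = ["code", "descriptor", "unit_cost_gbp"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class CostItem:
    code: str
    descriptor: str
    unit_cost_gbp: float


@dataclass
class CostTable:
    name: str
    items: Dict[str, CostItem] = field(default_factory=dict)

    def __getitem__(self, code: str) -> CostItem:
        try:
            return self.items[code]
        except KeyError:
            raise KeyError(f"code {code!r} not in cost table {self.name!r}") from None

    def __contains__(self, code: str) -> bool:
        return code in self.items

    def __len__(self) -> int:
        return len(self.items)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(i.code, i.descriptor, i.unit_cost_gbp) for i in self.items.values()],
            columns=COST_HEADER,
        )


def _normalise_code(code: str) -> str:
    return code.strip().replace("–", "-").replace("—", "-")


def _parse_money(text: str) -> float:
    cleaned = str(text).replace("£", "").replace("€", "").replace(",", "").strip()
    return float(cleaned)


def read_cost_table(path, name: Optional[str] = None) -> CostTable:
    """Read one NHS reference-cost table; validates header and uniqueness."""
    path = Path(path)
    frame = pd.read_csv(path, dtype=str)
    if list(frame.columns) != COST_HEADER:
        raise ConfigError(
            f"{path}: expected header {','.join(COST_HEADER)!r}, got {','.join(frame.columns)!r}"
        )
    if name is None:
        name = path.stem
        if name.startswith("costs_"):
            name = name[len("costs_"):]
    table = CostTable(name=name)
    duplicates = []
    for _, row in frame.iterrows():
        code = _normalise_code(row["code"])
        cost = _parse_money(row["unit_cost_gbp"])
        if cost < 0:
            raise ConfigError(f"{path}: negative unit cost {cost} for code {code!r}")
        if code in table.items:
            duplicates.append(code)
            continue
        table.items[code] = CostItem(code, str(row["descriptor"]).strip(), cost)
    if duplicates:
        raise ConfigError(f"{path}: duplicate code(s) {sorted(set(duplicates))}")
    return table


def write_cost_table(table: CostTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def _warn_cross_table_conflicts(tables: Mapping[str, CostTable]) -> None:
    seen: Dict[str, tuple] = {}
    for tname, table in tables.items():
        for code, item in table.items.items():
            if code in seen and abs(seen[code][1] - item.unit_cost_gbp) > 0.005:
                log.warning(
                    "code %s priced differently across tables: %s=%.2f vs %s=%.2f "
                    "(the table named on each parameter wins)",
                    code, seen[code][0], seen[code][1], tname, item.unit_cost_gbp,
                )
            else:
                seen[code] = (tname, item.unit_cost_gbp)


# ---------------------------------------------------------------------------
# model configuration
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    parameters: ParameterSet
    trees: Dict[str, StrategyTree]
    calibration_targets: Dict[str, float]
    description: str = ""


def _build_node(record, stack: List[int], path: str) -> TreeNode:
    if not isinstance(record, dict):
        raise ConfigError(f"{path}: node record must be a mapping, got {type(record).__name__}")
    if id(record) in stack:
        raise ConfigError(f"{path}: node is its own ancestor (YAML alias cycle)")
    stack.append(id(record))
    try:
        kind = record.get("kind")
        if kind not in ("decision", "chance", "terminal"):
            raise ConfigError(f"{path}: missing or invalid node kind {kind!r}")
        label = str(record.get("label", path))
        branches = []
        for i, br in enumerate(record.get("branches") or []):
            if not isinstance(br, dict) or "child" not in br:
                raise ConfigError(f"{path}.branches[{i}]: branch needs a 'child' record")
            prob = br.get("probability")
            child = _build_node(br["child"], stack, f"{path}.branches[{i}]")
            branches.append(Branch(
                probability=None if prob is None else _as_expr(prob, f"{path}.branches[{i}].probability"),
                child=child,
            ))
        return TreeNode(
            kind=kind,
            label=label,
            payload_cost=_as_expr(record.get("cost", 0.0), f"{path}.cost"),
            payload_effect=_as_expr(record.get("effect", 0.0), f"{path}.effect"),
            branches=branches,
        )
    finally:
        stack.pop()


def _as_expr(value, path: str):
    from .expressions import ExpressionError, as_expr
    try:
        return as_expr(value)
    except ExpressionError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def load_model(path, cost_tables: Optional[Mapping[str, CostTable]] = None) -> ModelConfig:
    """Load a model config document, optionally resolving parameter values
    from named cost tables via their reference codes."""
    path = Path(path)
    with path.open() as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: document must be a mapping")
    if doc.get("schema") != 1:
        raise ConfigError(f"{path}: unsupported schema {doc.get('schema')!r} (expected 1)")
    if cost_tables:
        _warn_cross_table_conflicts(cost_tables)

    params = ParameterSet()
    for name, spec in (doc.get("parameters") or {}).items():
        if not isinstance(spec, dict):
            raise ConfigError(f"{path}: parameter {name!r} must be a mapping")
        value = spec.get("value")
        code = spec.get("code")
        table_name = spec.get("table")
        if code is not None and cost_tables:
            if table_name is None:
                candidates = list(cost_tables.values())
            else:
                candidates = [cost_tables[table_name]] if table_name in cost_tables else []
            found = [t[code] for t in candidates if code in t]
            if found:
                table_value = found[0].unit_cost_gbp
                if value is None:
                    value = table_value
                elif abs(float(value) - table_value) > 0.005:
                    log.warning("parameter %s: declared value %.2f differs from table value %.2f; "
                                "keeping the declared value", name, float(value), table_value)
            elif value is None:
                raise ConfigError(f"{path}: parameter {name!r} code {code!r} not found in any table")
        if value is None:
            raise ConfigError(f"{path}: parameter {name!r} has no value and no resolvable code")
        bounds = spec.get("bounds")
        params.add(Parameter(
            name=name,
            role=spec.get("role", "unit_cost"),
            value=float(value),
            free=bool(spec.get("free", False)),
            bounds=None if bounds is None else (float(bounds[0]), float(bounds[1])),
            code=code,
            table=table_name,
            description=str(spec.get("description", "")),
        ))

    effects = doc.get("effects") or {}
    trees: Dict[str, StrategyTree] = {}
    strategies = doc.get("strategies") or {}
    if not strategies:
        raise ConfigError(f"{path}: no strategies defined")
    for sname, record in strategies.items():
        root = _build_node(record, [], f"strategies.{sname}")
        if sname in effects:
            trees[sname] = StrategyTree(sname, root, "scalar_override",
                                        _as_expr(effects[sname], f"effects.{sname}"))
        else:
            trees[sname] = StrategyTree(sname, root, "tree_accumulated")

    targets = {str(k): float(v) for k, v in (doc.get("calibration_targets") or {}).items()}
    for sname in targets:
        if sname not in trees:
            raise ConfigError(f"{path}: calibration target for unknown strategy {sname!r}")
    return ModelConfig(params, trees, targets, description=str(doc.get("description", "")))


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

def packaged_path(filename: str):
    """Path to a packaged data fixture (context-free; files are real on disk)."""
    return resources.files("stonecea.data").joinpath(filename)


def load_reference_model() -> tuple:
    """The packaged reconstruction of the published two-strategy comparison.

    Returns ``(ModelConfig, {name: CostTable})`` with the EUL/DUL unit-cost
    tables attached.
    """
    tables = {
        "eul": read_cost_table(packaged_path("costs_eul.csv"), name="eul"),
        "dul": read_cost_table(packaged_path("costs_dul.csv"), name="dul"),
    }
    model = load_model(packaged_path("model_acute_stone.yaml"), tables)
    return model, tables


# ---------------------------------------------------------------------------
# cohorts and comparison tables
# ---------------------------------------------------------------------------

def write_cohort(cohort: pd.DataFrame, path) -> None:
    out = cohort.copy()
    for col in OUTCOMES:
        if col in out.columns:
            out[col] = out[col].astype(int)
    out.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ConfigError(f"{path}: cohort file lacks column(s) {missing}")
    for col in OUTCOMES:
        frame[col] = frame[col].astype(bool)
    return frame[COHORT_COLUMNS]


def read_comparisons(path) -> List[Union[ProportionComparison, SummaryComparison]]:
    """Read a cohort-comparison table; the header decides the row type."""
    frame = pd.read_csv(path)
    cols = set(frame.columns)
    rows: List[Union[ProportionComparison, SummaryComparison]] = []
    if {"x1", "n1", "x2", "n2"} <= cols:
        for _, r in frame.iterrows():
            rows.append(ProportionComparison(int(r["x1"]), int(r["n1"]),
                                             int(r["x2"]), int(r["n2"]), label=str(r["label"])))
    elif {"mean1", "sd1", "n1", "mean2", "sd2", "n2"} <= cols:
        for _, r in frame.iterrows():
            rows.append(SummaryComparison(float(r["mean1"]), float(r["sd1"]), int(r["n1"]),
                                          float(r["mean2"]), float(r["sd2"]), int(r["n2"]),
                                          label=str(r["label"])))
    else:
        raise ConfigError(f"{path}: unrecognised comparison header {sorted(cols)}")
    return rows


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    model_file: Union[str, Path]
    cost_table_files: Sequence[Union[str, Path]] = ()
    cohort_file: Optional[Union[str, Path]] = None
    sensitivity_fraction: float = 0.10
    vary: Union[str, Sequence[str]] = "all"
    currency_rate: Optional[float] = None
    seed: int = 0
    output_dir: Union[str, Path] = "."
    log_level: str = "INFO"
    calibrate: bool = True

    def validate(self) -> None:
        if not (0.0 < self.sensitivity_fraction <= 0.5):
            raise ConfigError(
                f"sensitivity_fraction {self.sensitivity_fraction} outside (0, 0.5]"
            )
        if self.currency_rate is not None and self.currency_rate <= 0:
            raise ConfigError(f"currency_rate must be positive, got {self.currency_rate}")
        for p in [self.model_file, *self.cost_table_files] + (
                [self.cohort_file] if self.cohort_file else []):
            if not Path(p).exists():
                raise ConfigError(f"input file does not exist: {p}")


def evaluation_frame(results: Sequence[EvaluationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.strategy_name, r.expected_cost, r.expected_effect) for r in results],
        columns=["strategy", "expected_cost_gbp", "expected_effect_days"],
    )


def sensitivity_frame(ranges: Mapping[str, _cea.SensitivityRange]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.quantity, r.strategy, r.base, r.low, r.high, r.fraction)
         for r in ranges.values()],
        columns=["quantity", "strategy", "base", "low", "high", "fraction"],
    )


def tornado_frame(entries: Sequence[_cea.TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.parameter_name, e.low_result, e.high_result, e.swing) for e in entries],
        columns=["parameter", "low_result", "high_result", "swing"],
    )


def render_summary(results: Sequence[EvaluationResult], cea_result,
                   ranges: Optional[Mapping[str, _cea.SensitivityRange]] = None,
                   currency_rate: Optional[float] = None) -> str:
    """A compact cost-effectiveness summary table (GBP, optional EUR)."""
    rg = _cea.round_gbp
    lines = []
    header = (f"{'Strategy':<10}{'Cost (£)':>10}{'[low, high]':>18}{'Days':>8}"
              f"  {'ICER (£/day)':<26}")
    lines.append(header)
    for r in results:
        interval = ""
        if ranges and r.strategy_name in ranges:
            rr = ranges[r.strategy_name]
            interval = f"[{rg(rr.low)}, {rg(rr.high)}]"
        icer_cell = ""
        if r.strategy_name == cea_result.reference_strategy and cea_result.icer is not None:
            icer_cell = str(rg(cea_result.icer))
            if ranges and "icer" in ranges:
                icer_cell += f" [{rg(ranges['icer'].low)}, {rg(ranges['icer'].high)}]"
        lines.append(
            f"{r.strategy_name:<10}{rg(r.expected_cost):>10}{interval:>18}"
            f"{r.expected_effect:>8.2f}  {icer_cell:<26}".rstrip()
        )
    lines.append(
        f"Incremental cost ({cea_result.comparator_strategy} - "
        f"{cea_result.reference_strategy}): £{rg(cea_result.delta_cost)}"
        + (f" (€{rg(_cea.convert_currency(cea_result.delta_cost, currency_rate))})"
           if currency_rate else "")
    )
    lines.append(f"Dominance: {cea_result.dominance}")
    return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig) -> Dict[str, Path]:
    """validate -> (calibrate) -> evaluate -> ICER -> sensitivity -> reports.

    Returns a mapping of artifact names to written paths; raises on any
    fatal diagnostic (the CLI maps exceptions to nonzero exit codes).
    """
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    try:
        tables = {}
        for f in config.cost_table_files:
            t = read_cost_table(f)
            tables[t.name] = t
        model = load_model(config.model_file, tables)
        log.info("loaded model with strategies %s", list(model.trees))

        for sname, tree in model.trees.items():
            diags = validate_tree(tree, model.parameters)
            for d in diags:
                log.error("validate[%s]: %s", sname, d)
            if diags:
                raise ConfigError(f"strategy {sname!r} failed validation: {diags[0]}")

        params = model.parameters
        if config.calibrate and model.calibration_targets:
            params = calibrate_free_parameters(
                model.trees, params, model.calibration_targets, seed=config.seed)
            log.info("calibrated free parameters: %s",
                     {n: round(params[n].value, 4) for n in params.free_names()})

        if config.cohort_file:
            cohort = read_cohort(config.cohort_file)
            fragment, _ = estimate_parameters(cohort)
            injected = {p.name: p.value for p in fragment if p.name in params}
            params = params.with_values(injected)
            log.info("injected %d cohort-estimated parameters", len(injected))

        results = [rollback(tree, params) for tree in model.trees.values()]
        names = list(model.trees)
        reference, comparator = names[0], names[1] if len(names) > 1 else names[0]
        cea_result = _cea.cea_from_trees(model.trees, params, reference, comparator)
        ranges = _cea.joint_range(model.trees, params, config.sensitivity_fraction,
                                  vary=config.vary, reference=reference,
                                  comparator=comparator, seed=config.seed)
        entries = _cea.tornado(model.trees, params, config.sensitivity_fraction,
                               quantity="delta_cost", vary=config.vary,
                               reference=reference, comparator=comparator)

        artifacts: Dict[str, Path] = {"log": log_path}
        artifacts["evaluation"] = out_dir / "evaluation.csv"
        evaluation_frame(results).to_csv(artifacts["evaluation"], index=False)
        artifacts["cea"] = out_dir / "cea.csv"
        pd.DataFrame([cea_result.__dict__]).to_csv(artifacts["cea"], index=False)
        artifacts["sensitivity"] = out_dir / "sensitivity.csv"
        sensitivity_frame(ranges).to_csv(artifacts["sensitivity"], index=False)
        artifacts["tornado"] = out_dir / "tornado.csv"
        tornado_frame(entries).to_csv(artifacts["tornado"], index=False)
        artifacts["summary"] = out_dir / "summary.txt"
        artifacts["summary"].write_text(
            render_summary(results, cea_result, ranges, config.currency_rate))
        log.info("pipeline complete; artifacts in %s", out_dir)
        return artifacts
    finally:
        log.removeHandler(handler)
        handler.close()
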