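"""Synthetic two-arm patient cohorts and parameter recovery.

No patient-level dataset is deposited for the cohorts the analysis is
built on (100 emergency-ureteroscopy patients, 20 stented/delayed
patients), so this module generates cohorts with the same *marginal*
statistical structure: Normal ages, moment-matched Gamma stone sizes and
durations (right-skewed, nonnegative — note the detection-to-treatment
interval has SD larger than its mean, which a shape<1 Gamma represents),
categorical stone locations, and independent Bernoulli secondary outcomes
at the published rates.  Joint dependence between outcomes is *not*
modelled because only marginal rates are published; estimates recovered
from a generated cohort are therefore exactly the plug-in empirical
proportions and moments.

`estimate_parameters` maps a cohort back to tree-ready parameters
(re-admission / re-intervention / follow-up-imaging probabilities, mean
lengths of stay), letting the whole pipeline run end to end with no
external data.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .cea import cea_from_trees
from .parameters import Parameter, ParameterSet
from .tree import StrategyTree, rollback

__all__ = [
    "ARMS",
    "LOCATIONS",
    "OUTCOMES",
    "COHORT_COLUMNS",
    "CohortConfig",
    "CohortSummary",
    "generate_cohort",
    "estimate_parameters",
    "end_to_end_check",
]

ARMS = ("EUL", "DUL")
LOCATIONS = ("proximal", "mid", "distal")
OUTCOMES = ("complication", "clearance", "re_intervention", "re_admission", "imaging_followup")

COHORT_COLUMNS = [
    "arm", "age", "sex", "stone_size_mm", "location",
    "los_days", "detection_to_treatment_days",
    "complication", "clearance", "re_intervention", "re_admission", "imaging_followup",
]

#: minimum Gamma shape considered numerically meaningful
MIN_GAMMA_SHAPE = 0.01

#: cohort outcome/field -> tree parameter stem
_PARAM_STEMS = {
    "imaging_followup": "p_imaging",
    "re_admission": "p_readm",
    "re_intervention": "p_reint",
    "complication": "p_complication",
    "clearance": "p_clearance",
}


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort, keyed by arm.

    ``(mean, sd)`` pairs parameterise Normal (age) or moment-matched Gamma
    (sizes, durations) distributions; probabilities are Bernoulli rates.
    """

    n_eul: int = 100
    n_dul: int = 20
    age: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {"EUL": (55.66, 17.7), "DUL": (66.73, 14.8)})
    stone_size_mm: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {"EUL": (8.24, 4.46), "DUL": (10.12, 4.72)})
    location_shares: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {
            "EUL": {"proximal": 0.33, "mid": 0.16, "distal": 0.51},
            "DUL": {"proximal": 0.40, "mid": 0.35, "distal": 0.25},
        })
    sex_male_share: Dict[str, float] = field(
        default_factory=lambda: {"EUL": 0.73, "DUL": 0.55})
    outcome_probs: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {
            "EUL": {"complication": 0.04, "clearance": 0.66, "re_intervention": 0.09,
                    "re_admission": 0.18, "imaging_followup": 0.30},
            "DUL": {"complication": 0.05, "clearance": 0.70, "re_intervention": 0.15,
                    "re_admission": 0.20, "imaging_followup": 0.90},
        })
    los_days: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {"EUL": (3.76, 7.14), "DUL": (6.11, 5.20)})
    detection_to_treatment_days: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {"EUL": (2.13, 5.7), "DUL": (91.63, 50.6)})
    seed: int = 0
    duration_family: str = "gamma"  # or "lognormal"

    def n_for(self, arm: str) -> int:
        return {"EUL": self.n_eul, "DUL": self.n_dul}[arm]

    def validate(self) -> None:
        if self.n_eul < 0 or self.n_dul < 0:
            raise ValueError("cohort sizes must be nonnegative")
        if self.duration_family not in ("gamma", "lognormal"):
            raise ValueError(f"unknown duration family {self.duration_family!r}")
        for arm in ARMS:
            total = sum(self.location_shares[arm].values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{arm} location shares sum to {total}, not 1")
            for name, p in list(self.outcome_probs[arm].items()) + [("sex", self.sex_male_share[arm])]:
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"{arm} probability {name}={p} outside [0, 1]")
            for fieldname in ("age", "stone_size_mm", "los_days", "detection_to_treatment_days"):
                _, sd = getattr(self, fieldname)[arm]
                if sd < 0:
                    raise ValueError(f"{arm} {fieldname} has negative sd")


@dataclass
class CohortSummary:
    """Per-arm counts, outcome proportions and continuous summaries."""

    counts: pd.Series
    proportions: pd.DataFrame  # index outcome, columns arm
    continuous: pd.DataFrame  # index (variable, stat), columns arm
    locations: pd.DataFrame  # index location, columns arm


def _skewed_positive(mean: float, sd: float, size: int, rng, family: str,
                     floor: float = 0.0) -> np.ndarray:
    """Right-skewed nonnegative draws matched to (mean, sd) by moments."""
    if sd == 0.0:
        return np.full(size, mean)
    if mean <= 0.0:
        raise ValueError(f"cannot moment-match a positive distribution to mean {mean}")
    if family == "gamma":
        shape = (mean / sd) ** 2
        if shape < MIN_GAMMA_SHAPE:
            raise ValueError(
                f"infeasible moments (mean {mean}, sd {sd}): Gamma shape {shape:.4g} < {MIN_GAMMA_SHAPE}"
            )
        draws = rng.gamma(shape, sd**2 / mean, size=size)
    else:  # lognormal
        sigma2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - sigma2 / 2.0
        draws = rng.lognormal(mu, np.sqrt(sigma2), size=size)
    return np.maximum(draws, floor)


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate one patient per row; reproducible for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    frames = []
    for arm in ARMS:
        n = config.n_for(arm)
        if n == 0:
            continue
        mean, sd = config.age[arm]
        age = rng.normal(mean, sd, size=n)
        sex = np.where(rng.random(n) < config.sex_male_share[arm], "M", "F")
        smean, ssd = config.stone_size_mm[arm]
        size_mm = _skewed_positive(smean, ssd, n, rng, config.duration_family, floor=0.1)
        shares = config.location_shares[arm]
        location = rng.choice(LOCATIONS, size=n, p=[shares[l] for l in LOCATIONS])
        lmean, lsd = config.los_days[arm]
        los = _skewed_positive(lmean, lsd, n, rng, config.duration_family)
        dmean, dsd = config.detection_to_treatment_days[arm]
        interval = _skewed_positive(dmean, dsd, n, rng, config.duration_family)
        frame = {
            "arm": np.repeat(arm, n),
            "age": age,
            "sex": sex,
            "stone_size_mm": size_mm,
            "location": location,
            "los_days": los,
            "detection_to_treatment_days": interval,
        }
        for outcome in OUTCOMES:
            frame[outcome] = rng.random(n) < config.outcome_probs[arm][outcome]
        frames.append(pd.DataFrame(frame))
    if not frames:
        return pd.DataFrame({c: pd.Series(dtype=object) for c in COHORT_COLUMNS})
    return pd.concat(frames, ignore_index=True)[COHORT_COLUMNS]


def estimate_parameters(cohort: pd.DataFrame,
                        arms=ARMS) -> Tuple[ParameterSet, CohortSummary]:
    """Empirical per-arm rates and moments, shaped as model parameters.

    Returns a :class:`ParameterSet` fragment (fixed parameters named
    ``p_imaging_eul``, ``p_readm_dul``, ``los_mean_eul``, ...) plus a
    table-style :class:`CohortSummary`.
    """
    fragment = ParameterSet()
    counts = {}
    prop_records: Dict[str, dict] = {}
    cont_records: Dict[Tuple[str, str], dict] = {}
    loc_records: Dict[str, dict] = {}
    for arm in arms:
        sub = cohort[cohort["arm"] == arm]
        if len(sub) == 0:
            raise ValueError(f"arm {arm!r} is empty; cannot estimate its parameters")
        counts[arm] = len(sub)
        suffix = arm.lower()
        for outcome in OUTCOMES:
            rate = float(sub[outcome].mean())
            prop_records.setdefault(outcome, {})[arm] = rate
            stem = _PARAM_STEMS[outcome]
            fragment.add(Parameter(f"{stem}_{suffix}", "probability", rate,
                                   description=f"empirical {outcome} rate, {arm} arm"))
        for var in ("age", "stone_size_mm", "los_days", "detection_to_treatment_days"):
            cont_records.setdefault((var, "mean"), {})[arm] = float(sub[var].mean())
            cont_records.setdefault((var, "sd"), {})[arm] = float(sub[var].std(ddof=1)) if len(sub) > 1 else 0.0
        fragment.add(Parameter(f"los_mean_{suffix}", "duration_days", float(sub["los_days"].mean()),
                               description=f"empirical mean inpatient days, {arm} arm"))
        for loc in LOCATIONS:
            loc_records.setdefault(loc, {})[arm] = float((sub["location"] == loc).mean())
    summary = CohortSummary(
        counts=pd.Series(counts, name="n"),
        proportions=pd.DataFrame(prop_records).T.reindex(list(OUTCOMES)),
        continuous=pd.DataFrame(cont_records).T,
        locations=pd.DataFrame(loc_records).T.reindex(list(LOCATIONS)),
    )
    return fragment, summary


def _injectable(fragment: ParameterSet, params: ParameterSet) -> Dict[str, float]:
    return {p.name: p.value for p in fragment if p.name in params}


def end_to_end_check(
    config: CohortConfig,
    trees: Mapping[str, StrategyTree],
    params: ParameterSet,
    reference: str = "EUL",
    comparator: str = "DUL",
) -> dict:
    """Generate -> estimate -> inject -> roll back, against the exact rates.

    Rolls the strategy trees back twice: once with the cohort's plug-in
    estimates injected, once with the exact configured probabilities and
    mean stays injected, and reports both cost sets, their relative
    differences, and the plug-in ICER/dominance.
    """
    cohort = generate_cohort(config)
    fragment, summary = estimate_parameters(cohort)
    plug_values = _injectable(fragment, params)
    plug = params.with_values(plug_values)

    exact_values = {}
    for arm in ARMS:
        suffix = arm.lower()
        for outcome, stem in _PARAM_STEMS.items():
            name = f"{stem}_{suffix}"
            if name in params:
                exact_values[name] = config.outcome_probs[arm][outcome]
        name = f"los_mean_{suffix}"
        if name in params:
            exact_values[name] = config.los_days[arm][0]
    exact = params.with_values(exact_values)

    report = {"injected": plug_values, "n": {arm: config.n_for(arm) for arm in ARMS}}
    costs_plug, costs_exact = {}, {}
    for sname, tree in trees.items():
        costs_plug[sname] = rollback(tree, plug).expected_cost
        costs_exact[sname] = rollback(tree, exact).expected_cost
    report["expected_cost_plugin"] = costs_plug
    report["expected_cost_exact"] = costs_exact
    report["relative_cost_error"] = {
        s: abs(costs_plug[s] - costs_exact[s]) / costs_exact[s] for s in trees
    }
    res = cea_from_trees(trees, plug, reference, comparator)
    report["icer_plugin"] = res.icer
    report["delta_cost_plugin"] = res.delta_cost
    report["dominance_plugin"] = res.dominance
    report["summary"] = summary
    return report
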