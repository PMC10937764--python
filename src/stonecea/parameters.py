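"""Named model parameters: probabilities, unit costs, daily costs, durations.

The health-economic model is written entirely in terms of named parameters
(the source analysis uses no algebraic symbols): branch probabilities of
chance events, NHS reference unit costs in GBP, the inpatient bed-day cost,
and mean inpatient durations in days.  A parameter may be *free*, meaning
it is not pinned by published data and is resolved by calibrating the tree
to published expected-cost totals, in which case it carries a closed
bounds interval.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Iterator, Mapping, Optional, Tuple

__all__ = [
    "ROLES",
    "Parameter",
    "ParameterSet",
    "UnknownParameterError",
]

ROLES = ("probability", "unit_cost", "daily_cost", "duration_days")

#: roles expressed in GBP (varied in the "costs" sensitivity subset)
COST_ROLES = ("unit_cost", "daily_cost")


class UnknownParameterError(KeyError):
    """Lookup of a parameter name not present in the set."""


@dataclass(frozen=True)
class Parameter:
    """A single named model input.

    Parameters
    ----------
    name : str
        Unique identifier within a :class:`ParameterSet`.
    role : str
        One of ``probability`` (unitless, in [0, 1]), ``unit_cost`` (GBP),
        ``daily_cost`` (GBP per day) or ``duration_days`` (days).
    value : float
        Base-case value.
    free : bool
        True when the value is not fixed by published data and is subject
        to calibration; free parameters must carry ``bounds``.
    bounds : (float, float), optional
        Closed interval the value must lie in.  Defaults to [0, 1] for
        probabilities and [0, inf) for the other roles.
    code : str, optional
        NHS reference-cost code backing the value, for provenance and for
        resolution against a cost table.
    table : str, optional
        Name of the cost table (e.g. ``"eul"``/``"dul"``) the code should
        be looked up in, when the same code carries different tariffs.
    """

    name: str
    role: str
    value: float
    free: bool = False
    bounds: Optional[Tuple[float, float]] = None
    code: Optional[str] = None
    table: Optional[str] = None
    description: str = ""

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"parameter {self.name!r}: unknown role {self.role!r}")
        lo, hi = self.effective_bounds()
        if lo > hi:
            raise ValueError(f"parameter {self.name!r}: bounds {self.bounds} are inverted")
        if self.role == "probability":
            if not (0.0 <= self.value <= 1.0):
                raise ValueError(
                    f"parameter {self.name!r}: probability value {self.value} outside [0, 1]"
                )
            if lo < 0.0 or hi > 1.0:
                raise ValueError(
                    f"parameter {self.name!r}: probability bounds {self.bounds} outside [0, 1]"
                )
        elif self.role in COST_ROLES and self.value < 0.0:
            raise ValueError(f"parameter {self.name!r}: cost value {self.value} is negative")
        if self.free and self.bounds is None:
            raise ValueError(f"parameter {self.name!r}: free parameters require bounds")
        if not (lo - 1e-12 <= self.value <= hi + 1e-12):
            raise ValueError(
                f"parameter {self.name!r}: value {self.value} outside bounds [{lo}, {hi}]"
            )

    def effective_bounds(self) -> Tuple[float, float]:
        if self.bounds is not None:
            return (float(self.bounds[0]), float(self.bounds[1]))
        if self.role == "probability":
            return (0.0, 1.0)
        return (0.0, float("inf"))


class ParameterSet:
    """An ordered, name-addressable collection of :class:`Parameter`.

    Lookup of an unknown name raises :class:`UnknownParameterError`; there
    is deliberately no silent default.
    """

    def __init__(self, parameters: Iterable[Parameter] = ()):
        self._params: Dict[str, Parameter] = {}
        for p in parameters:
            self.add(p)

    def add(self, param: Parameter) -> None:
        if param.name in self._params:
            raise ValueError(f"duplicate parameter name {param.name!r}")
        self._params[param.name] = param

    def __getitem__(self, name: str) -> Parameter:
        try:
            return self._params[name]
        except KeyError:
            raise UnknownParameterError(name) from None

    def __contains__(self, name: str) -> bool:
        return name in self._params

    def __iter__(self) -> Iterator[Parameter]:
        return iter(self._params.values())

    def __len__(self) -> int:
        return len(self._params)

    def names(self) -> list:
        return list(self._params)

    def values(self) -> Dict[str, float]:
        """Base-case evaluation environment (name -> value)."""
        return {name: p.value for name, p in self._params.items()}

    def free_names(self) -> list:
        return [name for name, p in self._params.items() if p.free]

    def with_values(self, updates: Mapping[str, float]) -> "ParameterSet":
        """A copy with the given values replaced (names must exist)."""
        out = ParameterSet()
        unknown = set(updates) - set(self._params)
        if unknown:
            raise UnknownParameterError(", ".join(sorted(unknown)))
        for name, p in self._params.items():
            if name in updates:
                out.add(replace(p, value=float(updates[name])))
            else:
                out.add(p)
        return out

    def subset(self, roles: Iterable[str]) -> list:
        roles = set(roles)
        return [name for name, p in self._params.items() if p.role in roles]

    def __eq__(self, other) -> bool:
        return isinstance(other, ParameterSet) and self._params == other._params

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ParameterSet({len(self._params)} parameters)"
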