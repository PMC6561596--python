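"""Media ingredients as experimental factors.

A :class:`Factor` is a single ingredient varied between a low and a high
concentration; a :class:`FactorSpace` is the ordered collection of factors
entering one design iteration.  Coded levels -1/+1 map onto the low/high
concentrations; the conventional low level is 0 (ingredient absent).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

__all__ = [
    "Factor",
    "FactorSpace",
    "default_screening_space",
    "default_custom_space",
]

_ROLES = ("chemical", "bionutrient", "buffer")


@dataclass(frozen=True)
class Factor:
    """One media ingredient with its concentration range.

    Parameters
    ----------
    name : str
        Unique ingredient identifier (snake_case by convention).
    low, high : float
        Concentrations mapped to coded levels -1 and +1.  ``low`` defaults
        to 0, i.e. the ingredient is simply absent at the low level.
    units : str
        Concentration units, e.g. ``"mM"`` or ``"g/L"``.
    role : str
        One of ``chemical`` (defined salt/compound), ``bionutrient``
        (complex additive such as yeast extract) or ``buffer``.
    pinned : float or None
        If set, the ingredient is held at this fixed concentration in every
        run and is not part of the coded design.
    """

    name: str
    high: float
    low: float = 0.0
    units: str = "mM"
    role: str = "chemical"
    pinned: float | None = None

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(f"role must be one of {_ROLES}, got {self.role!r}")
        if self.low < 0:
            raise ValueError(f"{self.name}: low concentration must be >= 0")
        if self.high <= self.low:
            raise ValueError(f"{self.name}: high ({self.high}) must exceed low ({self.low})")

    def decode(self, coded: float) -> float:
        """Map a coded level in [-1, +1] to a concentration."""
        if self.pinned is not None:
            return self.pinned
        return self.low + (coded + 1.0) / 2.0 * (self.high - self.low)

    def encode(self, concentration: float) -> float:
        """Map a concentration back to the coded scale."""
        return 2.0 * (concentration - self.low) / (self.high - self.low) - 1.0


@dataclass
class FactorSpace:
    """Ordered set of factors with unique names."""

    factors: list[Factor] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate factor names: {dupes}")

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def free(self) -> list[Factor]:
        """Factors that vary in the design (not pinned)."""
        return [f for f in self.factors if f.pinned is None]

    def __len__(self) -> int:
        return len(self.factors)

    def __iter__(self) -> Iterator[Factor]:
        return iter(self.factors)

    def __getitem__(self, name: str) -> Factor:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)

    def subset(self, names: Sequence[str]) -> "FactorSpace":
        return FactorSpace([self[n] for n in names])


def default_screening_space() -> FactorSpace:
    """The 21-ingredient screening space for a thermophile growth medium.

    Mineral salts covering ammonium/potassium/sodium cations against
    carbonate/chloride/nitrate/sulphate anions, two phosphate salts, citric
    acid and urea as auxiliary C/N sources, a MOPS buffer, the chelators
    EDTA and NTA, trace elements, commercial amino-acid and vitamin mixes
    (opaque "1x" stocks) and yeast extract capped at 1 g/L.
    """
    gl = "g/L"
    x = "x"
    return FactorSpace([
        Factor("yeast_extract", 1.0, units=gl, role="bionutrient"),
        Factor("citric_acid", 8.0),
        Factor("edta", 0.5),
        Factor("ammonium_chloride", 20.0),
        Factor("ammonium_nitrate", 20.0),
        Factor("ammonium_sulphate", 25.0),
        Factor("potassium_chloride", 20.0),
        Factor("potassium_nitrate", 20.0),
        Factor("potassium_sulphate", 10.0),
        Factor("sodium_carbonate", 5.0),
        Factor("sodium_chloride", 85.0),
        Factor("sodium_nitrate", 20.0),
        Factor("monosodium_phosphate", 25.0),
        Factor("dipotassium_phosphate", 35.0),
        Factor("mops_buffer", 50.0, role="buffer"),
        Factor("urea", 15.0),
        Factor("calcium_chloride", 1.0),
        Factor("iron_sulphate", 0.05),
        Factor("magnesium_sulphate", 1.0),
        Factor("nta", 1.1),
        Factor("trace_metals", 1.0, units=x),
    ])


def default_custom_space() -> FactorSpace:
    """Nine-factor space for the second, response-surface iteration.

    One bionutrient (yeast extract) plus eight chemically defined
    ingredients; in the synthetic ground truth two of these play the
    "chelator-like" growth-inhibiting part.
    """
    return FactorSpace([
        Factor("yeast_extract", 1.0, units="g/L", role="bionutrient"),
        Factor("citric_acid", 8.0),
        Factor("edta", 0.5),
        Factor("ammonium_sulphate", 25.0),
        Factor("potassium_phosphate", 35.0),
        Factor("sodium_chloride", 85.0),
        Factor("magnesium_sulphate", 1.0),
        Factor("calcium_chloride", 1.0),
        Factor("trace_metals", 1.0, units="x"),
    ])
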