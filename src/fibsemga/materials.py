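"""Elemental compositions, densities, and the composition algebra of Ga implantation.

Everything downstream — stopping powers, mean free paths, HAADF signal models —
is evaluated on the :class:`Material` objects defined here.  The module also
carries the small pieces of "composition arithmetic" used throughout the
analysis: converting a Ga:C atomic ratio to at.% Ga, implanting gallium into a
resin (replacing carbon or diluting everything), applying ablation/mass-loss
retention scenarios, and the geometric-mean rule for the optimal implanted-ion
atomic number.

Units: atomic fractions are dimensionless and sum to 1; mass density in
g/cm^3; number densities in atoms/nm^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

AVOGADRO = 6.02214076e23

#: symbol -> (Z, atomic weight g/mol, elemental solid density g/cm^3 or None)
ELEMENT_TABLE: dict[str, tuple[int, float, float | None]] = {
    "H": (1, 1.008, None),
    "C": (6, 12.011, 2.0),
    "N": (7, 14.007, None),
    "O": (8, 15.999, None),
    "Al": (13, 26.982, 2.70),
    "Si": (14, 28.085, 2.33),
    "Ga": (31, 69.723, 5.91),
    "Os": (76, 190.23, 22.59),
    "Pb": (82, 207.2, 11.35),
    "U": (92, 238.03, 19.05),
}

_FRACTION_TOL = 1e-9


class CompositionError(ValueError):
    """Invalid or infeasible elemental composition."""


def _element_data(symbol: str) -> tuple[int, float]:
    try:
        z, a, _ = ELEMENT_TABLE[symbol]
    except KeyError as exc:
        raise CompositionError(f"unknown element symbol {symbol!r}") from exc
    return z, a


@dataclass(frozen=True)
class ElementComposition:
    """Atomic composition: parallel tuples of symbols and atomic fractions.

    Fractions must be non-negative and sum to 1 within 1e-9; each element may
    appear once.  Use :meth:`from_dict` for the common case.
    """

    symbols: tuple[str, ...]
    fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.symbols) != len(self.fractions):
            raise CompositionError("symbols and fractions differ in length")
        if len(self.symbols) == 0:
            raise CompositionError("empty composition")
        if len(set(self.symbols)) != len(self.symbols):
            raise CompositionError("duplicate element in composition")
        fr = np.asarray(self.fractions, dtype=float)
        if not np.all(np.isfinite(fr)) or np.any(fr < 0):
            raise CompositionError("atomic fractions must be finite and >= 0")
        if abs(fr.sum() - 1.0) > _FRACTION_TOL:
            raise CompositionError(f"atomic fractions sum to {fr.sum()}, not 1")
        for s in self.symbols:
            z, _ = _element_data(s)
            if not 1 <= z <= 92:
                raise CompositionError(f"Z out of range for {s}")

    @classmethod
    def from_dict(cls, fractions: Mapping[str, float]) -> "ElementComposition":
        items = [(s, float(f)) for s, f in fractions.items() if f != 0.0]
        total = sum(f for _, f in items)
        if total <= 0:
            raise CompositionError("empty composition")
        if abs(total - 1.0) > 1e-6:
            raise CompositionError(f"atomic fractions sum to {total}, not 1")
        # renormalise only when the input is off by more than the class
        # tolerance, so exact fractions (e.g. an implanted Ga fraction)
        # survive bit-for-bit
        if abs(total - 1.0) > _FRACTION_TOL:
            items = [(s, f / total) for s, f in items]
        return cls(
            symbols=tuple(s for s, _ in items),
            fractions=tuple(f for _, f in items),
        )

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.symbols, self.fractions))

    @property
    def atomic_numbers(self) -> np.ndarray:
        return np.array([_element_data(s)[0] for s in self.symbols], dtype=float)

    @property
    def atomic_weights(self) -> np.ndarray:
        return np.array([_element_data(s)[1] for s in self.symbols], dtype=float)

    @property
    def fraction_array(self) -> np.ndarray:
        return np.asarray(self.fractions, dtype=float)

    @property
    def mean_atomic_weight(self) -> float:
        return float(self.fraction_array @ self.atomic_weights)

    @property
    def mean_atomic_number(self) -> float:
        return float(self.fraction_array @ self.atomic_numbers)

    def mass_fractions(self) -> np.ndarray:
        w = self.fraction_array * self.atomic_weights
        return w / w.sum()

    def fraction_of(self, symbol: str) -> float:
        return self.as_dict().get(symbol, 0.0)


@dataclass(frozen=True)
class Material:
    """A named composition with a mass density."""

    name: str
    composition: ElementComposition
    mass_density: float  # g/cm^3

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mass_density) and self.mass_density > 0):
            raise CompositionError("mass_density must be finite and > 0")

    @property
    def number_density(self) -> float:
        """Total atomic number density, atoms/nm^3."""
        n = self.mass_density * AVOGADRO / self.composition.mean_atomic_weight
        return n * 1e-21  # cm^-3 -> nm^-3

    def element_number_densities(self) -> np.ndarray:
        """Per-element number densities, atoms/nm^3, aligned with composition.symbols."""
        return self.number_density * self.composition.fraction_array


@dataclass(frozen=True)
class RetentionScenario:
    """Per-element retention fractions (surviving atoms per original atom).

    Elements absent from ``retention`` are fully retained (fraction 1).
    """

    retention: Mapping[str, float] = field(default_factory=dict)
    label: str = "no-loss"

    def __post_init__(self) -> None:
        for s, r in self.retention.items():
            if not (0.0 <= r <= 1.0):
                raise CompositionError(f"retention for {s} outside [0, 1]")

    def fraction_for(self, symbol: str) -> float:
        return float(self.retention.get(symbol, 1.0))


NO_LOSS = RetentionScenario({}, label="no-loss")
#: the ablation scenario considered for the implanted layer: half the C (and the
#: trace N, treated like C) lost, all O lost.
C50_O100 = RetentionScenario({"C": 0.5, "N": 0.5, "O": 0.0}, label="c50-o100")


# ---------------------------------------------------------------------------
# composition arithmetic
# ---------------------------------------------------------------------------

def atomic_percent_from_ratio(ga_c_ratio: float) -> float:
    """at.% Ga among Ga+C for a Ga:C atomic ratio r: 100*r/(1+r)."""
    r = float(ga_c_ratio)
    if not np.isfinite(r) or r < 0:
        raise ValueError(f"Ga:C ratio must be finite and >= 0, got {ga_c_ratio}")
    return 100.0 * r / (1.0 + r)


def ratio_from_percent(at_percent: float) -> float:
    """Inverse of :func:`atomic_percent_from_ratio`."""
    p = float(at_percent)
    if not np.isfinite(p) or not 0.0 <= p < 100.0:
        raise ValueError(f"at.% must lie in [0, 100), got {at_percent}")
    return p / (100.0 - p)


def format_at_percent(value: float, sig: int = 3) -> str:
    """Display rounding (3 significant figures by default); internals stay exact."""
    if value == 0:
        return "0"
    from decimal import Decimal

    q = float(f"{value:.{sig}g}")
    return f"{Decimal(repr(q)).normalize()}"


def optimal_implant_z(z_organic: float, z_stain: float) -> float:
    """Geometric-mean design rule for the implanted-ion atomic number.

    The implant should raise the matrix Z enough to shrink the electron range
    while keeping the stain (Os/Pb/U, Z ~ 82) visible above it; the geometric
    mean of the organic-matrix Z and the stain Z balances the two.
    """
    if not (z_organic > 0 and z_stain > 0):
        raise ValueError("atomic numbers must be > 0")
    return float(np.sqrt(z_organic * z_stain))


def mix_density(components: Iterable[tuple[float, float]]) -> float:
    """Inverse-mass-fraction (ideal volume additivity) density of a mixture.

    ``components`` is an iterable of (mass_fraction, density) pairs.
    """
    comps = list(components)
    wsum = sum(w for w, _ in comps)
    if abs(wsum - 1.0) > 1e-9:
        raise ValueError("mass fractions must sum to 1")
    return 1.0 / sum(w / rho for w, rho in comps if w > 0)


def implant_gallium(
    base: Material,
    ga_atomic_fraction: float,
    mode: str = "replace_carbon",
    ga_density: float = 5.91,
) -> Material:
    """Return ``base`` with a Ga atomic fraction ``g`` implanted.

    ``replace_carbon``: g of the C atomic fraction is swapped for Ga and every
    other fraction is untouched (the assumption used for the simulated images).
    ``additive``: Ga atoms join the solid, so all base fractions rescale by
    (1-g).  The density of the implanted material is the inverse-mass-fraction
    mix of the base material and elemental Ga.
    """
    g = float(ga_atomic_fraction)
    if not (0.0 <= g < 1.0):
        raise CompositionError(f"Ga fraction must lie in [0, 1), got {g}")
    if g == 0.0:
        return base
    comp = base.composition.as_dict()
    if mode == "replace_carbon":
        c = comp.get("C", 0.0)
        if c < g - _FRACTION_TOL:
            raise CompositionError(
                f"cannot replace {g:.3f} of C: base has only {c:.3f} C"
            )
        comp["C"] = c - g
        comp["Ga"] = comp.get("Ga", 0.0) + g
    elif mode == "additive":
        comp = {s: f * (1.0 - g) for s, f in comp.items()}
        comp["Ga"] = comp.get("Ga", 0.0) + g
    else:
        raise ValueError(f"unknown implantation mode {mode!r}")
    new_comp = ElementComposition.from_dict(comp)
    # mass fraction of Ga among (base atoms mix, Ga) for the density rule
    a_ga = _element_data("Ga")[1]
    mean_a_base = base.composition.mean_atomic_weight
    if mode == "replace_carbon":
        # per final atom: (1) original non-C-replaced atoms keep base identity
        w_ga = g * a_ga
        w_base = new_comp.mean_atomic_weight - w_ga
    else:
        w_ga = g * a_ga
        w_base = (1.0 - g) * mean_a_base
    tot = w_ga + w_base
    rho = mix_density([(w_base / tot, base.mass_density), (w_ga / tot, ga_density)])
    return Material(
        name=f"{base.name}+Ga{100 * g:g}({mode})",
        composition=new_comp,
        mass_density=rho,
    )


def apply_retention(
    base: ElementComposition, scenario: RetentionScenario
) -> tuple[ElementComposition, float]:
    """Apply a mass-loss scenario; return (renormalised composition, survival factor).

    The factor is surviving atoms per original atom, sum_i f_i * retention_i.
    """
    fr = base.fraction_array
    ret = np.array([scenario.fraction_for(s) for s in base.symbols])
    surv = fr * ret
    factor = float(surv.sum())
    if factor <= 0:
        raise CompositionError("retention scenario removes every atom")
    kept = {
        s: v / factor for s, v in zip(base.symbols, surv) if v > 0
    }
    return ElementComposition.from_dict(kept), factor


# ---------------------------------------------------------------------------
# presets and config I/O
# ---------------------------------------------------------------------------

def _epon_araldite() -> Material:
    """Default Epon-Araldite stoichiometry (typical epoxy resin; overridable)."""
    return Material(
        name="epon_araldite",
        composition=ElementComposition.from_dict(
            {"H": 0.52, "C": 0.39, "O": 0.085, "N": 0.005}
        ),
        mass_density=1.25,
    )


def stain_with(base: Material, symbol: str, fraction: float) -> Material:
    """Substitute ``fraction`` of stain atoms proportionally from all base elements."""
    if not (0.0 < fraction < 1.0):
        raise CompositionError("stain fraction must lie in (0, 1)")
    comp = {s: f * (1.0 - fraction) for s, f in base.composition.as_dict().items()}
    comp[symbol] = comp.get(symbol, 0.0) + fraction
    new_comp = ElementComposition.from_dict(comp)
    a_st = _element_data(symbol)[1]
    rho_st = ELEMENT_TABLE[symbol][2]
    if rho_st is None:
        raise CompositionError(f"no elemental density tabulated for {symbol}")
    w_st = fraction * a_st
    w_base = (1.0 - fraction) * base.composition.mean_atomic_weight
    tot = w_st + w_base
    rho = mix_density([(w_base / tot, base.mass_density), (w_st / tot, rho_st)])
    return Material(
        name=f"{base.name}+{symbol}{100 * fraction:g}", composition=new_comp,
        mass_density=rho,
    )


def preset(name: str) -> Material:
    """Built-in named materials used throughout the analysis."""
    resin = _epon_araldite()
    if name == "epon_araldite":
        return resin
    if name == "epon_pb3":
        return stain_with(resin, "Pb", 0.03)
    if name == "epon_ga25":
        return implant_gallium(resin, 0.25, mode="replace_carbon")
    if name == "epon_ga50":
        # 50 at.% Ga cannot all come out of the 39 at.% carbon budget of the
        # H-inclusive resin stoichiometry, so the 50% preset dilutes all
        # resin elements instead of swapping C only.
        return implant_gallium(resin, 0.50, mode="additive")
    if name == "ga2o3":
        return Material(
            name="ga2o3",
            composition=ElementComposition.from_dict({"Ga": 0.4, "O": 0.6}),
            mass_density=5.88,
        )
    raise KeyError(f"unknown material preset {name!r}")


def material_from_dict(spec: Mapping) -> Material:
    """Build a material from a config mapping: {name, fractions, mass_density}."""
    return Material(
        name=str(spec.get("name", "material")),
        composition=ElementComposition.from_dict(spec["fractions"]),
        mass_density=float(spec["mass_density"]),
    )


def load_materials(path: str | Path) -> dict[str, Material]:
    """Load a YAML/JSON mapping of material name -> {fractions, mass_density}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = {}
    for name, spec in raw.items():
        spec = dict(spec)
        spec.setdefault("name", name)
        out[name] = material_from_dict(spec)
    return out
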