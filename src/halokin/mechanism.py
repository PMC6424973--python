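"""Kinetic schemes for two-cycle enzymatic halogenation.

PltM-type FAD-dependent halogenases install up to two halogens on a
phenolic substrate in two catalytic cycles: the free enzyme binds the
substrate, halogenates it once, releases the mono-halogenated product,
then rebinds the mono product and halogenates it a second time.

Two topologies are supported:

* ``sequential`` — a symmetric substrate gives a single mono-halogenated
  intermediate::

      E + S  <=>[ka1, kd1]  ES   -->[kcat1]  E + P1
      E + P1 <=>[ka2, kd2]  EP1  -->[kcat2]  E + P2

* ``branched`` — an asymmetric substrate gives two distinguishable mono
  products (labelled ``a`` and ``b``) from a single enzyme–substrate
  complex that partitions between two catalytic channels; both branches
  converge on the same di-halogenated product::

      E + S   <=>[ka1, kd1]    ES    -->[kcat1a] E + P1a
                               ES    -->[kcat1b] E + P1b
      E + P1a <=>[ka2a, kd2a]  EP1a  -->[kcat2a] E + P2
      E + P1b <=>[ka2b, kd2b]  EP1b  -->[kcat2b] E + P2

Units are fixed package-wide: time in min, concentrations in µM, so
``ka`` is µM⁻¹ min⁻¹ and ``kd``/``kcat`` are min⁻¹.

The halide, FAD, NADPH and the flavin-reductase/GDH regeneration system
are held in large excess or recycled in the assay and are not state
variables; the scheme contains only enzyme- and substrate-derived
species.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field, replace

__all__ = [
    "Species",
    "Reaction",
    "CycleRates",
    "RateParameters",
    "MacroscopicParameters",
    "KineticScheme",
    "SchemeError",
    "km_of",
    "microscopic_from_macroscopic",
    "build_sequential_scheme",
    "build_branched_scheme",
    "load_scheme_config",
]

#: default association rate constant (µM⁻¹ min⁻¹) used when instantiating
#: microscopic constants from (kcat, Km); progress-curve fractions do not
#: constrain ka, so it is fixed, not fitted.
DEFAULT_KA = 100.0

_ROLES = {"enzyme", "substrate", "mono_product", "di_product", "complex"}


class SchemeError(ValueError):
    """Invalid kinetic-scheme definition or parameterization."""


@dataclass(frozen=True)
class Species:
    """A chemical species of the mechanism.

    ``substrate_moiety_count`` counts substrate-derived aromatic cores the
    species carries (0 for free enzyme, 1 for S, P1, P2 and every complex).
    ``cargo`` names, for a complex, the observable class of its bound
    material (e.g. ES carries substrate, EP1 carries mono product); the
    HPLC quench/extraction releases bound material, so fractions assign a
    complex to its cargo's class.
    """

    name: str
    role: str
    substrate_moiety_count: int
    cargo: str | None = None

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise SchemeError(f"unknown species role {self.role!r}")
        if self.role == "enzyme" and self.substrate_moiety_count != 0:
            raise SchemeError("free enzyme carries no substrate moiety")
        if self.role == "complex" and self.substrate_moiety_count != 1:
            raise SchemeError("every complex carries exactly one substrate moiety")
        if self.role == "complex" and self.cargo is None:
            raise SchemeError(f"complex {self.name!r} must declare its cargo class")

    @property
    def contains_enzyme(self) -> bool:
        return self.role in ("enzyme", "complex")


@dataclass(frozen=True)
class Reaction:
    """One elementary mass-action step.

    Association steps are bimolecular (two reactants, one product);
    dissociation and catalytic steps are unimolecular.
    """

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate_label: str
    kind: str  # association | dissociation | catalytic

    def __post_init__(self) -> None:
        if self.kind == "association":
            if len(self.reactants) != 2 or len(self.products) != 1:
                raise SchemeError(f"association {self.rate_label}: must be 2 -> 1")
        elif self.kind in ("dissociation", "catalytic"):
            if len(self.reactants) != 1:
                raise SchemeError(f"{self.kind} {self.rate_label}: must be unimolecular")
        else:
            raise SchemeError(f"unknown reaction kind {self.kind!r}")


@dataclass(frozen=True)
class CycleRates:
    """Microscopic rate constants of one catalytic cycle (or branch)."""

    ka: float  # µM⁻¹ min⁻¹
    kd: float  # min⁻¹
    kcat: float  # min⁻¹

    def __post_init__(self) -> None:
        for name in ("ka", "kd", "kcat"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise SchemeError(f"rate constant {name} must be finite and >= 0, got {v}")
        if self.ka <= 0:
            raise SchemeError("ka must be > 0 for an active cycle")

    @property
    def km(self) -> float:
        return km_of(self.kd, self.kcat, self.ka)


@dataclass(frozen=True)
class RateParameters:
    """Microscopic constants per cycle.

    Keys are ``"1", "2"`` for the sequential topology and
    ``"1a", "1b", "2a", "2b"`` for the branched one.  The two first-cycle
    branches share a single enzyme–substrate complex, so ``1a`` and ``1b``
    must carry identical ``ka``/``kd`` and differ only in ``kcat``.
    """

    cycles: dict[str, CycleRates] = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = set(self.cycles)
        if keys == {"1", "2"}:
            return
        if keys == {"1a", "1b", "2a", "2b"}:
            a, b = self.cycles["1a"], self.cycles["1b"]
            if not (math.isclose(a.ka, b.ka) and math.isclose(a.kd, b.kd)):
                raise SchemeError(
                    "branches 1a/1b share one ES complex: ka and kd must match"
                )
            return
        raise SchemeError(
            f"cycle keys must be {{1,2}} or {{1a,1b,2a,2b}}, got {sorted(keys)}"
        )

    @property
    def topology(self) -> str:
        return "sequential" if "1" in self.cycles else "branched"


@dataclass(frozen=True)
class MacroscopicParameters:
    """Steady-state constants of one step: kcat (min⁻¹), Km (µM)."""

    kcat: float
    km: float

    def __post_init__(self) -> None:
        if self.kcat < 0 or self.km <= 0:
            raise SchemeError("kcat must be >= 0 and Km > 0")

    @property
    def efficiency(self) -> float:
        """Catalytic efficiency kcat/Km (min⁻¹ µM⁻¹)."""
        return self.kcat / self.km


def km_of(k_d: float, k_cat: float, k_a: float) -> float:
    """Michaelis constant (µM) from microscopic constants, (kd + kcat)/ka."""
    if k_a <= 0:
        raise SchemeError(f"invalid parameterization: ka must be > 0, got {k_a}")
    if k_d < 0 or k_cat < 0:
        raise SchemeError("kd and kcat must be >= 0")
    return (k_d + k_cat) / k_a


def microscopic_from_macroscopic(
    k_cat: float, k_m: float, k_a_fixed: float = DEFAULT_KA
) -> CycleRates:
    """Instantiate microscopic constants from (kcat, Km) at a fixed ka.

    Progress-curve fractions determine only the macroscopic constants, so
    the association rate is an assumption, not an estimate.  ``ka_fixed``
    must be at least kcat/Km, otherwise the implied dissociation rate
    kd = ka·Km − kcat would be negative.
    """
    if k_a_fixed <= 0:
        raise SchemeError("ka_fixed must be > 0")
    if k_cat < 0 or k_m <= 0:
        raise SchemeError("kcat must be >= 0 and Km > 0")
    kd = k_a_fixed * k_m - k_cat
    if kd < 0:
        raise SchemeError(
            f"ka_fixed={k_a_fixed} is below the catalytic efficiency "
            f"kcat/Km={k_cat / k_m:.4g} µM⁻¹min⁻¹; choose a larger ka_fixed"
        )
    return CycleRates(ka=k_a_fixed, kd=kd, kcat=k_cat)


@dataclass(frozen=True)
class KineticScheme:
    """Species + mass-action reactions + rate constants of one mechanism."""

    species: tuple[Species, ...]
    reactions: tuple[Reaction, ...]
    parameters: RateParameters
    topology: str
    rate_constants: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise SchemeError("species names must be unique")
        if self.topology == "sequential":
            if len(self.species) != 6 or len(self.reactions) != 6:
                raise SchemeError("sequential scheme must have 6 species, 6 reactions")
        elif self.topology == "branched":
            if len(self.species) != 8 or len(self.reactions) != 10:
                raise SchemeError("branched scheme must have 8 species, 10 reactions")
        else:
            raise SchemeError(f"unknown topology {self.topology!r}")
        by_name = self.species_by_name
        for rxn in self.reactions:
            for n in rxn.reactants + rxn.products:
                if n not in by_name:
                    raise SchemeError(f"reaction {rxn.rate_label}: unknown species {n!r}")
            if rxn.rate_label not in self.rate_constants:
                raise SchemeError(f"rate label {rxn.rate_label!r} has no constant")
            # enzyme-atom and substrate-moiety balance, checked symbolically
            for attr, what in (
                ("contains_enzyme", "enzyme"),
                ("substrate_moiety_count", "substrate moiety"),
            ):
                lhs = sum(int(getattr(by_name[n], attr)) for n in rxn.reactants)
                rhs = sum(int(getattr(by_name[n], attr)) for n in rxn.products)
                if lhs != rhs:
                    raise SchemeError(
                        f"reaction {rxn.rate_label}: {what} not balanced ({lhs} vs {rhs})"
                    )

    @property
    def species_by_name(self) -> dict[str, Species]:
        return {s.name: s for s in self.species}

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    def species_index(self, name: str) -> int:
        return self.species_names.index(name)

    @property
    def observable_classes(self) -> tuple[str, ...]:
        """Substrate-derived classes quantified by HPLC (S, mono(s), di)."""
        if self.topology == "sequential":
            return ("S", "P1", "P2")
        return ("S", "P1a", "P1b", "P2")

    def class_of(self, species_name: str) -> str | None:
        """Observable class a species' substrate moiety reports to (None for E)."""
        sp = self.species_by_name[species_name]
        if sp.substrate_moiety_count == 0:
            return None
        return sp.cargo if sp.role == "complex" else sp.name

    def with_parameters(self, params: RateParameters) -> "KineticScheme":
        """Same topology, new rate constants (used by the fitter)."""
        builder = build_sequential_scheme if self.topology == "sequential" else build_branched_scheme
        return builder(params)

    def macroscopic(self) -> dict[str, MacroscopicParameters]:
        """Per-step (kcat, Km).  The branched first cycle reports one shared
        Km = (kd1 + kcat1a + kcat1b)/ka1 — the Michaelis constant of the
        single partitioning complex — under each branch's key."""
        c = self.parameters.cycles
        if self.topology == "sequential":
            return {k: MacroscopicParameters(c[k].kcat, c[k].km) for k in ("1", "2")}
        km1 = (c["1a"].kd + c["1a"].kcat + c["1b"].kcat) / c["1a"].ka
        return {
            "1a": MacroscopicParameters(c["1a"].kcat, km1),
            "1b": MacroscopicParameters(c["1b"].kcat, km1),
            "2a": MacroscopicParameters(c["2a"].kcat, c["2a"].km),
            "2b": MacroscopicParameters(c["2b"].kcat, c["2b"].km),
        }


def _require_cycles(params: RateParameters, keys: set[str], topology: str) -> None:
    if set(params.cycles) != keys:
        raise SchemeError(
            f"{topology} scheme needs cycles {sorted(keys)}, got {sorted(params.cycles)}"
        )


def build_sequential_scheme(params: RateParameters) -> KineticScheme:
    """Two-cycle mechanism with a single mono-halogenated intermediate."""
    _require_cycles(params, {"1", "2"}, "sequential")
    c1, c2 = params.cycles["1"], params.cycles["2"]
    species = (
        Species("E", "enzyme", 0),
        Species("S", "substrate", 1),
        Species("ES", "complex", 1, cargo="S"),
        Species("P1", "mono_product", 1),
        Species("EP1", "complex", 1, cargo="P1"),
        Species("P2", "di_product", 1),
    )
    reactions = (
        Reaction(("E", "S"), ("ES",), "ka1", "association"),
        Reaction(("ES",), ("E", "S"), "kd1", "dissociation"),
        Reaction(("ES",), ("E", "P1"), "kcat1", "catalytic"),
        Reaction(("E", "P1"), ("EP1",), "ka2", "association"),
        Reaction(("EP1",), ("E", "P1"), "kd2", "dissociation"),
        Reaction(("EP1",), ("E", "P2"), "kcat2", "catalytic"),
    )
    rates = {
        "ka1": c1.ka, "kd1": c1.kd, "kcat1": c1.kcat,
        "ka2": c2.ka, "kd2": c2.kd, "kcat2": c2.kcat,
    }
    return KineticScheme(species, reactions, params, "sequential", rates)


def build_branched_scheme(params: RateParameters) -> KineticScheme:
    """Branched mechanism: one ES complex partitioning into two mono
    products that both proceed to the same di-halogenated product."""
    _require_cycles(params, {"1a", "1b", "2a", "2b"}, "branched")
    c = params.cycles
    species = (
        Species("E", "enzyme", 0),
        Species("S", "substrate", 1),
        Species("ES", "complex", 1, cargo="S"),
        Species("P1a", "mono_product", 1),
        Species("P1b", "mono_product", 1),
        Species("EP1a", "complex", 1, cargo="P1a"),
        Species("EP1b", "complex", 1, cargo="P1b"),
        Species("P2", "di_product", 1),
    )
    reactions = (
        Reaction(("E", "S"), ("ES",), "ka1", "association"),
        Reaction(("ES",), ("E", "S"), "kd1", "dissociation"),
        Reaction(("ES",), ("E", "P1a"), "kcat1a", "catalytic"),
        Reaction(("ES",), ("E", "P1b"), "kcat1b", "catalytic"),
        Reaction(("E", "P1a"), ("EP1a",), "ka2a", "association"),
        Reaction(("EP1a",), ("E", "P1a"), "kd2a", "dissociation"),
        Reaction(("EP1a",), ("E", "P2"), "kcat2a", "catalytic"),
        Reaction(("E", "P1b"), ("EP1b",), "ka2b", "association"),
        Reaction(("EP1b",), ("E", "P1b"), "kd2b", "dissociation"),
        Reaction(("EP1b",), ("E", "P2"), "kcat2b", "catalytic"),
    )
    rates = {
        "ka1": c["1a"].ka, "kd1": c["1a"].kd,
        "kcat1a": c["1a"].kcat, "kcat1b": c["1b"].kcat,
        "ka2a": c["2a"].ka, "kd2a": c["2a"].kd, "kcat2a": c["2a"].kcat,
        "ka2b": c["2b"].ka, "kd2b": c["2b"].kd, "kcat2b": c["2b"].kcat,
    }
    return KineticScheme(species, reactions, params, "branched", rates)


def scheme_from_macroscopic(
    topology: str,
    steps: dict[str, MacroscopicParameters],
    ka_fixed: float = DEFAULT_KA,
) -> KineticScheme:
    """Build a scheme directly from per-step (kcat, Km) at a fixed ka.

    For the branched topology the first-cycle Km is shared between
    branches; ``steps`` carries keys ``1a, 1b, 2a, 2b`` and the Km of
    ``1a``/``1b`` must agree.
    """
    if topology == "sequential":
        cycles = {
            k: microscopic_from_macroscopic(steps[k].kcat, steps[k].km, ka_fixed)
            for k in ("1", "2")
        }
        return build_sequential_scheme(RateParameters(cycles))
    if topology != "branched":
        raise SchemeError(f"unknown topology {topology!r}")
    m1a, m1b = steps["1a"], steps["1b"]
    if not math.isclose(m1a.km, m1b.km, rel_tol=1e-9):
        raise SchemeError("branched first-cycle Km is shared; 1a and 1b must match")
    kd1 = ka_fixed * m1a.km - m1a.kcat - m1b.kcat
    if kd1 < 0:
        raise SchemeError(
            "ka_fixed below the combined first-cycle efficiency; choose a larger ka_fixed"
        )
    shared = dict(ka=ka_fixed, kd=kd1)
    cycles = {
        "1a": CycleRates(kcat=m1a.kcat, **shared),
        "1b": CycleRates(kcat=m1b.kcat, **shared),
        "2a": microscopic_from_macroscopic(steps["2a"].kcat, steps["2a"].km, ka_fixed),
        "2b": microscopic_from_macroscopic(steps["2b"].kcat, steps["2b"].km, ka_fixed),
    }
    return build_branched_scheme(RateParameters(cycles))


def load_scheme_config(path) -> KineticScheme:
    """Read a scheme from a TOML config.

    Layout::

        [design]
        topology = "sequential"        # or "branched"

        [parameters.cycle1]
        kcat = 2.3     # min^-1
        km = 0.076     # uM
        ka = 100.0     # uM^-1 min^-1, optional

        [parameters.cycle2]
        kcat = 0.40
        km = 0.11

    The branched topology uses sections ``cycle1``/``cycle1b`` (first-cycle
    branches a and b; km shared, taken from cycle1) and ``cycle2``/``cycle2b``.
    """
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    try:
        topology = cfg["design"]["topology"]
        pars = cfg["parameters"]
    except KeyError as exc:
        raise SchemeError(f"scheme config missing section/key: {exc}") from exc

    def step(section: str, km_from: str | None = None) -> MacroscopicParameters:
        if section not in pars:
            raise SchemeError(f"scheme config missing [parameters.{section}]")
        d = pars[section]
        km = d.get("km", pars[km_from]["km"] if km_from else None)
        if "kcat" not in d or km is None:
            raise SchemeError(f"[parameters.{section}] needs kcat and km")
        return MacroscopicParameters(float(d["kcat"]), float(km))

    ka = float(pars.get("cycle1", {}).get("ka", DEFAULT_KA))
    if topology == "sequential":
        steps = {"1": step("cycle1"), "2": step("cycle2")}
    elif topology == "branched":
        steps = {
            "1a": step("cycle1"),
            "1b": step("cycle1b", km_from="cycle1"),
            "2a": step("cycle2"),
            "2b": step("cycle2b"),
        }
    else:
        raise SchemeError(f"unknown topology {topology!r}")
    return scheme_from_macroscopic(topology, steps, ka_fixed=ka)
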