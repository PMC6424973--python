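"""Halogenation-product identification: enumeration, masses, isotopes, XIC.

PltM installs at most two halogens per substrate (the helical C-terminal
region sterically excludes a third), drawing Cl, Br or I from the halide
pool; fluoride is accepted as an input but never yields product.  LC-MS
identification rests on three computations reproduced here:

* exact monoisotopic mass of each candidate product and its [M−H]⁻ /
  [M+H]⁺ adduct m/z;
* the chlorine/bromine isotope envelope (³⁵Cl/³⁷Cl and ⁷⁹Br/⁸¹Br
  binomials), the M/M+2 ratio being diagnostic for halogen count;
* extracted-ion-chromatogram (XIC) matching of observed m/z values
  against candidates within a ± tolerance window (±0.05 Da, or ±0.005 Da
  for the high-resolution assay) inside the 80–600 m/z instrument range.

A rule engine distills the observed regiochemistry: halogenation goes
ortho to hydroxyl/amino groups but not between two of them, unless a
methyl or styrenyl substituent sits meta to both hydroxyls, in which
case the between position is chlorinated preferentially.
"""

from __future__ import annotations

import itertools
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "RingSubstrate",
    "HalogenationProduct",
    "IsotopePattern",
    "AdductIon",
    "parse_formula",
    "formula_to_hill",
    "monoisotopic_mass",
    "adduct_mz",
    "enumerate_halogenation_states",
    "isotope_pattern",
    "xic_match",
    "predict_positions",
]

# ---------------------------------------------------------------------------
# atomic data, pinned from the IUPAC/CIAAW 2021 tables of atomic masses and
# isotopic abundances (Prohaska et al., Pure Appl. Chem. 94 (2022) 573)

#: monoisotopic (most abundant isotope) atomic masses, Da
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503,
    "C": 12.0,
    "N": 14.00307401,
    "O": 15.99491462,
    "S": 31.97207117,
    "Cl": 34.96885269,
    "Br": 78.91833760,
    "I": 126.90447190,
    "F": 18.99840316,
}

#: proton mass (electron-corrected), Da: [M−H]⁻ = M − this, [M+H]⁺ = M + this
PROTON_MASS = 1.00727646

#: two-isotope elements driving the halogen envelope: (heavy−light mass
#: difference in Da, light-isotope fractional abundance)
_TWO_ISOTOPE: dict[str, tuple[float, float]] = {
    "Cl": (36.96590260 - 34.96885269, 0.7576),  # 35Cl/37Cl
    "Br": (80.91628970 - 78.91833760, 0.5069),  # 79Br/81Br
}

#: carbon, for the full-envelope mode: 13C−12C shift and 12C abundance
_C13_SHIFT = 13.00335484 - 12.0
_C12_ABUNDANCE = 0.9893

HALIDES = ("F", "Cl", "Br", "I")

_ACTIVATING = {"OH", "NH2"}
_META_DONORS = {"CH3", "styrenyl(4-hydroxy)"}  # trigger the between exception

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-notation molecular formula string into element counts."""
    counts: Counter[str] = Counter()
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        pos = m.end()
        counts[m.group(1)] += int(m.group(2) or 1)
    if pos != len(formula) or not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    return dict(counts)


def formula_to_hill(formula: dict[str, int]) -> str:
    """Element counts to a Hill-notation string (C, H, then alphabetical)."""
    parts = []
    rest = sorted(e for e in formula if e not in ("C", "H"))
    for el in ["C", "H"] + rest:
        n = formula.get(el, 0)
        if n:
            parts.append(el + (str(n) if n > 1 else ""))
    return "".join(parts)


def monoisotopic_mass(formula: dict[str, int]) -> float:
    """Monoisotopic mass (Da) as the sum of standard atomic masses."""
    mass = 0.0
    for element, n in formula.items():
        if element not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element {element!r}")
        if n < 0:
            raise ValueError(f"negative count for element {element!r}")
        mass += MONOISOTOPIC_MASS[element] * n
    return mass


@dataclass(frozen=True)
class AdductIon:
    """An ionized species: [M−H]⁻ (negative mode) or [M+H]⁺ (positive)."""

    mode: str  # "negative" | "positive"
    mz: float

    def __post_init__(self) -> None:
        if self.mode not in ("negative", "positive"):
            raise ValueError(f"unknown ionization mode {self.mode!r}")
        if self.mz <= 0:
            raise ValueError("m/z must be positive")


@dataclass(frozen=True)
class RingSubstrate:
    """Abstract six-position aromatic ring plus whole-molecule formula.

    ``positions`` maps locants 1–6 to substituent labels; unlisted
    positions are hydrogen.  Halogenatable positions are those carrying H.
    The map is an abstraction sufficient for single-ring regiochemistry;
    fused or second rings are outside its scope.
    """

    name: str
    positions: dict[int, str]
    formula: dict[str, int]

    def __post_init__(self) -> None:
        full = {p: self.positions.get(p, "H") for p in range(1, 7)}
        if set(self.positions) - set(range(1, 7)):
            raise ValueError("ring positions must be locants 1..6")
        if any(n < 0 for n in self.formula.values()):
            raise ValueError("formula counts must be non-negative")
        object.__setattr__(self, "positions", full)

    def __hash__(self) -> int:  # dict fields defeat the generated hash
        return hash(
            (self.name, tuple(sorted(self.positions.items())), tuple(sorted(self.formula.items())))
        )

    def substituent(self, position: int) -> str:
        return self.positions[position]

    @property
    def halogenatable_positions(self) -> tuple[int, ...]:
        return tuple(p for p in range(1, 7) if self.positions[p] == "H")

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self.formula)


@dataclass(frozen=True)
class HalogenationProduct:
    """A halogenated derivative: parent ring + halogen counts (≤ 2 total).

    Each halogenation replaces one ring hydrogen (+X, −H), so the derived
    formula has ``parent H − total halogens`` hydrogens.
    """

    parent: RingSubstrate
    halogens: tuple[tuple[str, int], ...]  # sorted ((halide, count), ...)
    positions: frozenset[int] | None = None

    def __post_init__(self) -> None:
        counts = dict(self.halogens)
        if any(h not in HALIDES for h in counts):
            raise ValueError(f"unknown halide in {counts}")
        if any(n < 1 for n in counts.values()):
            raise ValueError("halogen counts must be >= 1")
        if self.total_halogens > 2:
            raise ValueError("at most two halogens can be installed")
        object.__setattr__(self, "halogens", tuple(sorted(counts.items())))

    def __hash__(self) -> int:
        return hash((self.parent, self.halogens, self.positions))

    @property
    def halogen_counts(self) -> dict[str, int]:
        return dict(self.halogens)

    @property
    def total_halogens(self) -> int:
        return sum(n for _, n in self.halogens)

    @property
    def formula(self) -> dict[str, int]:
        f = Counter(self.parent.formula)
        total = self.total_halogens
        if f["H"] < total:
            raise ValueError("parent has too few hydrogens to substitute")
        f["H"] -= total
        if f["H"] == 0:
            del f["H"]
        for hal, n in self.halogens:
            f[hal] += n
        return dict(f)

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self.formula)

    @property
    def label(self) -> str:
        hal = "".join(f"{h}{n if n > 1 else ''}" for h, n in self.halogens)
        return f"{hal}-{self.parent.name}"


def adduct_mz(product: HalogenationProduct | RingSubstrate, mode: str) -> AdductIon:
    """[M−H]⁻ or [M+H]⁺ m/z of a product (or the parent substrate)."""
    m = product.mass
    if mode == "negative":
        return AdductIon(mode, m - PROTON_MASS)
    if mode == "positive":
        return AdductIon(mode, m + PROTON_MASS)
    raise ValueError(f"unknown ionization mode {mode!r}")


def enumerate_halogenation_states(
    substrate: RingSubstrate,
    pool: set[str] | frozenset[str],
    max_total: int = 2,
    per_halide_caps: dict[str, int] | None = None,
    forbidden_combinations: set[frozenset[str]] | None = None,
) -> set[HalogenationProduct]:
    """All mono- and di-halogenated states reachable from a halide pool.

    Every multiset of 1..max_total halides drawn from the pool is a
    candidate; the unmodified substrate is excluded.  Fluoride never
    yields product.  ``per_halide_caps`` limits the count of a given
    halide per product and ``forbidden_combinations`` removes specific
    hetero-pairs; both encode observed, substrate-specific constraints
    (e.g. bromination of phloroglucinol stops at the mono product) for
    which no mechanism is modelled.
    """
    if max_total > 2:
        raise ValueError("the enzyme installs at most two halogens")
    unknown = set(pool) - set(HALIDES)
    if unknown:
        raise ValueError(f"unknown halide symbol(s): {sorted(unknown)}")
    caps = per_halide_caps or {}
    forbidden = forbidden_combinations or set()
    productive = sorted(set(pool) - {"F"})

    out: set[HalogenationProduct] = set()
    for size in range(1, max_total + 1):
        for combo in itertools.combinations_with_replacement(productive, size):
            counts = Counter(combo)
            if any(counts[h] > caps.get(h, max_total) for h in counts):
                continue
            if frozenset(counts) in forbidden:
                continue
            out.add(HalogenationProduct(substrate, tuple(sorted(counts.items()))))
    return out


@dataclass(frozen=True)
class IsotopePattern:
    """Isotope envelope as (mass shift from monoisotopic peak, abundance).

    Abundances are normalized so the base (most intense) peak is 100.
    """

    peaks: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError("pattern must contain at least one peak")
        if not any(abs(a - 100.0) < 1e-9 for _, a in self.peaks):
            raise ValueError("base peak (abundance 100) missing")
        if any(a <= 0 or a > 100 + 1e-9 for _, a in self.peaks):
            raise ValueError("abundances must lie in (0, 100]")
        if any(s < 0 for s, _ in self.peaks):
            raise ValueError("mass shifts must be non-negative")

    def abundance_at(self, nominal_shift: int, window: float = 0.5) -> float:
        """Abundance of the peak nearest an integer shift (0 if absent)."""
        for s, a in self.peaks:
            if abs(s - nominal_shift) < window:
                return a
        return 0.0


def _convolve(
    peaks: list[tuple[float, float]], shift: float, p_light: float, n: int
) -> list[tuple[float, float]]:
    """Convolve a peak list with n atoms of a two-isotope element."""
    from math import comb

    out: dict[float, float] = {}
    for s0, a0 in peaks:
        for k in range(n + 1):
            w = comb(n, k) * p_light ** (n - k) * (1 - p_light) ** k
            s = round(s0 + k * shift, 6)
            out[s] = out.get(s, 0.0) + a0 * w
    return sorted(out.items())


def isotope_pattern(
    product: HalogenationProduct, mode: str = "halogens_only"
) -> IsotopePattern:
    """Isotope envelope of a product.

    ``halogens_only`` convolves the ³⁵Cl/³⁷Cl and ⁷⁹Br/⁸¹Br binomials
    (iodine and fluorine are monoisotopic); ``full`` additionally folds
    in ¹³C at natural abundance.  Peaks within 0.01 Da are merged with
    abundance-weighted mean shift.
    """
    if mode not in ("halogens_only", "full"):
        raise ValueError(f"unknown isotope mode {mode!r}")
    formula = product.formula
    peaks: list[tuple[float, float]] = [(0.0, 1.0)]
    for element, (shift, p_light) in _TWO_ISOTOPE.items():
        n = formula.get(element, 0)
        if n:
            peaks = _convolve(peaks, shift, p_light, n)
    if mode == "full" and formula.get("C", 0):
        peaks = _convolve(peaks, _C13_SHIFT, _C12_ABUNDANCE, formula["C"])

    # merge near-coincident peaks (e.g. Cl and Br M+2 shifts differ by ~1 mDa)
    merged: list[tuple[float, float]] = []
    for s, a in sorted(peaks):
        if merged and abs(s - merged[-1][0]) < 0.01:
            s_prev, a_prev = merged[-1]
            tot = a_prev + a
            merged[-1] = ((s_prev * a_prev + s * a) / tot, tot)
        else:
            merged.append((s, a))
    base = max(a for _, a in merged)
    scaled = tuple(
        (s, 100.0 * a / base) for s, a in merged if a / base > 1e-6
    )
    return IsotopePattern(scaled)


def xic_match(
    observed_mz,
    candidates: set[HalogenationProduct],
    mode: str,
    tolerance: float,
    mz_range: tuple[float, float] = (80.0, 600.0),
) -> list[tuple[float, HalogenationProduct, float]]:
    """Assign observed m/z values to candidate products.

    Each observed value is matched to every candidate whose adduct m/z
    lies within the closed interval [m − tolerance, m + tolerance];
    candidates whose adduct falls outside the instrument m/z range are
    never assigned.  Ambiguous matches are all reported, not resolved.
    Returns (observed_mz, product, candidate_mz) triples.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if not candidates:
        warnings.warn("empty candidate set: no assignments possible", stacklevel=2)
        return []
    in_range = [
        (c, adduct_mz(c, mode).mz)
        for c in candidates
        if mz_range[0] <= adduct_mz(c, mode).mz <= mz_range[1]
    ]
    import math

    assignments = []
    for obs in observed_mz:
        for cand, mz in in_range:
            diff = abs(obs - mz)
            # closed interval, robust to rounding at exactly ±tolerance
            if diff <= tolerance or math.isclose(diff, tolerance, rel_tol=1e-9):
                assignments.append((float(obs), cand, mz))
    return assignments


# ---------------------------------------------------------------------------
# regiochemistry rule engine


def _ring_automorphisms(substrate: RingSubstrate):
    """Rotations/reflections of the hexagon preserving the substituent map."""
    def rot(p, k):
        return (p - 1 + k) % 6 + 1

    def refl(p, axis):
        return (axis - (p - 1)) % 6 + 1

    maps = [lambda p, k=k: rot(p, k) for k in range(6)]
    maps += [lambda p, a=a: refl(p, a) for a in range(6)]
    subst = substrate.positions
    return [m for m in maps if all(subst[m(p)] == subst[p] for p in range(1, 7))]


def predict_positions(
    substrate: RingSubstrate, n_halogens: int
) -> set[frozenset[int]]:
    """Predicted halogenation position sets under the observed site rules.

    Rules, in order:

    1. A nitro-substituted ring is not halogenated → empty set.
    2. Candidates are ring H positions ortho (adjacent) to at least one
       activating group (OH or NH₂); score = number of such neighbours.
    3. A candidate flanked by two activating groups ("between") is
       excluded whenever any non-between candidate exists.
    4. Exception: a methyl or styrenyl group meta to two hydroxyls
       re-admits the position between those hydroxyls with top priority.
    5. The ``n_halogens`` best-scoring positions are taken; ties break
       toward lower locants, and symmetry-equivalent position sets are
       collapsed to their lowest-locant representative.
    """
    if n_halogens not in (1, 2):
        raise ValueError("the enzyme installs one or two halogens, never more")
    subst = substrate.positions
    if "NO2" in subst.values():
        return set()
    activating = {p for p, s in subst.items() if s in _ACTIVATING}
    if not activating:
        raise ValueError(f"{substrate.name}: no activating group (OH/NH2) on the ring")

    def neighbours(p: int) -> tuple[int, int]:
        return ((p - 2) % 6 + 1, p % 6 + 1)

    score = {}
    between = set()
    for p in substrate.halogenatable_positions:
        nb = neighbours(p)
        s = sum(1 for q in nb if q in activating)
        if s:
            score[p] = s
        if s == 2:
            between.add(p)

    # meta exception: carbon donor at p, hydroxyls at both meta positions
    priority = set()
    for p, s in subst.items():
        if s in _META_DONORS:
            meta = {(p + 1) % 6 + 1, (p - 3) % 6 + 1}
            if all(subst[q] == "OH" for q in meta):
                opposite = (p + 2) % 6 + 1  # the position between the two OH
                if subst[opposite] == "H":
                    priority.add(opposite)
                    score[opposite] = score.get(opposite, 2)

    eligible = set(score)
    non_between = eligible - between
    if non_between:
        eligible -= between - priority
    if len(eligible) < n_halogens:
        return set()

    best: set[frozenset[int]] = set()
    best_key = None
    for combo in itertools.combinations(sorted(eligible), n_halogens):
        key = (
            sum(p in priority for p in combo),
            sum(score[p] for p in combo),
        )
        if best_key is None or key > best_key:
            best_key, best = key, {frozenset(combo)}
        elif key == best_key:
            best.add(frozenset(combo))

    # collapse symmetry-equivalent sets to the lowest-locant representative
    autos = _ring_automorphisms(substrate)
    canonical: set[frozenset[int]] = set()
    for combo in best:
        images = {frozenset(m(p) for p in combo) for m in autos}
        images &= best
        canonical.add(min(images, key=lambda s: tuple(sorted(s))))
    return canonical
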