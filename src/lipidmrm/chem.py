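"""Compositional algebra for shotgun lipidomics.

Builds elemental formulas for glycerophospholipid species identified at the
sum-composition level (class, total acyl carbons, total double bonds),
computes monoisotopic masses and adduct/fragment m/z values from a pinned
atomic-mass table, and derives the class-specific MRM transitions:

* PC  — [M+H]+ precursor scanned for the phosphocholine fragment cation
* PE  — [M+H]+ with neutral loss of phosphoethanolamine
* PI  — [M−H]− precursor scanned for the dehydrated inositol-phosphate anion
* PS  — [M−H]− with neutral loss of dehydrated serine
* CL  — [M−2H]2− precursor scanned for fatty-acid carboxylate anions

All printed transition constants (184.07, 141.02, 241.01, 87.03, and the
one-decimal GC-MS sterol channels) are reproduced from elemental
compositions; no m/z constant is hard-coded in any class rule.
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

__all__ = [
    "PROTON_MASS",
    "ELECTRON_MASS",
    "Formula",
    "Adduct",
    "LipidClass",
    "LipidSpecies",
    "Transition",
    "InvalidSpeciesError",
    "UnsupportedClassError",
    "isotope_table",
    "monoisotopic_mass",
    "ion_mz",
    "ionic_mz",
    "compose_formula",
    "transition_for",
    "default_classes",
    "make_species",
    "parse_species_id",
    "transitions_to_frame",
    "round_half_up",
    "truncate",
]

# Pinned charge-carrier masses (Da). The proton mass is m(1H) - m(e-), so
# protonation/deprotonation needs no separate electron term; radical cations
# ([M]+. in GC-EI) subtract one electron mass explicitly.
PROTON_MASS = 1.007276
ELECTRON_MASS = 0.000549


class InvalidSpeciesError(ValueError):
    """A species whose composition bookkeeping goes negative."""


class UnsupportedClassError(KeyError):
    """A lipid class with no transition (or correction) rule."""


# ---------------------------------------------------------------------------
# pinned isotope table
# ---------------------------------------------------------------------------

def _load_isotope_table() -> dict[str, list[tuple[int, float, float]]]:
    table: dict[str, list[tuple[int, float, float]]] = {}
    text = resources.files("lipidmrm.data").joinpath("isotopes.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        el, nominal, mass, abundance = line.split("\t")
        table.setdefault(el, []).append((int(nominal), float(mass), float(abundance)))
    for el in table:
        table[el].sort()
    return table


_ISOTOPES = _load_isotope_table()
#: monoisotopic (lightest-isotope) mass per element
_MONO = {el: rows[0][1] for el, rows in _ISOTOPES.items()}


def isotope_table() -> dict[str, list[tuple[int, float, float]]]:
    """The pinned (nominal, mass, abundance) rows per element symbol."""
    return {el: list(rows) for el, rows in _ISOTOPES.items()}


# ---------------------------------------------------------------------------
# printed-value conventions
# ---------------------------------------------------------------------------

def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero, as printed transition lists do."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def truncate(x: float, ndigits: int = 1) -> float:
    """Truncate toward zero, the convention of one-decimal GC-MS channels."""
    scale = 10**ndigits
    return math.trunc(x * scale) / scale


# ---------------------------------------------------------------------------
# elemental formulas
# ---------------------------------------------------------------------------

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class Formula:
    """An element -> count map with non-negative counts.

    Addition and subtraction are element-wise; subtraction that would drive
    any count negative raises :class:`InvalidSpeciesError`, which is how
    impossible species compositions surface.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: dict[str, int] | None = None):
        clean = {}
        for el, n in (counts or {}).items():
            if el not in _ISOTOPES:
                raise KeyError(f"unknown element symbol: {el!r}")
            if n < 0:
                raise InvalidSpeciesError(f"negative count for {el}: {n}")
            if n:
                clean[el] = int(n)
        self._counts = clean

    @classmethod
    def parse(cls, text: str) -> "Formula":
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_RE.finditer(text):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r}")
            pos = m.end()
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(counts)

    def __getitem__(self, el: str) -> int:
        return self._counts.get(el, 0)

    def items(self):
        return self._counts.items()

    def __add__(self, other: "Formula") -> "Formula":
        counts = dict(self._counts)
        for el, n in other.items():
            counts[el] = counts.get(el, 0) + n
        return Formula(counts)

    def __sub__(self, other: "Formula") -> "Formula":
        counts = dict(self._counts)
        for el, n in other.items():
            counts[el] = counts.get(el, 0) - n
            if counts[el] < 0:
                raise InvalidSpeciesError(
                    f"subtraction drives {el} negative: {self} - {other}"
                )
        return Formula(counts)

    def __mul__(self, k: int) -> "Formula":
        return Formula({el: n * k for el, n in self._counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other) -> bool:
        return isinstance(other, Formula) and self._counts == other._counts

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def __bool__(self) -> bool:
        return bool(self._counts)

    @property
    def carbons(self) -> int:
        return self._counts.get("C", 0)

    @property
    def mass(self) -> float:
        return sum(n * _MONO[el] for el, n in self._counts.items())

    def __repr__(self) -> str:  # Hill order
        order = ["C", "H"] + sorted(set(self._counts) - {"C", "H"})
        return "".join(
            f"{el}{self._counts[el] if self._counts[el] != 1 else ''}"
            for el in order
            if el in self._counts
        )


def monoisotopic_mass(formula: Formula) -> float:
    """Sum of lightest-isotope masses from the pinned table, in Da."""
    return formula.mass


# building blocks
WATER = Formula.parse("H2O")
GLYCEROL = Formula.parse("C3H8O3")
PHOSPHORIC_ACID = Formula.parse("H3PO4")
HYDROGEN_ATOM = Formula.parse("H")

HEAD_GROUPS = {
    "choline": Formula.parse("C5H13NO"),
    "ethanolamine": Formula.parse("C2H7NO"),
    "serine": Formula.parse("C3H7NO3"),
    "inositol": Formula.parse("C6H12O6"),
}


def acyl_formula(c: int, d: int, n_chains: int) -> Formula:
    """Combined free fatty acids with c total carbons and d double bonds."""
    if c < n_chains:
        raise InvalidSpeciesError(f"{c} acyl carbons over {n_chains} chains")
    if d < 0 or 2 * d > c:
        raise InvalidSpeciesError(f"impossible unsaturation {c}:{d}")
    return Formula({"C": c, "H": 2 * c - 2 * d, "O": 2 * n_chains})


# ---------------------------------------------------------------------------
# adducts and ions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Adduct:
    """Charge state of the measured ion.

    ``proton_delta`` protons are added (negative = removed); any remaining
    charge imbalance is carried by electron removal/addition (the GC-EI
    molecular radical cation [M]+. has proton_delta 0, charge +1).
    """

    kind: str
    proton_delta: int
    charge: int

    def __post_init__(self):
        if self.charge == 0:
            raise ValueError("adduct charge cannot be zero")


M_PLUS_H = Adduct("[M+H]+", +1, +1)
M_MINUS_H = Adduct("[M-H]-", -1, -1)
M_MINUS_2H = Adduct("[M-2H]2-", -2, -2)
M_RADICAL = Adduct("[M]+.", 0, +1)


def ion_mz(formula: Formula, adduct: Adduct) -> float:
    """m/z of a neutral under the given adduct, with electron accounting."""
    electrons_removed = adduct.charge - adduct.proton_delta
    m = (
        formula.mass
        + adduct.proton_delta * PROTON_MASS
        - electrons_removed * ELECTRON_MASS
    )
    return m / abs(adduct.charge)


def ionic_mz(ionic_formula: Formula, charge: int) -> float:
    """m/z of an ion given as its full ionic atom composition.

    The composition already contains every atom of the ion (e.g. the
    phosphocholine cation C5H15NO4P); only the electron imbalance of the
    charge is corrected.
    """
    if charge == 0:
        raise ValueError("ion charge cannot be zero")
    return (ionic_formula.mass - charge * ELECTRON_MASS) / abs(charge)


# ---------------------------------------------------------------------------
# lipid classes and species
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LipidClass:
    """Structural and MRM scan rules for one glycerophospholipid class."""

    name: str
    head_group: Formula
    polarity: str  # '+' or '-'
    charge: int  # magnitude of the precursor charge
    scan_mode: str  # 'precursor_ion' | 'neutral_loss' | 'acyl_anions'
    n_glycerol: int = 1
    n_phosphate: int = 1
    n_chains: int = 2
    n_phosphoester: int = 2
    #: light Q3 piece: monitored fragment ion (precursor_ion scans) or lost
    #: neutral (neutral_loss scans); None for per-species rules (CL)
    q3_formula: Formula | None = None
    #: signed charge of q3_formula when it is an ion; 0 when a neutral loss
    q3_charge: int = 0

    def __post_init__(self):
        if self.polarity not in "+-":
            raise ValueError("polarity must be '+' or '-'")
        if self.charge < 1:
            raise ValueError("charge magnitude must be >= 1")

    @property
    def adduct(self) -> Adduct:
        if self.polarity == "+":
            return M_PLUS_H if self.charge == 1 else Adduct(f"[M+{self.charge}H]{self.charge}+", self.charge, self.charge)
        if self.charge == 1:
            return M_MINUS_H
        if self.charge == 2:
            return M_MINUS_2H
        return Adduct(f"[M-{self.charge}H]{self.charge}-", -self.charge, -self.charge)


def default_classes() -> dict[str, LipidClass]:
    """The five measured glycerophospholipid classes with their scan rules.

    Q3 compositions are built from head-group neutrals and phosphoric acid,
    never from numeric m/z constants:

    * phosphocholine cation  = choline + H3PO4 - H2O + H  (C5H15NO4P, +1)
    * phosphoethanolamine NL = ethanolamine + H3PO4 - H2O (C2H8NO4P)
    * inositol-phosphate anion = inositol + H3PO4 - 2 H2O - H (C6H10O8P, -1)
    * serine NL              = serine - H2O               (C3H5NO2)
    """
    phosphocholine_cation = (
        HEAD_GROUPS["choline"] + PHOSPHORIC_ACID - WATER + HYDROGEN_ATOM
    )
    pe_neutral_loss = HEAD_GROUPS["ethanolamine"] + PHOSPHORIC_ACID - WATER
    inositol_phosphate_anion = (
        HEAD_GROUPS["inositol"] + PHOSPHORIC_ACID - WATER - WATER - HYDROGEN_ATOM
    )
    ps_neutral_loss = HEAD_GROUPS["serine"] - WATER
    return {
        "PC": LipidClass(
            "PC", HEAD_GROUPS["choline"], "+", 1, "precursor_ion",
            q3_formula=phosphocholine_cation, q3_charge=+1,
        ),
        "PE": LipidClass(
            "PE", HEAD_GROUPS["ethanolamine"], "+", 1, "neutral_loss",
            q3_formula=pe_neutral_loss, q3_charge=0,
        ),
        "PI": LipidClass(
            "PI", HEAD_GROUPS["inositol"], "-", 1, "precursor_ion",
            q3_formula=inositol_phosphate_anion, q3_charge=-1,
        ),
        "PS": LipidClass(
            "PS", HEAD_GROUPS["serine"], "-", 1, "neutral_loss",
            q3_formula=ps_neutral_loss, q3_charge=0,
        ),
        "CL": LipidClass(
            "CL", Formula(), "-", 2, "acyl_anions",
            n_glycerol=3, n_phosphate=2, n_chains=4, n_phosphoester=4,
        ),
    }


DEFAULT_CLASSES = default_classes()


@dataclass(frozen=True)
class LipidSpecies:
    """A sum-composition species: class, chain count, total C and C=C."""

    lipid_class: LipidClass
    c: int
    d: int
    n_chains: int | None = None

    def __post_init__(self):
        object.__setattr__(
            self, "n_chains", self.n_chains or self.lipid_class.n_chains
        )
        if self.c < self.n_chains:
            raise InvalidSpeciesError(
                f"{self.lipid_class.name} {self.c}:{self.d}: fewer carbons than chains"
            )
        if self.d < 0 or 2 * self.d > self.c:
            raise InvalidSpeciesError(
                f"{self.lipid_class.name} {self.c}:{self.d}: impossible unsaturation"
            )

    @property
    def species_id(self) -> str:
        return f"{self.lipid_class.name} {self.c}:{self.d}"


def make_species(class_name: str, c: int, d: int,
                 classes: dict[str, LipidClass] | None = None) -> LipidSpecies:
    classes = classes or DEFAULT_CLASSES
    try:
        cls = classes[class_name]
    except KeyError:
        raise UnsupportedClassError(class_name) from None
    return LipidSpecies(cls, c, d)


_SPECIES_ID_RE = re.compile(r"^(\w+) (\d+):(\d+)$")


def parse_species_id(species_id: str,
                     classes: dict[str, LipidClass] | None = None) -> LipidSpecies:
    m = _SPECIES_ID_RE.match(species_id)
    if not m:
        raise ValueError(f"cannot parse species id {species_id!r}")
    return make_species(m.group(1), int(m.group(2)), int(m.group(3)), classes)


def compose_formula(species: LipidSpecies) -> Formula:
    """Neutral elemental formula by constructive bookkeeping.

    backbone glycerols + phosphoric acids + head group + combined acyls,
    minus one water per ester bond and per phosphoester bond. Only species
    totals (c, d) enter, so the result is independent of the chain split.
    """
    cls = species.lipid_class
    n_waters = species.n_chains + cls.n_phosphoester
    return (
        cls.n_glycerol * GLYCEROL
        + cls.n_phosphate * PHOSPHORIC_ACID
        + cls.head_group
        + acyl_formula(species.c, species.d, species.n_chains)
        - n_waters * WATER
    )


# ---------------------------------------------------------------------------
# transitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Transition:
    """One MRM measurement address: (polarity, Q1, Q3) keyed to a species."""

    species_id: str
    class_name: str
    c: int
    d: int
    polarity: str
    charge: int
    q1_mz: float
    q3_mz: float
    neutral_loss_mz: float | None = None
    q3_alternatives: tuple[float, ...] = ()

    @property
    def q3_candidates(self) -> tuple[float, ...]:
        return (self.q3_mz, *self.q3_alternatives)


def _acyl_anion_mz(k: int, x: int) -> float:
    """Carboxylate anion [FA(k:x) - H]- m/z."""
    fa = Formula({"C": k, "H": 2 * k - 2 * x, "O": 2})
    return ion_mz(fa, M_MINUS_H)


#: default per-chain carbon range for CL acyl-anion candidates —
#: even-carbon fatty acids of biological chain lengths
CL_CHAIN_CARBONS = (10, 26)


def _cl_acyl_candidates(
    c: int, d: int, chain_range: tuple[int, int] = CL_CHAIN_CARBONS
) -> list[tuple[int, int]]:
    """Even-carbon (k, x) acyl chains compatible with CL species totals.

    A chain is feasible when the remaining three chains can still host the
    remaining carbons and double bonds within the same per-chain range.
    """
    k_min, k_max = chain_range
    out = []
    for k in range(k_min, k_max + 1):
        if k % 2:
            continue
        rest_c = c - k
        if not (3 * k_min <= rest_c <= 3 * k_max):
            continue
        for x in range(0, min(d, k // 2) + 1):
            if d - x <= 3 * (k_max // 2):
                out.append((k, x))
    return out


def transition_for(species: LipidSpecies) -> Transition:
    """Build the class-rule MRM transition for a species.

    Raises :class:`UnsupportedClassError` for classes without a Q3 rule.
    """
    cls = species.lipid_class
    neutral = compose_formula(species)
    q1 = ion_mz(neutral, cls.adduct)
    nl_mass: float | None = None
    alternatives: tuple[float, ...] = ()

    if cls.scan_mode == "precursor_ion":
        q3 = ionic_mz(cls.q3_formula, cls.q3_charge)
    elif cls.scan_mode == "neutral_loss":
        nl_mass = cls.q3_formula.mass
        q3 = q1 - nl_mass / cls.charge
    elif cls.scan_mode == "acyl_anions":
        cands = _cl_acyl_candidates(species.c, species.d)
        if not cands:
            raise UnsupportedClassError(
                f"no feasible acyl anions for {species.species_id}"
            )
        # canonical primary: the chain closest to an equal split
        k_star, x_star = min(
            cands,
            key=lambda kx: (abs(kx[0] - species.c / 4), abs(kx[1] - species.d / 4)),
        )
        q3 = _acyl_anion_mz(k_star, x_star)
        alternatives = tuple(
            sorted(_acyl_anion_mz(k, x) for k, x in cands if (k, x) != (k_star, x_star))
        )
    else:
        raise UnsupportedClassError(
            f"class {cls.name} has no transition rule"
        )
    return Transition(
        species_id=species.species_id,
        class_name=cls.name,
        c=species.c,
        d=species.d,
        polarity=cls.polarity,
        charge=cls.charge,
        q1_mz=q1,
        q3_mz=q3,
        neutral_loss_mz=nl_mass,
        q3_alternatives=alternatives,
    )


def transitions_to_frame(transitions) -> "pandas.DataFrame":
    """Transition list as the interchange CSV layout."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "species_id": t.species_id,
                "class": t.class_name,
                "c": t.c,
                "d": t.d,
                "polarity": t.polarity,
                "q1_mz": t.q1_mz,
                "q3_mz": t.q3_mz,
                "neutral_loss_mz": t.neutral_loss_mz,
            }
            for t in transitions
        ]
    )
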