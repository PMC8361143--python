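"""Isotopologue envelopes and the type-II isotopic-overlap correction.

In head-group MRM scans a species with d double bonds is contaminated by the
M+2 isotopologue (chiefly two 13C) of the species with d+1 double bonds,
which sits 2 Da lower in mass and therefore inside the same Q1 window. The
correction factor for that overlap is

    f = (M+2 theoretical) * (n_heavy / m_total)^2

where ``M+2 theoretical`` is the M+2 abundance of the precursor ion relative
to its monoisotopic peak after merging fine structure at the instrument's
mass resolution, ``m_total`` is the carbon count of the whole lipid ion and
``n_heavy`` the carbon count of the fragment that must carry both 13C for
the contaminated transition to still register: the complement of the
monitored light fragment in precursor-ion scans (PC, PI), or the retained
charged fragment in neutral-loss scans (PE, PS).

Envelopes are exact polynomial expansions over the pinned isotope table;
distinct isotope combinations (e.g. 13C2 vs 18O) keep their exact mass
shifts until the resolution merge.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

from .chem import (
    HYDROGEN_ATOM,
    Formula,
    LipidSpecies,
    UnsupportedClassError,
    compose_formula,
    isotope_table,
)

__all__ = [
    "Isotopologue",
    "CorrectionFactor",
    "isotopologue_envelope",
    "m2_theoretical",
    "class2_correction_factor",
    "correction_factors",
    "correction_factor_frame",
    "C13_MASS_SHIFT",
]

_TABLE = isotope_table()
#: mass difference 13C - 12C, the neutron-scale unit of the M+2 peak
C13_MASS_SHIFT = _TABLE["C"][1][1] - _TABLE["C"][0][1]


@dataclass(frozen=True)
class Isotopologue:
    """One distinct isotope combination of a formula."""

    nominal_shift: int  # nominal mass units above monoisotopic
    mass_shift: float  # exact Da above monoisotopic
    abundance: float  # fraction of the total species population


def _element_states(el: str, n: int, max_shift: int | None):
    """(nominal, mass shift, abundance) states for n atoms of one element.

    Enumerates counts of each heavy isotope; the light-isotope count is the
    remainder. Exact multinomial abundances.
    """
    rows = _TABLE[el]
    nom0, m0, p0 = rows[0]
    heavy = [(nom - nom0, m - m0, p) for nom, m, p in rows[1:]]
    states: list[tuple[int, float, float]] = []

    def expand(idx: int, kept: tuple[int, ...]):
        if idx == len(heavy):
            ks = kept
            total_heavy = sum(ks)
            if total_heavy > n:
                return
            nom = sum(k * heavy[i][0] for i, k in enumerate(ks))
            if max_shift is not None and nom > max_shift:
                return
            dmass = sum(k * heavy[i][1] for i, k in enumerate(ks))
            coeff = 1
            left = n
            for k in ks:
                coeff *= math.comb(left, k)
                left -= k
            ab = coeff * p0**left
            for i, k in enumerate(ks):
                ab *= heavy[i][2] ** k
            states.append((nom, dmass, ab))
            return
        dn = heavy[idx][0]
        kmax = n if max_shift is None else min(n, max_shift // dn)
        for k in range(kmax + 1):
            expand(idx + 1, kept + (k,))

    expand(0, ())
    return states


@lru_cache(maxsize=4096)
def _envelope_cached(formula: Formula, max_shift: int | None) -> tuple[Isotopologue, ...]:
    combined: list[tuple[int, float, float]] = [(0, 0.0, 1.0)]
    for el, n in formula.items():
        el_states = _element_states(el, n, max_shift)
        nxt = []
        for nom_a, dm_a, ab_a in combined:
            for nom_b, dm_b, ab_b in el_states:
                nom = nom_a + nom_b
                if max_shift is not None and nom > max_shift:
                    continue
                nxt.append((nom, dm_a + dm_b, ab_a * ab_b))
        combined = nxt
    return tuple(
        Isotopologue(nom, dm, ab)
        for nom, dm, ab in sorted(combined, key=lambda s: s[1])
    )


def isotopologue_envelope(
    formula: Formula, max_shift: int | None = 2
) -> list[Isotopologue]:
    """Exact isotopologue expansion up to ``max_shift`` nominal units.

    ``max_shift=None`` yields the complete expansion (abundances sum to 1);
    otherwise isotopologues above the cutoff are dropped. Each distinct
    isotope combination keeps its exact mass shift (13C2 at +2.00671 stays
    separate from 18O at +2.00425).
    """
    if not formula:
        raise ValueError("empty formula has no envelope")
    if max_shift is not None and max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    return list(_envelope_cached(formula, max_shift))


def m2_theoretical(formula: Formula, resolution: float = 5000.0) -> float:
    """M+2 abundance relative to the monoisotopic peak at finite resolution.

    All isotopologues whose exact mass falls within a window of full width
    (monoisotopic mass / resolution), centered on the 13C2 peak, are merged
    — the resolution model of a quadrupole that cannot separate the M+2
    fine structure.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    env = isotopologue_envelope(formula, max_shift=2)
    mono = formula.mass
    center = 2 * C13_MASS_SHIFT
    half_width = (mono / resolution) / 2
    m0 = next(iso.abundance for iso in env if iso.nominal_shift == 0 and iso.mass_shift == 0.0)
    m2 = sum(
        iso.abundance
        for iso in env
        if iso.nominal_shift > 0 and abs(iso.mass_shift - center) <= half_width
    )
    return m2 / m0


@dataclass(frozen=True)
class CorrectionFactor:
    """Per-species type-II overlap fraction, with its bookkeeping."""

    species_id: str
    m2_theoretical: float
    n_heavy: int
    m_total: int
    factor: float


def precursor_ion_formula(species: LipidSpecies) -> Formula:
    """Atom composition of the measured precursor ion (neutral ± protons)."""
    cls = species.lipid_class
    neutral = compose_formula(species)
    delta = cls.adduct.proton_delta
    if delta >= 0:
        return neutral + delta * HYDROGEN_ATOM
    return neutral - (-delta) * HYDROGEN_ATOM


def class2_correction_factor(
    species: LipidSpecies, resolution: float = 5000.0
) -> CorrectionFactor:
    """The overlap fraction f for one species' transition.

    Raises :class:`UnsupportedClassError` for classes whose scans do not fit
    the head-group fragmentation model (CL, whose Q3 monitors acyl anions
    and which the published scheme leaves uncorrected).
    """
    cls = species.lipid_class
    if cls.scan_mode not in ("precursor_ion", "neutral_loss") or cls.q3_formula is None:
        raise UnsupportedClassError(
            f"class {cls.name} has no type-II correction rule"
        )
    ion = precursor_ion_formula(species)
    m_total = ion.carbons
    n_heavy = m_total - cls.q3_formula.carbons
    if n_heavy < 0:
        raise UnsupportedClassError(
            f"{species.species_id}: light fragment larger than the lipid"
        )
    m2 = m2_theoretical(ion, resolution)
    return CorrectionFactor(
        species_id=species.species_id,
        m2_theoretical=m2,
        n_heavy=n_heavy,
        m_total=m_total,
        factor=m2 * (n_heavy / m_total) ** 2,
    )


def correction_factors(
    species_list, resolution: float = 5000.0
) -> dict[str, CorrectionFactor]:
    """Factors for every correctable species; uncorrected classes get 0.

    Classes without a head-group fragmentation rule (CL) receive an explicit
    zero factor so the de-isotoping cascade leaves them untouched.
    """
    out: dict[str, CorrectionFactor] = {}
    for sp in species_list:
        try:
            out[sp.species_id] = class2_correction_factor(sp, resolution)
        except UnsupportedClassError:
            ion = precursor_ion_formula(sp)
            out[sp.species_id] = CorrectionFactor(
                sp.species_id, 0.0, 0, ion.carbons, 0.0
            )
    return out


def correction_factor_frame(factors: dict[str, CorrectionFactor]):
    """Correction factors as the interchange CSV layout."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "species_id": f.species_id,
                "m2_theoretical": f.m2_theoretical,
                "n_heavy": f.n_heavy,
                "m_total": f.m_total,
                "factor": f.factor,
            }
            for f in factors.values()
        ]
    )
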