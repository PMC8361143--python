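"""Independent brute-force oracles used by the test suite.

The envelope oracle expands isotopologues one atom at a time (polynomial
multiplication keyed by isotope multisets) — a different algorithm from the
per-element multinomial expansion inside the package.
"""
from collections import Counter

from lipidmrm.chem import Formula, isotope_table
from lipidmrm.isotopes import C13_MASS_SHIFT

TABLE = isotope_table()


def envelope_oracle(formula: Formula, max_shift: int | None):
    """Atom-by-atom expansion: list of (nominal shift, mass shift, abundance)."""
    states = {frozenset(): 1.0}
    for el, n in formula.items():
        rows = TABLE[el]
        nom0 = rows[0][0]
        for _ in range(n):
            nxt: dict[frozenset, float] = {}
            for key, prob in states.items():
                for nom, _mass, ab in rows:
                    shift = nom - nom0
                    if shift == 0:
                        newkey = key
                    else:
                        counts = Counter(dict(key))
                        counts[(el, nom)] += 1
                        newkey = frozenset(counts.items())
                        total = sum(
                            cnt * (inom - TABLE[iel][0][0])
                            for (iel, inom), cnt in counts.items()
                        )
                        if max_shift is not None and total > max_shift:
                            continue
                    nxt[newkey] = nxt.get(newkey, 0.0) + prob * ab
            states = nxt
    out = []
    for key, ab in states.items():
        nom = sum(cnt * (inom - TABLE[iel][0][0]) for (iel, inom), cnt in key)
        dm = sum(
            cnt * (next(m for n_, m, _ in TABLE[iel] if n_ == inom) - TABLE[iel][0][1])
            for (iel, inom), cnt in key
        )
        out.append((nom, dm, ab))
    return out


def m2_oracle(formula: Formula, resolution: float = 5000.0) -> float:
    """M+2 : M+0 abundance ratio after merging within the resolution window."""
    states = envelope_oracle(formula, 2)
    center = 2 * C13_MASS_SHIFT
    half = formula.mass / resolution / 2
    m0 = next(ab for nom, dm, ab in states if nom == 0)
    return sum(ab for nom, dm, ab in states if nom > 0 and abs(dm - center) <= half) / m0
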