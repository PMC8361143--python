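"""Signal matching, the de-isotoping cascade, and normalization to Mol%.

The quantification chain mirrors the measurement: raw MRM intensities are
matched to transitions within an m/z window, corrected for type-II isotope
overlap by stepwise subtraction along each desaturation series (most
desaturated species first), converted to pmol against the class internal
standard, normalized to the sample's total phosphate, and finally reported
as Mol% so that run-to-run differences in total lipid recovery cancel.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem import LipidSpecies, Transition
from .isotopes import CorrectionFactor, correction_factors

__all__ = [
    "MatchResult",
    "Series",
    "match_signals",
    "build_series",
    "deisotope_series",
    "deisotope_table",
    "quantify",
    "to_molpercent",
    "run_pipeline",
    "PipelineResult",
    "DEFAULT_MZ_WINDOW",
]

DEFAULT_MZ_WINDOW = 0.5  # amu, the precursor selection window
SIGNAL_COLUMNS = ["sample", "polarity", "q1_mz", "q3_mz", "intensity"]


@dataclass
class MatchResult:
    """Outcome of assigning measured signals to transitions."""

    intensities: pd.DataFrame  # sample, species_id, class, c, d, intensity
    unassigned: pd.DataFrame  # signals matching no transition
    ambiguous: pd.DataFrame  # signals inside the window of >1 transition


def match_signals(
    signals: pd.DataFrame,
    transitions: list[Transition],
    window: float = DEFAULT_MZ_WINDOW,
    reducer: str = "mean",
) -> MatchResult:
    """Assign signal rows to transitions within ±window on Q1 and Q3.

    Boundary inclusive on both axes. A signal inside the window of several
    transitions is assigned to the nearest (Euclidean in the Q1/Q3 plane)
    and reported in the ambiguity table. Replicate measurements of one
    transition are reduced by ``reducer`` ('mean' or 'median'). Signals
    matching nothing are returned, not raised.
    """
    if reducer not in ("mean", "median"):
        raise ValueError("reducer must be 'mean' or 'median'")
    missing = [c for c in SIGNAL_COLUMNS if c not in signals.columns]
    if missing:
        raise ValueError(f"signals table lacks columns: {missing}")

    # candidate rows: one per (transition, q3 candidate)
    cand = []
    for idx, t in enumerate(transitions):
        for q3 in t.q3_candidates:
            cand.append((idx, t.polarity, t.q1_mz, q3))
    cand_idx = np.array([c[0] for c in cand])
    cand_pol = np.array([c[1] for c in cand])
    cand_q1 = np.array([c[2] for c in cand])
    cand_q3 = np.array([c[3] for c in cand])

    sig_q1 = signals["q1_mz"].to_numpy(float)
    sig_q3 = signals["q3_mz"].to_numpy(float)
    sig_pol = signals["polarity"].to_numpy()

    assigned = np.full(len(signals), -1)
    n_hits = np.zeros(len(signals), int)
    for pol in np.unique(cand_pol):
        cmask = cand_pol == pol
        smask = sig_pol == pol
        if not smask.any() or not cmask.any():
            continue
        dq1 = np.abs(sig_q1[smask, None] - cand_q1[None, cmask])
        dq3 = np.abs(sig_q3[smask, None] - cand_q3[None, cmask])
        inside = (dq1 <= window) & (dq3 <= window)
        dist = np.where(inside, np.hypot(dq1, dq3), np.inf)
        best = dist.argmin(axis=1)
        has = inside.any(axis=1)
        tids = cand_idx[cmask]
        # hits counted over distinct transitions, not q3 candidates
        order = np.argsort(tids, kind="stable")
        sorted_tids = tids[order]
        group_starts = np.flatnonzero(
            np.r_[True, sorted_tids[1:] != sorted_tids[:-1]]
        )
        per_transition = np.add.reduceat(inside[:, order], group_starts, axis=1)
        n_distinct = (per_transition > 0).sum(axis=1)
        sidx = np.flatnonzero(smask)
        assigned[sidx[has]] = tids[best[has]]
        n_hits[sidx] = n_distinct

    sig = signals.copy()
    sig["_transition"] = assigned
    unassigned = sig[assigned < 0].drop(columns="_transition").reset_index(drop=True)
    ambiguous = sig[n_hits > 1].drop(columns="_transition").reset_index(drop=True)

    hit = sig[assigned >= 0].copy()
    meta = pd.DataFrame(
        {
            "_transition": range(len(transitions)),
            "species_id": [t.species_id for t in transitions],
            "class": [t.class_name for t in transitions],
            "c": [t.c for t in transitions],
            "d": [t.d for t in transitions],
        }
    )
    hit = hit.merge(meta, on="_transition")
    grouped = (
        hit.groupby(["sample", "species_id", "class", "c", "d"], as_index=False)[
            "intensity"
        ]
        .agg(reducer)
        .sort_values(["sample", "class", "c", "d"])
        .reset_index(drop=True)
    )
    return MatchResult(grouped, unassigned, ambiguous)


# ---------------------------------------------------------------------------
# desaturation series and the de-isotoping cascade
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Series:
    """Species of one class sharing total carbons, ordered d descending."""

    class_name: str
    c: int
    ds: tuple[int, ...]  # descending double-bond counts present

    def __post_init__(self):
        if tuple(sorted(self.ds, reverse=True)) != self.ds:
            raise ValueError("series must be ordered by descending d")

    @property
    def species_ids(self) -> tuple[str, ...]:
        return tuple(f"{self.class_name} {self.c}:{d}" for d in self.ds)


def build_series(species_table: pd.DataFrame) -> list[Series]:
    """Partition species rows (class, c, d) into desaturation series.

    Species of one class with equal total carbons differ by 2 Da per double
    bond on the mass axis (2/z on m/z), which is exactly the M+2 overlap
    relation; different carbon counts never overlap and form separate
    series. Gaps (missing d) are kept as gaps — the cascade does not
    subtract across them.
    """
    out = []
    for (cls, c), grp in species_table.groupby(["class", "c"]):
        ds = tuple(sorted(grp["d"].unique(), reverse=True))
        out.append(Series(str(cls), int(c), ds))
    return sorted(out, key=lambda s: (s.class_name, s.c))


def deisotope_series(
    series: Series,
    intensities: dict[str, float],
    factors: dict[str, float],
) -> tuple[dict[str, float], dict[str, bool]]:
    """Stepwise M+2 subtraction from most desaturated to fully saturated.

    J(d_max) = I(d_max); then J(d) = I(d) − f(d+1)·J(d+1), clipped at zero
    with a flag when noise over-subtracts. If the d+1 member is absent
    (gap), no subtraction is applied to d.
    """
    corrected: dict[str, float] = {}
    clipped: dict[str, bool] = {}
    prev_d: int | None = None
    prev_j = 0.0
    for d, sid in zip(series.ds, series.species_ids):
        raw = intensities[sid]
        if prev_d is not None and prev_d == d + 1:
            upstream = f"{series.class_name} {series.c}:{prev_d}"
            if upstream not in factors:
                raise KeyError(f"no correction factor for {upstream}")
            j = raw - factors[upstream] * prev_j
        else:
            j = raw
        clipped[sid] = j < 0
        corrected[sid] = max(j, 0.0)
        prev_d, prev_j = d, corrected[sid]
    return corrected, clipped


def deisotope_table(
    intensities: pd.DataFrame, factors: dict[str, CorrectionFactor | float]
) -> pd.DataFrame:
    """Apply the cascade per sample and per series over a matched table."""
    fvals = {
        sid: (f.factor if isinstance(f, CorrectionFactor) else float(f))
        for sid, f in factors.items()
    }
    rows = []
    for sample, sgrp in intensities.groupby("sample"):
        series_list = build_series(sgrp[["class", "c", "d"]])
        meas = dict(zip(sgrp["species_id"], sgrp["intensity"]))
        meta = sgrp.set_index("species_id")
        for ser in series_list:
            corrected, clipped = deisotope_series(ser, meas, fvals)
            for sid in ser.species_ids:
                rows.append(
                    {
                        "sample": sample,
                        "species_id": sid,
                        "class": ser.class_name,
                        "c": ser.c,
                        "d": int(meta.loc[sid, "d"]),
                        "raw": meas[sid],
                        "corrected": corrected[sid],
                        "clipped": clipped[sid],
                    }
                )
    return pd.DataFrame(rows).sort_values(
        ["sample", "class", "c", "d"]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# internal-standard and phosphate normalization
# ---------------------------------------------------------------------------

class MissingStandardError(RuntimeError):
    pass


def quantify(
    corrected: pd.DataFrame,
    standards: pd.DataFrame,
    phosphate: pd.DataFrame,
) -> pd.DataFrame:
    """Intensity → pmol via class IS, then per-phosphate amounts.

    ``standards`` needs columns class, species_id, spiked_pmol — exactly one
    standard per measured class. ``phosphate`` needs sample, phosphate_nmol.
    IS species are consumed as denominators and excluded from the reported
    lipidome. A missing or zero-intensity IS is a hard error naming the
    sample and class.
    """
    is_by_class = standards.set_index("class")
    dup = is_by_class.index[is_by_class.index.duplicated()].tolist()
    if dup:
        raise ValueError(f"more than one internal standard for class(es) {dup}")
    phos = phosphate.set_index("sample")["phosphate_nmol"]

    rows = []
    for sample, sgrp in corrected.groupby("sample"):
        if sample not in phos.index:
            raise KeyError(f"no phosphate value for sample {sample!r}")
        p = float(phos.loc[sample])
        if p <= 0:
            raise ValueError(f"non-positive phosphate for sample {sample!r}")
        by_id = sgrp.set_index("species_id")
        for cls, cgrp in sgrp.groupby("class"):
            if cls not in is_by_class.index:
                raise MissingStandardError(
                    f"sample {sample!r}: no internal standard defined for class {cls}"
                )
            is_id = is_by_class.loc[cls, "species_id"]
            spiked = float(is_by_class.loc[cls, "spiked_pmol"])
            if is_id not in by_id.index:
                raise MissingStandardError(
                    f"sample {sample!r}: internal standard {is_id} not measured "
                    f"for class {cls}"
                )
            is_intensity = float(by_id.loc[is_id, "corrected"])
            if is_intensity <= 0:
                raise MissingStandardError(
                    f"sample {sample!r}: zero-intensity internal standard "
                    f"{is_id} for class {cls}"
                )
            for sid, r in cgrp.set_index("species_id").iterrows():
                if sid == is_id:
                    continue
                pmol = r["corrected"] / is_intensity * spiked
                rows.append(
                    {
                        "sample": sample,
                        "species_id": sid,
                        "class": cls,
                        "c": int(r["c"]),
                        "d": int(r["d"]),
                        "raw": r["raw"],
                        "corrected": r["corrected"],
                        "clipped": bool(r["clipped"]),
                        "pmol": pmol,
                        "pmol_per_phosphate": pmol / p,
                    }
                )
    return pd.DataFrame(rows).sort_values(
        ["sample", "class", "c", "d"]
    ).reset_index(drop=True)


def to_molpercent(quant: pd.DataFrame, category: str = "all") -> pd.DataFrame:
    """Add a molpct column: 100 × pmol / Σ pmol over the category.

    category 'all' normalizes over the whole lipidome per sample; 'class'
    within each class per sample. Phosphate cancels, so Mol% is identical
    whether computed on pmol or pmol_per_phosphate.
    """
    if category not in ("all", "class"):
        raise ValueError("category must be 'all' or 'class'")
    out = quant.copy()
    keys = ["sample"] if category == "all" else ["sample", "class"]
    totals = out.groupby(keys)["pmol"].transform("sum")
    if (totals <= 0).any():
        bad = out.loc[totals <= 0, keys].drop_duplicates().to_dict("records")
        raise ValueError(f"empty category: zero total amount in {bad}")
    out["molpct"] = 100.0 * out["pmol"] / totals
    return out


# ---------------------------------------------------------------------------
# the assembled pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    quant: pd.DataFrame
    factors: dict[str, CorrectionFactor]
    unassigned: pd.DataFrame
    ambiguous: pd.DataFrame


def run_pipeline(
    signals: pd.DataFrame,
    transitions: list[Transition],
    species: list[LipidSpecies],
    standards: pd.DataFrame,
    phosphate: pd.DataFrame,
    resolution: float = 5000.0,
    window: float = DEFAULT_MZ_WINDOW,
    reducer: str = "mean",
    molpct_category: str = "all",
) -> PipelineResult:
    """signals → match → de-isotope → IS/phosphate normalize → Mol%."""
    matched = match_signals(signals, transitions, window=window, reducer=reducer)
    factors = correction_factors(species, resolution=resolution)
    corrected = deisotope_table(matched.intensities, factors)
    quant = quantify(corrected, standards, phosphate)
    quant = to_molpercent(quant, category=molpct_category)
    return PipelineResult(quant, factors, matched.unassigned, matched.ambiguous)
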