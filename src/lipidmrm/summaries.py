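"""Lipidome profile aggregations: head groups, chain composition, contrasts.

These reproduce the two standard views of a quantified lipidome — the
head-group (class) distribution and the acyl-chain length × desaturation
matrix — plus descriptive between-condition contrasts. Saturation classes
are defined on species-total double bonds (head-group scans cannot resolve
per-chain unsaturation): saturated d = 0, MUFA-range d = 1–2, PUFA-range
d ≥ 3; the thresholds are arguments.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "headgroup_distribution",
    "chain_profile",
    "saturation_marginals",
    "condition_contrast",
]


def headgroup_distribution(quant: pd.DataFrame) -> pd.DataFrame:
    """Per-sample class Mol%: samples × classes, rows summing to 100."""
    if "molpct" not in quant.columns:
        raise ValueError("quant table has no molpct column; run to_molpercent first")
    return (
        quant.pivot_table(
            index="sample", columns="class", values="molpct", aggfunc="sum", fill_value=0.0
        )
        .rename_axis(columns=None)
    )


def chain_profile(quant: pd.DataFrame) -> pd.DataFrame:
    """Per-sample Mol% over (total carbons, total double bonds).

    Index: sample; columns: MultiIndex (c, d); entries sum to 100 per row.
    """
    if "molpct" not in quant.columns:
        raise ValueError("quant table has no molpct column; run to_molpercent first")
    return quant.pivot_table(
        index="sample", columns=["c", "d"], values="molpct", aggfunc="sum", fill_value=0.0
    )


def saturation_marginals(
    quant: pd.DataFrame, mufa_max: int = 2, pufa_min: int = 3
) -> pd.DataFrame:
    """Mol% in saturated (d=0), MUFA-range (1..mufa_max), PUFA-range (≥pufa_min)."""
    if pufa_min != mufa_max + 1:
        raise ValueError("saturation classes must partition the d axis")
    q = quant.copy()
    q["saturation"] = np.select(
        [q["d"] == 0, q["d"] <= mufa_max],
        ["saturated", "mufa"],
        default="pufa",
    )
    out = q.pivot_table(
        index="sample", columns="saturation", values="molpct", aggfunc="sum", fill_value=0.0
    ).rename_axis(columns=None)
    for col in ("saturated", "mufa", "pufa"):
        if col not in out.columns:
            out[col] = 0.0
    return out[["saturated", "mufa", "pufa"]]


def condition_contrast(
    profile: pd.DataFrame,
    groups: dict[str, str],
    group_a: str,
    group_b: str,
) -> pd.DataFrame:
    """Descriptive per-feature contrast between two sample groups.

    ``profile`` is a samples × features Mol% table (head-group distribution
    or chain profile); ``groups`` maps sample id → condition label. Returns
    per feature: group means, SEMs (NaN for singleton groups) and the mean
    difference A − B. No inferential statistics.
    """
    a_samples = [s for s in profile.index if groups.get(s) == group_a]
    b_samples = [s for s in profile.index if groups.get(s) == group_b]
    if not a_samples or not b_samples:
        raise ValueError(
            f"empty group: {group_a!r} n={len(a_samples)}, {group_b!r} n={len(b_samples)}"
        )
    a = profile.loc[a_samples]
    b = profile.loc[b_samples]

    def sem(df: pd.DataFrame) -> pd.Series:
        if len(df) < 2:
            return pd.Series(np.nan, index=df.columns)
        return df.std(ddof=1) / np.sqrt(len(df))

    return pd.DataFrame(
        {
            f"mean_{group_a}": a.mean(),
            f"sem_{group_a}": sem(a),
            f"mean_{group_b}": b.mean(),
            f"sem_{group_b}": sem(b),
            "mean_difference": a.mean() - b.mean(),
        }
    )
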