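"""GC-MS sterol quantification by extracted-ion chromatograms.

Free sterols eluting during the linear oven gradient are quantified from
single-ion traces of the EI molecular radical cation [M]+., integrated over
a retention-time window above a linear baseline, and converted to amounts
by ratio to the spiked ergosterol internal standard.

Channel m/z values are computed from elemental compositions with the pinned
mass table and truncated to one decimal — the printed-channel convention.
The ergosterol channel is read on the 13C2 (M+2) isotopologue of its
molecular ion, which is what the printed 398.3 corresponds to for C28H44O;
the monoisotopic ion would sit at 396.3.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, peak_widths

from .chem import M_RADICAL, Formula, ion_mz, truncate
from .isotopes import C13_MASS_SHIFT

__all__ = [
    "SterolChannel",
    "DEFAULT_STEROLS",
    "channel_mz",
    "extract_ion",
    "integrate_peak",
    "auto_window",
    "quantify_sterols",
]

DEFAULT_MZ_TOLERANCE = 0.5


@dataclass(frozen=True)
class SterolChannel:
    """A sterol's extracted-ion channel, derived from its composition."""

    name: str
    formula: Formula
    #: number of 13C in the monitored isotopologue (0 = monoisotopic ion)
    isotope_shift: int = 0
    is_internal_standard: bool = False

    @property
    def mz(self) -> float:
        return channel_mz(self.formula, self.isotope_shift)


def channel_mz(formula: Formula, isotope_shift: int = 0) -> float:
    """One-decimal truncated m/z of [M]+. shifted by ``isotope_shift`` 13C."""
    exact = ion_mz(formula, M_RADICAL) + isotope_shift * C13_MASS_SHIFT
    return truncate(exact, 1)


def default_sterols() -> list[SterolChannel]:
    return [
        SterolChannel("7-dehydrocholesterol", Formula.parse("C27H44O")),
        SterolChannel("cholesterol", Formula.parse("C27H46O")),
        SterolChannel("lophenol", Formula.parse("C28H48O")),
        SterolChannel(
            "ergosterol",
            Formula.parse("C28H44O"),
            isotope_shift=2,
            is_internal_standard=True,
        ),
    ]


DEFAULT_STEROLS = default_sterols()


def extract_ion(
    chromatogram: pd.DataFrame,
    mz: float,
    tolerance: float = DEFAULT_MZ_TOLERANCE,
) -> pd.DataFrame:
    """EIC: per retention time, sum of intensities with |m/z − mz| ≤ tol.

    The chromatogram table needs columns rt_min, mz, intensity. Returns a
    (rt_min, intensity) trace over all scan times, zero where the channel
    records nothing.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if chromatogram.empty:
        raise ValueError("empty chromatogram")
    inside = (chromatogram["mz"] - mz).abs() <= tolerance
    hits = (
        chromatogram[inside].groupby("rt_min")["intensity"].sum()
    )
    rts = np.sort(chromatogram["rt_min"].unique())
    trace = hits.reindex(rts, fill_value=0.0).rename("intensity").reset_index()
    return trace


def integrate_peak(trace: pd.DataFrame, rt_window: tuple[float, float]) -> float:
    """Trapezoidal peak area above a linear baseline through the window edges."""
    lo, hi = rt_window
    if lo >= hi:
        raise ValueError("empty retention-time window")
    sel = trace[(trace["rt_min"] >= lo) & (trace["rt_min"] <= hi)]
    if len(sel) < 3:
        raise ValueError(
            f"window ({lo:g}, {hi:g}) min contains {len(sel)} points; need >= 3"
        )
    rt = sel["rt_min"].to_numpy(float)
    y = sel["intensity"].to_numpy(float)
    slope = (y[-1] - y[0]) / (rt[-1] - rt[0])
    baseline = y[0] + slope * (rt - rt[0])
    return float(np.trapezoid(y - baseline, rt))


def auto_window(trace: pd.DataFrame, span: float = 2.0) -> tuple[float, float]:
    """Retention window around the dominant local maximum of a trace.

    The window spans ±span×FWHM around the tallest peak, clipped to the
    trace range — wide enough to capture >99.9% of a Gaussian's area while
    staying local.
    """
    y = trace["intensity"].to_numpy(float)
    rt = trace["rt_min"].to_numpy(float)
    if not np.any(y > 0):
        raise ValueError("trace has no signal to window")
    peaks, _ = find_peaks(y, height=y.max() * 0.5)
    if len(peaks) == 0:
        peaks = np.array([int(np.argmax(y))])
    top = peaks[np.argmax(y[peaks])]
    widths = peak_widths(y, [top], rel_height=0.5)[0]
    dt = np.median(np.diff(rt)) if len(rt) > 1 else 0.01
    fwhm = max(widths[0] * dt, 3 * dt)
    lo = max(rt[top] - span * fwhm, rt[0])
    hi = min(rt[top] + span * fwhm, rt[-1])
    return float(lo), float(hi)


def quantify_sterols(
    chromatogram: pd.DataFrame,
    spiked_pmol: float,
    channels: list[SterolChannel] | None = None,
    rt_windows: dict[str, tuple[float, float]] | None = None,
    tolerance: float = DEFAULT_MZ_TOLERANCE,
    response_factors: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Sterol amounts by EIC area ratio to the internal standard.

    amount(sterol) = area(sterol)/area(IS) × spiked_pmol / response(sterol).
    Retention windows default to automatic local-maximum detection per
    channel; response factors default to 1 (area ratio = mole ratio).
    """
    channels = channels if channels is not None else DEFAULT_STEROLS
    rt_windows = rt_windows or {}
    response_factors = response_factors or {}
    is_channels = [ch for ch in channels if ch.is_internal_standard]
    if len(is_channels) != 1:
        raise ValueError(
            f"need exactly one internal-standard channel, got {len(is_channels)}"
        )

    areas: dict[str, float] = {}
    for ch in channels:
        trace = extract_ion(chromatogram, ch.mz, tolerance)
        if ch.name in rt_windows:
            window = rt_windows[ch.name]
        else:
            try:
                window = auto_window(trace)
            except ValueError:
                areas[ch.name] = 0.0
                continue
        areas[ch.name] = max(integrate_peak(trace, window), 0.0)

    is_name = is_channels[0].name
    is_area = areas[is_name]
    if is_area <= 0:
        raise ValueError(f"internal standard {is_name!r} has no peak area")

    rows = []
    for ch in channels:
        if ch.is_internal_standard:
            continue
        rf = response_factors.get(ch.name, 1.0)
        rows.append(
            {
                "sterol": ch.name,
                "channel_mz": ch.mz,
                "area": areas[ch.name],
                "pmol": areas[ch.name] / is_area * spiked_pmol / rf,
            }
        )
    return pd.DataFrame(rows)
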