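"""Synthetic study generator: compositional lipidomes, MRM tables, GC-MS.

Emulates the inputs of a shotgun-lipidomics experiment on whole-animal
extracts so the entire quantification chain is testable at desk scale:

* a compositional lipidome — species amounts drawn from a Dirichlet over a
  (class, total carbons, total double bonds) grid whose within-class chain
  profile is a smooth length × desaturation distribution; a "treatment"
  condition tilts that profile toward shorter, more saturated species with
  exponential weights exp(−α·d − β·(c − c_ref)), mimicking a shift from
  PUFAs to saturated and mono-unsaturated acyls;
* MRM signal tables — the forward model of type-II isotopic overlap,
  measured(d) = response · [true(d) + f(d+1)·true(d+1)] · noise, with f
  taken from the same correction-factor engine the analysis uses, spiked
  internal standards, six replicate reads per transition (two technical
  replicates × three measurements) and mean-one log-normal noise;
* Gaussian-peak GC-MS chromatograms for four sterols on their computed
  single-ion channels, peak area equal to the simulated amount.

Every output is a pure function of (config, seed).
"""
from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from .chem import LipidSpecies, Transition, make_species, transition_for
from .isotopes import correction_factors
from .sterols import DEFAULT_STEROLS, SterolChannel

__all__ = [
    "ChainProfile",
    "SterolPeak",
    "SimulationConfig",
    "simulate_lipidome",
    "simulate_mrm_signals",
    "simulate_gcms",
    "simulate_experiment",
    "write_experiment",
]

logger = logging.getLogger("lipidmrm.simulate")


class ChainProfile(BaseModel):
    """Smooth within-class (c, d) abundance profile on a species grid."""

    c_values: list[int]
    d_values: list[int]
    c_mean: float
    c_sd: float
    d_mean: float
    d_sd: float

    @field_validator("c_sd", "d_sd")
    @classmethod
    def _positive(cls, v):
        if v <= 0:
            raise ValueError("profile widths must be positive")
        return v

    def log_weight(self, c: int, d: int) -> float:
        return (
            -((c - self.c_mean) ** 2) / (2 * self.c_sd**2)
            - ((d - self.d_mean) ** 2) / (2 * self.d_sd**2)
        )


class SterolPeak(BaseModel):
    name: str
    amount_pmol: float
    rt_min: float
    sigma_min: float = 0.04


def _default_chain_profiles() -> dict[str, ChainProfile]:
    diacyl = dict(
        c_values=[32, 34, 36, 38, 40], d_values=[0, 1, 2, 3, 4, 5, 6],
        c_mean=36.0, c_sd=2.5, d_mean=3.0, d_sd=1.6,
    )
    return {
        "PC": ChainProfile(**diacyl),
        "PE": ChainProfile(**diacyl),
        "PI": ChainProfile(**diacyl),
        "PS": ChainProfile(**diacyl),
        "CL": ChainProfile(
            c_values=[64, 68, 72], d_values=[0, 1, 2, 3, 4, 5, 6],
            c_mean=68.0, c_sd=4.0, d_mean=4.0, d_sd=1.6,
        ),
    }


def _default_sterols() -> list[SterolPeak]:
    # retention times inside the linear 195→230 °C elution segment
    return [
        SterolPeak(name="cholesterol", amount_pmol=50.0, rt_min=13.6),
        SterolPeak(name="7-dehydrocholesterol", amount_pmol=25.0, rt_min=14.2),
        SterolPeak(name="ergosterol", amount_pmol=100.0, rt_min=15.1),
        SterolPeak(name="lophenol", amount_pmol=15.0, rt_min=15.7),
    ]


class SimulationConfig(BaseModel):
    """Everything the generator draws from, plus the seed.

    Defaults reflect the emulated study: six biological replicates per
    condition, each transition read as two technical replicates of three
    measurements, di-lauryl / tetra-lauryl internal standards, ~10%
    multiplicative intensity noise, and a treatment tilt toward shorter,
    more saturated chains.
    """

    seed: int = 0
    n_samples: int = 6
    technical_replicates: int = 2
    measurements_per_replicate: int = 3

    class_weights: dict[str, float] = Field(
        default_factory=lambda: {"PC": 0.35, "PE": 0.35, "PI": 0.12, "PS": 0.10, "CL": 0.08}
    )
    chain_profiles: dict[str, ChainProfile] = Field(default_factory=_default_chain_profiles)
    # pooled whole-animal extracts vary little between replicates; this
    # concentration gives ~10% compositional CV for a 1 Mol% species
    dirichlet_concentration: float = 8000.0
    #: condition label → (α per double bond, β per carbon) exponential tilt
    condition_shifts: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: {"mock": (0.0, 0.0), "treatment": (0.25, 0.06)}
    )

    total_pmol: float = 2000.0
    total_cv: float = 0.15
    noise_cv: float = 0.1
    class_response: dict[str, float] = Field(
        default_factory=lambda: {"PC": 1.2, "PE": 1.0, "PI": 0.8, "PS": 0.9, "CL": 0.7}
    )
    internal_standards: dict[str, float] = Field(
        default_factory=lambda: {
            "PC 24:0": 100.0,
            "PE 24:0": 100.0,
            "PI 24:0": 100.0,
            "PS 24:0": 100.0,
            "CL 48:0": 100.0,
        }
    )

    phosphate_nmol: float = 25.0
    phosphate_cv: float = 0.1
    resolution: float = 5000.0

    sterols: list[SterolPeak] = Field(default_factory=_default_sterols)
    gc_rt_start: float = 11.5
    gc_rt_end: float = 20.25
    gc_rt_step: float = 0.01
    gc_baseline: float = 5.0
    gc_noise_sd: float = 0.5

    @field_validator("class_weights")
    @classmethod
    def _positive_weights(cls, v):
        if any(w <= 0 for w in v.values()):
            raise ValueError("class weights must be positive")
        return v

    @field_validator("noise_cv", "total_cv", "phosphate_cv")
    @classmethod
    def _nonneg(cls, v):
        if v < 0:
            raise ValueError("coefficients of variation must be >= 0")
        return v

    # -- derived structure ---------------------------------------------------

    def species_grid(self) -> list[LipidSpecies]:
        """Endogenous species of the configured grid (no standards)."""
        out = []
        for cls_name in self.class_weights:
            prof = self.chain_profiles[cls_name]
            for c in prof.c_values:
                for d in prof.d_values:
                    out.append(make_species(cls_name, c, d))
        if not out:
            raise ValueError("empty species grid")
        return out

    def standard_species(self) -> list[LipidSpecies]:
        from .chem import parse_species_id

        return [parse_species_id(sid) for sid in self.internal_standards]

    def all_species(self) -> list[LipidSpecies]:
        return self.species_grid() + self.standard_species()

    def transitions(self) -> list[Transition]:
        return [transition_for(sp) for sp in self.all_species()]

    def standards_frame(self) -> pd.DataFrame:
        from .chem import parse_species_id

        return pd.DataFrame(
            [
                {
                    "class": parse_species_id(sid).lipid_class.name,
                    "species_id": sid,
                    "spiked_pmol": pmol,
                }
                for sid, pmol in self.internal_standards.items()
            ]
        )

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(self.model_dump_json()), fh, sort_keys=False)


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative noise; degenerate to 1 when cv = 0."""
    if cv == 0:
        return np.ones(() if size is None else size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=size)


def _condition_rng(config: SimulationConfig, condition: str, stream: int) -> np.random.Generator:
    digest = hashlib.sha256(f"{condition}/{stream}".encode()).digest()
    sub = int.from_bytes(digest[:4], "big") % (2**31)
    return np.random.default_rng([config.seed, sub])


def composition_mean(config: SimulationConfig, condition: str) -> pd.Series:
    """Expected composition (proportions summing to 1) per species.

    Class weights are preserved; the condition tilt acts within each class
    on the chain profile, so a shift changes chain composition while the
    head-group distribution moves only through sampling noise.
    """
    try:
        alpha, beta = config.condition_shifts[condition]
    except KeyError:
        raise KeyError(
            f"condition {condition!r} not in config.condition_shifts"
        ) from None
    total_w = sum(config.class_weights.values())
    vals = {}
    for cls_name, cls_w in config.class_weights.items():
        prof = config.chain_profiles[cls_name]
        ids, logw = [], []
        for c in prof.c_values:
            for d in prof.d_values:
                ids.append(f"{cls_name} {c}:{d}")
                logw.append(prof.log_weight(c, d) - alpha * d - beta * (c - prof.c_mean))
        w = np.exp(np.array(logw) - max(logw))
        w = w / w.sum() * (cls_w / total_w)
        vals.update(dict(zip(ids, w)))
    return pd.Series(vals, name="proportion")


def simulate_lipidome(
    config: SimulationConfig, condition: str, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """True pmol amounts per sample × species under one condition.

    Per-sample compositions are Dirichlet draws around the condition's mean
    composition; totals vary log-normally around ``total_pmol`` (the
    between-replicate variation that Mol% reporting removes).
    """
    rng = rng if rng is not None else _condition_rng(config, condition, 0)
    mean = composition_mean(config, condition)
    alpha = config.dirichlet_concentration * mean.to_numpy()
    rows = []
    for i in range(config.n_samples):
        props = rng.dirichlet(alpha)
        total = config.total_pmol * _lognormal_factors(rng, config.total_cv, None)
        sample = f"{condition}_{i + 1}"
        for sid, p in zip(mean.index, props):
            cls_name, cd = sid.split(" ")
            c, d = cd.split(":")
            rows.append(
                {
                    "sample": sample,
                    "condition": condition,
                    "species_id": sid,
                    "class": cls_name,
                    "c": int(c),
                    "d": int(d),
                    "true_pmol": float(p * total),
                    "true_proportion": float(p),
                }
            )
    return pd.DataFrame(rows)


def simulate_mrm_signals(
    truth: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Forward-model MRM signal rows from true amounts.

    Applies the type-II contamination measured(d) = response·[true(d) +
    f(d+1)·true(d+1)] within every desaturation series, adds the internal
    standards at their spiked amounts, and emits one row per replicate
    measurement with mean-one log-normal noise.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    species = config.all_species()
    factors = correction_factors(species, resolution=config.resolution)
    fvals = {sid: cf.factor for sid, cf in factors.items()}
    transitions = {t.species_id: t for t in config.transitions()}
    n_rep = config.technical_replicates * config.measurements_per_replicate

    rows = []
    for sample, sgrp in truth.groupby("sample", sort=False):
        amounts = dict(zip(sgrp["species_id"], sgrp["true_pmol"]))
        for sid, pmol in config.internal_standards.items():
            amounts[sid] = pmol
        # contaminated (noise-free) intensity per species
        meta = {}
        for sid in amounts:
            cls_name, cd = sid.split(" ")
            c, d = map(int, cd.split(":"))
            meta[sid] = (cls_name, c, d)
        by_key = {(m[0], m[1], m[2]): sid for sid, m in meta.items()}
        for sid, (cls_name, c, d) in meta.items():
            response = config.class_response.get(cls_name, 1.0)
            contaminant = by_key.get((cls_name, c, d + 1))
            signal = amounts[sid]
            if contaminant is not None:
                signal = signal + fvals[contaminant] * amounts[contaminant]
            t = transitions[sid]
            noise = _lognormal_factors(rng, config.noise_cv, n_rep)
            for k in range(n_rep):
                rows.append(
                    {
                        "sample": sample,
                        "polarity": t.polarity,
                        "q1_mz": t.q1_mz,
                        "q3_mz": t.q3_mz,
                        "intensity": response * signal * noise[k],
                    }
                )
    return pd.DataFrame(rows)


def simulate_phosphate(
    samples: list[str], config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    vals = config.phosphate_nmol * _lognormal_factors(rng, config.phosphate_cv, len(samples))
    return pd.DataFrame({"sample": samples, "phosphate_nmol": vals})


def simulate_gcms(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    channels: list[SterolChannel] | None = None,
) -> pd.DataFrame:
    """Gaussian-peak chromatogram on the computed sterol channels.

    Each sterol contributes a Gaussian at its retention time on its own
    channel m/z, scaled so the trapezoidal peak area equals the configured
    amount; a constant baseline plus optional additive noise (clipped at
    zero) covers every channel.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    channels = channels if channels is not None else DEFAULT_STEROLS
    by_name = {ch.name: ch for ch in channels}
    for peak in config.sterols:
        if peak.name not in by_name:
            raise KeyError(f"no sterol channel defined for {peak.name!r}")
    for a in config.sterols:
        for b in config.sterols:
            if a.name < b.name and abs(a.rt_min - b.rt_min) < 3 * max(a.sigma_min, b.sigma_min):
                warnings.warn(
                    f"sterol peaks {a.name} and {b.name} closer than 3 sigma",
                    stacklevel=2,
                )
    rt = np.arange(config.gc_rt_start, config.gc_rt_end + config.gc_rt_step / 2, config.gc_rt_step)
    rows = []
    for scan_index, t in enumerate(rt):
        for ch in channels:
            y = config.gc_baseline
            for peak in config.sterols:
                if by_name[peak.name] is not ch:
                    continue
                amplitude = peak.amount_pmol / (peak.sigma_min * np.sqrt(2 * np.pi))
                y += amplitude * np.exp(-((t - peak.rt_min) ** 2) / (2 * peak.sigma_min**2))
            if config.gc_noise_sd > 0:
                y = max(y + rng.normal(0.0, config.gc_noise_sd), 0.0)
            rows.append(
                {
                    "scan_index": scan_index,
                    "rt_min": float(t),
                    "mz": ch.mz,
                    "intensity": float(y),
                }
            )
    return pd.DataFrame(rows)


def simulate_experiment(
    config: SimulationConfig, conditions: tuple[str, ...] = ("mock", "treatment")
) -> dict[str, pd.DataFrame]:
    """All pipeline inputs for a multi-condition experiment.

    Returns truth, signals, standards, phosphate and chromatogram tables;
    sample ids are '<condition>_<i>'. Deterministic in (config, seed).
    """
    truths, signals, phosphates = [], [], []
    for cond in conditions:
        truth = simulate_lipidome(config, cond, _condition_rng(config, cond, 0))
        truths.append(truth)
        signals.append(
            simulate_mrm_signals(truth, config, _condition_rng(config, cond, 1))
        )
        phosphates.append(
            simulate_phosphate(
                sorted(truth["sample"].unique()), config, _condition_rng(config, cond, 2)
            )
        )
    return {
        "truth": pd.concat(truths, ignore_index=True),
        "signals": pd.concat(signals, ignore_index=True),
        "standards": config.standards_frame(),
        "phosphate": pd.concat(phosphates, ignore_index=True),
        "chromatogram": simulate_gcms(config, _condition_rng(config, "gcms", 3)),
    }


def write_experiment(config: SimulationConfig, outdir: str | Path,
                     conditions: tuple[str, ...] = ("mock", "treatment")) -> dict[str, Path]:
    """Write every generator output as CSV plus the config used."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = simulate_experiment(config, conditions)
    paths = {}
    for name, df in tables.items():
        paths[name] = outdir / f"{name}.csv"
        df.to_csv(paths[name], index=False)
    config.to_yaml(outdir / "config.yaml")
    logger.info(
        "simulated experiment: seed=%d config_hash=%s -> %s",
        config.seed, config.config_hash(), outdir,
    )
    return paths
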