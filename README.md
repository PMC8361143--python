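# lipidmrm

Quantification pipeline for shotgun lipidomics by multiple-reaction
monitoring (MRM), with type-II isotopic-overlap correction, plus GC-MS
sterol quantification — the analysis chain used for whole-animal
(*C. elegans*-style) lipidome profiling.

Direct-infusion MRM identifies a glycerophospholipid by its class-specific
transition: Q1 selects the precursor adduct, Q3 a head-group fragment
(PC → 184.07, PI → 241.01) or a neutral loss (PE → 141.02, PS → 87.03);
cardiolipin is read as [M−2H]²⁻ with fatty-acid carboxylate fragments.
Because species of one class with equal total carbons differ by 2 Da per
double bond, the M+2 isotopologue (chiefly ¹³C₂) of a species with d+1
double bonds contaminates the transition of the species with d. The
correction subtracts, stepwise from the most desaturated species down,

    J(d) = I(d) − f(d+1) · J(d+1),
    f = M+2_theoretical · (n_heavy / m_total)²

where M+2_theoretical is the M+2 : M+0 abundance ratio of the precursor
ion after merging isotopologue fine structure at mass resolution 5000,
m_total is the lipid's carbon count and n_heavy the carbons of the
fragment that must carry both ¹³C for the contaminated transition to still
register. Corrected intensities become amounts via class internal
standards (amount = I/I_IS × spiked pmol), are normalized to total
phosphate, and are reported as Mol%. Sterols are quantified from GC-MS
extracted-ion traces (384.3 / 386.3 / 400.3) against the ergosterol
standard (398.3). A synthetic-data generator simulates every input with
known ground truth.

## Worked example

```python
from lipidmrm import (SimulationConfig, simulate_experiment, run_pipeline,
                      make_species, transition_for, class2_correction_factor,
                      saturation_marginals, condition_contrast)

t = transition_for(make_species("PC", 34, 2))
print(round(t.q1_mz, 4), "->", round(t.q3_mz, 4))
# 758.5694 -> 184.0733        (Q1 [M+H]+, Q3 phosphocholine cation)

cf = class2_correction_factor(make_species("PC", 34, 2))
print(round(cf.m2_theoretical, 4), cf.n_heavy, cf.m_total, round(cf.factor, 4))
# 0.1246 37 42 0.0967
```

A PC 34:2 ion has a 12.46% theoretical M+2 relative to its monoisotopic
peak; 37 of its 42 carbons sit outside the monitored C₅ head fragment, so
9.67% of the PC 34:3 corrected signal is subtracted from PC 34:2.

```python
cfg = SimulationConfig(seed=1)                     # 6 samples/condition, 10% noise
tables = simulate_experiment(cfg)                  # mock vs treatment
res = run_pipeline(tables["signals"], cfg.transitions(), cfg.all_species(),
                   tables["standards"], tables["phosphate"])
sat = saturation_marginals(res.quant)
groups = {s: s.rsplit("_", 1)[0] for s in sat.index}
print(condition_contrast(sat, groups, "treatment", "mock").round(2))
```

```
           mean_treatment  sem_treatment  mean_mock  sem_mock  mean_difference
saturated            8.17           0.13       4.11      0.08             4.06
mufa                42.06           0.32      31.89      0.31            10.17
pufa                49.77           0.21      64.00      0.29           -14.23
```

The simulated treatment shifts the lipidome from polyunsaturated (−14.2
Mol%) toward saturated (+4.1) and mono-unsaturated (+10.2) species — the
generator's injected acyl-chain shift, recovered through the full
match → de-isotope → normalize → aggregate chain.

The same pipeline is available from the shell:

```bash
lipidmrm simulate --seed 5 --out run/
lipidmrm quantify --signals run/signals.csv --standards run/standards.csv \
                  --phosphate run/phosphate.csv --out run/quant/
lipidmrm sterols  --chromatogram run/chromatogram.csv --is-amount 100 \
                  --out run/sterols.csv
```

See `docs/methods.md` for the model, conventions and generator details.

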