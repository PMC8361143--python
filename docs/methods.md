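# Methods

`lipidmrm` implements the quantification chain of a shotgun-lipidomics
experiment on whole-animal lipid extracts: class-resolved MRM transitions,
theoretical M+2 isotopologue abundances, the type-II isotopic-overlap
correction with its fragmentation term, the stepwise de-isotoping cascade,
internal-standard and phosphate normalization to Mol%, and single-ion GC-MS
sterol quantification. A synthetic-data generator produces every input the
chain consumes, with known ground truth, so the whole analysis runs and is
validated at desk scale.

## Mass engine

Species are identified at sum-composition level — (class, total acyl
carbons c, total double bonds d) — because head-group precursor-ion and
neutral-loss scans cannot resolve the chain split. Neutral formulas are
built constructively: glycerol backbone(s) + phosphoric acid unit(s) + head
group + combined acyls, minus one water per ester and per phosphoester bond
(4 waters for a diacyl glycerophospholipid; 3 glycerols + 2 phosphates + 4
acyls − 8 waters for cardiolipin). Only (c, d) enters, so the formula is
independent of how carbons are distributed over chains.

Masses come from a pinned plain-text table of monoisotopic masses and
natural abundances (`src/lipidmrm/data/isotopes.tsv`, CIAAW/NIST values).
The proton mass is pinned at 1.007276 Da (= m(¹H) − mₑ) and the electron
mass at 0.000549 Da; protonation/deprotonation therefore needs no separate
electron term, while fragment ions given as full ionic compositions and the
GC-EI radical cation [M]+• are corrected by one electron mass explicitly.
Consequently ion_mz([M+H]+) − ion_mz([M−H]−) = 2 × 1.007276 Da exactly.

Transitions per class, all derived from compositions (no hard-coded m/z):

| class | polarity / charge | Q1 | Q3 rule |
|---|---|---|---|
| PC | +1 | [M+H]+ | phosphocholine cation C5H15NO4P → 184.07 |
| PE | +1 | [M+H]+ | neutral loss of C2H8NO4P → 141.02 |
| PI | −1 | [M−H]− | inositol-phosphate anion C6H10O8P → 241.01 |
| PS | −1 | [M−H]− | neutral loss of C3H5NO2 → 87.03 |
| CL | −2 | [M−2H]²⁻ | fatty-acid carboxylate anions |

Printed-value conventions: two-decimal transition constants use
round-half-up; one-decimal GC-MS channels use truncation (386.3549 →
386.3). With the ±0.5 amu matching window the convention never changes an
assignment.

CL's "different fatty acid fragments" are under-determined by the species
totals; the default Q3 list enumerates all even-carbon acyl anions with
10–26 carbons per chain that are feasible given (c, d), with a canonical
near-equal-split chain as the primary Q3 (used by the simulator); users can
match on any candidate or supply their own list.

The ergosterol GC-MS channel is modeled as the ¹³C₂ (M+2) isotopologue of
the molecular ion: ergosterol is C28H44O with [M]+• at 396.3, and the
conventional 398.3 quantification channel corresponds to the two-¹³C
isotopologue (396.339 + 2 × 1.00336 → 398.3 truncated). The channel is
computed from the composition plus the pinned ¹³C mass shift — not stored
as a constant — and the `isotope_shift` field of `SterolChannel` makes the
choice explicit and overridable.

## Isotopologue envelopes and the overlap correction

Envelopes are exact polynomial expansions over ¹³C, ²H, ¹⁵N, ¹⁷O, ¹⁸O,
³³S, ³⁴S, ³⁶S (phosphorus is monoisotopic): per element a multinomial
enumeration of heavy-isotope counts, convolved across elements, pruned at
the requested nominal shift. Distinct isotope combinations keep their exact
mass shifts (¹³C₂ at +2.00671 vs ¹⁸O at +2.00425 vs ¹³C¹⁷O at +2.00757).

`m2_theoretical` merges this fine structure the way a unit-resolution
quadrupole sees it: all isotopologues within a window of full width
M/resolution (FWHM reading; resolution defaults to 5000), centered on the
dominant ¹³C₂ peak, summed and expressed **relative to the monoisotopic
peak** — the correction subtracts from a signal that is itself a
monoisotopic-dominated measurement. At resolution 5000 every M+2
contributor of a lipid ion lies inside the window, so the result is
insensitive to the exact width (tested at ±20%). The envelope is computed
on the precursor-ion composition (neutral ± protons); computing it on the
neutral instead changes the result by <0.1% of the factor.

The type-II correction factor for a species' transition is

    f = m2_theoretical × (n_heavy / m_total)²

with m_total the carbon count of the lipid ion and n_heavy the carbons of
the fragment that must carry *both* ¹³C for the contaminated transition to
register: the complement of the monitored light fragment for precursor-ion
scans (m_total − 5 for PC, m_total − 6 for PI) and the retained charged
fragment for neutral-loss scans (m_total − 2 for PE, m_total − 3 for PS).
The squared ratio treats ¹³C placement as uniform over carbons and ignores
the small chance that one heavy atom is a non-carbon isotope — the standard
approximation for this correction. CL transitions monitor acyl fragments,
not a common head fragment, and are left uncorrected (factor 0), matching
the published scheme in which only PC, PE, PI and PS are corrected.

## De-isotoping cascade

Within each desaturation series — same class, same total carbons, members
ordered by descending d (adjacent members sit 2 Da apart on the mass axis,
2/z on m/z) — the corrected signal is

    J(d_max) = I(d_max);   J(d) = I(d) − f(d+1) · J(d+1)

applied stepwise from the most desaturated to the fully saturated species.
On the noise-free forward model measured(d) = true(d) + f(d+1)·true(d+1)
this inverts exactly (tested on 1000 random series). Negative results are
clipped to zero and flagged — noise can over-subtract, and negative
concentrations are meaningless; the flag preserves auditability. A missing
series member (gap) blocks subtraction across it: only adjacent-d overlap
is physical. Series require equal total carbon count; "same class" alone
would group species that never overlap on m/z. Note the cascade's sign
structure: raising a factor lowers the member it directly corrects but can
*raise* members further downstream — only the adjacent step is monotone.

## Quantification

Replicate reads of a transition (two technical replicates × three
measurements by default) are averaged (mean; median available). Signals
match a transition when |ΔQ1| ≤ 0.5 and |ΔQ3| ≤ 0.5 amu, boundary
inclusive; ties go to the nearest transition in the (Q1, Q3) plane and are
reported. Unmatched signals are reported, never dropped silently.

Amounts: amount = intensity / intensity(class IS) × spiked pmol, one
designated internal standard per class (di-lauroyl PC/PE/PI/PS,
tetra-lauroyl CL by default — saturated 24- and 48-carbon species absent
from the animal's lipidome). The IS is excluded from the reported
lipidome. Missing or zero-intensity standards are hard errors naming the
sample and class. Amounts are divided by the per-sample total phosphate
(scalar from a two-column CSV; the phosphate assay itself is out of scope)
and finally reported as Mol% — species amount over the summed amounts of
the reported category ('all' or per class). Phosphate cancels in Mol%;
both invariances (global intensity scale, phosphate value) are tested.

## Sterol quantification

Extracted-ion traces (|m/z − channel| ≤ 0.5) on the four computed channels
— 7-dehydrocholesterol 384.3, cholesterol 386.3, ergosterol 398.3 (IS),
lophenol 400.3 — are integrated trapezoidally above a linear baseline
through the window edges. Retention windows default to automatic detection:
±2 FWHM around the channel's dominant local maximum (>99.9% of a Gaussian's
area); explicit windows are configuration. Amounts are area ratios to the
ergosterol standard times its spiked amount, with per-sterol response
factors defaulting to 1 (area ratio = mole ratio).

## Synthetic-data generator

The generator defines the study conditions the tests run under:

* **Composition.** 161 endogenous species: PC/PE/PI/PS on c ∈ {32…40},
  d ∈ {0…6}, CL on c ∈ {64, 68, 72}, class weights PC 0.35, PE 0.35,
  PI 0.12, PS 0.10, CL 0.08. The within-class chain profile is a discrete
  Gaussian in c (mean 36, sd 2.5; CL mean 68, sd 4) and d (mean 3, sd 1.6).
  The treatment condition tilts the within-class profile by
  exp(−α·d − β·(c − c_ref)) with α = 0.25/double bond, β = 0.06/carbon,
  reproducing a shift from polyunsaturated toward shorter, saturated
  species while leaving expected class weights unchanged.
* **Biological variation.** Per-sample compositions are Dirichlet draws
  with concentration 8000 around the condition mean — ≈10% compositional
  CV for a 1 Mol% species, the regime of replicate extracts each pooled
  from thousands of animals. Totals vary log-normally (CV 0.15) around
  2000 pmol; Mol% reporting removes this, by design.
* **Measurement.** Six samples per condition; per species the forward
  contamination model above, multiplied by a per-class response factor,
  read six times with mean-one log-normal noise (CV 0.1 — log-normal
  because intensities are positive and MS noise is multiplicative).
  Internal standards are spiked at 100 pmol. Phosphate per sample is
  log-normal around 25 nmol (CV 0.1).
* **GC-MS.** Gaussian peaks (σ 0.04 min) at configured retention times
  inside the 11.5–20.25 min elution segment, on each sterol's computed
  channel; amplitude scaled so peak area equals the simulated amount;
  constant baseline plus optional additive noise.

What the generator does **not** emulate: chromatographic drift and
carry-over, in-source fragmentation, detector saturation, isobaric
interference from classes outside the transition list, ether/plasmalogen
lipids, M+4-and-higher direct overlap (the cascade propagates M+2 effects
only, as in the published scheme), and chain-resolved isomerism. Passing
tests therefore demonstrate correctness of the computational chain under
its own model assumptions, not robustness to these real-data effects.

## Validation strategy and problem sizes

* The mass engine reproduces the four printed transition constants and the
  four sterol channels from compositions alone, and is cross-checked
  against an independent mass library on reference formulas.
* `m2_theoretical` agrees within 1e−6 with an independent atom-by-atom
  brute-force expansion on 50 random lipid-scale formulas (up to C60).
* The cascade inverts the forward contamination model exactly on 1000
  random noise-free series of length ≤ 8.
* End-to-end recovery: 100 seeded runs at CV 0.1, n = 6 per condition;
  per species the recovered Mol% (mean of six replicates) lies within
  3 SEM of the generator composition for ≥95% of species (measured ≈97%),
  and the injected saturation shift is recovered with the correct sign in
  ≥95/100 runs (measured 100/100). The 3-SEM/95% envelope was fixed by a
  one-time Monte-Carlo calibration under these exact conditions.
* Conservation: Mol% sums to 100 per sample at every aggregation level;
  Gaussian peak areas match A·σ·√(2π) within 1%.

These sizes (161 species, 12 samples, 100 runs) keep the full validation
in the order of a minute while exercising every code path at realistic
dimensionality.

## Known limitations

* Only the five glycerophospholipid classes ship with transition rules;
  sphingolipid fractions require user-supplied rules and standards (the
  machinery is class-agnostic).
* Species identity is (class, c, d); sn-positional and double-bond
  positional isomers are out of scope.
* mzML/raw ingestion is an extension point, not implemented; inputs are
  tabular signal lists.
* Inferential statistics on profiles are out of scope; contrasts are
  descriptive (means, SEMs, differences).
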