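# Methods

## Physical model

The screen measures the gas-phase stability of non-covalent
phenolic–nucleoside adducts formed during electrospray when a dG or G
solution is infused post-column. Because the nucleosides' proton affinities
exceed those of phenolics, an adduct [M+dG/G+H]⁺ is modeled as a neutral
phenolic bound to a protonated nucleoside, and its dissociation regenerates
exactly those species; the survival ratio [M+dG/G+H]⁺/[M+H]⁺ at a given
activation energy therefore tracks the adduct's binding strength. In the
10–30 V cone-voltage range the phenolics themselves do not fragment, so the
free-ion denominator is well defined at every voltage.

### Collision-energy scale

In-source CID on a single quadrupole has no collision cell; the cone
voltage plays the role of the laboratory collision energy, numerically
E_lab (eV) = cone voltage (V) for a singly charged ion. The maximum energy
transferable into internal modes in a single collision with a gas molecule
of mass m_g is the center-of-mass fraction E_lab·m_g/(m_p+m_g). Ions of
different size spread that energy over different numbers of vibrational
modes, so curves are compared on the corrected scale

    E_comδ = δ · E_lab · m_g / (m_p + m_g),    δ = DOF_ref / DOF_adduct,

with DOF = 3N − 6 counting every atom of the ion (added proton included)
and the reference chosen as the minimum-DOF adduct of the analyzed set, so
δ ∈ (0, 1] and δ = 1 for the reference. The correction factor δ multiplies
the whole center-of-mass term. When a caller supplies a non-minimal
reference, δ > 1 is computed without error but logged as a warning.

For the built-in five-compound panel the smallest nucleoside adduct is that
of the kavalactone glucoside C20H22O9 (51 atoms; its protonated-dG adduct
has 84 atoms → DOF 246, the G adduct 85 atoms → DOF 249). DOF values are
always derived from 3N − 6 at run time, never tabulated.

### Units and constants

Masses are monoisotopic, in Da treated interchangeably with amu; m_g
defaults to 28 (N₂). The electron mass (0.00055 Da) is ignored in all m/z
values — three orders of magnitude below the unit-resolution use case.
Nominal m/z is the sum of most-abundant-isotope integer mass numbers
(C=12, H=1, N=14, O=16, Cl=35), computed directly from the composition
rather than by rounding the monoisotopic mass, which would drift for large
ions. Chloride adducts use ³⁵Cl; formate is CHO₂. Only |z| = 1 is
supported: multiply charged species do not occur in this assay.

## Measurement pipeline

Peak lists are centroided spectra; the native dialect is a long-format CSV
(scan_time_min, cone_voltage_V, polarity, mz, intensity), with centroided
mzML also readable. Ion intensities are extracted with an absolute m/z
tolerance, default 0.5 Da (single-quadrupole unit resolution). Per
voltage, the [M+H]⁺ and [M+dG/G+H]⁺ chromatograms are integrated by the
trapezoidal rule over the compound's retention-time window — integrated
areas are robust to scan-rate changes; apex-height mode is available via
configuration. A voltage whose free-ion signal vanishes yields an
undefined ratio: the point is dropped with a warning and recorded on the
curve rather than silently propagated as an infinity, and ranking grids
are built from retained points only.

### Sigmoid summary and ranking

The survival curve is summarized by a 3-parameter logistic
r(E) = r₀/(1+exp(slope·(E−e50))) fitted by bounded least squares with a
fixed, data-derived initializer (r₀ = max ratio, e50 = median E_comδ,
slope = 4/range(E_comδ)), making fits deterministic. A flat curve or a
failed optimization returns a flagged fit instead of raising. The fit is a
package addition for reproducible single-number comparison — the
experiment itself only compares curves — so ranking also offers a
model-free mode: mean ratio on the energy interval shared by all curves
(linear interpolation, no extrapolation), which is the default. Ties break
lexicographically by compound name. Curves obtained with dG are never
ranked against curves obtained with G: the two reagents are infused from
different solvents, so absolute adduct yields are not comparable between
them.

## Synthetic-data generator

The simulator emulates the acquisition design of the screening experiment:
cone voltages 10, 15, 20, 25, 30 V; analytes eluting at 5–6 min; reagent
infusion over 4.5–6.5 min; m/z range 100–1000; scans every 0.02 min
(~100 scans across a 2-min window — desk scale). Each compound's [M+H]⁺
elutes as a Gaussian; inside the infusion window the adduct appears with
intensity

    I_adduct = I_free · adduct_fraction · S(E_comδ),
    S(E) = 1 / (1 + exp(slope_true · (E − e50_true))),

where E_comδ is computed by the same energetics code the analyzer uses,
with the reference auto-selected over the simulated adduct set. The
logistic survival shape is a modeling choice — the experiment implies only
a monotone decay — chosen because it is the standard survival-yield form
and makes the e50 summary well posed. Noise is multiplicative
mean-preserving lognormal per peak with CV 5%, matching the day-to-day
relative-abundance stability of the emulated instrument class; intensities
stay positive by construction. All randomness flows from a mandatory seed,
and a ground-truth JSON record (binding parameters, per-voltage E_comδ,
reference DOF) suffices to compute every expected ratio offline.

The built-in panel's binding parameters place the three extract phenolics
(adduct_fraction 0.50–0.60, e50 0.70–0.80 eV) above rutin (0.30, 0.55 eV)
above isoquercitrin (0.15, 0.42 eV), with ≥ 25% relative separation in e50
between the groups — a well-separated ordering consistent with the known
stabilizing effect of sugar moieties and C3-OH methylation. Slopes are a
uniform 8 eV⁻¹, in the middle of the decay rates the 0.3–1.2 eV energy
window can resolve with five voltages.

What the simulator does *not* emulate: isotope envelopes, chromatographic
tailing, ion suppression, detector saturation, drift between runs, or
m/z-dependent response. Passing tests therefore demonstrate the
correctness of the bookkeeping and statistics on idealized signals, not
robustness to real-instrument artifacts.

## Numerical choices

- Trapezoidal integration returns 0 for windows containing fewer than two
  scans; apex mode returns 0 for empty windows.
- The logistic's exponent is clipped at ±500 to avoid overflow during
  optimization; parameter bounds are (0, 10·max ratio] for r₀,
  (0, 10·max E] for e50 and (0, 10⁴/range(E)] for slope.
- Simulated peaks below 10⁻³ counts (far Gaussian tails) are not recorded —
  an effective detection floor that never touches a peak inside an elution
  window.
- Reference-adduct selection breaks DOF ties by monoisotopic mass, then
  label, for determinism.

## Known limitations

- E_comδ is a single-collision upper bound; multiple-collision conditions,
  kinetic shifts and RRKM effects are out of scope, as is any absolute
  thermochemistry (the e50 is an instrument-conditional midpoint, not a
  binding constant).
- The survival model treats adduct formation and decomposition as
  separable; competing in-source processes (e.g. glycosidic cleavage above
  30 V) are outside the modeled voltage range.
- Apex-vs-area choice can matter for strongly tailing real peaks; the
  simulator's symmetric peaks cannot distinguish the two.
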