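# Methods

## Quantification model

The deconvolution assumes that (i) signal area is proportional to proton
count with a single spectrum-wide constant *C*, (ii) the six integration
windows (3.91–3.95, 3.82–3.84, 3.72–3.74, 4.05–4.10, 4.11–4.38 and
2.28–2.38 ppm, treated as closed intervals) each contain the full signal
of the listed protons and nothing else, and (iii) every acyl chain —
esterified or free — contributes exactly 2 protons to the α-CH₂ window.
Under these assumptions the window × species proton-count matrix is
triangular and the per-species mole numbers are its back-substitution;
the implementation uses the explicit back-substitution formulas and the
test suite checks them against a generic linear solve (`numpy.linalg`)
on random compositions to 10⁻¹⁰.

2-MAG contributes no protons to the 4.11–4.38 ppm ester envelope: its
glyceryl CH₂OH resonates at 3.84 ppm and its single ester proton (CHOCO)
falls outside the envelope, which is what the TAG equation implies. FFA
carries `acyl_count = 1` purely for α-CH₂ bookkeeping; it has no glyceryl
protons anywhere.

Mole percentages divide by the sum over all six species, so they are
invariant under rescaling of *C*, of the raw intensities, or of the
instrument gain (TMS normalization cancels gain exactly). Weight
percentages weight the pooled classes by the oleoyl-reference masses;
both DAG isomers use M_DAG. The stored masses are the conventional
rounded constants and are used verbatim; the esterification balance
m(n chains) = M_MAG + (n−1)(M_FA − M_H₂O) reproduces them within
0.02 g/mol and serves as a validation cross-check, not as the source of
the numbers (the printed constants and IUPAC atomic weights disagree at
the 0.01–0.02 g/mol level, and reproducibility of reported values wins).

## Integration and referencing

Window integrals use the trapezoid rule on the native ppm grid with
linear interpolation of the intensity at the window borders — no peak
fitting, because the method is defined on window areas. An optional
per-window linear baseline (the chord between the border intensities) can
be subtracted; the default is no baseline correction. The TMS reference
window defaults to ±0.05 ppm around 0 and is configurable; a non-positive
TMS integral is a hard error since every downstream number would be
meaningless.

## Numerical tolerances

Two guards handle noise-induced negatives:

* a window area may be negative down to 1 % of the largest window area
  (beyond that the baseline or referencing is presumed corrupted and the
  quantification errors out);
* a back-substituted mole number may be negative down to 5 % of the total
  before it raises; smaller negatives are clamped to zero and recorded in
  the report diagnostics.

Both bounds were set from the measured noise excursions of the simulator
at its default noise level (about 0.2 % of the largest area and 1 % of
total moles, respectively, at reference-peak SNR ≈ 1000), with a safety
factor; both are keyword-configurable.

## Synthetic spectra

Simulated spectra place one Lorentzian per quantification window at the
window midpoint, carrying the window's total stoichiometric area
(gain × Σ moles × protons). Each line is amplitude-scaled so that its
trapezoidal integral *inside its own window* equals that area exactly:
a raw Lorentzian of realistic width loses 5–25 % of its area outside a
0.02–0.05 ppm window, which would make the simulator disagree with its
own stoichiometry before any estimator runs. What remains as the honest
error source is cross-window tail leakage — for the default half-width
at half-maximum of 0.001 ppm (0.6 Hz at 600 MHz, a well-shimmed line) the
ester envelope deposits ≈ 0.06 % of its area into the adjacent 1,3-DAG
window, which biases 1,3-DAG by roughly +1 % relative and total DAG
yields by about +1 % in the noiseless limit.

The TMS line at 0.00 ppm carries 12 protons × `tms_moles`; the default
`tms_moles = 0.125` per unit of total analyte moles corresponds to the
actual sample preparation (≈ 10 mg lipid, i.e. ~11 µmol, in 425 µL CDCl₃
containing ~0.03 % v/v TMS, ~1.4 µmol), giving a reference peak of the
same height scale as the analyte lines.

Cosmetic acyl-chain signals (CH₃ 0.88, bulk CH₂ 1.30, β-CH₂ 1.61, allylic
2.02, bis-allylic 2.76, olefinic 5.35 ppm) scale with the total chain
count and the mean double bonds per chain. They are rendered as broad
*Gaussians* (HWHM 0.008–0.02 ppm): these signals are clusters of many
overlapping multiplets, and a single broad Lorentzian's 1/Δ² wings would
deposit area in the analyte windows that no real multiplet cluster
produces. The glyceryl CH/CH₂OH signals of 1-MAG (3.65), 1,2-DAG (5.08)
and TAG (5.26 ppm) are added as small Lorentzians. Additive Gaussian
noise has sd = 10⁻³ × the tallest peak by default. All randomness flows
through explicit seeds; there is no global random state.

What the simulator does **not** model: J-coupling multiplet structure,
phase/baseline distortion, chemical-shift drift, solvent and impurity
signals, phospholipid signals (the 3.67 ppm region is observed in real
fungal extracts but excluded from quantification), and any correlation
between noise points. Passing the recovery tests therefore demonstrates
correctness of the stoichiometric inversion and robustness to white noise
and gain — not robustness to mis-referencing or baseline error in real
spectra.

Default problem sizes: 2¹⁶-point grid over 10.0 to −0.5 ppm; recovery
suites use 10 noiseless and 50 noisy compositions, and the batch fixture
five strains — small enough that the full suite runs in seconds while the
Monte-Carlo means are stable to well within the asserted bounds.

## FAME summaries

Area normalization is rel% = 100·area/Σarea over detected peaks; "nd"
(not detected) entries stay in the profile as exact zeros, which matches
how the reference table's own class sums treat them. Class membership is
decided purely by the Cx:y code (SFA y=0, MUFA y=1, PUFA y≥2); no isomer
or ω-position handling. Profiles whose percentages sum outside
[95, 100.5] warn rather than error, since printed columns round to ≈100.

The packaged reference table transcribes the published composition of
five endophytic fungal strains verbatim. Recomputing its class rows from
the FA rows reproduces the printed summary rows within print rounding
(0.02 points) for 16 of the 20 columns; nine printed cells in the
remaining four columns (MLP41 crude C16+C18, MLG23 crude MUFA/UFA,
MLY23 1,2-DAG SFA, and five cells of the MLGP11 TAG column) disagree by
0.09–2.78 points and are treated as errata of the printed table — the
package reports the recomputed values, and
`lipidquant.data.printed_sum_discrepancies()` lists the full set.

## Yield arithmetic

CDW = m₁/V (g/L); lipid yield = CDW × m₄/m₃ (g/L); DAG isomer yields are
lipid yield × wt% × 10 (mg/L) and the total is exactly their sum. Inputs
are validated (positive volume and powder mass, m₄ ≤ m₃, weight
percentages within [0, 100] and jointly ≤ 100).

## Design choices and limitations

* Reported CSVs round to two decimals (the conventional reporting
  precision for percentages and mg/L); JSON output keeps full precision.
* The CLI is a single `lipidquant` entry point with subcommands; each
  subcommand is a thin wrapper over one library function.
* Windows at exactly coincident boundaries (e.g. 4.10/4.11) follow the
  printed bounds literally; how a real integrator splits signal exactly
  at a boundary is not modeled.
* The undetermined 3.98/3.99 ppm signals and the phospholipid-like
  3.67 ppm signal are represented in the assignment table but never
  quantified.
* Per-sample molecular masses resolved from the measured FA composition
  are out of scope; the oleoyl reference is fixed.
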