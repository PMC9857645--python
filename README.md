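# lipidquant

Quantification of acylglycerol classes in microbial lipids from ¹H NMR
spectra, with GC-MS FAME composition summaries and fermentation yield
arithmetic.

## The problem

Oleaginous fungi accumulate storage lipids as a mixture of
triacylglycerol (TAG), the two diacylglycerol positional isomers
(1,2-DAG and 1,3-DAG), monoacylglycerols (1-MAG, 2-MAG) and free fatty
acids (FFA). When DAG is the product of interest — it is a reduced-calorie
fat substitute and emulsifier — a fermentation screen needs the *class
composition* of each crude lipid extract, not just the lipid mass. A 600
MHz ¹H spectrum of the extract in CDCl₃ resolves glyceryl-backbone signals
specific to each class, so the composition can be read off a single
spectrum without any chromatographic separation.

## The method

The area *A* of a signal is proportional to the number of protons that
produce it. With the TMS reference integral normalized to 1, six
chemical-shift windows determine the six species (N in units of the
proportionality constant *C* × area):

```
N_1-MAG  =  C·A[3.91-3.95]                      (glyceryl CHOH, 1H)
N_2-MAG  =  C·A[3.82-3.84] / 4                  (2 × CH2OH, 4H)
N_1,2-DAG = C·A[3.72-3.74] / 2                  (CH2OH, 2H)
N_1,3-DAG = C·A[4.05-4.10]                      (CHOH, 1H)
N_TAG    = (C·A[4.11-4.38] − 2N_1-MAG − 2N_1,2-DAG − 4N_1,3-DAG) / 4
N_FA     = (C·A[2.28-2.38] − 6N_TAG − 4N_1,2-DAG − 4N_1,3-DAG
                            − 2N_1-MAG − 2N_2-MAG) / 2
```

The 4.11–4.38 ppm window is the ester CH₂OCO envelope (4 protons per TAG
after removing the partial-glyceride contributions) and 2.28–2.38 ppm is
the α-CH₂ signal carrying 2 protons per acyl chain of *every* species,
which isolates the free fatty acid as the remainder. These are exactly the
back-substitution of the triangular window × species proton-count matrix;
*C* cancels in all mole percentages. Weight percentages use the oleoyl
(C18:1) reference masses M_MAG = 356.54, M_DAG = 620.98, M_TAG = 885.43,
M_FA = 282.46 g/mol, and DAG yields follow as

```
1,2-DAG yield (mg/L) = lipid yield (g/L) × 1,2-DAG wt% × 1000 / 100
```

with the lipid yield from cell-dry-weight productivity (CDW = m₁/V) times
the lipid fraction of the extracted mycelium powder (m₄/m₃).

GC-MS FAME peak tables are area-normalized to relative percentages and
summarized into SFA / MUFA / PUFA / UFA classes, the C16+C18 and C18
shares, and the weighted mean chain length. A reference composition table
of five DAG-producing endophytic fungal strains (crude lipids and their
TLC-separated TAG / 1,2-DAG / 1,3-DAG fractions) ships with the package.

Because no raw spectra accompany the reference data, the package includes
a synthetic-data generator: Lorentzian-line spectra with exact in-window
stoichiometric areas, a TMS reference, broad acyl-chain envelopes and
Gaussian noise; lognormal-noised FAME tables; and full fermentation batch
fixtures with a ground-truth manifest for end-to-end validation.

## Worked example

Simulate a spectrum of a typical composition (70 mol% TAG, 10% 1,2-DAG,
15% 1,3-DAG, 2% MAG, 3% FFA) and quantify it:

```
$ lipidquant simulate-nmr --seed 11 --out demo.txt
wrote demo.txt and demo.truth.json
$ lipidquant quantify-nmr --spectrum demo.txt --out demo_report
MAG: 1.78 mol%  0.80 wt%
1,2-DAG: 10.18 mol%  7.97 wt%
1,3-DAG: 15.03 mol%  11.77 wt%
DAG: 25.20 mol%  19.74 wt%
TAG: 70.24 mol%  78.47 wt%
FA: 2.78 mol%  0.99 wt%
```

The recovered mole percentages sit within a few tenths of a point of the
simulated truth at the default noise level; the weight percentages weight
each class by its reference molecular mass, so the heavy TAG dominates by
weight even more than by moles. `demo_report.json` holds the full
precision report plus diagnostics (TMS signal-to-noise, any clamped
near-zero classes); `demo_report.csv` is the two-decimal summary.

The same classes drive yields: a 2.5 g/L lipid yield with 3.10 wt%
1,2-DAG and 4.49 wt% 1,3-DAG gives 77.55 + 112.32 = 189.87 mg/L total DAG.

An end-to-end run over a generated five-strain batch:

```
$ lipidquant make-fixture --seed 42 --out fixture/
$ lipidquant pipeline --input fixture/ --out results/
processed 5 samples -> results/
```

`results/yields.csv` then reproduces the manifest's true total DAG yields
within 5 % relative at the default noise level.

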