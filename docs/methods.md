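# Methods

## The correction problem

A stable-isotope labelling experiment measures, for one compound, the
intensities of a set of *isotopologues*: the unlabelled species and the
species carrying one or more tracer atoms (e.g. the twice-acetylated
histone H3 peptide KQLATKAAR measured as M+0, M+2 and M+4, where each
labelled acetyl group contributes two ¹³C). The measured intensities are
not the labelling signal alone: every species also carries naturally
occurring heavy isotopes (~1.07% ¹³C per carbon atom, 0.36% ¹⁵N per
nitrogen, ...), so part of the intensity at a heavier isotopologue's peak
position is natural contamination from lighter species. For a peptide
with 46 carbons this contamination is large — about 19% of the
unlabelled species' signal lands on the M+2 position — and ignoring it
materially distorts estimated modification dynamics.

## Model

### Fine structure

For a formula with element counts `n_e` and per-element isotope
abundances `a_0, a_1, …` (index 0 = the principal, most abundant
isotope), the probability of one combination of heavy-isotope counts is
the product over elements of multinomial terms

    P = Π_e  multinomial(n_e; k_1, k_2, …) · a_0^(n_e − Σk) · Π_i a_i^(k_i)

and its exact mass shift is the sum of per-atom heavy-minus-principal
mass differences. Shifts are kept as exact masses throughout; nominal
(integer) grouping is only ever a limiting case. The abundance and mass
table ships as an editable YAML file (standard NIST/IUPAC values:
¹³C 0.0107, ²H 0.000115, ¹⁵N 0.00364, ¹⁷O 0.00038, ¹⁸O 0.00205,
³³S 0.0075, ³⁴S 0.0425, ³⁶S 0.0001) and can be overridden wholesale.

Enumeration is per element, bounded by the requested maximum shift, then
convolved across elements. Species with probability below a prune
threshold (default 1e-10) are dropped; since every convolution factor is
≤ 1, pruning partial products cannot discard a species whose final
probability would survive. The enumeration is cross-checked in the test
suite against an independent exact oracle that enumerates every per-atom
isotope assignment (feasible up to 8 atoms).

### Resolution-dependent merging

Whether a natural fine-structure species is distinguishable from a
tracer shift depends on resolving power R (m/z over FWHM). Orbitrap
analyzers are quoted at a reference m/z (commonly 200) and lose
resolving power as the inverse square root of m/z:

    R(mz) = R_ref · sqrt(mz_ref / mz)        (orbitrap mode)

Two species merge when their neutral-mass difference is below
`separation_coefficient × FWHM × charge`. The separation coefficient
defaults to 1.66, the multiple of the FWHM at which two equal Gaussian
peaks become baseline-separable; it is configurable. A `constant` mode
serves FT-free instruments, and a `nominal` mode (merge everything
within 0.5 Da of neutral mass) reproduces classical unit-resolution
correction. The merge window is evaluated once per correction run, at
the unlabelled compound's m/z: across a label series the window varies
by well under 1% and a single representative point keeps the matrix
construction simple.

### Skewed correction matrix

Let the measured isotopologues be labels `j = 0 … m` in ascending exact
shift. The transition probability

    T[i, j] = Σ { P(σ) : σ in fine structure of residual(formula, j),
                  |shift(σ) − (shift_i − shift_j)| < merge window }

uses the *residual* formula of column j — the molecule minus its
labelled atoms, which are isotopically fixed by the tracer. This is the
"skewed" construction: columns for more heavily labelled species have
fewer atoms able to pick up natural heavy isotopes, so their spillover
is strictly smaller, and a species whose tracer-element atoms are
exhausted cannot contribute to heavier carbon-shift positions at all. A
classical-matrix mode, which reuses the intact molecule's distribution
for every column, is provided for comparison; it inflates heavy
isotopologues (the test suite demonstrates the bias on simulated data).

The matrix is built only over the isotopologues actually supplied —
incomplete series (e.g. M+0/M+2/M+4 without the odd positions) are
supported, with a warning listing plausible skipped intermediates for
single-tracer experiments.

### Solving and normalising

T is lower-triangular with positive diagonal, so per sample
`obs = T·c` is solved by forward substitution in ascending shift order:

    c_j = (obs_j − Σ_{k<j} T[j,k]·c_k) / T[j,j]

Measured values are interpreted as the monoisotopic (lowest-mass) peak
of each isotopologue's envelope; dividing by the diagonal rescales them
to whole-species abundance, which is what makes the forward model and
the correction exact inverses of each other. A corrected value driven
negative by measurement noise is clipped to zero before heavier rows are
processed, and the clipped magnitude is logged; clipping was chosen over
a constrained least-squares refit because it is simple, reproducible,
and matches the expected behaviour at time zero, where every labelled
isotopologue should correct to exactly nothing. Relative fractions are
computed per sample after clipping; correction is applied per replicate,
with any averaging left to downstream analysis.

## Dynamics

Label incorporation is summarised by the slope of each isotopologue's
relative abundance against time: an ordinary least-squares line through
all (time, abundance) points pooled across replicates
(`scipy.stats.linregress`), with the analytic OLS slope standard error.
Pooled fitting is the default (per-replicate fits averaged afterwards
would weight unbalanced designs differently); an optional time window
restricts the fit to the early, approximately linear part of a
saturating curve. The relative slope change due to correction is
`(corrected − uncorrected) / |uncorrected|`.

## Synthetic data generator

`simulate.SimulationSpec` emulates a media-switch labelling experiment
on a compound with `n_sites` independently exchangeable modification
sites (default two, the acetylation sites of H3 K18/K23). Each site is
replaced by the labelled form with first-order kinetics, labelled
fraction `f(t) = 1 − exp(−k t)`, giving binomial species fractions; the
default rate 0.014 h⁻¹ yields roughly two thirds of molecules labelled
in at least one site by 24 h, matching the magnitude seen in histone
acetylation turnover. True fractions are pushed through the forward
model (`obs = T x`) and perturbed by multiplicative Gaussian noise per
peak (default CV 2%, truncated at zero), for 3 replicates over
0–24 h. The generator does not emulate chromatography, ionisation
efficiency, detector saturation, co-eluting interferences, or
tracer impurity — passing tests therefore demonstrate correctness of
the deconvolution and estimation machinery under the stated noise
model, not robustness to those instrumental effects.

## Numerical and design choices

- **Pruning threshold 1e-10, matrix entries from fine structure bounded
  at `delta + merge window`.** Discarded probability is orders of
  magnitude below the printed precision of any result.
- **Tracer atoms are treated as isotopically pure**; no enrichment
  (purity) correction is applied.
- **Protonation is the only adduct**; proton mass 1.007276 Da.
- **Deterministic ordering everywhere**: species ascending by exact
  shift with lexicographic tie-break, labels ascending by shift, so
  repeated runs are byte-identical.
- **Degenerate inputs**: an all-zero sample returns zeros with a warning
  and undefined (NaN) fractions; duplicate labels, labels exceeding the
  formula's atoms, negative or non-finite intensities, and unknown
  column names are rejected with named errors before any computation.
- **Peptide compositions** come from the standard residue table via
  `pyteomics`, plus a terminal water and named modification deltas
  (acetyl, carbamidomethyl, phospho, methyl, ... in an editable YAML
  dictionary).

## Limitations

- Quantification is MS1-level; positional isomers of the same
  isotopologue are indistinguishable and no MS/MS deconvolution is
  attempted.
- The resolution model assumes Gaussian-like peaks characterised by
  FWHM; peak-shape effects (tailing, coalescence) are out of scope.
- With very low resolving power the `orbitrap`/`constant` window can
  exceed the spacing of adjacent measured labels; the nominal mode is
  the sensible floor in that regime.
- Slope estimation is linear by design; saturating courses should be
  fitted on an early window or with an external kinetic model.
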