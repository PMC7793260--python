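# Methods

## The measurement being modelled

A spectrofluorimeter FRET experiment on fixed *E. coli* cells expressing a
donor fusion (mKO) and an acceptor fusion (mCherry). Each cuvette is scanned
twice: once with donor-band excitation (541/12 nm filter, emission collected
through a 550 nm long-pass, recorded here on a 550–700 nm grid) and once
with acceptor-band excitation (587/11 nm, 600 nm long-pass, 600–700 nm
grid). Every experiment carries its own reference cuvettes: PBS buffer, an
empty-vector ("empty cell") culture for cellular autofluorescence, a
donor-only fusion and an acceptor-only fusion. Scans are exchanged as
two-column text tables batched by a manifest; wavelengths are treated as
exact sample points (no bin semantics) and all scans of one experiment are
linearly interpolated onto a common 1 nm grid per channel, with no
extrapolation allowed.

## Spectral unmixing

After buffer subtraction, a measured spectrum is fitted as a nonnegative
linear combination of unit-Euclidean-norm component shapes measured in the
same experiment: autofluorescence background, donor emission (donor channel
only) and acceptor emission. The fit solves min‖y − Bα‖₂ s.t. α ≥ 0 via
`scipy.optimize.nnls`. Nonnegativity is a physical constraint — amplitudes
are abundances — and prevents the strongly overlapping mKO/mCherry bands
from compensating each other with opposite signs. When the unconstrained
least-squares solution is already elementwise nonnegative the two solutions
coincide (tested to 1e-8 relative).

Sensitized emission is spectrally identical to directly excited acceptor
emission, so it is **not** a basis column (it would be perfectly collinear
with the acceptor shape). Instead the acceptor-only reference is fitted in
both channels and the ratio of its fitted acceptor amplitudes,
ρ = α_A(541)/α_A(587), captures direct excitation of the acceptor at the
donor wavelength. Because both channel amplitudes refer to the same cuvette,
ρ transfers to any sample regardless of intensity units or per-channel grid
norms.

Degeneracy guards: a reference whose peak is below 3× its residual noise MAD
(robust scale from first differences) is rejected as weak; an identically
zero shape or a non-finite/non-positive ρ is a degenerate reference; the
basis condition number warns above 1e4 and fails above 1e6. Residual noise
is summarized as 1.4826 × MAD of the fit residuals; each fit also reports
R² and the full residual vector for plotting/inspection.

## Acceptor FRET efficiency

For one sample, with α_A^541 and α_A^587 the fitted acceptor-shaped
amplitudes in the two channels:

    F_direct = ρ · α_A^587
    F_sens   = α_A^541 − F_direct
    Ef_A(%)  = 100 · κ · F_sens / F_direct

κ is the acceptor/donor extinction ratio at the donor excitation wavelength.
No instrument-specific value is assumed; the default κ = 1 yields
instrument-relative efficiencies, and the synthetic generator uses the same
κ, so closed-loop recovery is exact for any value. Under this definition
Ef_A estimates (true transfer efficiency) × (fraction of acceptors in
complex with a donor).

Ef_A is deliberately **not** clipped at zero. For a sample with no
interaction, F_sens scatters symmetrically around zero at the noise level;
clipping would bias every negative-control mean upward by construction
(for a true-zero group the clipped mean sits near 3.3 standard errors above
zero no matter how small the noise). Negative-control groups with slightly
negative per-replicate values are therefore expected and correct; the
reported `sensitized` amplitude, being a physical quantity, is floored at 0
and such samples carry a `negative_sensitized` QC flag. Additional QC flags
mark donor or acceptor amplitudes below 3× the fit's residual scale.

Replicates are summarized as mean ± sample SD (n−1 denominator; a single
replicate reports SD 0 with a QC flag). Group comparisons use the two-sided
pooled-variance Student's t-test (`scipy.stats.ttest_ind`, equal_var=True),
with the degenerate all-constant case defined as t = 0, p = 1 for equal
means. Star annotations follow p<0.05 → `*`, p<0.01 → `**`.

Efficiencies convert to apparent fluorophore separations through the
Förster relation E = (1 + (r/R₀)⁶)⁻¹, R₀ = 6.4 nm for mCherry–mKO; the
inverse is r = R₀((1−E)/E)^{1/6}, defined for E ∈ (0,1). A helper bounds the
distance change attributable to shortening a transmembrane helix at
0.15 nm per residue.

## Muropeptide composition

Input tables list muropeptide species with oligomer class, optional peptide
length and modification annotations (anhydro, Lys-Arg), and one
percent-peak-area column per sample. Published tables are partial, so the
schema supports explicit per-class `total` rows which take precedence over
summing species rows; whether modification sub-rows partition a class or
overlap its length rows is a per-class layout flag (defaults: disjoint for
monomers, overlapping for dimers and higher — matching how such tables are
printed). Class totals are not forced to sum to 100%; the unassigned
remainder is reported and a warning is raised outside [95, 105]%.

Derived metrics: degree of cross-linkage Σₙ areaₙ·(n−1)/n (each n-mer
carries n−1 cross-links among n peptides); mean glycan chain length
100 / (% anhydro-MurNAc chain ends) in disaccharide units, consuming the
chain-ends row as printed (it is not reconstructable as a plain sum of the
anhydro species rows); and % peptides in cross-links, reported as the plain
dimer+trimer area fraction with an explicit provenance note — the weighting
used in published tables is not derivable from the printed rows and can sit
a few percent higher (44.9 vs a printed 47.4 on the packaged plasmid-free
column), so the estimate never silently matches printed values. Likewise,
printed chain lengths can deviate from 100/chain-ends by more than the
one-decimal rounding of the printed chain-end inputs allows (e.g. a printed
2.5% cannot reproduce a printed 38.3 DS); the package computes strictly
from its inputs.

## Synthetic data generator

Emission bands are skew-normal curves with the mode anchored at the nominal
emission peak (mKO-like donor: peak 559 nm, width 25 nm, skew 4, excited
0.90 at 541 nm and 0 at 587 nm; mCherry-like acceptor: peak 610 nm, width
30 nm, skew 2.5, excited 0.30 at 541 nm and 0.95 at 587 nm). These are
nominal published-shape approximations stated in `data/defaults.yaml`, not
fits to any particular instrument. Background autofluorescence is a broad
exponential decay (60 nm constant); buffer is a flat baseline (20 counts).
Default abundances are 1000 brightness units for donor and acceptor and 200
for background.

For a sample with donor abundance D, acceptor abundance A, complex fraction
f and true efficiency E, the donor-channel amplitudes are
x_D(541)·(D − E·f·min(D,A)) for the donor (donor quenching included for
realism, though Ef_A does not use it), and x_A(541)·A + x_A(541)·E·f·min(D,A)/κ
for the acceptor; the acceptor channel carries x_A(587)·A. Because the
generator expresses amplitudes on the same unit-norm shapes the analyzer
fits, the estimator is exactly unbiased at zero noise:
Ef_A = 100·E·f·min(D,A)/A. Tandem (positive-control) samples share one
abundance for both fluorophores — one molecule carries both — so their
Ef_A equals 100·f·E exactly; heterodimer pairs scatter the two abundances
independently. Noise is additive Gaussian per wavelength with SD a fixed
fraction (default 1%) of each scan's peak; biological replicate variation
is log-normal scatter (CV 10%) on abundances and background.

Replicate structure matters: biological repeats span separately measured
cultures, and each experiment rebuilds its reference basis. The pipeline
helper therefore simulates N repeats as N independent experiments (seeds
spawned from one master seed via `numpy.random.SeedSequence`). Sharing one
noisy reference set across all repeats would instead impose a common
crosstalk-ratio offset that does not average out (group-mean scatter ~1.9
percentage points versus ~0.6 with independent references).

What the generator does **not** emulate: photobleaching, Poisson-dominated
shot noise at low counts (at fluorimeter integration times per-point counts
are high enough that Gaussian noise is adequate), wavelength-dependent
detector response, spectral bleed-through
beyond the modelled cross-excitation, and any cell-to-cell heterogeneity
beyond the log-normal abundance scatter. Passing closed-loop tests
therefore demonstrates correctness of the estimator under the stated model,
not robustness to instrument systematics absent from it.

## Problem sizes and observed performance

Closed-loop checks run at the study's replicate counts: 22 independent
tandem experiments (true efficiency 0.31) and 24 negative-control
experiments, at 1% noise on 151/101-point grids. Under these conditions the
recovered tandem group mean deviates from truth by ~0.6 percentage points
(SD across master seeds), per-replicate Ef_A scatter is ~2–3 percentage
points — the same scale as published biological-replicate SDs — and the
negative-control mean is statistically consistent with zero. The full test
suite and the acceptance script each complete in a few seconds on one CPU.

## Known limitations

- κ is not calibrated to real mKO/mCherry extinction coefficients; absolute
  efficiencies require the user to supply κ (`--kappa`).
- The fit window is the full channel grid, unweighted; a restricted or
  weighted window is configurable via the manifest grid but no automatic
  window selection is attempted.
- Muropeptide per-peptide-length totals are plain area sums over rows with
  an assigned length; dimer lengths are annotation-dependent and printed
  per-length totals that use peptide-count weighting will differ.
- One averaged scan per role is assumed (instrument-side triplicate
  averaging); raw repeated scans should be averaged upstream.
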