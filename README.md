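# fretpg

Quantification of in-vivo protein–protein interactions from spectral FRET
measurements, plus peptidoglycan muropeptide composition metrics — the two
computational workhorses of bacterial elongasome studies that pair
spectrofluorimeter FRET (mKO donor / mCherry acceptor fusions, e.g. of RodA,
PBP2, MreC, MreD) with HPLC analysis of the cell wall.

## What it computes

**Spectral unmixing.** Each emission scan (excitation 541 nm for the donor
channel, 587 nm for the acceptor channel) is decomposed by nonnegative least
squares into fixed, per-experiment reference shapes:

    y(λ) ≈ α_bg · B(λ) + α_D · D(λ) + α_A · A(λ),   α ≥ 0

where B is the empty-cell autofluorescence, D the mKO emission shape and A
the mCherry emission shape (buffer- and background-subtracted, unit
Euclidean norm). Sensitized emission is spectrally identical to directly
excited acceptor emission, so it is separated arithmetically rather than as
a basis column: the acceptor-only reference yields the crosstalk ratio
ρ = α_A(541)/α_A(587), and for a FRET sample

    F_direct = ρ · α_A^587,    F_sens = α_A^541 − F_direct,
    Ef_A(%) = 100 · κ · F_sens / F_direct

with κ the acceptor/donor extinction ratio at 541 nm (default 1, i.e.
instrument-relative efficiencies). Ef_A estimates (transfer efficiency) ×
(fraction of acceptors in complex).

**Statistics and distances.** Replicate Ef_A values are summarized as
mean ± SD (ddof 1) with n, compared by the two-sided pooled-variance
Student's t-test, and converted to apparent fluorophore separations through
the Förster relation E = (1 + (r/R₀)⁶)⁻¹ with R₀ = 6.4 nm for the
mCherry–mKO pair.

**Muropeptide composition.** From an HPLC percent-peak-area table (Glauner
nomenclature) the package derives class totals, the degree of cross-linkage
(Σₙ areaₙ·(n−1)/n over n-mers), and the mean glycan chain length in
disaccharide units (100 / % anhydro-MurNAc chain ends). A reference table
of *E. coli* LMC500 strains is packaged.

**Synthetic data.** `fretpg.synthetic` generates complete spectral panels
(references + FRET samples, both channels, known complex fraction and true
efficiency, Gaussian noise, log-normal replicate scatter) and muropeptide
tables with known targets, so the whole pipeline is testable closed-loop.

## Worked example

```sh
$ fretpg simulate --out demo/data --seed 11 --n-replicates 4 --complex-fraction 0.41
wrote 31 scans; manifest at demo/data/manifest.csv

$ fretpg unmix --manifest demo/data/manifest.csv --out demo/report
negative: Ef_A = 2.2 +/- 2.5% (n=4)
pair: Ef_A = 12.4 +/- 1.9% (n=4)
tandem: Ef_A = 30.3 +/- 2.3% (n=4)
```

The simulated panel contained a tandem donor–acceptor fusion (maximal
Ef_A: every acceptor sits next to a donor, true efficiency 0.31), a
non-interacting pair (complex fraction 0, Ef_A ≈ 0 within noise) and an
interacting pair with complex fraction 0.41 (expected Ef_A ≈ 100·0.41·0.31
≈ 12.7%). The recovered group means land on the generator's ground truth
within replicate scatter. `demo/report/` additionally holds per-scan
amplitudes and residual diagnostics, per-sample FRET results, and pairwise
t-tests with star annotations (p<0.05 → `*`, p<0.01 → `**`).

```sh
$ fretpg distance 12.7
8.8 nm
$ fretpg distance 7.9
9.6 nm
```

An Ef_A drop from 12.7% to 7.9% corresponds to an apparent separation
increase from 8.8 nm to 9.6 nm at R₀ = 6.4 nm.

```sh
$ fretpg muro | cut -f1,6,7
sample        mean_chain_length_ds  degree_crosslinkage_pct
LMC500        43.4783               23.1833
mKO           41.6667               23.4667
mKO_PBP2WT    40                    23.3
mKO_PBP2L61R  52.6316               23.3833
mKO_GlpT      43.4783               23.35
```

Cells expressing the hyperactive PBP2 L61R variant stand out with ~52
disaccharide-unit glycan chains while cross-linkage stays at ~23%.

## Layout

- `src/fretpg/spectra_io.py` — scan/manifest formats, validation, resampling
- `src/fretpg/unmixing.py` — reference basis, NNLS decomposition, diagnostics
- `src/fretpg/fret_quant.py` — Ef_A, replicate statistics, Förster conversion
- `src/fretpg/muropeptides.py` — peak-table aggregation and derived metrics
- `src/fretpg/synthetic.py` — spectral-panel and muropeptide generators
- `src/fretpg/pipeline.py` — manifest → report glue
- `src/fretpg/cli.py` — `fretpg unmix | distance | muro | simulate`

See `docs/methods.md` for the model, its assumptions, and numerical choices.
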