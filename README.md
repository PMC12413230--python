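# multipletfit

Multiplet-aware fitting of 1D and pseudo-2D NMR spectra.

`multipletfit` extracts chemical shift, intensity, area, coupling constants
and linewidth — with covariance-based uncertainties — by fitting processed
spectra with pseudo-Voigt signal models that encode coupling multiplicity
(singlet, doublet, triplet, quadruplet, doublet of doublets, plus
user-defined patterns). Pseudo-2D series are fitted row by row with
parameters propagated from a user-chosen reference spectrum, so hundreds of
kinetic spectra run unattended.

## Features

- **Signal models** (`multipletfit.models`): pseudo-Voigt lineshapes, exact
  rational first-order multiplet expansion (positions as ±½-integer
  combinations of named couplings, binomial weights summing to 1), a model
  registry with peak-count-based suggestions, and declarative YAML model
  files for custom patterns (e.g. a doublet of triplets).
- **I/O** (`multipletfit.io`): Bruker processed directories (`1r`/`2rr` with
  `procs`/`proc2s`, submatrix deblocking, `NC_proc` scaling), delimited text
  spectra (delimiter auto-detection, multi-column pseudo-2D), full-precision
  CSV export of parameters and fitted curves, and a versioned JSON session
  file whose reload reproduces exports byte-for-byte.
- **Peak picking** (`multipletfit.peaks`): local-maximum detection with
  plateau handling and a robust MAD-based automatic threshold; grouping of
  picked or manual peaks into signals (a peak may belong to several signals);
  initialization of all parameters from the peak list, with couplings solved
  exactly from inter-peak spacings.
- **Fitting** (`multipletfit.fitting`): sum-of-squared-residuals cost over
  all signals of a region, bounded L-BFGS-B minimization with an optional
  seeded differential-evolution refinement, and standard deviations from the
  finite-difference residual Jacobian (`sd = sqrt(diag(s² (JᵀJ)⁻¹))`).
- **Batch pipeline** (`multipletfit.batch`): outward visit order from the
  reference row, previous-row or reference-always propagation, relative
  bounds recentred on propagated inits, retry-then-flag failure handling.
- **Synthetic benchmarks** (`multipletfit.bench`): seeded generators for
  spectra and kinetic series (exponential/logistic/linear trajectories,
  isotopologue-style co-located multiplets), a recovery experiment over an
  overlap × noise grid, and a paired comparison of multiplet fitting against
  individually fitted peaks.

## Command line

```sh
# fit a pseudo-2D series (text file or Bruker directory) in a ppm region
fit-batch --input series.tsv --region 1.6:2.4 --signals signals.yaml \
          --reference 0 --mode prev --output results/

# write synthetic text spectra + ground-truth JSON
make-fixtures --out fixtures/ --seed 1

# run the overlap x noise recovery benchmark
run-validation --design design.yaml --out report.csv
```

The signal config is YAML:

```yaml
signals:
  - id: d1
    model: doublet
    peaks: [[1.95, 5.0], [2.05, 5.0]]   # (ppm, intensity) pairs
# model_files: [my_doublet_of_triplets.yaml]   # optional custom models
```

All three commands are also available as subcommands of `multipletfit`.

## Library example

```python
import numpy as np
import multipletfit as mf

spectrum = mf.read_text("spectrum.tsv")            # or mf.read_bruker(dir, expno, procno)
region = mf.Region(1.6, 2.4)
peaks = mf.pick_peaks(spectrum, region)            # auto threshold
print(mf.suggest_models(len(peaks)))               # e.g. ['doublet']
signal = mf.group_signal(peaks, "doublet", "d1")
signal = mf.initialize_parameters(signal, spectrum, region)
x, a = region.slice(spectrum)
result = mf.fit(mf.FitProblem(x, a, [signal], sf_mhz=spectrum.sf_mhz))
print(result.value_of("d1", "J"), "+/-", result.sd_of("d1", "J"))
```

## Conventions

- The ppm axis is normalized to ascending order internally; regions are
  closed `(ppm_min, ppm_max)` intervals.
- `lw` is the Gaussian sigma-like width and the Lorentzian half width at half
  maximum of the mixed profile; the half-height full width (which depends on
  the Gaussian fraction `a`) is reported separately as `fwhm`.
- `I` is the sum of component-peak amplitudes; component apex heights are
  `I x weight` for resolved peaks. Signal `area` is analytic:
  `I·lw·(a·√(2π) + (1−a)·π)`.
- Couplings are handled in ppm internally and additionally reported in Hz
  (`J_hz`) whenever the spectrometer frequency is known.
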