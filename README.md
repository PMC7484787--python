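# mcflim

Label-free identification of dermal mast cells with two-photon excited
fluorescence lifetime imaging (TPE-FLIM), rebuilt as a tested, fully
synthetic-data-driven pipeline.

## The problem

Mast cells (MCs) are granule-rich immune cells of the papillary dermis whose
activation (degranulation) drives urticaria, mastocytosis and allergic
disease. The routine way to count them — immunohistochemistry of punch
biopsies — is invasive and cannot follow the same cell over time. TPE-FLIM
offers a staining-free alternative: under femtosecond excitation at 760 nm,
each pixel's autofluorescence decay is fit with a bi-exponential model

    f(t) = a1 exp(-t/τ1) + a2 exp(-t/τ2),   τ1 ≤ τ2,

convolved with the instrument response function (IRF), and summarized by the
amplitude-weighted mean lifetime

    τ_m = (a1 τ1 + a2 τ2) / (a1 + a2).

Resting MCs show a longer mean lifetime (τ_m > 1,000 ps) and
activated/degranulated MCs a shorter one (τ_m < 800 ps), distinguishing both
populations from elastin background (τ_m ≈ 1,600 ps), capillaries
(ultrashort decay) and other dermal cells. On top of a rule cascade (dermal
depth > 70 µm, ≈10 µm cell size, intensity floor, τ_m gates) a CART decision
tree — Gini impurity, maximum depth 6, minimum 2 samples per split — is
trained on a 265-dimensional feature vector per cell
(1 shape flag + 1 normalized intensity + 256 decay-curve samples + 7
bi-exponential parameters) and evaluated over 1,000 randomized 60/40
train/test splits.

Because the original raw recordings are proprietary microscope data, this
package ships a first-class synthetic generator: per-class truncated-normal
parameter distributions for nine dermal cell classes across in vitro,
ex vivo and in vivo contexts (407 cells in the default cohort), plus an
image mode that renders full TCSPC decay cubes with elastin background,
capillaries, granule texture, IRF convolution and Poisson noise.

## Who it is for

Researchers in label-free microscopy / FLIM methodology who want a
reproducible reference implementation of TCSPC bi-exponential fitting,
phasor analysis and the MC classification protocol, with every stage
testable against ground truth.

## Layout

- `src/mcflim/` — the library: `synthetic` (cohort + scene generation),
  `decay` (binning, IRF-convolved weighted least-squares fitting), `phasor`
  (first-harmonic transform), `cellscan` (bright-spot detection, morphology,
  search rules), `classify` (feature vector, CART tree, repeated-split
  evaluation), `stats` (Kolmogorov–Smirnov comparisons), `io` (TIFF+JSON
  cubes, pipeline driver), `cli`.
- `analysis/` — numbered narrative drivers writing tables under `results/`.
- `scripts/acceptance.py` — recomputes the headline numbers (below).

A `mcflim` console script exposes the stages
(`simulate`, `fit`, `phasor`, `detect`, `classify`, `stats`, `run-all`).

## Worked example

```bash
python analysis/01_generate_cohort.py --seed 0
python analysis/05_classify_cohort.py --seed 0 --repeats 200
```

prints (abridged):

```
generated 407 cells -> results/cohort.csv
mast cells: 250 (resting 154, activated 96)
healthy in vivo resting fraction: 0.60 (71/119 = 0.60)

binary (200 repeats of 60/40 splits):
  class 0: sensitivity 0.93 +- 0.03, specificity 0.85 +- 0.04

three_class (200 repeats of 60/40 splits):
  class 0: sensitivity 0.83 +- 0.07, specificity 0.95 +- 0.02   # activated MC
  class 1: sensitivity 0.88 +- 0.05, specificity 0.90 +- 0.04   # resting MC
```

Class 0 of the binary scheme is "mast cell (either population)": the tree
recovers MCs against macrophages, dendritic cells, fibroblasts and
neutrophils with ~0.93 sensitivity and ~0.85 specificity on synthetic data.
In the three-class scheme the one-vs-rest sensitivities for activated and
resting MCs are ~0.83 and ~0.88. The elastin-background sanity check

```bash
python analysis/02_fit_elastin_scene.py --seed 0
# fit 1012 pixels: tau_m = 1583 +- 30 ps (generator mean 1600 ps)
```

recovers the extracellular matrix lifetime within ~1%.

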