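# survbind

Quantitative analysis of survivin–peptide interactions: peptide-microarray
composition profiling and Bayesian inference for three biophysical binding
assays (MST, BLI, NMR titration).

Survivin is a small inhibitor-of-apoptosis protein that also associates with
chromatin factors, including the polycomb repressive complex 2 (PRC2:
EZH2/EED/SUZ12/JARID2). Its peptide-binding behavior can be profiled with a
microarray of overlapping 15-mers tiled across candidate partner proteins,
and individual interactions characterized by MicroScale Thermophoresis
(MST), biolayer interferometry (BLI) and NMR titrations. This package
implements the bespoke computations behind such a study as a tested library
plus analysis drivers, with a synthetic-data generator for every assay so
the full pipeline runs with known ground truth and no downloads.

## What it computes

**Peptide array** (`survbind.peptide_array`, `survbind.atom_types`)

- Tiling of protein sequences into 15-mers with 10-residue overlap
  (C-terminal anchoring or flagged filler residues).
- Heavy-atom composition features: each residue maps to counts over atom-type
  categories (aliphatic/aromatic/carboxamide C, amide/basic/aromatic N,
  hydroxyl/amide/carboxylate O, S, and the four backbone atoms); a peptide's
  feature vector is the sum over its residues. The taxonomy is replaceable
  from YAML.
- Interaction labels from duplicate fluorescence intensities: non-interacting
  if the duplicate mean is 0 or the duplicates differ by more than 40%
  relative to their mean; an explicit exclusion list handles His-rich
  peptides that bind the anti-His detection antibody.
- Ward/Euclidean hierarchical clustering, train/test splitting (random
  halves, or every third tile to remove sequence overlap), a standardized
  multi-layer-perceptron classifier, and confusion-matrix
  precision/recall.
- Composition combinatorics: P(specific sequence) = a^(−L);
  P(mean composition) = 1/C(a+L−1, L) (combination with repetition).

**MST** (`survbind.mst`) — monomer–dimer equilibrium M + M ⇌ D with
Kd = [M]²/[D]. The dimer-bound chain fraction at total chain concentration c
is the mass-action root

    α(c, Kd) = (4c + Kd − √(Kd² + 8cKd)) / 4c ,

and each normalized progress curve is 1 before IR-laser-on, then
ν₀t + R·A·e^(−ν₁t) + (1−R)·A·e^(−ν₂t) + (1−A) with total exponential
amplitude A = U + (B−U)α interpolating between the pure-monomer (U) and
pure-dimer (B) amplitudes. Priors: Kd ~ U(1, 10⁶) nM; U, B ~ Beta(1,1);
ε ~ LogNormal(0, τ=1) shared across capillaries; per-capillary R ~ Beta(2,1),
ν₀ ~ U(−1,1), ν₁, ν₂ ~ LogNormal(0,1).

**BLI** (`survbind.bli`) — 1:1 Langmuir kinetics fitted jointly over both
phases and all analyte concentrations: association mean
A·c/(K_D,app+c)·(1−e^(−(k₁c+k₋₁)t)) with k₁ = k₋₁/K_D,app; dissociation mean
Δλ(0)·e^(−k₋₁t) with a per-trace empirical-Bayes truncated-normal prior on
Δλ(0) (mean of the first-second dissociation samples, one tenth of their
population SD). Uniform priors K_D,app ~ U(10⁻¹⁵,10⁻³) M,
k₋₁ ~ U(10⁻²⁰,10) s⁻¹, A ~ U(10⁻⁶,10), ε ~ U(10⁻⁶,1).

**NMR titration** (`survbind.nmr`) — global spectrum intensity as the sum of
the 200 highest cells, normalized to the lowest-concentration reference; the
normalized intensity versus dimensionless peptide concentration (c/1 mM) is
modelled as a logistic in log₁₀c whose midpoint is the *critical peptide
concentration* (cpc): I(c) = L/(1+e^(−k(log₁₀c−log₁₀cpc))) + b, with
log₁₀cpc ~ U(−10,1), k ~ U(−10,10), L ~ U(−3,3), b ~ U(−10,10),
ε ~ U(0,0.05). Also: 1–2–1 weighting of per-residue secondary chemical
shifts with edge renormalization.

Posteriors are sampled with an affine-invariant ensemble MCMC
(differential-evolution moves, least-squares warm start, split-R̂
diagnostics over walker groups); see `docs/methods.md` for the numerical
choices.

## Worked example

```python
import numpy as np
from survbind import mst, synthetic
from survbind.sampling import SamplerConfig

# 16-capillary dilution series: 97 nM labeled protein constant,
# unlabeled titrated 23.2 nM - 761 uM, true Kd = 2000 nM, noise 0.005
capillaries, truth = synthetic.gen_mst(seed=3)
posterior = mst.fit_mst(capillaries, SamplerConfig(steps=600, burn=1500, seed=3))
print(mst.summarize_kd(posterior, unit="uM"))
```

prints (seed 3)

```
{'unit': 'uM', 'mean': 2.354, 'median': 2.349, 'ci68': (2.166, 2.539),
 'ci95': (2.026, 2.73), 'rhat': 1.017}
```

i.e. the monomer–dimer dissociation constant is recovered as
2.35 μM with a 95% credible interval (2.03, 2.73) μM against a generating
truth of 2.0 μM, with converged diagnostics (R̂ ≈ 1.02). The analysis
drivers under `analysis/` (numbered `01_simulate.py` …
`05_fit_nmr.py`) run the same workflow for all four assays and write their
tables under `results/`.

The command-line interface mirrors the library:

```
survbind simulate mst --seed 1 --out results/data
survbind fit-mst --input results/data/mst_traces.csv --seed 1
survbind tile --input proteins.fasta --out tiles.csv
survbind classify --input array.tsv --out report.json --scheme every_third
```

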