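# Methods

This note documents the models, the numerical choices behind them, what the
synthetic-data generators do and do not emulate, and the design decisions
taken where the problem left the design open.

## Peptide-array pipeline

**Tiling.** Proteins are cut into 15-mers advancing 5 residues per tile
(10-residue overlap). When the length does not fit the stride the final
window is, by default, right-anchored at the C-terminus (it then overlaps
its predecessor by more than 10 residues); alternatively (`filler` mode) the
final short tile is padded with a configurable residue and every filler
position is flagged. Filler residues are physically present on the chip and
are therefore included in the composition features.

**Features.** A residue is represented by its heavy-atom counts over 14
categories: 10 side-chain categories (aliphatic C; aromatic C; the sp²
carbon of amide/carboxylate/guanidinium groups; amide N; protonatable basic
N; aromatic N; hydroxyl O; amide O; carboxylate O; S) and the four backbone
atoms (N, Cα, C′, O) as separate categories. A peptide's feature vector is
the sum of its residues' vectors, hence additive and order-free; the
per-residue totals equal the standard heavy-atom counts (Gly 4 … Trp 14).
The taxonomy lives in `survbind.atom_types` and can be replaced wholesale
from a YAML/JSON table (`load_atom_type_map`) when a specific published
atom-type assignment should be used instead.

**Labels.** A peptide measured in duplicate is non-interacting when the
duplicate mean is zero or when |FI₁−FI₂|/mean > 0.40 (irreproducible spots
are treated as evidence against interaction), otherwise interacting. The
interacting threshold is applied to the duplicate mean, not to each
replicate. His-rich peptides that cross-react with the anti-His detection
antibody are removed through an explicit exclusion-ID list;
`propose_his_exclusions` flags candidates at a configurable histidine count
(default ≥ 5) because "high histidine content" has no canonical numeric
definition.

**Splits.** `half_random` is a seeded permutation into halves differing by
at most one. `every_third` retains tiling indices 0, 3, 6, … within each
protein before the half split; a stride of 3 tiles × 5 residues spans the
15-mer window, so retained tiles share no sequence — except possibly one
C-terminal anchored tile per protein, which sits off the stride grid and may
keep a partial overlap. Any stride-3 phase would do; phase 0 is fixed for
reproducibility.

**Classifier.** One hidden layer of rectified units (default 100, variant
9), adaptive-moment gradient training, at most 200 epochs, fixed seed
(scikit-learn `MLPClassifier` defaults). Features are standardized with
training-set statistics only, applied unchanged to the test set, to avoid
leakage. Precision/recall with an empty predicted (or true) class is
reported as NaN with a warning, never as 0, so summaries cannot be silently
distorted.

**Combinatorics.** P(specific sequence) = a^(−L) under a uniform residue
model; the mean composition probability is approximated by the reciprocal
combination-with-repetition count 1/C(a+L−1, L), computed with exact integer
arithmetic before inversion. For a = 20, L = 15 these give 3.1×10⁻²⁰ and
5.4×10⁻¹⁰; for the 5 residues free between 10-overlap neighbors, 2.4×10⁻⁵.

## Bayesian assay models

All three models are fully specified by the printed priors and Gaussian
likelihoods in their modules and are sampled the same way (below). Units:
MST concentrations in nM (the Kd prior support [1, 10⁶] then brackets the
titration range 23.2 nM–761 μM and the micromolar transition it targets,
mid-support); BLI concentrations in molar (the only unit in which the
K_D,app prior support [10⁻¹⁵, 10⁻³] is sensible; the CSV reader accepts nM
and converts); NMR concentrations dimensionless after division by 1 mM, with
summaries printed in both mM and μM. The lognormal τ parameter is a
precision (τ = 1 ⇒ σ = 1).

Model-specific notes:

- **MST.** The linear component is read as ν₀·t, a drift starting at
  laser-on. Pre-heating points (t < 0) enter the likelihood with mean 1
  rather than being dropped, which pins the observation scale ε. The degree
  of association is evaluated in the conjugate form
  α = 4c/(4c + Kd + √(Kd²+8cKd)) — algebraically identical to the quadratic
  root but immune to catastrophic cancellation when Kd ≫ c. Raw traces can
  be renormalized by the mean of the samples in [−5.0, −4.5] s.
- **BLI.** K_D,app, k₋₁, A and ε are shared across traces and phases
  (single printed ε); Δλ(0) is per trace. The empirical-Bayes σ of the
  Δλ(0) prior is floored at 10⁻³ of |μ| so a constant first-second window
  still yields a proper prior. Each phase runs on its own clock from 0 s;
  spans are configurable (600/1200 s defaults, 900/1750 s also used in
  practice). k₁ is always the derived ratio k₋₁/K_D,app, summarized from
  per-draw ratios, never refit.
- **NMR.** Zero-concentration points serve only to normalize (log₁₀ 0 is
  undefined); the logistic fit uses the c > 0 points. A series with
  constant intensities is flagged non-identifiable with a warning and the
  (prior-wide) posterior is still returned. Because the logistic is a
  computational convenience, relative cpc between peptides is more
  trustworthy than absolute cpc; the rank-order recovery test encodes
  exactly that claim. Random-coil shifts are an input table; 1–2–1
  smoothing renormalizes its weights over available neighbors at termini
  and next to missing residues, so a constant series is preserved and
  missing values propagate as missing.

## Posterior sampling

Sampling uses the affine-invariant ensemble MCMC of `emcee` with a mixture
of differential-evolution moves (80% `DEMove`, 20% `DESnookerMove`), which
mix far better than stretch moves once the parameter count is large (the
16-capillary MST model has 68 parameters). The schedule is:

1. **Warm start.** A bounded least-squares fit of the curve parameters
   (priors are nearly flat over the relevant region) gives a center; ε is
   initialized from the residual spread.
2. **Initialization.** Walkers start overdispersed at 3× the Laplace scale
   — per-parameter standard deviations from the diagonal second differences
   of the log-density at the center. This matters: a tight initialization
   ball gives the ensemble no information about posterior scale, and the
   whole ensemble then drifts coherently, yielding an arbitrary center with
   spuriously tight intervals that no grouped diagnostic can detect.
3. **Sampling.** Default 2·ndim+2 walkers (minimum 64), a burn-in phase and
   a kept phase (module defaults: MST 1500+600, BLI 1000+500, NMR 800+400
   steps per walker).
4. **Diagnostics.** Split-R̂ is computed with `arviz` over four walker
   groups of the ensemble (walkers' trajectories concatenated per group).
   Individual walkers are not independent chains and their per-walker
   chains are short relative to their autocorrelation; the grouped
   statistic flags disagreement between separate parts of the ensemble. A
   fit whose key parameters exceed R̂ = 1.05 raises a `ConvergenceWarning`.
   The mean acceptance fraction is reported alongside.

Prior-only sampling (likelihood suppressed, walkers drawn from the priors)
is supported for calibration checks; the test suite verifies it reproduces
the analytic prior means (e.g. Beta(1,1) → 0.5; U(−10,1) → −4.5).

Determinism: every fit is a pure function of (data, `SamplerConfig`); the
ensemble's random state derives from the config seed.

## Synthetic data

Generators call the same mean functions the models fit — a zero-noise
dataset equals the model mean pointwise by construction — and serialize
their exact generating parameters as a `GroundTruth` JSON sidecar.

- **MST**: 16 capillaries, 97 nM labeled chains constant, unlabeled chains
  in a two-fold series 23.2 nM–761 μM; time grid −5…25 s at 0.5 s steps
  (the problem size used throughout the tests); truth Kd = 2000 nM,
  U = 0.15, B = 0.45, ε = 0.005, R = 0.7, ν₀ = 10⁻³ s⁻¹, ν₁ = 2.0 s⁻¹,
  ν₂ = 0.4 s⁻¹. The default rates sit in the bulk of the model's
  LogNormal(0,1) rate priors; a much slower ν₂ (decay time comparable to
  the 25 s window) is locally indistinguishable from the free linear drift,
  leaving the amplitude curve — hence Kd — unidentified. Under these
  conditions Kd is recovered within 30% across 200–20 000 nM and the 95%
  interval covers truth in 19/20 seeds.
- **BLI**: analyte ladder {3.7, 11.1, 33.3, 100} nM, 600 s association,
  1200 s dissociation at 1 Hz; truth K_D,app = 10 nM, k₋₁ = 10⁻³ s⁻¹,
  A = 1, ε = 0.005. The dissociation phase starts at the *noise-free*
  association endpoint while the fit still treats Δλ(0) as unknown, so the
  empirical-Bayes prior is tested honestly.
- **NMR**: 10 points log-spaced 0.1–3000 μM; truth log₁₀cpc = −2.68
  (cpc ≈ 2.1 μM), k = −5, L = 0.6, b = 0.4, ε = 0.02. The negative slope
  makes the series decay from 1 at low concentration to b at high
  concentration, emulating the loss of free-protein signal as peptide is
  added; mirroring the slope sign does not move the midpoint, so cpc
  recovery is unaffected by this orientation choice.
- **Peptide array**: i.i.d. protein-like sequences from Swiss-Prot-like
  residue frequencies (natural sequences are compositionally biased, unlike
  a uniform alphabet) are tiled by the package's own tiler; a linear rule
  over standardized composition features, thresholded at the 60th score
  percentile (the steep limit of a logistic interaction probability),
  assigns hidden labels so ~40% of peptides interact. Optional label noise
  flips a fraction of labels before intensities are drawn; interacting
  peptides receive log-normal intensities (median 1500, σ = 1) truncated at
  the 16-bit scanner ceiling 64193, and duplicates are perturbed with 10%
  relative noise by default.

**What the generators do not emulate.** Spatial array artifacts, scanner
saturation *gradients*, sequence-position effects (the hidden rule is purely
compositional — real binding also depends on order and structure),
capillary-shape or adsorption artifacts in MST, mass-transport limitation or
heterogeneous ligands in BLI, and real 2D NMR lineshapes (only global
intensity series and toy matrices). Passing recovery tests therefore show
the inference machinery is correct and calibrated under the stated designs,
not that real data meet those assumptions. Quantities that require the
deposited experimental datasets (real-array confusion counts, experimental
cpc values, the measured micromolar MST transition) are represented by these
ground-truth stand-ins.

## Known limitations

- The BLI model is strictly 1:1; a well-defined K_D,app under model
  misspecification is *apparent* only.
- The MST model assumes labeled and unlabeled chains are kinetically
  indistinguishable and that errors do not vary between capillaries.
- Ensemble MCMC explores the 68-parameter MST posterior adequately at the
  default schedule, but heavier designs (many more capillaries) would
  warrant longer chains; the grouped split-R̂ warning is the guard.
- `every_third` leaves a possible partial overlap at one anchored terminal
  tile per protein (see above).
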