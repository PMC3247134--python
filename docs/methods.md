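# Methods

## Feature definitions and conventions

**Solvent accessibility.** SASA is computed Shrake–Rupley style: for each
heavy atom, the fraction of 960 deterministic golden-spiral points on its
probe-expanded sphere that lie inside no neighbor's expanded sphere, times
the expanded-sphere area. The deterministic point set makes results
bit-stable; doubling the point count changes chain totals by well under
1 %. Atom radii follow the NACCESS defaults (C 1.87, N 1.65, O 1.40,
S 1.85, otherwise 1.80 Å) and are configurable. The probe radius defaults
to 1.9 Å, the customary lipid-probe size for membrane proteins (1.4 Å
would model water). Relative values divide by the same residue's area as
the central X of an extended Ala-X-Ala tripeptide (φ=ψ=180°) built with
the package's own peptide constructor and measured with the same probe and
point set, so training and evaluation always share one reference state.
Relative ASA is not clamped at 100 %: an isolated residue lacks the
flanking-peptide occlusion of the reference and can legitimately exceed it.
Groupings: total = all heavy atoms; side chain = atoms outside
{N, CA, C, O, OXT}, with glycine's CA counted as its side chain;
non-polar = carbon and sulfur atoms.

**Helix–helix contact.** A TM residue is in contact (HHC = 1) when any of
its heavy atoms is within 3.5 Å of any heavy atom of a residue in a
different TM helix of the same chain; only intra-chain contacts are
considered. Non-TM residues carry no label: HHC is undefined outside the
membrane, and masked labels contribute nothing to training losses or
error averages. The per-residue closest inter-helix distance is exported
alongside the label (its histogram is what motivates a 3.5 Å cutoff).

**Conformational angles.** φ/ψ follow the IUPAC sign convention
(verified against MDAnalysis) with range (−180°, 180°]. κ at residue i is
the angle between the virtual bonds Cα(i−2)→Cα(i) and Cα(i)→Cα(i+2): a
straight trace gives 0° and an ideal α-helix ≈110°. (The alternative
vertex-angle convention would give ≈70° for helices and is not used.)
α is the virtual torsion over Cα(i−1…i+2), ≈+50° for right-handed
helices. Any angle whose window lacks a required atom is NaN.

**Kink angle.** At each position with at least four helical residues on
both sides, local axes are fitted to the four preceding and four
following residues (a 9-residue running window) and the kink is the angle
between them. The local axis uses the HELANAL/Kahn bisector construction:
bisectors of the flanking virtual bonds at the two interior points of a
4-Cα window point at the helix axis, and their cross product is the axis
direction. On an exactly periodic helix this is exact (it matches the
discrete screw axis to numerical precision); a total-least-squares line
fit is kept as a cross-check but is only meaningful over a full trace —
fitting a line to 4 points of a helix yields a near-planar arc direction,
not the axis. The central residue is excluded from both half-windows so
the two axes are independent.

## Scaling

Features are mapped to [0, 1] by fixed linear ranges — ASA [0, 150] %,
κ [0, 180]°, φ/ψ/α [−180, 180]°, HHC unchanged — rather than per-dataset
min/max, so models transfer across datasets and model files are
self-describing (the ranges are stored inside them). Values outside a
range are clamped with a warning. Angle periodicity is ignored by the
linear map; for φ near ±180° this inflates errors, a known limitation of
sigmoid-output regression on angles.

## Prediction networks

Inputs per residue: the PSSM rows of the residue and its eight sequence
neighbors, squashed elementwise by the logistic function (log-odds 0 →
0.5), concatenated with the chain's 20-dim amino-acid composition — 200
inputs. Window positions beyond the termini are filled with zeros, which
the logistic range cannot produce, so "no residue" is distinguishable
from "neutral score". A side effect worth knowing: the padding pattern
marks proximity to the chain termini, and since terminal residues are
systematically more exposed, a trained network predicts some accessibility
variation even from content-free profiles. Null checks of the
profile-signal channel therefore evaluate interior residues, where the
window is fully populated.

Architecture: one sigmoid hidden layer with twice as many units as output
features (16 integrated, 2 per individual net), sigmoid outputs, weights
initialized uniform(−0.5, 0.5) from a seed. Counting biases, the
integrated design has 3352 parameters versus 3240 for eight individual
nets — a 3.46 % difference, so the two designs are capacity-matched; the
gap is exactly 2(n_out−1)/405 with 200 inputs and stays below 5 % up to
11 features.

Training is backpropagation on a masked MSE for a fixed epoch count
(default 300, learning rate 0.1) with per-epoch reshuffling from the run
seed. Updates use mini-batches of 16; the gradient is the batch-averaged
error summed over output units, so a multi-output network and a bank of
single-output networks see identical per-output step sizes — normalizing
by the number of defined target cells instead would shrink the integrated
model's steps 8-fold and bias any integrated-vs-individual comparison.
Masked targets contribute zero gradient and are excluded from loss
normalization. (seed, data, config) fully determines the trained weights.

The leave-one-out protocol trains one model (or one bank of individual
models) per left-out protein; every reported prediction comes from the
model that never saw that protein. For unseen query sequences, the model
whose left-out protein has the highest global-alignment identity to the
query is selected — the query is then predicted by a network trained
without its closest relative.

## Evaluation

MAE is averaged per protein, then across proteins ("AMAE"); pooled-residue
MAE is also available and the two differ slightly by construction. The
binary HHC is scored by ROC AUC computed from the rank statistic with
half-credit for ties, identical to the cutoff-sweep curve area. The
correlation coefficient uses the summation form of the product-moment
formula. Model pairs are compared by a paired two-tailed t-test on
per-protein scores, with the p-value from the incomplete-beta closed form
of the Student t distribution (cross-checked against scipy in tests, and
calibrated: under a simulated null its p-values are uniform). Error
cross-correlation tables are Pearson matrices of protein-wise MAE vectors
(AUC for HHC). Kink detection converts observed kink angles to binary at
a threshold (default 30°) and scores positions by predicted κ.
Randomized-target backgrounds permute the targets, retrain, and report the
fit correlation; a real fit is only meaningful above this background.
Error-versus-observed profiles use 10 equal-width bins by default.

## Synthetic corpus

The generator emulates the study conditions the pipeline expects:

- **Helices** are built from ideal internal coordinates (NeRF chaining;
  N-Cα 1.458, Cα-C 1.525, C-N 1.329 Å, standard angles, ω=180°) with
  φ=−66°, ψ=−40°, the observed TM-helix means. Side chains beyond Cβ are
  one centroid pseudo-atom at a residue-specific distance and radius —
  enough for SASA and contacts to behave realistically without a rotamer
  library. Kinked helices rotate the C-terminal arm rigidly about the
  hinge Cα, giving exact axis-angle control; the single hinge peptide
  bond distorts by up to ~1 Å at 30°, the price of that exactness.
- **Bundles** place helices on a circle with ~9.5 Å inter-axis spacing,
  alternating antiparallel, centered so membrane z comes straight from
  the construction; short loops (with side-chain pseudo-atoms, since
  loops without side chains would artificially zero scASA) connect them.
  Default corpus: 12 proteins, 2–4 helices of 16–24 residues, 30 % kink
  probability with angles 15–45°, 0.15 Å coordinate noise — desk-scale
  stand-ins for a non-redundant TM dataset.
- **PSSMs** carry a tunable signal: each row is
  `signal · 8 · P(2·esf−1) + (1−signal) · N(0,3)`, integer-rounded and
  clipped to [−10, 10], with P a fixed unit-row 20×8 projection shared
  across the corpus so the mapping is learnable between proteins. At
  signal 1 a linear probe recovers scaled tASA from the window encoding
  (R² > 0.8); at signal 0 the profile is pure noise.
- **Fluctuations** come from a Cα Gaussian network model (Kirchhoff matrix
  at 7 Å, pseudoinverse diagonal, mean 1): exact, deterministic, and
  qualitatively right — termini and membrane-boundary residues fluctuate
  more than the core.

What the synthetic data does *not* emulate: real rotamer packing and
atom-level chemistry, evolutionary correlations between sequence columns,
loop backbone realism, lipid molecules, and inter-chain contacts. Passing
tests therefore demonstrate correctness of the computations and the
protocol (and directional phenomena such as the integration benefit), not
the absolute error levels attainable on crystallographic datasets.

## Numerical choices and degenerate inputs

Angles for incomplete windows, HHC outside the membrane, and ASA of
atom-less residues are NaN and masked everywhere downstream. Metrics on
degenerate input (single-class labels, constant vectors, zero-variance
paired differences) raise a dedicated error instead of returning a
number. Model selection ties break toward the first model. Corpus
generation derives per-protein seeds by seed-sequence spawning, so corpora
are bit-reproducible and individual proteins independent.

Problem sizes used by the test suite (12-protein corpora, 300 training
epochs, 960 SASA points) were chosen so the full pipeline — corpus
generation, LOO in both modes over three seeds, flexibility regression —
completes in a few minutes on one CPU while keeping every directional
effect comfortably resolved.

## Known limitations

- The extended-state reference is this package's construction, not the
  NACCESS internal table; relative ASA levels are internally consistent
  but not bit-comparable to NACCESS output.
- PDB files do not carry radius overrides, so reloading a written corpus
  reuses its stored feature tables rather than recomputing ASA from the
  PDB (recomputation with element radii would differ slightly for the
  pseudo-atoms).
- φ near ±180° suffers from the non-periodic linear scaling.
- The TM-region predictor is a configuration of the same machinery, not a
  tuned topology predictor.
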