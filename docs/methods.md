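# Methods

`fvfold` implements an antibody variable-region (Fv) structure-prediction
stack of the AlphaFold2 structure-module lineage, specialised to paired
heavy/light chains, together with the losses used to train such models, the
evaluation protocol used to score them, and the dataset-curation rules used
to build their training corpora.  Everything is exercisable on synthetic
fixtures; no downloads, external models or experimental data are required.

## Model

**Inputs.** A paired Fv sequence with per-residue IMGT numbers.  Node
features are either the one-hot residue encoding plus a two-slot chain
indicator (width 23) or an externally computed per-residue embedding
supplied through the same interface; each chain is embedded separately and
the rows concatenated heavy-then-light.  A deterministic mock embedder
(hash-seeded Gaussian rows keyed on the residue's 5-mer context) stands in
for protein language models in tests.  Edge features are relative positional
encodings: the within-chain sequence offset clipped to ±32 as a one-hot
bucket, with a single dedicated bucket for all cross-chain pairs.

**Structure module.** Eight sequential blocks with independent weights (two
in the desk-scale profiles).  Each block applies invariant point attention
(IPA) to the node features — attention logits combine a scaled scalar
query–key product, a learned per-head edge bias, and a softplus-weighted
squared distance between query and key points expressed in global
coordinates through the current residue frames — followed by a residual
transition MLP with layer normalisation, and then a backbone update: a
per-residue rigid delta parametrised by a quaternion with fixed unit first
component (so zero output is exactly the identity) and a local translation.
Frames start at the identity at the origin.  The final backbone-update
projection of every block is zero-initialised, so an untrained model
produces the identity trajectory; rotation gradients are stopped between
blocks (config flag, default on).  IPA channel counts (4 heads, 16 scalar
and 4/8 point channels by default) follow the published defaults of the
architectural family.

Backbone atoms are placed at fixed idealized frame-local coordinates
(x-axis along CA→C, N in the xy-plane; CA at the origin), the same
convention used by frame construction, so measuring frames on an emitted
backbone returns the emitting frames exactly.

**Heads.** The chi head consumes the final node representation concatenated
with the full-sequence one-hot and emits unnormalised (sin, cos) pairs for
χ1–χ4; angles come from epsilon-guarded normalisation and are masked to the
canonical chi count of each residue type.  The pLDDT head is a softmax MLP
over 50 equal bins spanning lDDT ∈ [0, 1]; the per-residue pLDDT is
100 × the expectation of the bin midpoints, hence always in [1, 99].

**All-atom reconstruction.** Side chains are rebuilt from backbone plus chi
angles by NeRF extension over a shipped internal-coordinate template table
(Engh–Huber-style rounded literature values; see
`fvfold/geometry/templates.py` for provenance notes).  Reconstruction is an
exact right-inverse of chi measurement, and every bond length/angle internal
to a rigid group equals its template value by construction.

## Losses

* **FAPE** — every point expressed in every residue frame for prediction and
  truth; mean clamped deviation divided by Z = 10 Å.  Clamps are 30 Å for
  CDR↔framework pairs and 10 Å otherwise.  Z is fixed at 10 Å for both clamp
  regimes: tying Z to the clamp would silently rescale the long-range term,
  so a single documented scale is used (a config switch restores Z = clamp).
  The training total sums the average backbone FAPE over all block outputs
  and the all-atom FAPE of the final reconstruction.
* **Torsion loss** — minimum Euclidean distance on the unit circle between
  the normalised (sin, cos) prediction and the true or alternate angle
  (π-flipped for the 180°-symmetric terminal groups of Asp/Glu/Phe/Tyr),
  plus 0.02 × the deviation of the raw norm from one.  Chi-only by default;
  backbone φ/ψ/ω supervision exists behind a flag but is off, since the
  architecture's own output is chi.
* **Violation loss** — flat-bottom penalties on bond lengths and angles
  against the template tables (tolerance 12 standard deviations of
  literature spreads: 0.24 Å, 24°) and on non-bonded clashes (pairs of
  residues ≥ 2 apart in the chain closer than the sum of van der Waals radii
  minus 1.5 Å).  Exactly zero on template-built structures.
* **pLDDT cross-entropy** — the true per-residue lDDT-Cα of the current
  prediction is discretised into the 50 bins (left-closed, last bin
  right-closed: `floor(l·50)` capped at 49) and scored against the predicted
  distribution; weight 0.01 in the total, active in both stages.

The public loss functions are plain numpy (oracle-testable); the optimiser
uses tensor re-expressions on the package's reverse-mode autodiff tape
(`fvfold.autodiff`, float64, finite-difference-tested).  A pinned test keeps
the two FAPE routes equal to 1e-12.  Gradients flow through backbone frames
and head outputs; the final all-atom FAPE is evaluated rather than
differentiated (the backbone FAPE plus torsion terms determine the all-atom
output at desk scale, because reconstruction is a deterministic function of
both), and the stage-2 violation gradient uses the differentiable
backbone-level peptide-bond term.

## Training schedule

Two stages.  Stage 1: RAdam, cosine-annealing schedule warm-restarting
every 50 epochs (base lr 1e-3 in the desk profile; the language-model
variant of the published setup starts at 5e-4 with the scheduler minimum
annealed to 0 — both are config values).  Stage 2 adds the violation term
and uses a fixed lr of 1e-4.  Both stages stop after 100 epochs without
validation improvement and keep the best checkpoint.  Batch size defaults
to 2 at desk scale (64 in the published profile).  bfloat16/distributed
settings are representable in config but not exercised; all desk
computation is float64 for bitwise reproducibility.

## Evaluation

* **lDDT-Cα** — 15 Å inclusion radius measured on the true structure,
  thresholds 0.5/1/2/4 Å, strict inequalities at radius and thresholds;
  cross-chain pairs count by default (the Fv is one assembly; a flag
  restricts to within-chain).  Residues with no neighbours inside the
  radius return NaN rather than a fabricated score.
* **Region RMSD** — each chain is Kabsch-aligned to the reference on all its
  backbone atoms (N, CA, C, O; O optional by flag), then the RMSD of each of
  the eight regions (CDR1–3 and framework per chain, IMGT boundaries 27–38,
  56–65, 105–117) is measured under its chain's alignment.  Empty regions
  report absent, not zero.
* **Confidence** — region/domain pLDDT is the unweighted mean of per-residue
  values; calibration is plain Pearson/Spearman between per-structure region
  pLDDT and region RMSD (constant inputs raise rather than returning a
  silent NaN); retention curves use strict inequalities (pLDDT > threshold
  retained, RMSD < cutoff counted).

## Curation pipeline

Filters run in the published order with all thresholds as config values:
nanobody removal (light chain required), resolution ≤ 3.5 Å ("above" read
strictly; missing resolution removes the entry with a flag), VH/VL
orientation outliers with |z| > 3.5 on any of the six orientation statistics
(means/SDs computed once on the post-resolution pool; zero-spread statistics
excluded), CDRH3 length ≤ 30, and the species-frequency rule.  Two printed
rules are ambiguous and are therefore explicit config modes rather than
silent choices: the species rule (`literal` removes species occurring > 15
times, as printed; `rare` removes under-represented species, the reading
suggested by the outlier-removal motivation) and the validation CDRH3-length
rule (`long` = > 22, as printed; `short` = ≤ 22).  Validation structures
must be human-annotated with resolution < 2.5 Å; the legacy test ids are
always retained inside the test split; training entries sharing any
same-region CDR sequence (exact, case-normalised) with any evaluation entry
are removed.  Every stage logs input/removed/retained counts, and
removed + retained = input is asserted per stage.

## Synthetic fixtures

`make_mini_fv` builds a paired Fv with idealized stereochemistry: each chain
is an extended strand-like backbone (φ ≈ −139°, ψ ≈ 135°, ±15° seeded
jitter on torsions only) built by NeRF from the template tables, with
synthetic IMGT numbering covering all eight regions (insertion codes at
position 111 for long CDRH3), seeded sequences, and side chains rebuilt at
seeded near-anti chi angles.  Chains are offset ~15 Å so cross-chain lDDT
pairs exist without clashes.  The fixtures carry valid geometry and full
region structure but make no attempt at real immunoglobulin topology,
canonical loop conformations or sequence realism — so green tests
demonstrate the correctness of the machinery (losses, metrics, equivariance,
bookkeeping), not predictive accuracy on real antibodies.  The curation
table generator plants a known number of violations of every filter with
guaranteed-unique CDR strings elsewhere, so expected removal counts are
exact; the calibration generator plants exact retention statistics.

## Desk-scale overfit run

`overfit_smoke` trains the two-block model (node width 48, RAdam lr 2e-2,
frozen seeds) on one 34-residue mini-Fv with the stage-1 objective and
tracks per-region backbone RMSD every 25 steps.  With the frozen settings
the run reaches all-region backbone RMSD < 1 Å at step 475 of its 500-step
budget (~10 s on one CPU), with the backbone FAPE strictly decreasing from
the first step.  Problem sizes throughout the suite (≤ 48 residues,
≤ 2 blocks, 200-entry curation tables) were chosen as the smallest that
still exercise every code path meaningfully.

## Known limitations

No recycling, MSA processing, ensembling or physics-based refinement;
numbering is consumed, never computed (no ANARCI); orientation statistics
are consumed as table columns, never derived from structures; training at
published scale (SAbDab, batch 64, GPU) is configured but not exercised;
the all-atom FAPE term does not backpropagate (see Losses); PDB/mmCIF round
trips quantise coordinates to the format's printed precision.
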