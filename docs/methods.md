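# Methods

`macroperm` models passive membrane permeability of macrocycles (and small
molecules) from 2D structure, in the beyond-Rule-of-Five regime where label
noise across assays is a first-order problem. This note documents the models,
the synthetic study conditions, the numerical choices, and the known
limitations.

## Permeability scale and labels

Permeability is carried as −log10(P_app) with P_app in cm/s; the unified
classification threshold is −log P = 6 (P_app = 1e−6 cm/s). Under the default
convention a compound with −log P below the threshold (high P_app) is
PERMEABLE = 1; a `label_direction` switch inverts this, because published
statements of the positive-class direction are contradictory and downstream
users may need either.

**Swing range.** Inter-laboratory replicates of the same macrocycle routinely
disagree by several tenths of a log unit, so binary labels near the threshold
are unreliable. The swing range excludes the half-open interval
[center − halfwidth, center + halfwidth) before training; halfwidth 0.5 around
center 6 reproduces the 5.5 ≤ −log P < 6.5 exclusion window. The halfwidth is
a noise/size dial: wider swings discard more data but flip fewer labels
relative to the noiseless ground truth (the package's swing study measures
exactly this trade-off). The boundary is half-open by convention; it matters
only for values landing exactly on an endpoint.

**Caco-2 three-bin rule.** P_app < 1e−6 cm/s: poorly absorbed; 1e−6–1e−5:
moderate; > 1e−5: well absorbed. The same thresholds are applied to MDCK and
RRCK, which are used as Caco-2 surrogates.

**Deduplication** is by standard InChIKey within each assay (first record per
(key, assay) after a stable sort on source id); cross-assay duplicates are
kept because each assay is a distinct supervision signal. An `aggregate=mean`
mode instead averages replicate measurements in −log P space before labeling.

## Featurization

Molecules are heavy-atom graphs. Node channels: element one-hot (C, N, O, S,
F, Cl, Br, I, P, other), degree one-hot, formal charge, aromaticity,
hybridization one-hot, chirality one-hot, hydrogen-bond donor flag (N/O with
≥ 1 H), acceptor flag (N/O with ≥ 1 lone pair), lone-pair count
((valence e− − charge − bonding e−)/2, floored at 0), membership in a ring of
≥ 12 atoms (the macrocycle threshold), and total hydrogen count. Edge
channels: bond-type one-hot, conjugation, ring membership, stereo one-hot.
The schema is versioned and configurable; it is this package's
reconstruction, since no canonical channel list was available to copy.

Global representations: a 20-descriptor RDKit 2D panel (size, lipophilicity,
polarity, flexibility axes), ECFP (radius 2, 2048 bits), and MACCS (167
bits). Descriptors are standardized with training-set statistics only;
non-finite values are excluded from the fit and imputed to 0.

## Models

**Encoder.** Bond-message passing: per directed bond,
m_uv = MLP(e_uv ⊕ x_u ⊕ x_v); node aggregation m_v = Σ_{u∈N(v)} m_uv; updates
e_uv ← MLP(e_uv ⊕ m_uv), x_v ← MLP(x_v ⊕ m_v); after T rounds node states are
pooled (mean by default; pooling is configurable because the choice is a
design decision, not a fixed fact). This formulation aggregates over *all*
neighbours including the reverse bond; the canonical directed variant that
excludes the reverse message is available behind `directed_exclusion`. A
`test_mode_identity` flag replaces every MLP by the identity on its
concatenated input so a round can be verified exactly against a brute-force
dictionary implementation.

**Mixture of experts.** One expert MLP per representation (graph embedding,
descriptors + global features, ECFP, MACCS) produces a hidden vector e_i; a
linear gate over the concatenated representations emits softmax weights g
(a probability simplex by construction); the output is o = Σ g_i e_i followed
by a linear head. By default each expert sees only its own representation; a
`shared_input` flag gives every expert the full concatenation (the literal
reading of a shared-input formulation). Assay identity enters as a global
one-hot so one model spans Caco-2/MDCK/RRCK/PAMPA.

**Training.** Binary cross-entropy (classification) or mean squared error
(regression), Adam (lr 1e−3), early stopping on validation loss. All
parameters are float64; initialization is Glorot-uniform from a seeded
generator, and a fixed seed reproduces parameters bit-for-bit. The gradient
engine is a small reverse-mode autodiff core over numpy written for this
package; its gradients are verified against central finite differences to
1e−6 in the test suite. An optional proximal-L1 penalty on the encoder input
projection (`l1_node_in`) drives unused feature channels to exactly zero.

**Regression variant.** Node states pass through multi-head self-attention
(heads attend within their own molecule) before readout, and assay conditions
(pH, temperature) are appended either as standardized global values (GLOBAL,
with a missingness indicator; missing values default to pH 7.4, 37 °C) or as
bin one-hots (ONEHOT). GLOBAL is the default.

**Distillation.** A teacher is trained on the large pooled multi-assay set;
its logits on the task molecules are frozen and softened,
p = σ(z/T). The student minimises L = BCE(y, p_hard) + λ·D(p_teacher,
p_student at T) with D the binary KL divergence (optionally scaled by T² so
the soft-gradient magnitude is temperature-independent); mean squared error
on logits is an alternative divergence. Defaults λ = 0.5, T = 2 (conventional
values; no published setting was available). At λ = 0 the student's training
trajectory is bit-identical to the plain classifier under the same seed — the
soft branch is skipped entirely, not multiplied by zero.

## Interpretability

**Channel masking.** Δloss per node-feature channel: rebuild the evaluation
graphs with the channel zeroed, re-evaluate BCE, subtract the (once-computed)
unmasked baseline. Channels are masked as whole blocks (a one-hot group is
one channel).

*Limitation found on synthetic ground truth:* when a driver is redundantly
encoded — donor-ness is recoverable from element, total-H, lone pairs, and
the acceptor flag — trained models spread their reliance, and single-channel
masking does not reliably isolate the planted driver. In addition, zeroing a
channel that is constant across the dataset (e.g. the chirality "unspecified"
bit in an achiral library) removes what the network has learned to use as a
per-atom bias, inflating Δloss for an uninformative channel. Mean-imputation
masking removes the second artifact but not the first; sparsity pressure on
the input projection does not resolve it either. Attribution rankings from
this method should therefore be read as "what this trained model relies on",
not "what drives the property".

**Conformer geometry.** Ensembles are selected greedily by ascending energy,
skipping candidates within 0.5 Å heavy-atom RMSD (Kabsch superposition,
SVD-based) of an already-selected conformer. Intramolecular hydrogen bonds
use d(H···A) ≤ 2.5 Å and ∠(D–H–A) ≥ 120° (vertex at H), with A ≠ D and A not
covalently bonded to H. Shrake–Rupley SASA places a deterministic
golden-spiral lattice of 960 points on each probe-expanded sphere
(R_i + 1.4 Å, Bondi radii); a point is accessible iff outside every other
expanded sphere, and SASA_i = 4π(R_i+R_p)²·(accessible/total). 960 points put
the discretization error well inside 1% for single spheres and 2% for
two-sphere overlaps (verified against analytic sphere and spherical-cap
areas). Polar-exposure profiles sum donor-hydrogen SASA and acceptor
heavy-atom SASA per conformer and average uniformly over the ensemble; a
molecule with no donors reports NaN for per-donor SASA.

## Synthetic study conditions

The generator assembles peptide-like molecules from amino-acid-style blocks
(side chains: none, methyl, hydroxymethyl, carboxymethyl, benzyl; optional
backbone N-methylation), closed head-to-tail into 12–24-membered macrocycles
(4–8 residues, 3 backbone atoms each) or left linear (30% of molecules).
The latent permeability is linear in interpretable descriptors:

    μ = 3.85 + 0.35·HBD + 0.15·(MW/100) − 2.0·hydrophobic_fraction + 0.2·is_macrocycle

with coefficients calibrated once against the block library's covariate
distribution so that μ is centred near the threshold 6 with ~50/50 classes
and the HBD term dominates the variance (sd ≈ 0.84 log units vs ≤ 0.25 for
the others) — donor count is the planted driver, mirroring the field's
understanding that shed donors buy permeability. Observed records add an
assay offset (Caco-2 0, MDCK +0.1, RRCK +0.1, PAMPA +0.2 — small relative to
signal, fixed) and Gaussian noise with sd 0.4 log units, the scale of
inter-laboratory deviations that motivates the swing range. Per-(molecule,
assay) RNG streams are derived from the master seed by SHA-256 hashing, so
extending the library never perturbs existing draws.

The teacher/student benchmark uses 2000 large-set molecules (Caco-2/MDCK/RRCK,
1–3 assays each, threshold labels) and 200 disjoint task molecules (PAMPA,
swing 0.5 labels).

What the generator does *not* emulate: real conformational behaviour
(chameleonicity), assay-specific mechanisms (paracellular transport, efflux),
correlated measurement errors, and realistic chemical diversity. Tests passing
on this benchmark demonstrate that the machinery recovers planted structure
under controlled noise — not that the models are accurate on real
permeability data.

## Problem sizes and defaults

Network defaults are sized for CPU training in double precision: hidden
dimension 32, T = 2 message-passing rounds, expert hidden 32, batch 32
(teacher 64), Adam lr 1e−3, early stopping patience 10. The studies shipped
with the package use: teacher 8 epochs on ~3700 records; students 30 epochs
on ~90 records over 5 paired seeds; attribution study 10 seeds × 25 epochs on
300 records; swing study 5 seeds × 800 molecules. These are the package's
chosen study sizes; all are config-exposed.

## Numerical conventions

Probabilities are clamped to [1e−7, 1 − 1e−7] before logarithms. MCC returns
0 when its denominator is 0. AUC uses the tie-corrected Mann–Whitney rank
form and matches all-pairs concordance exactly; PR-AUC uses conservative step
integration (equal to average precision). Zero-variance descriptor columns
standardize to centred zeros. The pair-deviation "within δ" comparison is
boundary-inclusive with a 1e−12 float guard. k-fold assignment shuffles
units (unique SMILES) round-robin; scaffold and cluster units are greedily
bin-packed in descending size, so fold record counts stay balanced despite
uneven unit sizes. Elbow detection for cluster counts takes the maximum
second difference of within-cluster SSE; silhouette wins conflicts, ties
break toward smaller k. t-SNE embedding (perplexity min(30, (n−1)/3), seeded)
precedes k-means by default; a `cluster_space` flag clusters the raw
fingerprint space instead, since which space to cluster is genuinely open.

## Known limitations

- The masking-attribution identifiability limit described above.
- The distillation benefit on the synthetic benchmark is modest: with
  swing-cleaned task labels both students approach ceiling AUC; with swing 0
  the distilled student wins most seeds but medians nearly tie. The
  label-shuffled-teacher control at large λ reliably *degrades* the student,
  which is the sharper signature that soft labels carry information.
- Checkpoints reproduce predictions bit-identically on the same platform and
  BLAS; cross-platform bit-identity is not promised.
- The condition-aware regressor's attention block runs per molecule and is
  the slowest path; it is intended for the small condition-annotated sets it
  is tested on.
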