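# Methods

## Chain splitting and Chothia-style numbering

An scFv is parsed as `VH – linker – VL` (orientation configurable). The
linker is the unique maximal match of a configurable regex, default
`(?:GGGGS){2,}` — the standard (G4S)n construct. A raw "Gly/Ser run"
rule is deliberately not the default: natural heavy frameworks end in
`...VTVSS`, so a run-based matcher would swallow framework serines and
shift the domain boundary. Zero matches or more than one match raise an
annotation error (listing the candidate spans in the ambiguous case).

Numbering is template-anchored. The package ships two consensus
templates — a VH3-23-like heavy domain and an IGKV1-39-like kappa light
domain — whose residues carry sequential Chothia positions (1..113 heavy,
1..107 light) with CDR windows at the standard Chothia rows (H1 26–32,
H2 52–56, H3 95–102; L1 24–34, L2 50–56, L3 89–97, inclusive). Framework
segments are treated as fixed length: insertions and deletions are
confined to the CDR windows, where they overwhelmingly occur in natural
variable domains. The parse is then a choice of three CDR lengths; the
implementation enumerates all triples compatible with the chain length
and keeps the one maximising exact framework identity (ties broken
toward canonical loop lengths, then lexicographically). Because each
framework segment's match count depends on a single offset, the search
is O(slack · chain length). A chain whose best framework identity falls
below a configurable gate (default 0.40, mirroring the common antibody
annotators' similarity threshold) is rejected as unalignable, as are
chains outside the 90–150 residue bounds.

Within a CDR window the fill rule is deterministic: a loop shorter than
the window fills positions left of the per-loop insertion anchor first
(anchors H1:31, H2:52, H3:100, L1:30, L2:54, L3:95), then from the window
end backwards; a longer loop places lettered insertions (100A, 100B, …)
at the anchor. The exact indel convention of the original Chothia
annotators is not standardised across tools; this rule is monotone,
idempotent, and span-preserving, which is what the downstream features
need. The boundary table and anchors are configuration, so alternative
schemes can be swapped in.

Known limitation: framework indels (rare, e.g. some lambda light chains)
are mis-assigned into the adjacent CDR; full IMGT/Kabat support and
VHH-only nanobodies are out of scope.

## Biochemical features (F46)

The default registry holds exactly 46 named features:

* **Net charges (4)** of the concatenated CDRs and of the pooled
  CDR1/CDR2/CDR3 loops, under an integer side-chain model at neutral pH
  (K,R = +1; D,E = −1; H = 0; termini ignored, since loops are internal
  substrings). A Henderson–Hasselbalch mode with fractional charges at a
  configurable pH is available.
* **Lengths (4)**: per loop index (heavy + light pooled) and their sum.
* **Hydrodynamic factors (13)**, below.
* **Isoelectric points (3)**: whole molecule, concatenated CDRs,
  concatenated CDR3 (H3+L3). The raw pI is the bisection root (tolerance
  1e-4 on pH ∈ [0, 14]) of the Henderson–Hasselbalch net charge over
  D, E, C, Y, H, K, R and both termini, with an EMBOSS-style pKa table
  shipped as editable configuration. Raw values are calibrated by affine
  maps (antibody scale for the whole molecule, peptide scale for loop
  concatenates): slopes/intercepts 2.0306/−7.8541 and 1.1552/−0.8839.
* **Motif statistics (22)**: counts and count-to-length ratios of
  G, Q, R, V, W in the concatenated CDR3 and in CDR-H3, plus VV and WW
  counts in CDR3. Doublet counting is overlapping (WWW contains two WW),
  the conservative superset. Ratios divide by the length of the region
  they are computed in; empty regions yield 0 with a flag.

The 24 non-motif features are fixed by their definitions; the motif
subset completing the panel to 46 is recorded in a versioned registry
(`f46-v1`) and is configurable. Records without a structure get NaN in
the 13 structure slots and an `incomplete` flag rather than zeros.
Solvent-accessibility and aggregation-propensity descriptors are
deliberately not panel members; a Shrake–Rupley SASA helper is available
behind a separate call.

## Hydrodynamic panel

The convex hull of the heavy atoms (scipy Qhull) models the
hydrodynamic envelope. From atom masses and residue composition:

* v̄ — mass-weighted Cohn–Edsall partial specific volume (mL/g);
* R₀ = (3 M v̄ / 4π N_A)^{1/3} — anhydrous sphere radius (Å);
* R_g — mass-weighted radius of gyration (uniform weighting by flag);
* D_max — largest pairwise distance among hull vertices;
* axial ratio — √(λ_max/λ_min) of the gyration tensor;
* asphericity — 1 − 3(λ₁λ₂+λ₂λ₃+λ₃λ₁)/(λ₁+λ₂+λ₃)², in [0, 1];
* R_trans, R_rot — hull-equivalent sphere radius scaled by hydration
  expansion factors (defaults 1.10 and 1.16);
* D_t = kT/6πηR_trans (cm²/s), D_r = kT/8πηR_rot³ (s⁻¹),
  τ_C = 1/6D_r (ns), s = M(1−v̄ρ)/N_A 6πηR_trans (sec),
  f/f₀ = R_trans/R₀ (floored at 1; sub-unity values only arise for
  degenerate point sets).

Defaults: T = 293.15 K, η = 1.002 mPa·s, ρ = 0.998 g/mL; all constants
are carried in the returned panel. Degenerate (coplanar/collinear)
clouds get hull volume 0 with a flag and fall back to the anhydrous
radius. The contracts are geometric oracles (Delaunay decomposition,
direct summation) and algebraic self-consistency (D_t·R_trans constant
at fixed T, η); numerical agreement with any particular external
hull-based tool's constants is not asserted.

## Dataset handling

Curation is three steps: collapse exact (sequence, label) duplicates;
remove *every* copy of a sequence observed with conflicting labels;
append configurable pre/post overhang strings (default empty). The
stratified split puts ⌈(1−f)·N⌉ records in the test set, allocated
across classes by largest remainder, so train/full class proportions
differ by ≤ 1 record per class; with 8,867 + 10,559 labelled records at
f = 0.8 this reproduces the 15,540 / 3,886 partition exactly. Membership
is a seeded permutation, reproducible bit-for-bit.

## Synthetic generator

The generator emulates the shape of a FACS nonspecificity screen of an
scFv library: consensus frameworks, CDR lengths H1 6–8, H2 4–6, H3 8–16,
L1 10–12, L2 6–8, L3 8–10, residues drawn from a loop-biased composition
(Gly/Ser-rich, moderate Trp/Arg), (G4S)3 linker, positive fraction
defaulting to 8,867/19,426 ≈ 0.456. Labels are Bernoulli draws from
σ(4·(z − t)) with z = 9.0·(CDR-H3 Trp ratio) − 0.55·(CDR2 net charge)
+ 0.14·(CDR1 length) and t the (1 − balance) quantile of z in the batch —
the three drivers follow the loop properties repeatedly implicated in
antibody nonspecificity, with magnitudes set so the rule is strongly but
not perfectly learnable. Per-record pseudo-structures are seeded compact
random-walk Cα coils (3.8 Å steps with a centroid pull), which make the
structure block computable and record-specific; they carry no
sequence-dependent geometry, so hydrodynamic features act as realistic
nuisance dimensions rather than label signal. Ground truth (domain and
CDR spans, planted feature values, logits, probabilities) is stored with
every record.

Consequently, passing tests demonstrate that the pipeline recovers
annotations exactly and learns planted loop-composition signals; they do
not demonstrate transfer to real immune repertoires, where framework
diversity, somatic indels, and genuine structure–label coupling are all
richer.

## Models and ensembles

Training uses stratified tenfold grid-search CV scored by ROC AUC and
refits the winner on all training rows (CV statistics are recorded
before the refit). The full default grids span n_estimators {500, 1000,
3000}, learning_rate {0.01, 0.05}, max_depth {10, 15}, max_features
{sqrt, log2, none} as applicable per family; the test-suite and
acceptance runs use the shipped compact grids (≈1–2 points per axis,
shallower trees) with n = 2,000 synthetic records — sizes chosen so a
full four-family comparison completes in about a minute on one core
while leaving the planted signal comfortably learnable. Evaluation
reports threshold-free AUC plus accuracy/precision/recall/F1 at 0.5.
Feature screening reports per-feature raw-orientation AUC (inversely
predictive features legitimately fall below 0.5; an orientation flag is
available), a pooled-variance two-tailed Student's t-test (Welch by
flag), and stars at 0.05/0.01/0.001. Importances are normalized
impurity/gain importances (gain for LightGBM).

Member selection: A⟨k⟩ takes the top k of the whole pool by the ranking
score; B⟨k⟩ keeps the best model per descriptor set first. The default
ranking score is CV AUC; a `paper_faithful` option ranks on test-set AUC
instead, reproducing the published-style procedure while flagging its
information leak. The AVG combiner is the unweighted mean of member
probabilities; the LR combiner solves min‖Pw − y‖² with no intercept
(exact least squares; minimum-norm with a warning when P is rank
deficient) and clips outputs to [0, 1].

## Numerical and degenerate-input choices

* pI bisection: tolerance 1e-4 pH; sequences whose charge cannot change
  sign on [0, 14] (impossible with termini enabled) raise an error.
* Ties in the annotation parse break toward canonical loop lengths,
  then smaller CDR1/CDR2 — fully deterministic.
* Zero-variance features get NaN p-values with a flag rather than a
  division error; empty motif regions yield flagged zeros.
* All stochastic steps (generator, splits, CV shuffles, tree seeds) take
  explicit integer seeds; identical seeds give bit-identical tables and
  predictions.

## Limitations

Pretrained language-model weights are external adapters and never
required; the mock provider exercises the embedding plumbing only. The
hydrodynamic constants are generic solution defaults, not fitted to any
particular measurement set. The annotation templates cover human-like
VH/Vκ scFvs; divergent germlines may fall below the identity gate and
should be annotated with a dedicated tool before featurization.
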