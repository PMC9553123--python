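# Methods

## The analysis problem

Single-cell RNA-seq of a branching differentiation system — nerve-associated
Schwann-cell precursors (SCPs) resolving into a glial fate and, through a
transient bridge state, into chromaffin fates — asks four questions this
package answers in order: which cells are usable (QC), where is each cell
going (velocity → fate probabilities), where does each cell sit along the
process (principal tree → pseudotime), and which genes define each decision
(association, branching and early-bias tests).

## Simulator

The generator is the package's study system. A lineage is a tree of
segments (default: root 0–1, glial 1–2 terminal, bridge 1–1.5, two
chromaffin branches 1.5–2.5 terminal; three terminal segments). Cells are
placed uniformly along root-to-leaf paths. Per gene, unspliced/spliced
abundances follow

    du/dt = α(t) − β u,     ds/dt = β u − γ s,

integrated exactly for piecewise-constant α from the fixed point of α(0).
Transcription programs are logistic in pseudotime: every segment (including
the root — SCPs mature, which is also what makes the flow's source
identifiable from kinetics) carries 60 activating genes; 40% of background
genes deactivate along pseudotime, giving progenitors their higher
transcriptional diversity (the signal a CytoTRACE-style score requires);
the rest are constant. Counts are negative binomial (gamma–Poisson) with
gene-level dispersion θ ~ lognormal(ln 3, 0.5); the per-cell expected
library over cellular genes equals the configured depth (default 2×10⁵,
detecting ≈7300 of 8000 genes at SmartSeq2 depth); 92 ERCC spike-in genes
are appended with a fixed, cell-independent expected profile at ~5% of
depth.

Fate bias: two antagonistic 20-gene modules are constitutively transcribed
and modulated by a per-cell latent bias b — multiplicatively, so the ODE
solution stays exact. Root cells are a mixture: 60% unbiased
(b ~ N(0, 0.25), clipped at ±0.5), 20% glial-committed and 20%
chromaffin-committed (|b| ~ U(0.6, 1)); branch cells inherit b = ±1. The
modulation is asymmetric (fold-activation κ₊ = 2.0, bounded repression
κ₋ = 0.3): expression cannot fall far below a lowly expressed baseline, and
the asymmetry keeps each module's dataset average above its level in
unbiased cells — exactly the property that makes expression-matched control
scoring assign unbiased cells to the SCP class while preserving the covert
intra-SCP module covariance that the repulsion analysis measures.

Low-quality cells are planted by one mechanism per QC violation: binomial
depth thinning (transcripts), masking to the 2500 highest-count genes
(detected genes, with counts rescaled so the transcript criterion stays
satisfied), or inflating ERCC counts to ~44% of the library.

What the simulator does **not** emulate: plate/batch effects, doublets,
empty wells, gene–gene regulatory correlations beyond the two bias modules,
read-level artifacts, or transcriptional bursting beyond NB dispersion.
Passing tests therefore demonstrate that the pipeline recovers planted
structure under realistic depth and overdispersion — not robustness to
batch structure or ambient contamination.

## Parameter defaults and rationale

| stage | parameter | default | why |
|---|---|---|---|
| QC | transcripts / genes / ERCC | >5×10⁴, >3000, <25% | the study's published keep-conditions, strict inequalities; all three must hold (an OR-keep would retain near-empty wells) |
| normalization | log10(FPM+1) over non-ERCC genes | — | figure-level convention of the source analyses |
| overdispersion | LOWESS frac 0.3, FPR 0.02 | — | robust-z residual of the log mean–variance trend; FPR is the expected Poisson-gene selection rate |
| graph | 30 PCs, k=15, clip ±10 SD | — | study parameters; clip bounds outlier leverage |
| connectivities | Gaussian, bandwidth = distance to k-th neighbor, max-symmetrized | — | monotone in distance, 1 for coincident cells |
| Leiden | resolutions 0.1/0.3/1.5, seed 0 | — | study parameters; internally connected communities guaranteed |
| velocity | shared counts ≥20, top 4000 by spliced overdispersion, quantile 0.05 | — | study gene filters; extreme-quantile steady-state fit |
| velocity kernel | softmax temperature 0.1 | — | free parameter; chosen so the backward stationary distribution concentrates at the simulated source rather than diffusing over the progenitor pool |
| fate | connectivity share w = 0.30, 6 macrostates, 3 terminals | — | study parameters; terminal = lowest total outgoing flow among metastable candidates |
| root cells | velocity kernel only, lazy power iteration, eps 0.01 | — | the source workflow computes root cells on the velocity graph itself; blending in the symmetric connectivity kernel demonstrably flattens the backward stationary distribution |
| potential | top 200 GC-correlated genes, 3 smoothing rounds, α=0.7 | — | fixed deterministic variant of data-driven smoothing |
| tree | 300 nodes; σ = (0.15·RMS spread)²; λ = 10 | — | see below |
| GAM | cubic B-splines, 6 basis functions, 2nd-difference penalty, pooled-GCV λ, FDR 10⁻⁴ | — | see below |
| bias scoring | 25 bins, 50 controls per set gene | — | documented defaults of the cited scoring function |

## Numerical and design choices

**SimplePPT.** The three block updates each exactly minimize the joint
objective Σ R‖x−f‖² + σ Σ R log R + λ Σ‖f_a−f_b‖² (soft assignments:
row-softmax; topology: MST over squared node distances, computed with a
constant offset so coincident nodes cannot silently disconnect the tree;
positions: one sparse ridge solve), so the objective is non-increasing and
is asserted at every iteration. The bandwidth default (0.15 × RMS distance
to the centroid, squared — ≈5×10⁻³ on the unit-scale fate-simplex
embedding) and λ = 10 were chosen on the simulator as the widest regime
that both resolves the three branches and suppresses noise twigs; the
squared-median-NN-distance rule (~4×10⁻⁶ here) overfits any embedding whose
point spacing is far below its feature scale. Root selection restricted to
tree tips is the pipeline default: a differentiation origin is an endpoint,
and interior nodes carry too few cells for a stable weighted average.

**Fate probabilities.** Absorption probabilities solve (I−Q)A = R by sparse
LU after an explicit reverse-BFS reachability check (a transient cell with
no path to any terminal set is reported by index). Root probabilities
iterate the lazy backward chain (I+B)/2 — the same stationary vector,
immune to oscillation from complex eigenvalues.

**GAM testing.** One smoothing parameter is selected per gene *family* by
summed GCV rather than per gene: per-gene selection makes the F-test
anti-conservative (empirically ~12% rejections at nominal 5% on nulls),
while the pooled choice amortizes selection across thousands of genes and
is calibrated (measured 5.1% on 1000 permuted-pseudotime nulls). With the
basis restricted to a line and λ = 0 the test reduces exactly to the
classical regression F-test. In the branching test the roughness level is
chosen on the reduced (shared-smooth) model and applied to both blocks of
the full design, keeping the models nested; each branch's pseudotime is
rescaled to [0, 1] over its own span first, because genes activating beyond
the shorter branch's maximum otherwise have no cross-branch contrast and
are absorbed by the shared smooth.

**Early markers and bias.** The "first chromaffin bifurcation" is located
structurally as the divergence node of the two late-splitting fate leaves
(the deepest pairwise least common ancestor); taking the globally earliest
bifurcation instead would make the two pre-bifurcation trajectories the
same cell set. Marker lists passed to fate-bias scoring keep significant
*rising* genes only — the association F-test is two-sided, so each path's
list would otherwise include the opposite module's fall-off genes. The
repulsion score is defined here as (intra_A + intra_B)/2 − inter over the
SCP-restricted local Pearson correlations and is always reported alongside
its three components so alternative summaries can be recomputed. Cells
entering the correlation analysis are selected deterministically (all
SCP-assigned cells) rather than manually.

**Summary t-tests.** Pooled (Student) rather than Welch, df = n₁+n₂−2;
with n₁ = n₂ = 3 the standard error reduces to √(SEM₁²+SEM₂²) and df = 4,
which reproduces the published p-values to four decimals for all
arithmetically consistent table entries.

## Problem sizes

Recovery analyses run at the study's default scale: 1000 cells × 8000 genes
per simulation; tree-topology and pseudotime recovery aggregate ten
independent simulations, velocity γ recovery pools the steady-state module
genes of three, and GAM calibration uses 1000 permuted-pseudotime null
genes at n = 300 cells.

## Known limitations

- The steady-state velocity slope carries a small attenuation bias from
  negative-binomial noise surviving the 16-cell moment smoothing
  (≈5% downward at θ = 3); the dynamical (EM) velocity model is out of
  scope.
- Terminal-state selection is cluster-level metastability ranking, a
  deliberate simplification of spectral coarse-graining; it requires the
  clustering to separate the terminal populations.
- Cells within ~0.3 pseudotime units after the chromaffin bifurcation are
  pre-commitment by construction; absorption-probability argmax recovers
  their side (glial vs chromaffin) essentially perfectly but the specific
  chromaffin fate only ~75–85%, even though the generative Bayes classifier
  can separate them — a limit of graph-kernel resolution at k = 15.
- Latent time from spliced/unspliced kinetics is not implemented; the
  principal-tree pseudotime is the supported ordering.
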