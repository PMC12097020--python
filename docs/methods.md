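# Methods

This note documents the models, conventions and deliberate design choices
behind `covpanel`, in the spirit of a statistical software methods appendix.
It states no empirical claim that the test suite or `scripts/acceptance.py`
does not itself compute.

## Coverage model and panel search

A cell's antigen status is binary; the coverage of a panel is the fraction
of cells positive for at least one member (union-of-positives). This treats
any positive cell as targetable regardless of expression level — a
deliberate simplification matching how multi-target CAR cocktails act: a
cell is killed if any constituent CAR finds its antigen. Consequences:

* coverage is monotone under panel growth and sandwiched between the
  largest marginal and the (capped) sum of marginals; the pair identity
  `cov({a,b}) = cov(a) + cov(b) − cov(a∧b)` holds exactly;
* optimization is the maximum-coverage problem. With the default 9-antigen
  bank and `k ≤ 3` exhaustive enumeration is trivial (≤ 84 panels) and is
  the reference method; the greedy selector exists for larger banks and
  carries the usual `1 − 1/e` approximation guarantee, which the test suite
  verifies against the exhaustive optimum on random instances.

Panels larger than three are refused without an explicit override: beyond
triples the clinical manufacturing burden grows while marginal coverage
gains shrink, so the search space is capped by design (an `allow_large`
flag lifts it).

Tie-breaking is everywhere lexicographic on canonically sorted panels, so
every ranking and recommendation is deterministic and auditable.

**Recommendation rule.** The recommended panel is the smallest
`k ∈ [k_min, k_max]` whose best panel meets the per-`k` coverage bar
(pairs 0.80, triples 0.90 by default). "Meets" is inclusive
(coverage 0.80 meets the 0.80 bar): the published thresholds describe
observed coverage bands, not a decision rule, so the weakly-satisfying
convention was chosen and is documented here. When no `k` qualifies the
best `k_max` panel is returned with `met = false` rather than an error —
the honest clinical answer.

Cohort summaries report per-panel mean and SD (n−1 denominator) across
patients; both the per-patient best panel and cross-patient averages are
computed, since "best on average" and "best per patient" genuinely differ.

## Target-bank screening

An antigen enters the working pool only if (i) literature expression rate
strictly exceeds 0.70, (ii) protein expression is flagged stable, and
(iii) tumor expression exceeds normal by a one-sided Wilcoxon rank-sum test
at strictly `p < α` (default 0.05). The rank-sum test uses exact
enumeration when both groups have ≤ 10 observations and no cross-group
ties, else the normal approximation with tie correction (scipy's
`mannwhitneyu`). A worked boundary case is frozen in the tests: tumor
(5,6,7) vs normal (1,2,3) gives exact `p = 1/20 = 0.05`, which the strict
rule excludes at `α = 0.05`. GD2, a ganglioside, is proxied at the RNA
level by its synthase gene ST8SIA1; the NKG2D-ligand family is proxied by
MICA. Both proxies live in the configurable antigen→gene map, not in code.

## QC, normalization, positivity

* **QC** removes a cell iff mito fraction > 0.20 OR detected genes < 200 OR
  detected genes > 2500 — all comparisons strict, so boundary cells (exactly
  200 or 2500 genes, exactly 20% mito) are retained. The filter is
  idempotent. The mito fraction is consumed as metadata; a helper computes
  it from gene-name prefixes (default `MT-`) for real matrices.
* **Normalization** is counts-per-10k followed by natural-log `log1p`
  (scanpy's `normalize_total` + `log1p`, in float64). The upstream tool the
  convention mirrors defaults to exactly this transform.
* **Positivity** is strict: flag = 1 iff normalized value > τ. The default
  τ = 0 ("any detected transcript") is deliberate: with heavy dropout any
  higher threshold only discards true positives and biases coverage
  downward. τ is exposed everywhere (API and CLI) because the right value
  is data- and platform-dependent. For imaging data, positivity is a strict
  per-marker intensity threshold applied to tumor-class cells only.
* Malignant-cell selection is a metadata column; the package does not
  cluster or annotate. Clustering-based malignancy calls are an upstream
  concern and arrive as input.

## Synthetic cohort generator

The generator exists because the patient data this analysis style needs
(per-patient malignant-cell matrices, organoid imaging tables) are not
publicly available. It emulates the features the pipeline is sensitive to
and nothing more:

* **Heterogeneity.** Each patient mixes `subclones_per_patient` (default 3)
  subclones with Dirichlet(2) weights; each subclone has its own
  per-antigen positivity probability (default Beta(2,2) draws), giving both
  inter- and intra-tumor heterogeneity. Within a subclone, antigens are
  independent — which yields the closed-form expected panel coverage
  `Σ_s w_s (1 − Π_a (1 − p_sa))` used as the recovery oracle. Correlated
  antigen modes are a possible config extension, not implemented.
* **Counts.** Per-cell library size is lognormal (σ = 0.35) around
  `mean_library_size` (default 5000). A truly positive antigen transcript
  survives dropout with probability `1 − dropout_rate` (default 0.7) and,
  when it survives, is counted as `1 + Poisson(2)` — the shift guarantees a
  surviving positive is never a zero count, so the generator's detection
  guarantee holds exactly rather than up to `e^{−λ}`. Background genes
  (default 3000) are detected per cell at a rate targeting a realistic
  detected-gene count (default mean 1000 ± 150) with counts spreading the
  remaining library size.
* **Planted QC violators.** A fraction (default 5%) of cells is planted to
  violate exactly one QC rule (mito 0.25–0.60, detected genes 20–150 or
  2650–2900, cycled); non-violators are clipped well inside the QC bands,
  so the planted set equals the removed set exactly — verified per run.
* **Spatial.** Tumor cells uniform in a disc (default radius 400 µm,
  matching 0.5–1 mm organoids); T cells either uniform (full infiltration)
  or confined to the outer 20% annulus (exclusion). Tumor cells carry
  per-antigen marker intensities (bright lognormal when positive, faint
  half-normal noise otherwise) so the imaging positivity caller can be
  exercised against the same truth.
* **Trajectories.** Isotropic Gaussian random walks (default per-axis step
  SD 2 µm, 49 frames over 24 h, i.e. 30-min imaging intervals). The mean
  step norm is `σ√(π/2)`, giving closed-form expected path lengths.
* **Determinism.** Every output is a pure function of `SimConfig.seed`.
  Purpose-named RNG substreams (per-patient, parameters, spatial,
  trajectories) are derived via `SeedSequence` spawn keys, so adding a
  patient never perturbs earlier patients.

What the generator does *not* emulate: full transcriptomes, gene–gene
covariance beyond the antigen set, batch effects, segmentation error, cell
division or death during imaging. Tests passing on this generator therefore
demonstrate the *analysis logic* is correct under known truth — not that
real tumors satisfy the model.

## Infiltration geometry

The organoid center is the tumor-cell centroid (the data give no image
mask). Concentric rings of width 50 µm are tiled outward; a ring is
included while its mid-radius still lies within the maximum tumor-cell
radius, so probe circles are never centered beyond the organoid (a naive
"ceil" tiling creates a trailing sliver ring of near-empty probes that
biases radial profiles toward zero at the rim). On each ring's mid-radius
circle, 8 probe circles of diameter 50 µm are placed at seeded-uniform
angles; each reports T cells / all cells inside. Empty probes score 0 and
are flagged rather than dropped, keeping ring means defined at sparse rims;
probes are never clipped to the organoid boundary. The profile is exactly
invariant to coordinate translation (the center moves with the data) and
statistically invariant to rotation (probe angles are seeded, not
data-relative).

**Movement distance** is total path length (sum of Euclidean step lengths);
net start-to-end displacement is computed alongside because the two answer
different questions (motility vs transport) — path length is the headline
grouping variable. Distance groups are left-closed/right-open bins with an
open-ended final bin (default 50-µm bins from 0, mirroring the ring
interval); a distance exactly on an edge falls in the upper bin.

## Efficacy metrics

* **Killing fraction** = 100 × (tumor-stain⁺ ∧ death-stain⁺) /
  tumor-stain⁺, per condition × timepoint, never pooled across timepoints.
  The denominator is nuclear-label-positive (tumor) cells only, so
  bystander effector cells cannot dilute the measurement.
* **Viability**: dead% = 100·dead/(live+dead); live% is its exact
  complement.
* **Growth**: relative size = diameter(day)/diameter(earliest day per
  spheroid); unordered observations are sorted first.
* **Diameter→count calibration** fits `count = a·d^b` by OLS on logs with
  the exponent free rather than forcing `b = 3`: sphericity becomes a
  checkable outcome (noiseless cubic data recover `b = 3` to 1e-9; the test
  suite also checks recovery to ±0.1 under 5% multiplicative noise).
* **Success rate** rounds half-up to two decimals (banker's rounding would
  silently disagree with conventionally printed percentages).
* **GvHD score**: five fixed criteria (weight loss, activity, posture, fur
  texture, skin integrity), each 0/1/2, summed to 0–10.

## Numerical and interface choices

* Positivity matrices are int8 DataFrames wrapped with their calling rule,
  so every coverage number is traceable to a threshold and modality.
* MatrixMarket triplets are 1-based on disk (per the standard), 0-based in
  memory; the reader layers line-aware validation (header, declared vs
  actual entry counts, integrality, non-negativity, barcode uniqueness,
  dimension agreement with features/barcodes) over `scipy.io`, since scipy
  alone reports none of that context. All parse errors are typed and carry
  file/line information.
* Degenerate inputs fail loudly with typed errors: empty QC results,
  zero-total cells at normalization, empty killing strata (named), empty
  distance lists, non-simplex subclone weights.
* Problem sizes in the test and acceptance suites (e.g. 10,000-cell
  single-subclone cohorts over 100 seeds, 5,000 + 5,000-cell spatial nulls)
  were chosen so statistical checks have the power their bounds require
  (3-SE binomial bands, 95% t-CIs) while a full run stays in the
  tens-of-seconds range on one CPU; simulation-heavy checks use small
  background-gene counts because positivity and coverage structure do not
  depend on them.

## Known limitations

* Binary union coverage ignores expression level, antigen density and CAR
  avidity; a weighted-coverage extension would need a potency model the
  underlying data cannot currently calibrate.
* The rank-sum screen tests location shift only; an antigen highly
  expressed in a normal-tissue subset can pass it.
* The uniform/rim spatial modes bracket, but do not span, real infiltration
  geometries (gradients, channels, necrotic cores).
* Trajectory analysis assumes complete tracks; gaps and track-splitting
  artifacts from real trackers are out of scope.
* With default dropout (0.3) and τ = 0, observed coverage understates true
  antigen coverage — by design the generator makes this visible (true vs
  called flags both available), but on real data the bias is unidentifiable
  without spike-ins or imaging confirmation.
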