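# Methods

## Data model

The unit of observation is the ROI: a segmented region of one arterial layer
(intima, media, adventitia or PVAT) from one patient, whose deduplicated
transcript counts form one column of the count matrix. Negative probes —
targets with no genomic complement — measure per-ROI background. Patient,
disease status (GCA / control), layer and sex annotate each ROI; the patient
id defines the grouping structure of the mixed model, since all layers of one
biopsy share patient-level biology and technical handling.

## Segment QC and limit of quantification

Per ROI, the limit of quantification is

    LOQ = geomean(NegProbe) × geoSD(NegProbe)²

with geometric statistics computed from natural-log negative-probe counts.
Numerical choices:

- **geoSD estimator.** Sample (n−1) standard deviation of log counts — the
  conservative choice; at least two negative probes are therefore required.
- **Pseudocount.** `compute_loq` defaults to 0 and refuses non-positive
  shifted counts (the log is undefined). The pipeline default is 1.0 because
  negative-binomial background counts include zeros; all worked LOQ examples
  and oracle tests use strictly positive vectors with pseudocount 0.
- **Boundary semantics.** Exclusion gates are strict `<` (an ROI with Q3
  exactly 2, or detection fraction exactly 1%, is retained); target retention
  is `>=` ("at least 10% of ROIs"); "above LOQ" is strict `>`.
- **Q3 convention.** Upper quartiles use linear interpolation (the common
  numpy/pandas default). Q3 of small vectors depends on this; it is fixed
  and documented rather than configurable.
- Negative probes are excluded from the Q3 and detection-fraction statistics
  (they measure background, not signal) and never appear in the retained
  gene list. Detection fractions are always computed over all non-negprobe
  targets, which makes QC idempotent: re-running on the retained submatrix
  excludes nothing new.

The raw-read gate (≥ 1 million) applies only when raw read totals are
supplied; probe-level outlier testing and alignment/saturation QC happen
upstream of the count matrix and are out of scope.

## Q3 normalization

Each ROI is scaled by factor = Q3(ROI) / anchor, where the anchor defaults to
the geometric mean of per-ROI Q3 values (the platform convention; a fixed
anchor of 1 is available). After normalization every ROI's upper quartile over
retained genes equals the anchor. With the geometric-mean anchor, scaling one
ROI's counts by c changes all normalized values by the common factor c^(1/R);
with the fixed anchor the scaled ROI's normalized values are exactly
unchanged. Rank order within an ROI is always preserved.

## Differential expression

Response: log₂(Q3-normalized + 1). The pseudocount makes β directly a log₂
fold change consistent with the |FC| > 2 threshold; it is configurable. Per
layer and gene:

    log2 expression ~ status + (1 | patient),  REML

- **Inference.** Wald z on the status coefficient by default. A `t` switch
  uses a between-within degrees-of-freedom approximation (df = #patients − 2);
  it is an approximation, not a Satterthwaite computation, and is off by
  default. The null-calibration test guards the default choice.
- **OLS fallback.** When every patient contributes exactly one ROI to the
  layer (the default design), the random intercept is unidentifiable and the
  model is exactly equivalent to OLS; the implementation then uses a
  vectorized pooled-variance two-group comparison with exact t p-values
  (df = n − 2), which is both faster and exactly calibrated. A forced mixed
  fit on such a design agrees with OLS to ~1e-14. Mixed fits that fail to
  converge or return non-finite standard errors also fall back to OLS, which
  is the boundary (zero-variance) solution.
- **Untestable genes.** A gene constant across the layer, or a layer with an
  empty status group, is reported with p = 1 and flagged `untestable` rather
  than dropped silently.
- **Multiplicity.** Benjamini–Hochberg step-up within each layer (each layer
  is its own inferential family, matching per-layer DEG reporting);
  `adjust_scope="global"` pools all layers instead.
- **DEG call.** up ⇔ 2^β > 2 and adjusted p < 0.01; down ⇔ −2^(−β) < −2 and
  adjusted p < 0.01. The signed fold change is 2^β for β ≥ 0 and −2^(−β)
  otherwise, so its magnitude is always ≥ 1 and its sign matches β.
- **Ranking.** Top-N lists order by |β| descending, ties by adjusted p then
  gene id, so outputs are reproducible.

Sex and slide are not model covariates by default; the model formula accepts
only status and the patient intercept, and widening it is future work.

## Cross-layer meta-analysis

- **Venn partition.** Exact set algebra over layer DEG sets; region counts
  sum to the union size by construction (and are asserted against a per-gene
  brute-force enumeration in tests). The pipeline partitions the three
  arterial layers, leaving PVAT aside when four layers are present.
- **Meta up/down.** Union rule: a gene is meta-up when it is an up-DEG in at
  least one layer and a down-DEG in none (symmetrically for down). Genes up
  in one layer and down in another are set aside as conflicts and counted in
  neither set.
- **Profile similarity.** A gene's profile is its vector of per-layer β.
  Similarity to a seed gene is Pearson r over layers where both are
  non-missing (≥ 3 required); genes with r ≥ 0.95 (configurable) are
  reported, sorted by r then gene id. Pearson correlation makes the notion
  scale-free: a gene with exactly twice the seed's profile scores r = 1.
- **Clustering / PCA.** ROI-ROI Pearson correlation on log₂ expression;
  average-linkage clustering on distance 1 − r with ROIs pre-sorted by id for
  a deterministic leaf order; constant ROIs get correlation 0 with a unit
  diagonal. PCA operates on centered log₂ expression via SVD, with each
  component's sign fixed by its largest-magnitude loading.

## Enrichment and network

- **EASE score.** Fisher p is the one-sided hypergeometric tail P(X ≥ k) for
  an overlap of k between a query list of n and a set of K in a universe of
  N. The EASE score removes one gene from the overlap: the same tail with
  k − 1 successes in a list of n − 1. EASE p ≥ Fisher p always; k ≤ 1 gives
  EASE p = 1. Sets with raw EASE p < 0.05 are flagged enriched; BH adjustment
  is available but off by default.
- **Universe.** Defaults to the post-filter detected gene list (the
  detection-conditioned sampling frame), not the whole panel. Query genes
  outside the universe are dropped with a reported count.
- **Network.** Edge tables are assumed pre-combined confidence scores with
  text-mining evidence already excluded; recombining per-channel scores is
  out of scope. Edges with score ≥ 0.900 induce a graph on the query genes;
  the one or two largest connected components are kept (ties broken by the
  lexicographically smallest member) and singletons removed. Drug annotation
  attaches each node's drug list, filtered to approved drugs by default;
  nodes without drugs are kept but flagged undruggable. The shared-drug
  report lists drugs hitting annotated genes in two or more layer networks.

## Synthetic cohort generator

The generator defines the conditions every statistical claim is tested under.
Counts follow a negative binomial with log link:

    count(g, roi) ~ NB(mean = 2^(b_g + u_p + δ) × s_roi, size = r)

- `b_g` — gene baseline, uniform on `baseline_log2_mean_range` (default
  (3, 9), i.e. means of 8–512 counts: a realistic detectable range).
- `u_p` — patient random intercept, N(0, `patient_sd`), default 0.5 on the
  log₂ scale — exactly the structure the DE mixed model assumes, enabling
  honest calibration tests.
- `δ` — planted log₂ fold change, applied multiplicatively and only to
  case-status ROIs of the affected layer. Direction is up with probability
  `up_fraction` (default 0.9, echoing the predominance of upregulation in
  inflamed arteries). The default burden is graded 280/225/40/5 genes at
  |log₂FC| = 2 in intima/media/adventitia/PVAT.
- `s_roi` — log-normal ROI size factor, SD 0.3 (log₂), emulating
  library-size variation between segments.
- `r` — negative-binomial size (default 10, moderate overdispersion).
- Background: a third of targets (`undetectable_frac`) plus all 139 negative
  probes (`n_neg_probes`, the whole-transcriptome panel convention) are drawn
  from one background law (mean 2^1 counts, size factor only — no patient or
  condition effect), making negative probes and background-only targets
  exchangeable in distribution, which the LOQ filter relies on.

Defaults mirror the study design: 9 case and 7 control patients, 4 layers,
one ROI per patient-layer, ~2,000 targets at desk scale so the routine test
suite runs in seconds; `full_scale_config()` provides the ~18,000-target
panel-scale profile. The per-layer ROI allocation before exclusions is not
fixed by the design, so `rois_per_patient_layer` is exposed rather than
guessed.

What the generator does **not** emulate: probe-level (pre-deduplication)
reads, sequencing error, segmentation artifacts, spatial autocorrelation
between neighbouring ROIs, gene-gene correlation beyond the shared patient
effect, and cell-type composition differences between layers. Passing tests
therefore demonstrate the statistical machinery is correct under the model's
own assumptions — not that real arterial data meet those assumptions.

Companion generators plant known structure for downstream validation: half
the generated gene sets are enriched for true DE genes (member drawn from the
DE pool with probability `enrichment_bias`), the edge table plants a 5-gene
clique of DE genes at score 0.95 with one approved drug per member, and all
outputs are deterministic functions of (config, seed).

## Problem sizes and runtime

Routine tests use 100–2,000-gene cohorts; calibration and recovery checks use
2,000 genes × 16 ROIs in a single layer, where the vectorized OLS path fits
in well under a second. Mixed-model paths are exercised on 30–150-gene
fixtures (~0.1 s per gene fit). The full default pipeline (2,139 targets ×
64 ROIs, four layers) completes in about two seconds.

## Known limitations

- The mixed model assumes Gaussian residuals on the log scale; counts near
  the detection limit are discrete and mildly violate this. The target
  filter removes the worst cases, and calibration is verified empirically.
- The union rule for meta up/down sets is one defensible operationalization;
  a pooled cross-layer model would weight layers differently.
- EASE thresholds are applied to raw p-values by default, so the enriched
  flag is exploratory, not family-wise.
- Network confidence scores are taken as given; no propagation through a GO
  DAG or live database queries.
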