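# Methods

## Model and assumptions

The method rests on one biological assumption: the splicing factor
driving a condition's splicing changes must physically bind near the
events that changed. Binding evidence comes from public CLIP experiments;
"near" is operationalised as the **splicing region** — every genomic
interval of an event's two alternative paths extended by `window_nt`
(default 400 nt, the distance within which most splicing-regulatory
binding is reported; exposed as a parameter since estimates in the
300–400 nt range are common) on each side, merged. The reference path is
excluded: it is shared by both isoform groups and carries no
discriminating signal.

All coordinates are 0-based half-open on a single genome build; the
package performs no assembly conversion, so peaks and events must be
supplied on the same build.

### CLIP consolidation

Databases disagree on peak sets, so consolidation is deliberately
simple and inclusive: a site annotated by *any* experiment of an RBP
counts. One priority rule is applied per RBP: if the RBP appears in the
reference database (default `POSTAR2`, the broadest one), only its peaks
are used; otherwise the union over the remaining databases is taken.
The rule is all-or-nothing per RBP — a literal reading of how the
integrated resource was assembled. Experiments on mutated proteins are
dropped via a metadata flag rather than a hard-coded list. RBP symbols
are upper-cased before grouping; strand-unknown peaks (BED3 sources)
match either strand when a stranded overlap policy is requested
(default policy ignores strand, since many source BEDs carry none).

### The enrichment statistic

With `M` tested events, `K` selected (differentially spliced) events,
`m` events bound by an RBP and `k` bound events among the selected, the
CLIP p-value is the inclusive upper tail of the hypergeometric
distribution, `P(X ≥ k)`. The inclusive convention follows the
definition of the statistic as a one-sided Fisher exact test (the
observed table is part of its own tail). It is evaluated through the
log-space survival function, exact to machine precision down to
p ≈ 1e-300 at M ≈ 1e5; a `k = 0` tail is exactly 1. `M` is the number
of events passing the expression filter, not the full annotation —
untestable events carry no information about the selection. Raw
p-values are used for ranking (with ties broken by `k` descending, then
symbol, for determinism); BH-adjusted values are reported alongside for
transparency but play no role in the ranking, matching how the
statistic is used in practice.

### PSI and the built-in differential test

`PSI = p1/(p1+p2)` with path expression summed over member transcripts;
`pref` defaults to `p1 + p2` unless reference-path transcripts are
quantified explicitly. A silent event (0/0) has missing PSI.

Per-event differential-splicing p-values are preferably **imported**
from a dedicated event-level test; the built-in test is an explicit
stand-in: a two-sided Welch t-test on logit-PSI (PSI winsorized to
[0.01, 0.99] because exact 0/1 values are common at low depth), gated by
a direction check — mean `p1` and `p2` expression must move in opposite
directions between groups, otherwise the change is an expression change,
not a splicing change, and the event gets p = 1 with a flag. Degenerate
events (zero variance in both groups with equal means, or fewer than two
quantified samples per group) also get p = 1 and a flag; the pathological
zero-variance-unequal-means case gets float-tiny rather than 0 so that
p stays in (0, 1].

### Expression filters

Both filters are *relative*, per sample:

- **events**: each of the three paths must reach the `q_event = 0.1`
  quantile of all pooled path-expression values of that sample, in at
  least `ceil(0.75 · n_samples)` samples (ceiling: a strict reading of
  "75 % of samples"). The quantile estimator is linear interpolation
  (NumPy default, type 7).
- **genes**: a gene is kept iff it reaches the per-sample
  `q_gene = 0.25` quantile in at least one sample.

In both filters a value of exactly 0 never passes, even if pooled zeros
drag the quantile threshold itself to 0 — a silent path cannot count as
"expressed".

### Selection and ranking

Default selection is the `top_n = 1000` smallest differential-splicing
p-values (boundary ties broken by larger |ΔPSI|, then event id); a
p-value threshold mode (`p_threshold`, e.g. 0.001) is available instead,
since both conventions are in common use. Candidates must pass
`p_clip < 0.05`, `p_expr < 0.05` and `|log2 FC| > 0.58` (≈1.5-fold; all
exposed as parameters). The two p-values are *not* combined by default:
in knock-down settings the expression change is near-certain by design,
and folding it into the statistic would flatter the method. Fisher,
Stouffer and Irwin–Hall combination rules are provided for contexts
where combination is appropriate.

### Similarity network

For every RBP pair the phi coefficient of the 2×2 co-binding table
(identical to the Pearson correlation of the binary ExS columns) is
computed, with a one-sided exact hypergeometric test for co-binding
above expectation and BH adjustment across all pairs. Pairs involving a
constant column have undefined correlation; they are reported with
r = NA, p = 1 and excluded from the BH ranking. Edges with
`r ≥ r_min = 0.46` and `q < q_max = 0.1` are kept; clusters are the
connected components of the kept graph (the method's simplest
reproducible choice; greedy modularity is available behind a flag, in
which case inter-cluster links are marked in the edge table).

## Synthetic data: what it emulates, and what it does not

`simulate_dataset` builds a desk-scale dataset with the structure the
method exploits:

- **binding families**: RBPs are partitioned into families; a member
  binds its family's events with probability 0.6 and any event at a
  background 0.05, reproducing the family-coherent binding that the
  similarity network detects;
- **a driver**: one RBP additionally binds a fraction (default 0.1) of
  events whose PSI shifts by `delta_psi_effect` (default 0.3) in the
  condition group, and whose gene expression is scaled by
  `2^driver_knockdown_log2fc` (default −1.5) — the siRNA knock-down
  signature; optional "decoy" RBPs can co-change expression to mimic
  the downstream expression ripples seen in real knock-downs;
- **events** are uniform cassette exons on one toy chromosome, two
  transcripts each (inclusion/skipping carriers); peaks of bound RBPs
  are placed uniformly inside the event's splicing region.

Generator realism choices worth knowing (they interact with the
filters):

- baseline PSI is uniform on [0.3, 0.7] and the planted shift is
  directed across 0.5, so a shifted event keeps both paths expressed —
  otherwise the expression filter would silently delete much of the
  planted signal and the dataset would not contain what it claims to;
- event expression is log-normal with σ = 0.8 (≈3 decades, TPM-like),
  so the relative expression filter removes genuinely low-expressed
  events rather than events with skewed path balance;
- the gene table carries 300 non-RBP background genes spanning low to
  moderate expression, anchoring the relative gene filter the way a
  full transcriptome does; with RBP genes alone, a quarter would fall
  below the 0.25 quantile by construction;
- PSI noise is truncated-normal on [0, 1] (sd 0.05 by default);
  expression noise is multiplicative log-normal with CV 0.1.

Defaults (2000 events, 30 RBPs, 3 families, 5+5 samples) are the study
conditions for the recovery tests. What the generator does **not**
emulate: read-level sequencing noise and quantification uncertainty,
correlated event co-regulation beyond the driver, isoform complexity
beyond two transcripts per event, realistic genome sequence, and batch
effects. Passing recovery tests therefore demonstrate the statistical
machinery under the model's own assumptions, not performance on real
RNA-seq.

Two test-design notes. First, under the planted two-family conditions
used for network recovery (bind probabilities 0.6 / 0.05, 200 events)
the expected within-family phi is ≈ 0.35 and the cross-family phi
≈ −0.35, so recovery is evaluated at `r_min = 0.2` — the midpoint
separator for those conditions; 0.46 remains the analysis default, whose
appropriate value in general depends on the binding density of the data
at hand. Second, the "stronger planted effect ⇒ stronger driver signal"
sanity check is run in a selection-limited regime (top 100 events): with
the default top-1000 out of ~1400 surviving events, selection saturates
at ΔPSI = 0.1 already and the residual trend is dominated by how many
perturbed events survive the expression filter (larger shifts lose
more), which reverses the naive expectation.

## Problem sizes used by the test suite

Recovery and calibration tests run the full pipeline at the default
2000-event scale: 10 seeds for driver recovery, 100 seeds for the null
calibration of the driver's CLIP p-value (ΔPSI = 0), 10 seeds at
200 events for family recovery. The exhaustive hypergeometric check
sweeps every margin combination up to M = 30 against exact rational
arithmetic; ExS construction is verified against an all-pairs overlap
oracle on twenty 50×5 fixtures.

## Known limitations

- The built-in differential-splicing and differential-expression tests
  are pragmatic two-group Welch tests; they do not model quantification
  uncertainty or moderate variances across events/genes. Import
  externally computed event statistics where fidelity matters.
- The CLIP p-value cannot separate direct from indirect regulation when
  RBPs share binding sites (the similarity network shows exactly how
  much sharing there is); the expression filter is what restores
  specificity, and it presumes the driving factor itself changes
  expression — knock-out designs that leave expression unchanged need
  the filter disabled.
- Consolidation trusts database peak calls as-is; no peak-quality
  weighting or score thresholding is applied.
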