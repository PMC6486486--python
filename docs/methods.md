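# Methods

## The measurement model

The unit of observation is a protein-level relative abundance from label-free
MS of a pooled synaptosome sample — one pool per (brain region, age group),
measured in a small number of technical replicates. Because pooling happens
before measurement, biological variance between individuals is not
observable; all replicate scatter is technical. The analysis therefore treats
the per-(region, age) expected abundance as the quantity of interest and the
replicates as multiplicative noise around it.

All inference happens on the Arc-Sinh scale, `g(x) = ln(x + √(x²+1))`. The
transform is strictly increasing, defined at zero (zero intensities are
legal; missing cells are not — ingest rejects them, imputation is out of
scope), and asymptotically `ln(2x)`, so differences of normalized group
means read as log fold changes for all but very faint proteins. Fold-change
gates, by contrast, are evaluated on back-transformed (`sinh`) group means,
because "1.2-fold" is a raw-intensity-scale statement.

## Differential filtering

Per protein and region, a one-way fixed-effects ANOVA across the three age
groups (computed vectorized; verified against `scipy.stats.f_oneway`).
Degenerate proteins with zero within- and between-group variance get
`F = 0, p = 1`; zero within-group variance with a real effect gives `p = 0`.

Post-hoc power is the probability that this ANOVA rejects at level α given
the *observed* effect size: with `η² = SSB/SST`, the noncentral-F tail
`P(F′ > F_crit)` at noncentrality `λ = N·η²/(1−η²)`. At `η² = 0` the test
runs at its size (power = α); zero total variance yields power 0 with a
warning. Power here is a filtering heuristic in the tradition of
vendor-software "power" columns, not a prospective design quantity.

A protein is retained iff `p ≤ α` (default 0.05), max pairwise fold change
`≥ 1.2`, power `≥ 0.8` and unique peptides `≥ 2`. The published wording of
these gates is phrased as removal criteria ("p > 0.05" eliminated); this
package implements the keep-direction reading, which is the only one
consistent with selecting significantly changed proteins. The unique-peptide
floor is configurable because reasonable practice varies between 1 and 2.
No multiple-testing correction gates by default — the filter chain is a
candidate-generation device, not a hypothesis-testing procedure — but a
Benjamini–Hochberg FDR column is emitted for information.

## Correlation network and Markov clustering

Nodes are the retained proteins; an edge joins two proteins when the Pearson
correlation of their sample-expression vectors (all samples of the region,
ordered young→mid→old) is at least `r_threshold` (default 0.95). Only
positive correlations link by default — co-moving profiles — with an
`use_absolute` flag for signed analyses. Constant vectors have undefined
correlation and are excluded with a warning.

MCL is implemented from first principles on a dense matrix: self-loops with
weight equal to each node's maximum incident weight (1 for isolated nodes),
column normalization, then alternating expansion (matrix power, default 2)
and inflation (elementwise power, default 2.2, plus renormalization), with
entries below `prune_threshold` zeroed, until the matrix change falls below
`convergence_tol` or `max_iterations` is hit (then the current state is
interpreted and flagged non-converged). Clusters are attractor systems:
attractors are nodes with recurring flow (positive diagonal); attractors
sharing support merge; every node joins the attractor holding its largest
steady-state mass, ties going to the smallest-labelled attractor, so the
output is deterministic and invariant to node input order. Inflation 2.2 is
the package's default granularity setting. Singleton clusters are retained
in the output but excluded from cluster-level profile classification by
default. One caveat: on highly symmetric graphs (e.g. a bridge node exactly
between two equal clusters) the max-mass assignment of the tied node is
decided by floating-point round-off; real correlation graphs are never
exactly symmetric.

## Profile classes

A temporal profile is the triple of mean normalized abundances (young, mid,
old) with steps `d₁, d₂`. With `step_min = 0.18` (the Arc-Sinh-scale
analogue of the 1.2-fold gate, `ln 1.2 ≈ 0.182`) and `flat_max = step_min/2`:

- steady_up: `d₁ ≥ step_min`, `d₂ ≥ 0`, total rise ≥ `2·step_min`
- late_up: `|d₁| ≤ flat_max`, `d₂ ≥ step_min` (mirrors for the down classes)
- flat: both `|dᵢ| ≤ flat_max`; anything else is early_change.

The classes are exhaustive and, because `flat_max < step_min`, mutually
exclusive. The underlying biology defines these classes qualitatively (by
the shape of cluster mean curves); the numeric thresholds are this package's
own operationalization, chosen for internal consistency with the fold-change
gate.

## Subtraction and candidate selection

Subtraction removes proteins present in both regions' filtered sets with the
*same* class — shared behaviour cannot explain differential regional
vulnerability. It operates on (protein, class) pairs rather than on matched
cluster pairs, so cluster identity never leaks across regions and the result
is well-defined when the two regions yield different cluster counts. The
pipeline subtracts over **all** filtered proteins with their exact classes
(not only the four changing classes): a protein kept in one region only is
informative regardless of its label, and restricting to changing classes
would silently discard divergent proteins whose first step lands in the
early_change band under noise.

A candidate must be concordant between regions at young and at mid age
(`|Δ| ≤ concord_max = 0.18`), divergent at old age
(`|Δ| ≥ diverge_min = 0.36`, i.e. ≥ 1.44-fold), and — by default — show a
Welch-test rejection (`p ≤ 0.05`) between the regions' old-age replicates.
Divergence is unsigned: vulnerable-region candidates may shoot up or drop.
`concord_max` equals `step_min` and `diverge_min` doubles it, so "concordant"
and "divergent" are separated by a factor-2 dead band. Candidates are ranked
by `|Δ_old| − max(|Δ_young|, |Δ_mid|)`. With noiseless replicates the Welch
test is degenerate; equal values yield p = 1 and unequal values p = 0.

## Upstream regulator scoring

Over user-supplied signed edges (regulator → target, +1 activating / −1
repressing) and observed per-protein directions (+1/−1; the pipeline uses the
sign of old − young in the vulnerable region over its differential set), each
regulator with ≥ 1 observed target receives
`z = (n_consistent − n_inconsistent)/√n_observed` under the activated
hypothesis, so `|z| ≤ √n_observed`, negating all directions negates every z,
and under fair random signs z is asymptotically standard normal. The state
calls use the conventional ±2 cutoff. The accompanying overlap p is the
hypergeometric tail of drawing at least the observed number of the
regulator's targets into the observed set from a universe of
`universe_size` proteins. This is the simple (unweighted) activation score;
commercial implementations add edge-confidence weighting and bias correction
on top of a proprietary knowledge base, neither of which is reproduced —
the network is entirely the caller's input.

## The synthetic-data generator

The generator emulates the study design the analysis assumes: 2 regions × 3
age groups × `n_replicates` (default 3) technical replicates, log-normal
baseline abundances across proteins (`ln`-mean 8, `ln`-sd 1, i.e. intensities
in the 10³–10⁴ range), and planted per-protein profile classes (default: 1/8
each of steady_up/steady_down/late_up/late_down, 1/2 flat). A class scales
the baseline per age: steady_up = (1, f, f²), late_up = (1, 1, f²), down
classes reciprocal, with `effect_fc` f = 1.5 — comfortably above the 1.2
gate so the planted signal is detectable but not trivial. Replicates are
expected mean × mean-one log-normal noise with CV 0.10 (σ = √ln(1+CV²));
technical replicates of pooled MS samples at this scale typically sit near
that figure, and CV → 0 reproduces the expected means exactly.

Divergence candidates (default 20) are planted on flat backgrounds —
identical in both regions at young and mid — with the vulnerable region's
old-age mean multiplied or divided (random direction) by
`candidate_divergence_fc = 2.0`, so the cross-region split is the only age
signal they carry and they instantiate the candidate rule by construction.
Planted regulators draw sign-matched targets from proteins moving the
corresponding direction in the vulnerable region (an activated driver);
decoys (`coherent=False`) draw targets at random. Unique-peptide counts are
1 + Poisson(3), giving the ≥2-peptide gate a real but small bite (~5%
removed). Ages are ordered categories; the analysis is group-wise and never
uses numeric ages. Everything is driven by one `numpy` Generator seeded from
`SimConfig.seed`; identical configs give byte-identical outputs.

What the generator does *not* model — and what passing tests therefore do
not show about real data: biological between-subject variance (unobservable
under pooling), missing values and limit-of-detection censoring, correlated
noise across proteins (shared-run effects), peptide-level rollup, and any
real biological network structure. Recovery rates on synthetic data are
upper bounds for real-data behaviour.

## Problem sizes and numerical choices

Simulation-based checks run at 500–1000 proteins with 3 replicates — large
enough for stable rates (binomial SE on a 5% rate at n=1000 is ~0.7%) while
keeping the whole suite and the acceptance script in the low minutes on one
core. The null z-score calibration uses 10,000 independent regulator draws.
Convergence and pruning tolerances (1e-8, 1e-7) are far below any mass that
affects cluster readout; ANOVA p-values at F = ∞ (zero within-group
variance) are set to 0 rather than propagating NaN; power at η² ≥ 1−1e-12 is
clamped to 1.

## Known limitations

- Cluster-level class labels are computed from cluster mean profiles for
  reporting, but the inferential path (subtraction, candidates) is
  protein-level; a cluster-pairing subtraction mode is deliberately not
  implemented (ambiguous when region cluster counts differ).
- The candidate Welch test uses 3-vs-3 technical replicates; its p-values
  quantify measurement repeatability, not biological significance.
- The activation score treats the supplied network as ground truth; edge
  errors propagate directly into z.
- Per-region graphs are the default; a joint two-region graph is available
  (`build_graph(..., region=None)`) but mixes within- and between-region
  correlation structure.
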