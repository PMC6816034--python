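# Methods

This note documents the statistical model behind `ppientropy`, the
parameters that matter, the synthetic data the tests run on, and the
numerical conventions — in enough detail that results can be interpreted
and reproduced without reading the source.

## Degree-distribution entropy of induced subnetworks

A patient's subnetwork is the *edge-induced* subgraph of the human
interactome on the proteins of that patient's up-regulated genes: only
interactions with both partners in the set are kept. Up-regulated proteins
with no partner inside the set are excluded (and counted in the log):
subnetworks are built from interaction records, and a degree-0 class would
have no defined mass in the entropy formula.

The complexity readout is the Shannon entropy of the degree distribution,

    H = − Σ_k p(k) · log2 p(k)    [bits],

with `p(k)` the fraction of subnetwork nodes of degree `k`, degrees counted
*inside the induced subnetwork*, and the sum running over observed degrees
only (so 0·log 0 never arises). H is bounded by log2(#distinct degree
classes), is invariant under node relabeling, and — because it depends only
on proportions — is unchanged by disjoint duplication of the network. No
size normalisation is applied; subnetworks of different sizes are compared
directly, which is the point of using proportions.

## Up-regulation calling

Per patient, differential expression is tumor − control per gene (RSEM
units). Its frequency distribution is an approximately Gaussian bulk of
unchanged genes plus a right tail of genuine up-regulation. The bulk is
estimated by fitting `A·exp(−(x−μ)²/2σ²)` by unweighted least squares to
the `log10(y+1)`-transformed relative frequencies of a 100-bin equal-width
histogram. The transform compresses the peak and stabilises the fit
against tail contamination; since it rescales heights, not positions, μ
and σ remain on the differential-expression axis, and the gene-level cut
is the upper one-tail point of the fitted bulk:

    threshold = μ + σ·z(1−α),   α = 0.05 by default.

Membership is strict (`diff > threshold`). Initialisation: μ₀ = modal bin
center, σ₀ = half the interquartile range of the raw differentials, A₀ =
maximum transformed frequency; optimizer tolerances 1e−8, at most 10,000
evaluations. If the fit fails to converge the threshold falls back to the
empirical (1−α) quantile of the raw differentials and the patient is
flagged; a cohort run never aborts on one pathological profile.

Calibration, measured by the test suite on pure-null profiles
(9,190 N(0,1) differentials, 10 seeds): 4.6–5.2% of genes called,
thresholds 1.60–1.69 — i.e. the fitted bulk recovers the generating
quantile. With effects planted at 5σ, recovery is ≥ 90% at a ≤ 7% null
call rate.

### Tunables

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.05 | one-tail mass of the fitted bulk above the cut |
| `n_bins` | 100 | histogram bins over ~9,000 genes; keeps the bulk smooth |
| `null_remove` | 5 | nodes deleted per null replicate (and hubs per attack) |
| `null_reps` | 1000 | random-removal replicates per patient |
| `max_targets` | 20 | cap of the cumulative hub-removal trajectory |
| `five_years_days` | 1825 | horizon of the "5-year" survival rate |
| `correction` | holm | multiplicity correction of pairwise rank tests |

## Hub removal versus the random-removal null

Target inactivation is node deletion: the victim and its incident edges go,
and nodes thereby isolated are dropped too (consistent with subnetwork
construction). For each patient, 1,000 replicates delete `null_remove`
nodes chosen uniformly without replacement; the entropies of what remains
form an empirical null. The observed statistic is the entropy after
deleting the top-`null_remove` hubs (degree rank, ties broken
lexicographically by accession for determinism). The one-sided
pseudo-count estimator

    p = (1 + #{null H ≤ observed H}) / (1 + reps)

never returns 0 and counts exact ties (on a regular graph the null is a
point mass and p = 1, as it should be). Replicate r of patient q draws
from a stream keyed on (master seed, q, r), so per-patient nulls are
reproducible and independent of cohort ordering.

A mechanistic caveat worth recording: hub removal lowers *degree-histogram*
entropy only in leaf-heavy graphs. Edge-induced subnetworks of a sparse
scale-free interactome are dominated by a large degree-1 class; deleting a
hub erases its leaf neighbours and its own singleton high-degree class, so
entropy falls well below random removal (left tail, small p). In a graph
with minimum degree ≥ 2 (for instance a preferential-attachment graph with
two edges per arriving node), hub deletion instead *splits* the dominant
minimum-degree class and entropy rises. The hub-dominance checks therefore
run on what the pipeline actually analyses — subnetworks induced from a
scale-free interactome (2,000 proteins, attachment 2; ~250–300-node
subnetworks from degree-weighted protein sets), where the top-5 attack is
significant at p < 0.05 in 20/20 seeds.

## Survival, regression and target counts

Five-year survival per cancer type is `100·S(1825)` from the Kaplan–Meier
product-limit estimator (lifelines), right-continuous step lookup, with
censored records shrinking the risk set without dropping the curve. The
same lookup at a patient's days-to-death/last-follow-up gives per-patient
rates for the within-tissue analysis, which averages entropy and survival
inside the intervals 100–81%, 80–61%, 60–41%, 40–21% (cut at each lower
bound; at least 3 patients in each of the four intervals required).

Cohort mean entropy is regressed on the 5-year rate by ordinary least
squares; the report carries slope, intercept, Pearson r, the two-sided p
for slope ≠ 0 and a 95% t-based CI. Cross-cohort entropy heterogeneity:
tie-corrected Kruskal–Wallis (χ² p, df = groups − 1) plus two-sided
Mann–Whitney rank-sum tests for every pair under Holm correction. The
pairwise test is the *unpaired* rank-sum, not the signed-rank test: cancer
cohorts contain different patients in unequal numbers, so a paired test is
not computable across them (a paired mode exists for genuinely paired
designs).

The entropy goal is the fitted line at X = 100% survival. Per patient, the
top-20 hubs of the *baseline* subnetwork are frozen once (no re-ranking
between removals, matching a fixed top-20 target list) and removed
cumulatively; `n_required` is the smallest n with post-removal entropy ≤
goal, 0 if the baseline already meets it, and "unreached" past 20 — capped
rather than extrapolated, and counted at 20 (a lower bound) in cohort
means. An emptied subnetwork scores entropy 0 (goal trivially reached) and
is flagged.

## Synthetic data: what it emulates, and what it does not

The generator is the package's study-condition definition:

* **Interactome** — Barabási–Albert preferential attachment, 2,000
  proteins, 2 edges per arriving node; scale-free with the right-skewed
  degree distribution the hub analysis assumes.
* **Expression** — 2,000 genes mapped one-to-one onto a seeded permutation
  of proteins; control values log-normal (meanlog 4, sdlog 1, an
  RSEM-like positive skew); tumor = control + N(0, σ=1) for null genes
  plus a +5σ shift for each patient's planted set. Planted genes are drawn
  with probability proportional to interactome degree, so induced
  subnetworks contain hubs — mirroring the empirical observation that
  recurrent high-degree proteins dominate patient subnetworks. The planted
  fraction (2% at center) is scaled 0.5×–1.5× across the 9 cohorts of 30
  patients, so cohorts genuinely differ in subnetwork size and entropy.
* **Survival** — exponential event times per cohort with the rate solving
  S(1825 d) = link(H), link slope −250 and intercept 626.75 — the inverse
  of an entropy-on-survival line with slope −0.004 and intercept 2.507 —
  clamped to (1, 99)%, with 20% independent uniform censoring. The dataset
  writer spaces the cohorts' generating entropies over 2.1–2.5 bits, the
  range reported for real tumors.

Everything is a pure function of the spec and seed (bit-identical reruns),
and the writer emits the same TSV/PSI-MITAB formats the readers parse, so
synthetic runs exercise the real I/O path. The default desk-scale study
(9 × 30 patients, 2,000 genes) runs end to end in well under a minute on
one CPU; the acceptance script completes in under a minute.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: read-level RSEM noise and gene–gene expression
correlation; tumor heterogeneity (mixtures of clones or stem-cell
signatures that can push a tumor's entropy *below* its control); biological
edge semantics (the synthetic interactome is scale-free but has no protein
families, complexes or annotation structure); non-exponential hazards; and
informative censoring. Desk-scale subnetworks are also smaller than
TCGA-scale ones (tens of nodes rather than hundreds), so absolute
entropies are lower than those of real cohorts even though every
qualitative relationship — entropy up with planted burden, survival down
with entropy, hub attacks in the null's left tail — is preserved.

## Numerical conventions and edge cases

* Entropy sums run in ascending degree order in both the graph path and
  the vectorised null path, so the two produce bit-identical floats; ties
  against the null are counted with 1e−12 slack.
* Degenerate inputs fail loudly and early: all-identical differentials
  (degenerate histogram), fewer than 4 non-empty bins (fit), empty induced
  subnetworks (flagged per patient, never fatal to a cohort), all-equal X
  or Y in the regression, survival rates outside (0, 100].
* All text I/O is UTF-8, tab-separated, "." decimal; report writers are
  deterministic byte for byte given identical inputs and seed.
* Seeds: one master seed per run; every stochastic component (generator
  streams, null replicates) derives its stream from it with fixed offsets,
  so any single piece can be re-run in isolation.

## Known limitations

The analysis treats the network statically — no expression-weighted edges,
no dynamics, no attractor modelling — and prescribes target *counts*, not
validated drug targets. The entropy measure ignores which degrees are
large (a graph of hubs and a graph of small fans can share p(k)); it is a
complexity summary, not a topology fingerprint. Regression across cohorts
weights each cancer type equally by its mean, not by patient count. These
are properties of the method itself, faithfully implemented.
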