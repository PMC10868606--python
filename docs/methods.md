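# Methods

This note documents the models and numerical choices behind
`bgcnovelty`: what each stage computes, the tunable parameters and their
defaults, what the synthetic-data generator does and does not emulate,
and the package's known limitations.

## Novelty model

The central object is the membership matrix **D** ∈ ℝ^(B×G), *d(b, g)* ≥ 0
the distance from BGC *b*'s feature vector to the centroid of
gene-cluster family *g*, as produced by BiG-SLiCE-style query mode
against a pre-computed GCF model. Lower distance means higher confidence
that *b* belongs to *g*. Three derived quantities:

- **Top-X hits**: per BGC, the X smallest distances, ascending, ties
  broken by ascending GCF id (deterministic and column-order
  independent). Default X = 10.
- **Best distance** *d\** = the top hit. The clustering rule is
  *clustered ⇔ d\* ≤ T* with **T = 900** (the threshold at which the
  public GCF model itself was built); strictly above T means the BGC
  failed to cluster and is flagged novel. The boundary is inclusive on
  the clustered side and unit-tested, since both readings circulate.
- **Top-k mean**: the arithmetic mean of the k smallest distances,
  k = 3 by default — a smoother novelty score than *d\** alone (values
  above ≈2400 indicate strong dissimilarity from everything known).

Clustered BGCs are split by whether the best GCF contains an
experimentally characterized MIBiG reference BGC (`has_mibig` in the
GCF catalog): `clustered_mibig` (likely known chemistry) vs
`clustered_novel`. The three categories always partition the
collection, and the unclustered count is non-increasing in T (both are
property-tested).

## Product categories

Raw antiSMASH product labels resolve case-insensitively to one of eight
base classes (PKS-I, PKS-other, NRPS, RiPP, Terpene, Siderophore,
Saccharide, Other) via a ~50-entry default map following the BiG-SCAPE
class scheme, except that siderophores keep their own class because
they are a first-class stratum here. Unknown labels map to Other with a
logged warning — the partition is total by construction. The region
rule: one distinct base class → that category; exactly
{PKS-I, NRPS} → PKS/NRPS-hybrid; any other ≥2 classes → Hybrid-other.
Duplicate labels collapse before the rule is applied ("only two
products" is read as two distinct chemistry classes, since antiSMASH
can emit repeated labels). The map is overridable via TSV; whether
`NRPS-like` should count towards the exact PKS/NRPS pair is therefore a
user decision — the default maps it to NRPS, so it does.

RiPP subclasses are tallied per verbatim label over RiPP-bearing
regions. Note the two counting universes deliberately differ: a hybrid
region containing a lanthipeptide counts in the subclass tally but is
not categorized "RiPP". Both tallies are exposed; neither is asserted
against the other.

## Pairwise distances and SMACOF

Membership profiles (full rows of **D**, never just the top-X) are
compared under eight metrics. Formulas are the standard ones
(chebyshev = max |aᵢ−bᵢ|, braycurtis = Σ|aᵢ−bᵢ|/Σ|aᵢ+bᵢ|, canberra with
0/0 terms contributing 0, correlation = 1 − Pearson r, …); "l2" is kept
alongside "euclidean" for interface fidelity and asserted identical.
Computation delegates to `scipy.spatial.distance.pdist` with a
degeneracy policy layered on top for cosine (zero vector) and
correlation (zero variance): both members degenerate → distance 0,
exactly one → 1, always with a warning. The test suite checks every
metric against an independent double-loop evaluation of the formulas to
1e-12.

Metric MDS is SMACOF implemented from scratch: iterated Guttman
transforms minimize raw stress σ(Z) = Σ_{i<j} (d_ij(Z) − δ_ij)²; the
reported quality is stress-1 = √(σ / Σ δ²). Defaults: dims = 2,
tol = 1e-6 on the relative stress decrease, max_iter = 300, 4 restarts
(first = classical Torgerson scaling, which is exact for
Euclidean-embeddable inputs; the rest seeded Gaussian). The Guttman
step guarantees a non-increasing stress sequence, which is asserted on
random instances. Degenerate cases: a single point embeds at the
origin; an all-zero distance matrix embeds all points coincident with
stress 0.

Stratification: one embedding per (product category, metric) with at
least 3 members — 2 points embed trivially with zero information, so
smaller strata are skipped with a logged notice. A fully populated
10-category collection yields exactly 80 stratified embeddings; the
unstratified "all" embedding per metric comes from the same primitives
(CLI `--no-stratify`). Each stratum/metric job draws its own child seed
from a `SeedSequence`, so results do not depend on evaluation order.
Plot export min–max-scales the top-k mean onto marker size [s_min,
s_max] and hue [0, 1]; normalization is stratum-local by default, with
an explicit `norm_range` for global scaling across strata (both scopes
are legitimate reading conventions; equal scores map to the midpoint).

## Network integration

A **singleton** is a family with exactly one collection BGC and no
MIBiG co-member — a BGC paired only with a MIBiG node is "known", not a
singleton, and MIBiG nodes count towards family size but never towards
collection counts. The unique-chemical-class estimate is
singletons + families without MIBiG. Singleton percentages are reported
to one decimal without special-casing (196/779 = 25.16 % → 25.2 %).
MIBiG nodes are recognized by the accession pattern `BGC` + seven
digits; BiG-SCAPE's `.gbk` suffix is stripped during reading, other id
normalization is the caller's responsibility and mismatches fail
loudly, listing the first ten offenders.

## Genus statistics

The two-sided Mann–Whitney U test is implemented directly.
U_x = Σ [xᵢ > yⱼ] + ½[xᵢ = yⱼ], computed via midranks. Small samples
(max n ≤ 8, tie-free) use exact enumeration of the C(N, n₁) equally
likely rank labellings, with the two-sided p defined as
P(|U − n₁n₂/2| ≥ |u_obs − n₁n₂/2|) — a definition that remains valid
under ties (the exact path can be forced). Larger or tied samples use
the normal approximation with tie-corrected variance
σ² = (n₁n₂/12)((N+1) − Σ(tⱼ³−tⱼ)/(N(N−1))) and continuity correction ½,
capped at 1. Identical samples return U = n₁n₂/2, p = 1. The
implementation matches brute-force enumeration to 1e-12 and scipy's
asymptotic path to machine precision; the continuity-corrected
approximation tracks the exact p within ~0.011 already at n₁ = n₂ = 8.
The direction of a genus shift is reported from the common-language
effect size U/(n₁n₂) — i.e. from the statistic the test actually uses —
rather than from sample medians, which are noisier at moderate shifts.
Box-plot summaries use Tukey conventions (quartiles by linear
interpolation, whiskers at 1.5·IQR, means marked). No multiple-testing
correction is applied across genus pairs; the intended use is a single
pairwise comparison.

## Synthetic-data generator

The generator defines the study conditions the tests run under:

- **Genera**: Micromonospora (29 strains, median best distance 908) and
  Micromonospora_E (6 strains, median 1004) by default.
- **BGCs per genome**: uniform on 13–34.
- **Category weights**: Terpene 156/779, Hybrid-other 146/779, RiPP
  129/779, remainder spread over the other seven categories (Other 80,
  NRPS 60, PKS-I 55, PKS/NRPS 50, PKS-other 40, Siderophore 38,
  Saccharide 25).
- **Best distances**: log-normal with genus-specific median and log-sd
  `home_sigma` = 0.5. The log-normal is chosen because membership
  distances are non-negative and right-skewed; 0.5 is the calibration
  implied by observed mean/median ratios of such distributions
  (1006/908 → σ ≈ 0.45; 1174/1004 → σ ≈ 0.56). A pleasant consistency
  check: with median 908 and T = 900 roughly half the BGCs fail to
  cluster, matching the ≈51 % unclustered rate the model is meant to
  emulate.
- **Background distances** (to non-home GCFs): log-normal, median 2500,
  log-sd 0.35, truncated strictly above the home distance so the
  planted home GCF is always the top hit and truth flags are exact. A
  background median at or below a genus median is a configuration
  error.
- **Type coherence**: probability that a BGC's home GCF is its
  category's anchor GCF (default 0.5); at 1.0 categories separate
  cleanly in embeddings, which the planted-structure test uses.
- **Families**: BGCs sharing a home GCF form a family, unique homes are
  singletons, and multi-member families on a MIBiG-flagged GCF receive
  one synthetic `BGC0000001`-style reference node.

All randomness flows through `numpy.random.default_rng` (PCG64) from a
single seed; identical config + seed gives identical output byte for
byte.

What the generator does **not** emulate: real BiG-SLiCE distances are
not independent across GCFs (feature vectors induce strong column
correlations), best-distance distributions are not exactly log-normal,
and family structure in a real similarity network is not a function of
the best GCF alone. Consequently, passing tests demonstrate that the
pipeline's arithmetic, ranking, calibration and recovery behaviour are
correct under controlled conditions — not that any particular biological
collection will show a given effect size. In particular, a two-lognormal
model at medians 908/1004 yields a more modest expected rank separation
than strongly structured real data can produce, so single-replicate
p-values on synthetic data are often non-significant at these sample
sizes even though the direction of the shift is recovered reliably
(≈97 % of replicates), and the null rejection rate is calibrated at
α = 0.05.

The deterministic `reference_fixture()` (no RNG) pins the count
arithmetic instead: 779 BGCs over 38 strains, 413/94/272 novelty
partition, 196 singletons + 132 families (16 with MIBiG holding 83
BGCs; the other 116 holding 500), 148 unclustered singletons, 108
families with ≥1 unclustered member, per-strain unclustered means
291/29 ≈ 10.03 and 89/6 ≈ 14.83, and one flagship strain with a
17-singleton / 21-unclustered / 16-overlap pattern. Its distances are
arbitrary deterministic values satisfying exactly these constraints;
only the counts are contractual.

## Problem sizes and runtime

The default test run keeps everything desk-scale: brute-force metric
oracles at n ≤ 10, dim ≤ 20; SMACOF instances of 3–15 points plus
strata of ~30 points in the 80-embedding grid (~300 BGCs, 40 GCFs);
Mann–Whitney enumeration at n ≤ 8; Monte-Carlo calibration with 200
direction-recovery and 1000 null replicates at sample sizes 570 vs 147.
The full suite completes in well under a minute; `scripts/acceptance.py`
in a few seconds.

## Known limitations

- The package consumes membership distances; it cannot produce them
  (no pHMM featurization or BIRCH model construction), and it does not
  run antiSMASH or BiG-SCAPE.
- The SQLite reader extracts only (bgc_id, gcf_id, distance) triples
  from a table carrying those columns; the long-form TSV is the
  canonical interchange format because report schemas vary by tool
  version.
- The exact Mann–Whitney path is limited to enumerations below 2×10⁶
  labellings; beyond that the asymptotic path must be used.
- `correlation`/`cosine` distances on near-constant profiles are
  numerically delicate; the explicit degenerate-vector policy covers
  the exact-zero case only.
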