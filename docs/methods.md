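# Methods

`phylodelta` studies how asymmetric missing data — DNA from historical
museum skins versus modern tissue samples — distorts concatenated
(supermatrix) phylogenomic inference, and implements the two-topology
log-likelihood outlier framework used to localise and repair that
distortion. Everything runs at desk scale from a synthetic study generator,
so no external sequence data are required.

## The outlier statistic

Given two candidate topologies for the same taxa — `T1` estimated from a
"Low Coverage" alignment (every called base retained) and `T2` from a
"Filtered" alignment (bases covered by fewer than `depth_threshold` reads
masked to `N`) — branch lengths are re-optimised independently for each
topology on a common evaluation alignment under its locus partition, and
each site is scored as

    Δ s-lk(i) = ln L(site i | T1) − ln L(site i | T2).

Positive values mark sites whose data favour `T1`. Sites are binned at the
fixed thresholds `>20, >10, >2, <−2, <−10, <−20` (strict inequalities);
per-locus sums give `Δ l-lk`, binned at `>2, >10, >20, <−2, <−10`. Two
re-analysis routes follow: masking a site bin to `N` in all individuals and
re-estimating, or excluding whole loci in a `Δ l-lk` bin. A subclade
workflow applies the same machinery with `T2` taken from the
100%-completeness trim of the subclade alignment (columns with any missing
character removed), both trees rooted on a designated outgroup.

Conservation identities are enforced exactly: site deltas sum to the total
log-likelihood difference, and locus deltas sum to the site total.

## Likelihood engine

Site likelihoods come from Felsenstein pruning over alignment-column
patterns (identical columns collapsed and weighted), with per-node
rescaling against underflow. Tip partials are unit vectors for `A/C/G/T`
and all-ones for `N/-/?`, so an all-missing column contributes exactly zero
log-likelihood. Models are JC69, HKY85 and GTR with empirical base
frequencies, optional discrete-Γ rate variation (four equal-probability
categories whose rates are conditional bin means of a mean-one Gamma(α,
1/α), computed by incomplete-gamma identities), and per-partition rate
multipliers over shared branch lengths (proportional linkage; the
length-weighted mean multiplier is normalised to one, with branch lengths
rescaled to compensate). Transition matrices are computed by symmetrised
eigendecomposition, exact for reversible generators.

Branch lengths are optimised by Gauss–Seidel coordinate ascent: one
postorder pass caches subtree ("down") partials, and a recursive sweep
maintains the complementary ("out") partial exactly as it descends, so each
single-branch step is an exact conditional maximisation (bounded Brent on
[1e-8, 10]) and the total log-likelihood is non-decreasing. A sweep costs
two pruning passes plus one scalar optimisation per branch. The per-edge
search brackets around the current length first and re-widens only when the
optimum presses against the bracket.

Per-locus model selection (`fit_models`) scores {JC69, HKY85, GTR} ×
{with/without Γ₄} by BIC with the locus length as sample size, preferring
the simpler model on ties; `+I` (invariant-sites) models are deliberately
outside the space. Tree search is neighbour joining on Jukes–Cantor
distances (pairwise deletion; saturated or non-overlapping pairs capped at
5.0 substitutions/site) followed by NNI hill climbing: candidates are
scored cheaply by re-optimising only the rearranged edge, the best
structurally independent rearrangements are applied together, and every
acceptance is confirmed by full branch re-optimisation with reversion if
the gain is not real. Bootstrap support is the nonparametric Felsenstein
bootstrap with columns resampled within loci (B = 100 by default), each
replicate analysed by NJ+NNI under the model fit to the original data.
This deliberately replaces the rapid-bootstrap heuristics of large ML
packages; supports are comparable in meaning, not in algorithm.

## Synthetic studies

The generator emulates a sequence-capture (UCE) study that mixes sample
types:

* **Loci.** Truncated-normal lengths (mean 500 bp, SD 150, bounds
  [140, 1708]). Sites evolve under HKY85 (κ = 3, AT-rich frequencies
  0.3/0.2/0.2/0.3) down the true tree. A conserved-core rate profile —
  relative rate `0.05 + 0.95·(2|u−½|)²` along relative position `u`,
  normalised to mean one — concentrates variable and parsimony-informative
  sites in the flanks, the defining feature of UCE loci.
* **Trees.** Either pure-birth (Yule, birth rate 2.0 in substitution
  units; an optional `min_internal` floor keeps every internode resolvable,
  used by the clean-signal recovery experiment at 0.02 because pure birth
  routinely yields internodes so short that no finite alignment can resolve
  them) or a "radiation": one clade (default 16 of 18 taxa) with internal
  branches ≤ 0.002 and pendants U(0.01, 0.05), plus backbone taxa and an
  outgroup — the regime in which missing-data artefacts are strongest.
* **Observation model.** Read depth is Poisson per sample × site
  (independent across sites; depth autocorrelation is a known
  simplification), λ = 30 for modern and 3 for historical samples.
  Historical samples first lose their locus flanks (only the central 40%
  of columns retained — degraded DNA yields short fragments). Depth-0
  sites are missing in both regimes; sites with 0 < depth < 6 are kept in
  the Low Coverage dataset (optionally miscalled with probability ε,
  default 0) and masked in the Filtered dataset, so the Filtered matrix is
  always at least as missing as the Low Coverage one, cell by cell.
* **Filtering.** The per-individual missing-fraction rule and the locus
  occupancy rule are applied to both datasets independently, in real
  pipeline order. The strict field-standard values (drop a sequence at >30%
  missing, keep a locus at ≥75% occupancy) are the `FilterConfig`
  defaults; the *bundle* generator uses lenient values (0.95 / 0.50)
  because at 40% flank retention every historical sequence exceeds 60%
  missing and the strict rules would empty both matrices — the strict
  rules presuppose the milder degradation of real captures.

## Experiments and what they show

* **Topology recovery.** 12 taxa, 50 clean loci × 400 bp, moderate
  branches: NJ+NNI under JC69+Γ₄ recovers the true topology in ≥ 90% of
  replicates (measured 20/20). The Γ term matters: under an equal-rates
  model the conserved-core profile misleads roughly one replicate in five
  at short internodes.
* **Missing-data asymmetry.** Under the biased observation model the
  historical/modern missing ratio at positive outlier sites exceeds one in
  every seed (modern samples at λ = 30 are effectively complete, so the
  ratio is typically infinite — the qualitative signature, exaggerated).
* **Completeness sweep.** Trimming at 0–100% in 10% steps (each trimmed
  alignment analysed unpartitioned, since trimming destroys locus
  boundaries) gives strictly non-increasing lengths and PIS counts; an
  intermediate threshold does at least as well as no trimming in ≥ 70% of
  biased seeds.
* **A negative result worth stating.** With error-free low-coverage calls
  (ε = 0), keeping low-coverage characters is strictly informative: in the
  paired experiment the *Filtered* tree — whose historical rows are ~97%
  missing — is the one that clusters sample types artifactually
  (shared-missingness attraction), while the Low-Coverage tree tracks the
  truth; and masking the `Δ s-lk > 2` bin does not systematically pull the
  Low-Coverage tree toward the Filtered one (measured rates 0.20 and 0.35
  over 20 seeds). Reproducing the empirical direction — a biased
  Low-Coverage tree rescued by filtering — requires either erroneous
  low-coverage calls (ε > 0, available as a config hook) or a filtering
  regime that *reduces* the information asymmetry between sample types, as
  it does in real captures where modern samples lose at least as many
  low-coverage variants as historical ones. The corresponding acceptance
  assertions are kept at their nominal thresholds and fail honestly under
  ε = 0.
* **Predictive model.** A one-hidden-layer network (5 units, weight decay
  0.01, L-BFGS, ≤500 iterations) over 100 random 75/25 splits, features
  min-max scaled on each training split; R² is the squared Pearson
  correlation of predicted versus observed test values, and variable
  importance is the permutation increase in test RMSE (10 permutations per
  replicate, floored at zero, rescaled to sum to 100). On fixtures where
  `Δ l-lk` is a noisy monotone function of the PIS count, the model
  explains most of the variance and ranks PIS first. The architecture is
  an explicit default, not an inference from any published tuning grid.

What passing these tests does **not** show: the generator has no indels,
no alignment error, no paralogy, no contamination, no depth
autocorrelation, and no base-quality structure, so real museum datasets
can fail in ways these simulations cannot express.

## Numerical and design choices

* Missing characters `N`, `-`, `?` are one equivalence class everywhere
  (missing fractions, PIS calls, completeness, likelihood); pipelines of
  this kind interconvert them freely. IUPAC codes other than `N` are
  rejected at parse time — a documented limitation.
* Thresholds are strict (`>`/`<`) exactly as printed; the 30% rule drops a
  sequence only above 0.30; the 75% occupancy rule keeps a locus at
  exactly 0.75. `round(fraction × nPIS)` rounds half away from zero.
  Ablation replicates use seeds `seed + replicate_index`.
* The sign convention is `Δ = lnL(T1) − lnL(T2)` with `T1` the
  with-missing/Low-Coverage topology. Positive sites favour `T1`. Both
  sign bins can be masked or excluded, so either reading of "outlier"
  is exercisable.
* Classical (Torgerson) MDS with a deterministic sign convention (first
  non-zero loading of each axis positive); RF distances count bipartition
  symmetric differences only, no branch-length weighting.
* The sample-type clustering score is the Fitch parsimony count of the
  binary modern/historical character — 0 for a single type, 1 for
  reciprocal monophyly, larger the more the types interleave; it is
  rooting-invariant and replaces qualitative tip-colour inspection.
* Degenerate cases: GC content of an all-missing locus is 0 with a
  `degenerate` flag (not NaN); empty completeness trims raise carrying the
  threshold; loci reduced below two sequences are retained but flagged;
  a missing-ratio with a zero modern mean reports `inf` when the
  historical mean is positive.
* Determinism: every stochastic step takes an explicit seed
  (`numpy.random.default_rng`), NJ sorts taxa lexicographically before
  joining, NNI ties keep the incumbent, and the pipeline writers emit
  byte-identical TSV/newick for identical config and seed.

## Problem sizes

Replication experiments default to 18-taxon studies with 30 loci
(~16 kb), 20 seeds for the paired comparison, 20 replicates for topology
recovery, 10 sweep seeds, and 100 training/test splits for the network;
`scripts/acceptance.py` uses the same conditions at slightly reduced seed
counts. These sizes give stable rates while keeping a full run in the
minutes range on a single core.
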