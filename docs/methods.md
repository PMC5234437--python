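# Methods

This note records the models implemented, the defaults and why they were
chosen, the numerical conventions, and what the synthetic-data generator
does and does not emulate.

## Scope and data model

The package operates on OTU tables (rows = OTUs, columns = samples,
integer read counts, a final semicolon-delimited `taxonomy` column),
per-sample mapping files (first column sample ID, declared categorical
group columns and numeric meta columns, `NA` for missing), and rooted
Newick trees whose leaves are OTU IDs.  Orientation of the OTU table is
fixed; no transposition auto-detection is attempted, because a silently
transposed table is a classic source of corrupted analyses.  Unrooted
trees (basal trifurcation) are midpoint-rooted and the rooting is logged.
OTUs present in the table but absent from the tree are a hard error:
silently dropping them would bias UniFrac.  Tree leaves absent from the
table may be pruned on request (`prune_extra` / `--prune-missing`), with
a log entry.  Joint analyses use the intersection of the OTU-table and
mapping sample sets, with a warning listing any asymmetry.  Every
pipeline invocation writes a run log with all thresholds, seeds and input
names.

## Normalization

Default: `n_ij = c_ij · min_k(S_k) / S_j`, where `S_j` is sample j's
total.  This removes depth differences deterministically, preserves
within-sample proportions exactly, and loses no reads.  Normalized values
are kept as reals — rounding would double-apply a threshold, because the
alpha-diversity step already applies a 0.5-count floor downstream.
Classical rarefaction (uniform subsampling without replacement, i.e. a
multivariate-hypergeometric draw per sample) is provided for users who
want it; the depth is a required argument rather than silently defaulting
to the minimum library size.  A depth report flags samples at or below
1/10 of the median library size (the canonical failure mode being a
~2,000-read library among ~20,000-read ones); flagged samples are never
removed automatically — judging whether a shallow library is an
experimental failure is the analyst's responsibility.  The flag boundary
is inclusive so that the exact 1/10 case is caught.

No variance-stabilizing (log) transformation is offered: several
downstream steps require counts or proportions.

## Alpha-diversity

Richness counts OTUs strictly above a floor of 0.5 normalized counts;
fractional counts that small are likely artifacts of rescaling unequal
depths.  The floor applies uniformly before computing the proportions
used by Shannon `H = −Σ p ln p` (natural log, the R-ecosystem
convention) and Simpson `D = Σ p²`, so richness, H and D all describe the
same filtered community.  Effective numbers are the Hill numbers
`exp(H)` (order 1) and `1/D` (order 2, the inverse Simpson).  `1/D` is
used rather than `1/(1−D)` because it is the Hill number proper: it makes
a uniform community of S species score exactly S on all three scales and
satisfies the doubling property.  `--floor 0` disables the filter.

## Beta-diversity

Generalized UniFrac with balance parameter `a ∈ [0, 1]`:

    d⁽ᵃ⁾(A,B) = Σᵢ bᵢ (p_Ai+p_Bi)ᵃ · |p_Ai−p_Bi|/(p_Ai+p_Bi)
                ───────────────────────────────────────────────
                Σᵢ bᵢ (p_Ai+p_Bi)ᵃ

with `bᵢ` the branch length and `p_Ai` the summed proportion of sample
A's community descending from branch i.  Branches with `p_Ai+p_Bi = 0`
are skipped in both sums (the limit convention).  Default `a = 0.5`, the
balanced compromise between the rare-lineage sensitivity of the
unweighted (`a = 0`) and the dominant-lineage sensitivity of the fully
abundance-weighted (`a = 1`) ends of the family.  The implementation
accumulates branch proportions in one postorder pass; tests verify it to
1e-10 against an independent brute-force evaluation that enumerates every
branch's descendant leaf set from scratch.

PCoA is classical scaling: double-centre `−D²/2`, eigendecompose, scale
eigenvectors by the square roots of the positive eigenvalues.  Negative
eigenvalues (non-Euclidean input) are reported and their axes dropped; no
Cailliez/Lingoes correction is applied in v1.

NMDS minimizes Kruskal stress-1 by non-metric SMACOF: disparities from
isotonic regression of configuration distances on the rank order of the
dissimilarities (ties pooled/averaged by adjacent-violators), then a
Guttman-transform update; an increasing-stress step terminates the run
with the best previous configuration, so accepted stress is monotone
non-increasing.  The first start is the PCoA configuration and the
remaining `n_starts − 1` (default 19) are random; the lowest-stress start
wins, and a `converged` flag is always reported — a non-converged result
is flagged, never silent.

PERMANOVA uses Anderson's pseudo-F from the partition of the total sum of
squared distances into among/within components;
`p = (1 + #{F_perm ≥ F_obs}) / (n_perm + 1)` under uniform label
permutation, default 999 permutations (the common `adonis` convention —
the permutation count is configurable since no canonical value exists).
Perfectly separated groups give `F = ∞`, which the permutation p-value
handles naturally.  Pairwise tests run on each group pair's sub-matrix
with BH adjustment across pairs.

Ward clustering uses scipy's `linkage(…, 'ward')` on the raw
dissimilarities, which is the ward.D2 criterion (squared dissimilarities)
— the criterion-faithful variant; ward.D semantics would require
pre-squaring and is not offered.  Output is both a scipy merge table and
a Newick string (edge lengths from merge-height differences).

## Taxonomic binning

At each of six positional ranks (kingdom…genus) OTU relative abundances
are summed over identical lineage prefixes.  An OTU unknown at the target
rank but known higher up forms a bin labelled by its deepest known prefix
plus a terminal `Unknown` (e.g. `Bacteria;Firmicutes;Unknown`), so
unknowns under different roots never merge into a single "unclassified"
pool.  The exact label string is a convention of this package.  Ranks are
positional (split-lineage column index) rather than name-matched, because
classifier output formats vary; short lineages are padded with unknowns.
Binning is a partition — per-sample bin sums equal the input sums — and
is consistent under coarsening.  The stacked-bar display may merge bins
below a display cutoff into "Other"; data tables are never affected.

## Serial group comparisons

The filter cascade for relative-abundance variables, in order:

1. **Abundance cutoff** (default 0.5%): values strictly below the cutoff
   become 0.  Rationale: taxa this shallow appear and disappear
   essentially at random between technical replicates of one sample (see
   the replicate-CV analysis below).  Boundary convention: "below the
   threshold" is read literally, so a value exactly at the cutoff is kept.
2. **Zeros to missing**: non-detection is treated as censoring at the
   detection limit, not as a true zero; all downstream statistics use
   detected values only.
3. **Prevalence gate** (default 0.30): tested only if some group has the
   variable detected in strictly more than 30% of its samples — 4 of 10
   passes, 3 of 10 does not.
4. **Median gate** (default 1%): tested only if some group's median over
   detected values strictly exceeds 1% — differences like 0.25% vs 0.70%
   are too small a community fraction to interpret.

Tested variables get Kruskal–Wallis across groups (tie-corrected H,
chi-square p; the all-identical degenerate case returns H = 0, p = 1),
pairwise Mann–Whitney when more than two groups (exact two-sided p when
min(n) ≤ 8 without ties, else normal approximation with continuity and
tie correction), and an exact prevalence test on the groups ×
present/absent table: Fisher's exact test for 2 groups, exact
multivariate-hypergeometric enumeration for 2×k up to total n = 40, and
Monte-Carlo (≥ 1e5 draws, standard error reported) beyond.  The exact-test
switchover points are implementation choices recorded in the run log.

BH correction runs within each test family — KW p-values across
variables, MW p-values pooled across all variable × pair tests (the more
conservative pooling; a per-variable family would be the alternative),
Fisher p-values across variables — rather than one global pool, so each
analysis type carries one corrected value.  Raw and adjusted p are both
reported, since adjustment philosophy differs between exploratory and
confirmatory studies.

Alpha-diversity values and numeric meta-variables can ride through the
same machinery; the cascade and the zero-masking apply only to
relative-abundance variables (a measured zero in a meta-variable is a
real value).  A variable can pass both gates yet have fewer than two
groups with any detected values; it is skipped with reason `groups`,
alongside the `prevalence` and `median` reasons.

Skipping sparse variables is not cosmetic: pre-filtering reduces the
multiple-testing burden, and prevalence context guards against reading a
significant abundance shift in a 4/10-vs-12/12 detection pattern as a
general group difference — which is why the prevalence test is reported
next to the abundance tests.

## Correlations

Variables are either meta (continuous measurements) or taxonomic
(relative abundances).  Taxa pipeline: abundance cutoff → zeros to
missing → prevalence filter (default: detected in ≥ 30% of all samples;
the boundary is inclusive here, so 9 of 30 qualifies) → CLR → centre and
scale.  Meta pipeline: centre and scale only.  The CLR geometric mean is
computed over each sample's detected taxa re-closed to sum 1 — mirroring
the zero-as-missing philosophy rather than imputing a pseudocount — so
CLR rows sum to zero over detected entries; `pseudocount` restores the
conventional all-taxa transform.  Note the prevalence boundary differs
from the strict ">30%" of the group-comparison gate; both conventions are
deliberate and documented here.

Pearson r is computed on pairwise-complete observations with a two-sided
t-test p (`t = r √((n−2)/(1−r²))`, n−2 df; |r| = 1 ⇒ p = 0); below 3
complete pairs the p-value is withheld (t undefined), below 2 the
correlation itself.  A permutation p-value would be the alternative; the
t-distribution was chosen as the standard default.  BH correction runs
across all pairs computed in the invocation.  Every record carries
`n_obs`, because zero-masking makes support vary wildly between pairs.

Why CLR: proportions are compositional — an independent change in one
member moves every other member's relative abundance, producing spurious
correlations.  The test suite demonstrates this: with one taxon's
absolute abundance varying and all others held constant, raw-proportion
correlations between the varying taxon and the constant ones average
r ≈ −0.7 (pure closure artifact; the constant taxa also correlate
spuriously with each other through the shared denominator), while CLR
correlations for the same pairs are centred on zero (mean |r| < 0.1 at
n = 100 samples).

## Synthetic data generator

`simulate_dataset` emulates a grouped host-associated 16S study:

- **Tree**: pure-birth (Yule) process, branch lengths scaled to
  root-to-tip depth 1.  A death rate adds nothing the pipeline consumes
  (extinct lineages would be pruned), so the birth-death model is run at
  death rate 0.
- **Taxonomy**: derived by cutting the tree at fixed height fractions
  (0.15/0.35/0.55/0.70/0.85 for phylum…genus), so taxonomy and phylogeny
  agree by construction, as they approximately do in real data.
- **Base composition**: log-normal OTU weights (sd 1.5 on the log scale)
  normalized to proportions — a heavy-tailed abundance distribution with
  a few dominant and many rare OTUs, as in real gut profiles.  An explicit
  base composition can be supplied instead.
- **Counts**: per sample, composition ~ Dirichlet(concentration × group
  mean) with default concentration 50 (clear between-subject variation),
  group means obtained by applying fold-changes to designated effect OTUs
  and re-closing; depth ~ negative binomial (mean 20,000, size 20,
  matching MiSeq-era library sizes with moderate spread); counts ~
  multinomial.

`simulate_replicates` emulates repeated library construction from one
DNA extract: one shared composition, optional Dirichlet-multinomial
overdispersion (`noise`; composition redrawn from Dirichlet(comp/noise)),
multinomial sampling at negative-binomial depth.  `replicate_cv` computes
per-OTU mean relative abundance and CV = sd/mean·100 across replicates
and assigns the <0.1% / 0.1–0.5% / ≥0.5% abundance bands used to justify
the 0.5% near-zero cutoff: under multinomial sampling the CV of a
proportion p at depth N scales as √((1−p)/(Np)), so rare OTUs are
intrinsically irreproducible between replicates.  The acceptance test
asserting the published banded CV values of the real 10-library
faecal-sample series requires that external replicate OTU table (not
redistributable here, and the test environment is offline); it fails with
an explanatory message unless the table is placed at
`tests/data/replicate_otu_table.tab`.  The banding machinery itself is
fully covered by synthetic-replicate tests.

What the generator does **not** emulate: chimeras and spurious OTUs,
taxon-specific PCR/primer bias, true zero inflation beyond
Dirichlet-multinomial sparsity, phylogenetically correlated effect sizes,
and batch structure across sequencing runs.  Passing tests therefore
demonstrate correctness of the statistical machinery under a standard
overdispersed count model, not robustness to every artifact of real
amplicon data.

## Numerical conventions and problem sizes

- Exact Mann–Whitney below min(n) ≤ 8 without ties; exact 2×k prevalence
  enumeration up to n = 40; Monte-Carlo beyond with reported SE.
- Two-sidedness of the exact prevalence tests is by summation of all
  table probabilities ≤ the observed one, with a 1e-7 relative guard
  against floating-point equality at the boundary (the R convention).
- BH adjustment passes missing p-values through and excludes them from m.
- One master seed per invocation; per-test streams are derived from it
  and logged.  NMDS and rarefaction are bit-reproducible under a fixed
  seed.
- Calibration checks use 500 null PERMANOVA datasets (2×10 samples, 199
  permutations), 150–300 × 200 null Kruskal–Wallis variables, 50 random
  gUniFrac fixtures of ≤ 20 leaves, and 20 planted-effect replicates —
  sizes at which the Monte-Carlo error bands in the tests are decisive
  while the whole suite stays fast on a laptop.

## Known limitations

- No BIOM or Excel I/O; the tab-separated dialect only.
- No Bray–Curtis acceptance coverage (offered as a convenience through
  the distance layer only), no unweighted-UniFrac output, no
  Cailliez/Lingoes correction, no count-model (negative-binomial)
  differential abundance, no network inference or partial correlations.
- PERMANOVA assumes exchangeability under the null; no strata/blocking.
- The Fisher prevalence test for > 2 groups tests the overall 2×k table;
  pairwise 2×2 breakdowns are available but not run by default.
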