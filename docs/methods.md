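# Methods

This note records the models, parameter choices and numerical decisions
behind `swabdiv`, and what the synthetic-data validation does and does
not demonstrate.

## Read filtering

Reads are Phred+33 FASTQ. The mean Q-score of a read is computed in
error-probability space — convert each per-base Phred score to an error
probability, average, convert back — which is the value nanopore
basecallers report as a read's "mean Q" and is always at or below the
arithmetic mean of the Q values (Jensen's inequality); the arithmetic
mean is available as an option. Defaults are mean Q ≥ 12 and length in
[115, 315] bases, both bounds inclusive, bracketing the ~215 bp 16S
amplicon. Length is checked before quality, so a rejected read carries a
single reason (`too_short` / `too_long` / `quality`). Filtering is a
partition (kept + rejected = input) and idempotent.

## Clustering and consensus

Pairwise identity is matches over alignment columns (gaps count as
columns) of the optimal global alignment with match +1, mismatch −1,
gap −2, no free end gaps (Bio.Align.PairwiseAligner). Arguments are
put in canonical order before aligning so that co-optimal alignments are
resolved identically and identity is exactly symmetric. A unit-cost edit
distance (edlib) provides a sound upper bound `1 − d/(len a + len b)`
used only to skip hopeless comparisons.

The sorting stage is a transparent greedy algorithm: shuffle reads with
the run seed, process in batches of 1000; each read joins the
best-matching existing cluster whose *seed* (first member) it matches at
≥ 97% identity, else founds a new cluster. Consensus sequences are a
column-wise majority over members globally aligned to the cluster
*medoid* (the member minimising summed alignment distance; brute force
up to 200 members, seeded sampling beyond). Gap-plurality columns are
deleted; base ties break lexicographically A<C<G<T; insertions relative
to the medoid are kept when more than half the members carry the same
inserted segment, so an indel error in the medoid itself is outvoted.
Clusters whose consensi match at ≥ 98% are merged by single linkage
(merging is transitive, so the no-pair-above-threshold guarantee applies
to the pre-rebuild consensi only), and consensi are rebuilt from all
members.

Because the greedy pass compares reads to seed *reads*, which carry
their own sequencing errors, reads in the error tail can fall outside
the 97% radius of their true cluster. `cluster_reads` therefore
alternates merging with a rescue pass that re-compares singleton
clusters against the denoised consensi of multi-member clusters and
absorbs them where they meet 97%, iterating (at most five rounds) until
the partition stabilises. Reads too error-laden even for the rescue
remain as singleton or pair clusters — the counterpart of the reads the
original sorting tool leaves unassigned — and can be dropped at export
with the `min_cluster_size` filter (default 1, i.e. keep everything).
At ~2% per-read error, majority-vote denoising needs on the order of
tens of reads per taxon; the validation suite uses 12–40 reads per
taxon, far below the ~10³ reads per cluster of a real run, and still
recovers every template exactly.

## Taxonomic assignment

Hits arrive as BLAST outfmt-6 (12 columns, or 13 with `qcovs`; without
`qcovs` the query coverage is computed from qstart/qend and supplied
query lengths). Coverage means *query* coverage — the fraction of the
consensus aligned — the conventional criterion for amplicon queries.
Filtering: e ≤ 1e−3, identity ≥ 80%, coverage ≥ 80%, then the top 20 by
bitscore with ties at the cutoff all retained.

Assignment per query: take the hits tied at maximal bitscore, form the
lowest common ancestor (longest common rank-prefix) of their lineages,
and truncate it by the identity thresholds — species kept only at
≥ 98%, genus at ≥ 96%, family at ≥ 90% — where the identity compared is
the maximum among the tied-top hits. Ranks above family are retained
whenever the 80% search floor was met, which is how order-level
detections arise. This makes the assigned rank monotone in identity for
a fixed hit set.

Lineages are six ranks (phylum…species) with the prefix invariant (an
absent rank forces all finer ranks absent), parsed from MIDORI2-style
headers (`id###root_1;…;Genus species_taxid` or whitespace-separated)
or a two-column TSV. Hexapod filtering keeps any lineage containing a
hexapod label (Insecta, Collembola, Entognatha, …— springtails are
retained as hexapods); lineages with no resolved ranks are excluded as
too general, resolved non-hexapods (human, deer) as non-target.
Queries with identical assigned lineages collapse to one taxon whose
read counts are summed per sample.

`naive_search` — an exhaustive global-alignment search in which percent
identity doubles as the score — stands in for an external similarity
search on toy references, so the assignment logic can be exercised end
to end with exact ground truth. It is quadratic and meant for tens of
reference sequences, not a production search.

## Diversity statistics

*Rarefaction.* Sample-based, exact:
`E[S(t)] = Σ_i [1 − C(T−Y_i, t)/C(T, t)]` over incidence frequencies
`Y_i` in `T` sampling units, evaluated with log-gamma for stability.
This equals the average richness over all C(T, t) subsets, which the
tests verify by exhaustive enumeration for every T ≤ 6.

*Accumulation models.* Three classical parameterisations fitted to the
curve points (t, E[S(t)]) by nonlinear least squares:
asymptotic regression `S = Asym + (R0 − Asym)·exp(−exp(lrc)·t)`,
Lomolino `S = Asym / (1 + slope^log(xmid/t))` (slope bounded > 1 to keep
the power real), logistic `S = Asym / (1 + exp((xmid − t)/scal))`.
Self-starts: Asym at 1.05 × max(S), R0 at S(1), lrc = 0, xmid at the
median t, slope/scale from a crude two-point slope. AIC uses the
Gaussian-likelihood convention `n·ln(2π·RSS/n) + n + 2(p+1)`, so AIC
differences between models on the same points are constant-free;
selection takes the lowest AIC among converged fits, ties broken by
fewer parameters then model name. Non-convergence returns a flagged fit
rather than raising. Note that on the packaged incidence curves the
bounded Lomolino fit converges with a lower AIC than the asymptotic
model (R's self-starting Lomolino fails on the same points, which is
why published analyses of such short curves usually end up with the
asymptotic model); the per-habitat report carries all three fits, and
the headline asymptotes are those of the asymptotic model.

*Hill numbers.* `(Σ p_i^q)^(1/(1−q))` with the continuous limit
`exp(−Σ p_i ln p_i)` at q = 1; zero counts dropped. q1 ≤ q0 with
equality iff all nonzero counts are equal. Evenness is summarised per
sample (q1 of the read counts within a sample), then compared across
habitats.

*β-diversity.* Presence/absence Jaccard dissimilarity partitioned into
turnover and nestedness: with a shared, b and c site-unique taxa,
`β_jac = (b+c)/(a+b+c)`, `β_jtu = 2·min(b,c)/(a+2·min(b,c))`,
`β_jnes = β_jac − β_jtu`. The identity β_jac = β_jtu + β_jnes holds
exactly; both matrices (jac and jtu) feed PERMANOVA and PCoA.

*PERMANOVA.* The total sum of squared distances is `tr(G)` of the
Gower-centered inner-product matrix `G = J(−½D²)J`. Terms are
partitioned sequentially (type-I) in the order habitat, replicate,
time-of-day via pseudo-inverse hat matrices on cumulative dummy-coded
designs; term df is the rank increment. Pseudo-F per term is
(SS/df)/(SS_res/df_res); p-values come from free row permutations of G
(no strata) with the add-one convention `p = (1+#{F* ≥ F})/(1+n_perm)`,
default 999 permutations, explicit seed. R² values plus the residual
sum to 1 by construction. The single-factor statistic matches
scikit-bio's PERMANOVA to machine precision (checked in the tests).

*PCoA.* Eigendecomposition of the same centered matrix; axes are
eigenvectors scaled by the square root of their positive eigenvalues,
sorted descending. Negative eigenvalues — expected for non-Euclidean
dissimilarities like the turnover component — are reported and their
axes dropped; proportions explained are relative to the positive
eigenvalue sum. On Euclidean inputs the embedding reproduces all
pairwise distances to 1e−9.

*Power.* For a balanced one-way ANOVA with k groups of n, the F
statistic under the alternative is noncentral F with df (k−1, k(n−1))
and noncentrality λ = k·n·f² (Cohen's f). `anova_power_n` returns the
smallest integer n with power ≥ the target — the defensible
"required sample size". `anova_power_n_continuous` root-finds the
fractional n at which power equals the target exactly, evaluating the
error df at non-integer n; this is the number R-style solvers print,
and published sample sizes are typically a rounding of it. For k = 3,
f = 0.75, α = 0.05, power 0.8 the continuous requirement is 6.81: its
integer part is 6 (the group size this survey design used and
reported), while the smallest n whose power actually reaches 0.8 is 7
(power 0.813). Both are exposed and both facts are asserted in the
tests.

## Synthetic data

`make_reference` grows a lineage tree by seeded mutation: family
ancestors at ~15% substitutions from an order root, genus ancestors at
~4% from their family, species at ~0.5% from their genus, then verifies
with true global alignments that within-genus identity is ≥ 98% and
between-family identity ≤ 90%, rejection-sampling the whole tree until
the bands hold. This guarantees data that exercise all three rank
thresholds. Optional mammal records exercise the non-target exclusion.

`simulate_reads` draws reads per (sample, taxon) with independent
per-base substitution/insertion/deletion rates (defaults 1%/0.5%/0.5%,
~2% total — representative of quality-filtered nanopore amplicons). A
configurable fraction of reads (default 10%) gets per-base qualities
with an error-domain mean below Q12, the rest safely above, so the
intake filter's behaviour is testable read-by-read. Ground truth
records every read's source taxon and sample.

`simulate_community_matrix` emulates the survey design: three habitats
with 6/6/5 samples, replicates 1–3 at two locations per habitat,
per-sample richness Poisson around habitat means (defaults 14/8/7,
the observed per-sample richness gradient), habitat taxon pools of
sizes 48/32/21 from a 76-taxon universe with a `pool_overlap` fraction
drawn from a shared core (default 0.15, giving the high between-habitat
turnover seen in such surveys; when the exclusive demand exceeds the
universe, pools reuse taxa and overlap rises accordingly), and
lognormal read counts. Everything is bit-reproducible given
(spec, seed).

What the synthetic validation does **not** show: real nanopore error is
not i.i.d. per base (homopolymer indels dominate), references are
incomplete and unevenly curated, PCR introduces chimeras and abundance
distortion, and real communities are not Poisson-richness mixtures of
clean pools. Passing these tests demonstrates the correctness of the
algorithms under their stated models, not field-level accuracy.

## The packaged incidence table

`swabdiv/data/table2_hexapoda.tsv` is the published taxon × habitat
table: 76 hexapod taxa, incidence frequencies (`nb_*`: number of samples
in the habitat where the taxon occurred, the only reading consistent
with sample-based rarefaction) and summed read counts per habitat, with
an explicit `rank` column (binomial → species, bare capitalised name →
genus, family/order names → their rank) so rank bookkeeping does not
depend on typography. T = 6/6/5 samples per habitat (one forest sample
was lost in the field). The loader verifies a SHA-256 checksum. The
grassland asymptote is reported in the source once as 69.3 and once as
68.3; the recomputation from the table gives 68.3, and the acceptance
suite checks only membership in [68.3, 69.3] for grassland.

## Problem sizes and budgets

Default test and acceptance runs use small problem sizes chosen for
desk-scale iteration: tens of reads per synthetic taxon, toy references
of 8–17 records, 17-sample community matrices, 199–999 permutations.
All published-value recomputations (rarefaction, model fits, power,
bookkeeping) are deterministic and complete in seconds.

## Known limitations

- The greedy clusterer is order-dependent by design (made reproducible
  by the seed); it is a transparent stand-in for the original sorting
  tool, whose internals are not described.
- No chimera detection, no signal-level polishing, no per-base error
  model beyond the majority vote.
- PERMANOVA permutes rows freely; no restricted/strata permutation.
- The naive search is an oracle for tests, not a substitute for a real
  similarity search at reference-database scale.
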