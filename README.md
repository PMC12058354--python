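# swabdiv

Insect biodiversity from vegetation-swab eDNA, sequenced as nanopore
amplicons of a ~215 bp mitochondrial 16S marker. The package covers the
full desk-side analysis for this kind of survey:

1. **Read intake** — Phred+33 FASTQ in, mean-Q ≥ 12 (error-domain
   average) and length-window [115, 315] filters.
2. **Amplicon sorting** — greedy seeded clustering of reads at 97%
   global identity (match +1, mismatch −1, gap −2), majority-vote
   consensus per cluster, single-linkage merging of clusters whose
   consensi match at 98%, and a rescue pass for stray high-error reads.
3. **Taxonomic assignment** — BLAST outfmt-6 hits filtered at e ≤ 1e−3,
   identity and query coverage ≥ 80%, top 20 by bitscore (ties kept);
   the lowest common ancestor of the tied-top-bitscore hits, truncated
   by rank thresholds (species ≥ 98%, genus ≥ 96%, family ≥ 90%
   identity); non-hexapod lineages excluded (Collembola retained).
4. **Diversity statistics** — exact sample-based rarefaction
   E[S(t)] = Σᵢ [1 − C(T−Yᵢ, t)/C(T, t)], asymptotic/Lomolino/logistic
   accumulation models selected by AIC, Hill numbers (q0 richness, q1 =
   exp of Shannon entropy as evenness), the Jaccard β-diversity
   partition β_jac = β_jtu + β_jnes, PERMANOVA with sequential sums of
   squares, PCoA by Gower double-centering, and noncentral-F power for
   a balanced one-way ANOVA.
5. **Synthetic data** — lineage-annotated references, nanopore-like
   reads from known communities, and habitat-structured site×taxon
   matrices, all seeded and bit-reproducible, for end-to-end validation
   with ground truth.

A published taxon × habitat incidence table (76 hexapod taxa over 6
grassland, 6 shrub and 5 forest samples) ships as a checksummed fixture
(`swabdiv.synthdata.load_table2_fixture`).

Intended users: molecular ecologists running eDNA metabarcoding surveys
who want a transparent, fully parameterised re-implementation of this
pipeline rather than a chain of opaque binaries.

## Worked example

The packaged incidence table, summarised from the shell:

```
$ swabdiv fixture
76 taxa; ranks: {'species': 35, 'family': 22, 'genus': 10, 'order': 9}
  grassland: T=6, richness=48
  shrubs: T=6, richness=32
  forest: T=5, richness=22
```

Rarefaction plus the asymptotic accumulation model per habitat:

```python
import numpy as np
from swabdiv import ecodiv, synthdata

fx = synthdata.load_table2_fixture()
for h in ("grassland", "shrubs", "forest"):
    T = fx.n_samples(h)
    curve = ecodiv.rarefaction_curve(fx.incidence(h), T)
    fit = ecodiv.fit_accumulation(np.arange(1, T + 1), curve, "asymptotic")
    print(f"{h:9s} T={T} observed={curve[-1]:.0f} asymptote={fit.asymptote:.1f}")
```

```
grassland T=6 observed=48 asymptote=68.3
shrubs    T=6 observed=32 asymptote=50.6
forest    T=5 observed=22 asymptote=35.7
```

Grassland vegetation hosts the richest insect assemblage: 48 taxa were
observed in six samples and the fitted asymptote predicts ~68 with
exhaustive sampling, against ~51 for shrubs and ~36 for forest canopy.

The sample-size calculation behind a three-habitat design (Cohen f =
0.75, α = 0.05, power 0.8):

```
$ swabdiv power -k 3 -f 0.75
n = 7 per group (power = 0.8134)
```

`ecodiv.anova_power_n_continuous(3, 0.75)` returns the fractional
requirement 6.81 that R-style solvers print; `anova_power_n` is the
smallest integer group size whose power actually reaches the target.

An end-to-end run on synthetic reads (`swabdiv simulate`, then
`swabdiv run --config run.cfg`) writes filtered FASTQ, consensus FASTA,
membership and community-matrix TSVs, and a JSON report with per-stage
counts and all diversity results.

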