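# Methods

## Statistical model

All screen read-outs reduce to counts of *unique* gene-trap insertions — a
distinct (chromosome, position, cassette orientation) triple within one
library — classified per gene as sense (cassette strand equals gene strand,
disruptive) or antisense (neutral). Uniqueness keeps the count a proxy for
independent mutagenised clones rather than sequencing depth; two
opposite-orientation insertions at the same base are distinct events because
orientation is the phenotype-relevant variable. Positions are collapsed at
exact-base resolution; near-duplicate positions from alignment jitter are
not merged.

### Exact tests

Both exact tests use the point-probability definition of the two-sided
p-value: the sum of null probabilities of all outcomes whose point
probability does not exceed the observed one. Point probabilities are
compared with a relative tolerance of 1e-7 so that outcomes tied with the
observed one up to floating-point rounding enter the tail sum; this matters
only on knife-edge tables (e.g. exactly symmetric configurations).
Log-pmfs are computed directly from log-gamma functions and agree with
exact rational enumeration to < 1e-10 over all 2×2 tables with total ≤ 40
and sampled binomial cases up to n = 500 (verified in the test suite by an
integer/Fraction oracle that shares no code with the implementation).

* FACS enrichment: Fisher exact test on
  `[[c_high, T_high − c_high], [c_low, T_low − c_low]]` of sense counts —
  the gene against the rest of its population. Antisense insertions are
  excluded because the enrichment signal rides on disruptive integrations
  and the normalisation is to total sense insertions.
* Fitness: exact binomial test of the gene's sense count against
  n = sense + antisense at null fraction p₀.
* Synthetic lethality: Fisher exact test on
  `[[sense_query, antisense_query], [sense_ctrl, antisense_ctrl]]` with the
  sample cross-product odds ratio as effect size.

Benjamini–Hochberg adjustment (statsmodels `fdr_bh`) is applied across genes
within one screen (FACS) or within one replicate (fitness). The
query-vs-control Fisher p in synthetic-lethality calling is used raw — the
multiplicity control there lives in the within-genotype consensus step.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.05 | threshold on adjusted p; FACS uses q ≤ α, fitness consensus uses q < α |
| `pseudocount` | 1 | added to gene counts for the MI display only; inference uses raw counts |
| `min_combined` | 1 | minimum combined (high+low) insertions before a FACS gene may be classified |
| `p0` | 0.5 | null sense fraction of the binomial test; optionally estimated as the library-wide sense fraction to absorb cassette bias |
| `p_thresh`, `or_thresh` | 0.05, 0.8 | synthetic-lethality hit thresholds on raw Fisher p and odds ratio |
| overlap `policy` | `exclude_all` | see below |

Boundary conventions follow the screen literature's stated rules: FACS
significance uses q ≤ α, the fitness consensus uses the strict q < α. Both
are configurable; the choice only matters for genes sitting exactly on the
threshold.

## Region index and overlap policy

Gene bodies are the union of transcript spans, introns included, because
gene-trap integrations are predominantly intronic (an exon-only reader mode
exists). Coordinates are 0-based half-open everywhere; refFlat input is
converted on read.

Unambiguous assignment requires non-overlapping regions. Under the default
`exclude_all` policy every base covered by two or more genes — whatever
their strands — is excluded from all of them, so each indexed base maps to
exactly one gene; a nested gene disappears entirely and the outer gene keeps
its flanks. The alternative `same_strand` policy computes the exclusion per
strand: genes overlapping only an opposite-strand neighbour keep their
shared bases, a strand-hinted lookup can resolve them, and a strand-less
lookup treats doubly-covered bases as unassigned. Whether the original
screens' exclusion was strand-aware is not documented; `exclude_all` is the
default because full exclusion is the only policy under which assignment
needs no extra information. Lookups use binary search over per-(chromosome,
strand) sorted arrays, which vectorises bulk assignment.

## Replicate consensus

Fitness replicates are independent clonal lines, so evidence is combined
conservatively: FDR correction within each replicate first, then the *least
significant* adjusted p across replicates is the gene's consensus value, and
all replicates must deviate on the same side of p₀. A gene absent from any
replicate cannot be significant. This "weakest replicate decides" rule
trades sensitivity for robustness against clone-specific artefacts.

Control handling in synthetic-lethality calling defaults to pooling the
control datasets into one table before the Fisher test (maximum power); a
`per_control` mode instead requires the p/odds-ratio criteria to hold
against every control separately, reporting the least significant p and the
odds ratio closest to 1. Neither mode is asserted to be the original
pipelines' behaviour; pooling is this package's documented default.

## Synthetic-data generator

The generator emulates the structure the analyses assume: per-gene unique
insertion counts proportional to gene length, ~50% sense orientation under
the null, population-specific totals, and configurable per-gene effects.

* One synthetic chromosome; gene lengths log-normal (default median 20 kb,
  σ_log = 0.75 — roughly the shape of human protein-coding gene bodies),
  2,000 genes, half the genome intergenic.
* `library_size` (default 2×10⁵) is the expected number of unique insertions
  per output sample. For FACS screens, each simulated cell carries one
  insertion and the two retained bins are 5% tails, so
  `library_size / 0.05` cells are drawn; a cell whose insertion is
  disruptive (sense, in-gene) in a regulator gene with sort bias b keeps the
  baseline total retention probability but splits high:low with odds b, so
  the mutational index estimates b.
* Fitness screens thin each sense insertion in an (active) fitness gene to
  survival probability `sense_survival`; `conditional_fitness` effects
  activate only when the simulated genotype matches, which is the
  synthetic-lethal configuration.
* Sub-streams derive as `default_rng([seed, stage, replicate, crc32(genotype)])`,
  making every output byte-identical for a given config and seed.

What the generator does **not** model: insertion hotspots and chromatin
accessibility bias, multi-insertion clones, growth dynamics during
passaging, read-level sequencing error, and alignment ambiguity. Passing
calibration and recovery tests therefore demonstrates the statistical
machinery is correct and well-calibrated under the assumed sampling model,
not that real screens are free of those biases.

## Calibration and recovery experiments

The benchmark experiments (also rerun by `scripts/acceptance.py`) use
2,000 genes and 2×10⁵ insertions per sample — a deliberate desk-scale
stand-in for real screens (~19,000 genes, 10⁷–10⁸ cells) that keeps every
gene's expected insertion count in a realistic range (tens per sample):

* Null calibration: 20 independent effect-free screens per pipeline; the
  mean fraction of significant genes at α = 0.05 stays well below 0.05
  (BH plus the consensus rule are conservative under the global null).
* Regulator recovery: 20 negative (sort bias 8) and 20 positive (bias 1/8)
  spikes placed in genes ≥ 20 kb so each expects ≥ 30 disruptive insertions
  across the bins; sensitivity ≥ 0.9 with no direction errors.
* Synthetic-lethal recovery: 20 spikes with sense survival 0.1 in the query
  genotype and 1.0 in four wild-type controls, placed in genes ≥ 50 kb so
  each expects ≥ 50 insertions per replicate; sensitivity ≥ 0.9, neutral
  hit rate ≤ 0.05.

## Numerical and degenerate-input choices

* MI requires positive sense totals in both populations; an empty population
  is an error, not a silent zero.
* Genes with zero insertions in a replicate are excluded from that
  replicate's orientation test (sense ratio undefined at n = 0) and genes
  with zero combined insertions are dropped from fishtail tables (log
  domain).
* Odds ratios with a zero denominator are reported as `inf` (`nan` when the
  numerator is also zero); such genes can never satisfy the OR < 0.8 hit
  criterion.
* Rank tables break Δ-sense-ratio ties by ascending Fisher p, then gene id,
  so output order is fully deterministic.
* TSV outputs serialise floats with 10 significant digits and carry a
  commented column-definition header.

## Known limitations

The orientation-only fitness model ignores where within a gene a sense
insertion lands (a 3'-terminal sense insertion may not be disruptive), the
FACS model assumes one insertion per cell, and the comparative mock filter
is a hard set-difference rather than an interaction test. The GTF/GFF3
format, BAM input and alignment itself are out of scope; the pipeline
consumes pre-mapped insertion coordinates.
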