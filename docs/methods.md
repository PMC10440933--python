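# Methods

## Scope and data model

`rohscan` analyses autosomal biallelic diploid genotypes. The in-memory
container is a samples × variants matrix of calls coded 0 (hom-ref),
1 (het), 2 (hom-alt), −1 (missing), with variant metadata
(chromosome, 1-based position, REF/ALT) in a DataFrame. Input is
VCFv4.2 (read with cyvcf2); multi-allelic records are skipped and
counted, half calls and non-diploid genotypes become missing. Sample →
species assignments come from a two-column TSV, chromosome lengths from
a FASTA-index-style TSV, gene annotation from BED (0-based half-open)
or GFF3 (1-based inclusive), both normalised internally to 1-based
inclusive coordinates.

## Quality control

Stage order: per-sample call-rate filter, then relatedness filter, then
a branch split. The ROH branch deliberately uses the unpruned variant
set (MAF or LD filtering would delete the very homozygous stretches the
caller looks for); the structure branch applies the MAF filter and LD
pruning before distances are computed.

* **Call rate** — a sample is retained iff its fraction of non-missing
  calls is ≥ `min_call_rate` (default 0.99; the boundary is inclusive
  on the retained side).
* **MAF** — minor allele frequency is computed from non-missing calls
  pooled over all samples; variants with MAF < `min_maf` (default 0.05)
  are removed, variants at exactly the threshold retained. Variants
  with every call missing are removed and counted separately.
* **LD pruning** — PLINK `--indep-pairwise` semantics with defaults
  window = 1500 variants, step = 150, r² = 0.1. Within each window,
  scanning left to right over surviving variants, any pair with squared
  Pearson correlation of allele dosages (pairwise-complete over
  samples) strictly above the threshold loses its later member. The
  window unit is a variant count, matching PLINK's unsuffixed syntax.
* **Relatedness** — PI-HAT = P(IBD=2) + ½·P(IBD=1) by the classical
  method of moments: per pair, IBS 0/1/2 counts over jointly observed
  variants are equated to their expectations under each IBD state given
  the cohort allele frequencies; the solved state probabilities are
  clamped to [0,1] and renormalised (no small-sample bias correction —
  with structured cohorts the estimate is conservative/inflated, which
  is the safe direction for a removal filter). Pairs sharing < 50
  variants are flagged unreliable. Pairs at PI-HAT ≥ 0.5 are broken by
  removing the lower-call-rate member (ties: the lexicographically
  larger ID), iterating worst-first until no pair exceeds the bound —
  so a triangle of duplicates loses exactly two members.

## ROH detection

The caller follows PLINK `--homozyg` semantics. Parameters, with
defaults:

| parameter | default | unit | meaning |
|---|---|---|---|
| `min_kb` | 100 | kb | minimum segment length |
| `min_snp` | 15 | variants | minimum variants per segment |
| `max_gap_kb` | 500 | kb | split runs at larger inter-variant gaps |
| `window_snp` | 50 | variants | scanning window span |
| `window_het` | 3 | calls | max heterozygous calls per homozygous window |
| `window_missing` | 1 | calls | max missing calls per homozygous window |
| `window_threshold` | 0.05 | fraction | min fraction of covering windows that are homozygous |
| `density_kb_per_snp` | 50 | kb/variant | max average spacing within a segment |

The five explicitly set values (100 kb, 15 variants, 500 kb gap, 3
hets, 1 missing) are a consensus parameterisation for medium-density
livestock/pet panels; the remaining three stay at PLINK defaults.
Chromosomes with fewer than `window_snp` variants are scanned with a
single all-variants window. Segment coordinates are the first/last
variant positions of the trimmed run, 1-based inclusive, and
`length_kb = (end − start + 1)/1000`; `n_variants` counts the
non-missing calls spanned. Leading/trailing heterozygous or missing
calls are trimmed before the length/count/density tests; interior
missing calls never break a run (the window limits already police
them). Cohort tables stratify segments into a [100, 500] kb class
(closed at both ends — a segment of exactly 500 kb is "short") and a
\> 500 kb class.

The caller is verified against a brute-force implementation that
enumerates every window and candidate run directly; the two agree
exactly on hundreds of randomised instances mixing planted tracts,
heterozygous miscalls, missing calls and large gaps.

## Inbreeding and species comparison

F_ROH = L_ROH / L_aut per individual, from the `min_kb` = 100 run.
L_aut is the sum of the chromosome lengths in the provided TSV
(overridable via `--autosome-length`). Species summaries report N and
mean/sd/min/max (sample sd, n−1; single-sample species report sd = 0
with a flag) of segment count, total kb, F_ROH and mean segment size
(the per-sample ratio total kb / count; zero-segment samples are
excluded from that one statistic). One-way ANOVA (closed-form F with
scipy's F distribution for the p-value, cross-checked against
`scipy.stats.f_oneway` and the pooled-t identity F = t² in tests)
compares segment count, mean segment length and F_ROH across species.
Degenerate inputs are handled explicitly: identical constant groups
give F = 0, p = 1; zero within-group variance with unequal means gives
F = ∞, p = 0.

## ROH islands

Per species, an event sweep (+1 at each segment start, −1 at end+1,
after merging each sample's segments so a sample contributes at most 1
anywhere) yields the carrier count as a step function. An island is a
maximal interval where the count reaches ceil(threshold × N), with
threshold 0.70 by default; its reported carrier count is the minimum
over the interval and the displayed percentage is round-half-up of
100·n/N — which reproduces the familiar printed values (5/7 → 71,
6/7 → 86, 5/6 → 83, 13/18 → 72, 16/18 → 89) and correctly excludes 4/6
(67%). We considered splitting islands at every carrier-count change
instead; the single-interval definition was adopted because the
carrier minimum is the quantity the sharing threshold is about, and
count fluctuations above the threshold do not change which region is
shared. Island coordinates are sweep breakpoints, i.e. variant
positions. Variant content is counted inclusively; genes are attached
on ≥ 1 bp overlap, and islands without overlap print `---`.

## The simulator

The generator emulates the ingredients the pipeline must cope with,
with defaults chosen as a desk-scale version of a four-species
comparative study:

* **Divergence** — ancestral ALT frequencies uniform on [0.05, 0.95];
  population frequencies Beta(p(1−F)/F, (1−p)(1−F)/F) around ancestral
  p (Balding–Nichols), F = 0.2 by default (strong, species-level
  differentiation; F = 0 short-circuits to the ancestral values, F = 1
  is rejected). Four populations × 8 diploids, two 25-Mb chromosomes ×
  5,000 variants (mean spacing 5 kb), positions uniform, sorted,
  deduplicated so density varies and the caller's gap/density rules are
  exercised.
* **Autozygosity** — planted shared tracts (population, carrier
  fraction, interval) and/or per-individual random tracts (count and
  length range configurable). Inside a tract both haplotypes copy one
  population haplotype, so calls are homozygous except for heterozygous
  miscalls at `het_error_rate` (default 0.005). Truth intervals are
  merged per sample and recorded.
* **Noise** — uniform missingness at 0.2%. This sits well inside the
  1% per-sample budget of the default call-rate filter, as in a real
  cohort of passing samples; a uniform 1% rate would put every sample
  exactly at the filter boundary, which emulates a borderline batch,
  not a QC'd study.
* **Admixture** — hybrid individuals draw each variant's population of
  origin independently with the stated weights (default 50/50 between
  two source populations). This is simpler than tract-based admixture
  and sufficient to place hybrids between their sources in MDS space.
* **Determinism** — one integer seed fixes everything; fixture sets
  (VCF, sample map, chromosome lengths, per-sample truth BEDs, gene
  BED with one named gene inside each planted shared tract) are
  byte-reproducible.

What the simulator does **not** model: recombination maps and
coalescent linkage structure (variants are exchangeable given
frequencies, so LD pruning removes little by construction),
mutation-rate heterogeneity, genotype-likelihood-level error, sex
chromosomes (ploidy is fixed at 2; X is out of scope), and realistic
site-frequency spectra (no rare-variant excess). Passing tests
therefore demonstrate that the algorithms implement their definitions
and recover planted signal under controlled noise — not that any
particular biological cohort would yield particular values.

## Numerical and scoring choices

* Beta draws are clipped to (10⁻⁶, 1 − 10⁻⁶) to keep Hardy–Weinberg
  draws polymorphic.
* r² with pairwise-complete observations; pairs with < 2 joint samples
  or a zero-variance member score 0.
* Percentage display rounds half up (floor(x + 0.5)), not banker's
  rounding.
* MDS axes are ordered by descending eigenvalue; negative eigenvalues
  are reported but never used for scaling, and each axis's first
  nonzero loading is made positive so output is deterministic.
* Recovery scoring merges planted tracts whose gap contains at most
  `window_het` (3) variants before matching: the window scan tolerates
  that many heterozygous calls per window, so such tracts are provably
  indistinguishable from one ROH at marker resolution.
* Resolution limit: with a 50-variant window at 5 kb spacing, segment
  boundaries can overshoot a true tract end by up to roughly a window
  span (the 5% window-hit threshold keeps flanking variants eligible),
  and tracts spanning fewer variants than one window can be missed
  entirely. At the default simulation density this bounds per-sample
  F_ROH accuracy at roughly ±0.01; the mean absolute error is about
  half that. At real WGS densities (variant spacing ≪ 1 kb) the same
  overshoot is negligible.

## Known limitations

* PLINK 1.9 internals are not replicated bit-exactly; equivalence is
  asserted against this package's own brute-force oracle.
* The PI-HAT estimator omits PLINK's finite-sample bias corrections
  and, on strongly structured cohorts, reflects relatedness relative to
  the pooled frequency spectrum.
* Islands are defined by the carrier-count sweep; consensus-region
  definitions from segment pooling (PLINK `--homozyg-group`) can place
  boundaries slightly differently.
* ANOVA assumes exchangeable individuals within species; with a
  handful of genomes per species it is a descriptive screen, not a
  calibrated test.
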