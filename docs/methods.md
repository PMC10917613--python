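# Methods

## The problem being measured

Host-DNA depletion protocols enrich the microbial fraction of a sequencing
library by lysing host cells with saponin and digesting the freed DNA with
DNase before microbial DNA extraction. Because saponin also permeabilizes
bacterial envelopes — Gram-negative cells far more than Gram-positive ones —
the treated sample's taxonomic profile is a biased version of the untreated
one. The package quantifies three observable consequences: the host-read
fraction removed (read accounting), the overall profile divergence (TVI),
and the Gram-class shift along a saponin dose series.

## Statistics

**Host-filtered percentage.** `100 · (HQ − retained)/HQ`, where HQ is the
high-quality read count and retained the count surviving alignment-based
human-read removal. Rounding is half-up at two decimals (via exact `Decimal`
arithmetic), chosen so a published table's percentage column is reproduced
bit-exactly from its count columns; all 21 cells of the bundled example
tables reproduce. Machine outputs (TSV/JSON) keep counts unformatted; only
the human-readable rendering uses thousands separators. The
treated/untreated contrast is reported both as an absolute percent-point
difference and as a relative reduction; neither is privileged because
published prose mixes the two.

**Taxonomic variation index.** For percent profiles normalized to 100,
`TVI(p, q) = Σ_t |p_t − q_t|` over the union of taxa matched by exact name.
A taxon absent from one profile contributes its full abundance — this is
forced by the stated range: 200 is attainable only if disjoint profiles
contribute both totals. TVI is an L1 metric (symmetry, identity, triangle
inequality) and equals 2 × 100 × Bray–Curtis dissimilarity on this scale;
the test suite cross-checks against SciPy's independent Bray–Curtis
implementation on 1,000 random profile pairs. Inputs must be explicitly
normalized; the package refuses to renormalize silently.

**Lost/gained taxa.** Lost = untreated abundance above the presence
threshold and treated abundance exactly zero; gained symmetric. The default
threshold is 0 (any positive abundance counts as present) — published
"lost taxa between 0.5% and 25.7%" style figures are descriptive, not a
filter. Lists are sorted by descending abundance then name, for
deterministic reports.

**Subsampling comparability.** Drawing a depth-d subset of reads is
multivariate hypergeometric across all bins (taxa, host, unclassified):
a *selection* from existing reads, without replacement, matching what
"re-analyze with a subset of n reads" means. The check reports the TVI
distribution between the full-depth profile and subsampled replicates;
no comparable/not-comparable verdict is attached, because any cutoff is
study-specific. 200 reads is a conventional example depth, not a constant.

**Survival contrast.** Under exponential survival, abundances after
treatment at concentration c are proportional to `n_t · exp(−k_t c)`, so
`log(p_t(c)/p_ref(c)) = (log n_t − log n_ref) + (k_ref − k_t) c` exactly —
linear in c with slope `β_t = k_ref − k_t`. β is fitted per taxon by
ordinary least squares on the log-ratios, restricted to taxa with positive
abundance at every concentration (zeros are dropped with a warning, never
imputed). The log-ratio cancels each profile's closure constant, so the
estimate is invariant to renormalization — and, by the same token, absolute
rates are unidentifiable from composition alone. Concentration enters on
the linear % wt/vol scale (untreated = 0 rules out a log scale), which is
also the scale on which the model is linear. `gram_rate_contrast` pools
this into a single `k_neg − k_pos` estimate: the reference is the
Gram-positive taxon with the largest minimum abundance across the grid (the
most reliably observed one), and the estimate is the median of `−β_t` over
Gram-negative taxa, the median guarding against taxa near the detection
limit.

**Dose response.** Gram fractions per concentration, the Spearman rank
correlation between concentration and Gram-negative percent, and the OLS
slope of that percent versus concentration. With four or fewer points these
are descriptive; no p-values are attached. A constant series has an
undefined correlation and is flagged as such rather than reported as 0.
Unannotated taxa accumulate in an explicit `unknown` bucket; prorating them
over the two known classes would fabricate data.

## The simulator

The generator emulates the experiment on an absolute copies/mL scale:

1. **Community.** `n_taxa` bacterial taxa with log-normal copy numbers
   (median-preserving parameterization: mean `mean_copies`, log-sd
   `abundance_spread`), independent Bernoulli Gram labels, and host copies
   set to `host_to_bacteria_ratio ×` total bacterial copies (the ratio is
   exact by construction).
2. **Depletion.** Deterministic class-wise exponential survival
   `exp(−k_class · c)` applied to copies. Exponential-in-concentration is
   the minimal monotone one-parameter-per-class form consistent with a
   monotone dose response; no mechanistic claim is made. DNase removal of
   host DNA is folded into `k_host`, since only the net host fraction is
   observable downstream. Taxa of unknown Gram class survive at the
   Gram-positive rate (the conservative choice). Per-taxon rate jitter is
   deliberately absent so class-level recovery tests are exact in
   expectation.
3. **Sequencing.** A multinomial draw of `depth` labeled reads with
   probabilities proportional to surviving copies, host as one bin; an
   optional misclassification rate relabels bacterial reads as
   "unclassified" (default 0; host reads are identified by alignment
   downstream and are exempt). Reads are *generated* with replacement here,
   whereas the comparability check *selects* reads without replacement —
   the distinction is deliberate: a sequencer samples molecules from an
   effectively infinite pool, a subsample selects from a finite file.

Expected composition after depletion is
`copies_t e^(−k_t c) / Σ_j copies_j e^(−k_j c)`; the suite verifies sampled
profiles against this law within binomial error at depth 10⁶.

**Default scenario ("sputum-like").** `k_host = 2.0`, `k_neg = 0.8`,
`k_pos = 0.05` per % wt/vol; 40 taxa, Gram-negative fraction 0.5,
`abundance_spread = 1.0`, host-to-bacteria ratio 1.13 (≈53% host reads
untreated, matching a host-rich respiratory sample); depth 150,000 reads
(the order of a typical shallow shotgun run); concentration grid
{0, 0.0125, 0.05, 0.1, 0.5, 1.5, 2, 2.5} % wt/vol — the assayed doses plus
the 2.5% standard-protocol dose, with 0 denoting untreated. Under these
defaults the host-read percentage falls monotonically in concentration and
the Gram-negative share falls monotonically in expectation, the qualitative
pattern the real protocol shows. Parameter-recovery exercises use an evenly
spaced five-point grid {0, 0.5, 1.0, 1.5, 2.0} so leverage is spread across
the concentration range rather than concentrated at the two largest doses.

Seed handling: one `numpy` `SeedSequence` per scenario seed, spawned into
independent child streams for the community draw and each concentration's
sequencing draw, so identical configs give byte-identical outputs.

**What the simulator does not emulate.** Matrix-dependent absolute yields
(real specimens show the same protocol increasing bacterial DNA in one
matrix and decreasing it in another), PCR/GC and extraction-kit bias,
classifier error structure beyond a flat misclassification rate, read
sequences themselves (reads are abstract labels; no FASTQ), and taxon-level
susceptibility variation within a Gram class. Passing recovery tests
therefore demonstrates the statistics' correctness under the stated
generative model, not protocol performance on any real specimen.

## Numerical and design notes

- Taxon identity is byte-exact string equality; no rank parsing or fuzzy
  matching, avoiding silent merges. The host row is the literal
  `"Homo sapiens"` (configurable).
- Percent values are stored at full float precision; rounding happens only
  at report time. Profile normalization tolerance is 1e-6 on the sum.
- Input dialect (percent vs count) is declared by the caller, never
  sniffed — small percentages are indistinguishable from counts.
- Unclassified reads are excluded from the relative-abundance denominator
  by default (flag available): profiles describe the classified microbial
  fraction.
- The evaluation pipeline attaches a baseline TVI — two independent
  sequencing draws of the same untreated community — so observed
  divergences can be read against pure resampling noise.
- Reports are JSON-first with deterministic key order; provenance blocks
  record inputs, a SHA-256 config hash, seed and package version.

## Problem sizes used in the checks

Acceptance-style checks run at: 1,000 random profile pairs/triples for the
metric properties; 1,000 subsampling replicates at depths 200 and 5,000 on
a fixed 10-taxon, 20,000-read table against a brute-force resampling
oracle; parameter recovery at depth 10⁶ over 5 concentrations × 10 seeds
(tolerance 0.1 on the rate contrast); slope-sign checks over 100 runs at
depth 10⁶ and null-slope calibration over 200 runs at depth 10⁵. These
sizes give standard errors comfortably inside the asserted tolerances.

## Known limitations

- TVI weights all taxa equally on the percent scale; it is insensitive to
  phylogenetic relatedness (no UniFrac-style distances) and dominated by
  abundant taxa.
- Survival-contrast estimation drops any taxon that hits zero at any
  concentration, biasing the eligible set toward abundant taxa at high
  doses; at shallow depth the pooled contrast is correspondingly noisier.
- Exact zeros in profiles are treated as true absence; detection-limit
  modeling is out of scope.
- The half-up rounding rule is a reporting convention; two tables rounded
  by different conventions may disagree in the last digit.
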