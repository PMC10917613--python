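# deplete-bias

Quantify the taxonomic bias introduced by host-DNA depletion in shallow
shotgun metagenomics.

Clinical and host-associated specimens (saliva, sputum, biopsies, swabs) are
often dominated by human DNA, so wet-lab depletion protocols — saponin lysis
of host cells followed by DNase digestion — are used to enrich the microbial
fraction before sequencing. The catch: saponin is a surfactant that also
lyses bacteria, and it hits Gram-negative cells (thin wall, outer membrane)
much harder than Gram-positive ones. The recovered taxonomic profile can
therefore differ sharply from the untreated sample's. This package is for
microbiome researchers and clinical metagenomics groups who need to measure
that trade-off before trusting a depletion protocol.

## What it computes

Given per-sample taxonomic profiles (taxon → relative abundance in percent),
read-count tables, read-filtering records and a Gram annotation:

- **Read accounting** — the host-filtered percentage
  `100 · (HQ − retained) / HQ`, rounded half-up at 2 decimals, and
  treated-vs-untreated host-reduction contrasts (absolute percent points and
  relative percent).
- **Taxonomic variation index (TVI)** — for normalized percent profiles
  *p*, *q*, the L1 divergence over the union of taxa,
  `TVI = Σ_t |p_t − q_t|`, ranging 0 (identical) to 200 (disjoint); equal to
  2 × 100 × Bray–Curtis dissimilarity. Comparison reports add per-taxon
  deltas and lost/gained taxa.
- **Subsampling comparability** — fixed-depth subsampling without
  replacement (multivariate hypergeometric) and the TVI distribution between
  full-depth and subsampled profiles, for judging whether a shallow run is
  deep enough to compare.
- **Gram-stratified dose response** — Gram-negative/positive/unknown
  fractions per saponin concentration, with a Spearman rank correlation and
  least-squares slope of the Gram-negative percent versus concentration.
- **Survival-rate contrasts** — under an exponential survival model
  (copies of taxon *t* scaled by `exp(−k_t · c)` at concentration *c*), the
  log abundance ratio against a reference taxon is linear in *c*:
  `log(p_t(c)/p_ref(c)) = α_t + β_t c` with `β_t = k_ref − k_t`, fitted by
  OLS. Only contrasts are identifiable from compositional data.
- **A synthetic differential-lysis simulator** — host + bacterial community
  on an absolute copies/mL scale, class-wise exponential survival in saponin
  concentration (`k_host ≫ k_neg > k_pos`), and sequencing as a multinomial
  labeled-read draw — the fully controlled test bed for all of the above.

## Worked example

Reproduce a published-style filtering table from its count columns:

```python
from deplete_bias import filtering_table
from deplete_bias.example_data import matrix_accounting

accs = [a for a in matrix_accounting() if a.sample_id.startswith(("Saliva", "Sputum"))]
print(filtering_table(accs))
```

```
Sample   	Reads produced	High-quality reads	Retained after host filtering	% filtered host
Saliva-NT	134,011       	131,338           	30,156                       	77.04%
Saliva-T 	225,114       	218,562           	208,893                      	4.42%
Sputum-NT	77,837        	52,182            	9,776                        	81.27%
Sputum-T 	208,337       	203,745           	200,275                      	1.70%
```

Saponin treatment cut the saliva sample's host reads from 77.04% to 4.42% of
high-quality reads — a 72.62-point (94.3% relative) reduction
(`host_reduction(treated, untreated)` → `(72.62, 94.26)`).

Run the full simulated workflow — community, dose-dependent lysis,
sequencing, treated-vs-untreated evaluation:

```python
from deplete_bias import default_scenario, SequencingConfig, end_to_end

cfg = default_scenario(sequencing=SequencingConfig(depth=150_000), seeds=(1,))
summary = end_to_end(cfg, "reports")
```

The per-seed block of `summary` prints as:

```
baseline TVI at c=0: 2.35          # two independent draws: pure sampling noise
host% untreated: 53.06
c=0.0125  host%=52.78  gram_neg%=52.25  TVI=2.92
c=0.05    host%=51.04  gram_neg%=52.28  TVI=2.69
c=0.1     host%=48.97  gram_neg%=50.83  TVI=4.04
c=0.5     host%=33.88  gram_neg%=43.22  TVI=18.52
c=1.5     host%=8.63   gram_neg%=26.52  TVI=51.93
c=2       host%=3.7    gram_neg%=19.92  TVI=65.12
c=2.5     host%=1.54   gram_neg%=14.61  TVI=75.74
dose-response: slope=-15.78 %-points per %wt/vol, spearman rho=-0.976
k contrast estimate: 0.749 (true k_neg - k_pos = 0.75)
```

Reading it: host DNA falls from 53% of reads to 1.5% across the saponin
grid (the depletion works), but the Gram-negative share collapses from ~53%
to ~15% and the profile drifts to TVI ≈ 76 against an untreated baseline of
~2.4 — the bias the package exists to expose. The log-ratio fit recovers the
simulator's true Gram-negative/positive rate contrast to three decimals.

The same workflows are available from the shell:

```sh
deplete-bias filter-table accounting.tsv
deplete-bias compare untreated.tsv treated.tsv --annotation gram.tsv
deplete-bias subsample counts.tsv --depth 200 --reps 1000 --seed 1
deplete-bias dose-response manifest.tsv --annotation gram.tsv
deplete-bias simulate scenario.json --out sim/
deplete-bias end-to-end scenario.json --out reports/
```

Exit codes: 0 success, 2 invalid input/config, 3 I/O error.

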