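# ssrcore

Diversity statistics, DNA fingerprinting and core-collection extraction for
codominant SSR (microsatellite) genotype tables — the standard toolkit a
germplasm curator needs between "a box of gel scores" and "a managed,
de-duplicated collection".

The package grew out of a published survey of 955 *Akebia trifoliata*
germplasms genotyped at 28 SSR loci; it reimplements that study's analysis
chain as a reusable library:

* **Genotype model & I/O** — accessions × loci matrices of unordered diploid
  allele pairs (`A`–`I` per locus in decreasing band molecular weight, one
  band = homozygote, no band = missing), read/written as a plain CSV/TSV
  dialect or GenePop, plus recoding of raw band weights into letters.
* **Per-locus diversity panel** — for allele frequencies $p_i$: observed
  alleles $N_a$, effective alleles $N_e = 1/\sum p_i^2$, observed
  heterozygosity $H_O$, unbiased expected heterozygosity
  $H_E = \frac{2n}{2n-1}\left(1 - \sum p_i^2\right)$, Nei's gene diversity
  $D = 1 - \sum p_i^2$, Shannon index $I = -\sum p_i \ln p_i$, and
  $\mathrm{PIC} = 1 - \sum p_i^2 - \sum_{i<j} 2 p_i^2 p_j^2$.
* **Distances & UPGMA** — shared-allele distance between individuals
  (pairwise deletion of missing loci), Nei's (1972) standard distance
  between frequency-characterised collections, deterministic UPGMA with
  Newick export.
* **Molecular identity cards** — the single-character genotype coding
  (homozygotes → `1`–`4`…, A–D heterozygotes in the order
  A/B, A/C, A/D, B/C, B/D, C/D → `A`–`F`, missing → `0`) and greedy
  PIC-descending selection of the minimal marker prefix that distinguishes
  every accession.
* **Core collections** — stepwise clustering: each round drops one random
  member of every *cherry* (two-leaf group) of the UPGMA tree and
  re-clusters, until an exact target size is reached; validated against
  random "pseudo-cores" with retention percentages, one-way ANOVA over
  loci and a within-locus permutation test.
* **Simulator** — structured populations under the Balding–Nichols F-model
  with inbreeding (autozygosity) and missing bands, including a calibrated
  profile matching the published survey's panel (955 accessions, 28 loci
  with 104 alleles, four subpopulations, $H_O \approx 0.24$,
  $D \approx 0.46$).

The survey's raw 955 × 28 table was never deposited, but its printed
164-accession core-collection identity cards are bundled
(`ssrcore.load_core164()`) and decode into a real genotype matrix used
throughout the tests and examples.

## Worked example

Extract a core collection from a survey-profile simulation
(`examples/04_core_collection.py`):

```python
from ssrcore import (akebia_profile, simulate, stepwise_core,
                     random_cores, compare_collections)

matrix, _ = simulate(akebia_profile(), seed=42)
core = stepwise_core(matrix, size=164, seed=7)
print(core.retention)
```

prints (run it yourself — it takes a few seconds):

```
core of 164 selected in 4 rounds
retention vs full collection (%): {'Na': 97.9, 'Ho': 102.8, 'Nei': 103.9, 'PIC': 104.2}

panel means per collection:
                Na      Ho     Nei     PIC
Collection
core        3.3571  0.2500  0.4911  0.4353
random1     3.2500  0.2399  0.4736  0.4181
random2     3.3214  0.2401  0.4702  0.4166
random3     3.3571  0.2405  0.4699  0.4154

           F  p_anova  p_perm
stat
Na    0.1068   0.9559  0.4150
Ho    0.0794   0.9710  0.3562
Nei   0.1002   0.9597  0.0024
PIC   0.1056   0.9566  0.0009
```

Reading this: the stepwise core keeps ~98% of the allele richness while its
per-accession diversity (Nei's $D$, PIC) *exceeds* the full collection —
pruning cherries removes near-duplicates first.  Random cores of the same
size merely track the full-collection means; the within-locus permutation
test (which respects the paired per-locus design) flags the core's excess
$D$ and PIC, while the unpaired ANOVA across collections is far less
powerful on panel means this close together.

The other examples cover the diversity panel on the bundled 164-card
matrix (`01`), greedy fingerprint-marker selection (`02`), UPGMA/Newick
(`03`) and simulator parameter recovery (`05`); each prints a short
explanation with its numbers.

A thin CLI wraps the same functions:

```sh
ssrcore simulate --profile akebia --seed 1 -o pop.csv
ssrcore stats pop.csv
ssrcore identity pop.csv
ssrcore core pop.csv --size 164 --seed 7 -o core_out
```

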