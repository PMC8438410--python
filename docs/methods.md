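# Methods

This note records the scientific and numerical choices behind `ssrcore`:
what each procedure assumes, where a convention had to be chosen among
several defensible ones, and what the synthetic populations do and do not
emulate.

## Genotype model

An SSR locus is scored from gel bands: alleles are labelled `A`, `B`, …
in decreasing band molecular weight. A diploid shows at most two bands;
one band is recorded as a homozygote and zero bands as a missing cell.
Two consequences are baked into the data model:

* *Missingness is cell-level.* A cell is either a full unordered allele
  pair or missing; "one allele known, one unknown" is not representable,
  because band scoring cannot produce it.
* *At most nine alleles per locus.* The single-character identity coding
  assigns the k-th homozygote the digit *k*, so the alphabet stops at `I`.
  Real SSR panels of this kind run 2–5 alleles per locus.

A locus's allele set is declared by the data (contiguous letters up to the
highest observed), not by a separate schema. The native file dialect is
one row per accession, two concatenated letters per cell (`AB`), `--` for
missing; GenePop import/export (4-digit codes, `A`→`01`) is provided for
interoperability. Half-missing GenePop codes (`0100`) are rejected rather
than guessed at.

The one-band-equals-homozygote rule deserves a caveat: with codominant
gels, a true heterozygote whose second band failed to amplify (null
allele) is indistinguishable from a homozygote. Loci with observed
heterozygosity exactly 0 despite multiple alleles are treated as ordinary
data; the package does not attempt null-allele correction.

## Diversity statistics

Frequencies are counted over gene copies (a heterozygote contributes one
copy of each allele), with missing cells excluded listwise per locus, so
the per-locus sample size *n* varies with missingness.

* Nei's gene diversity `D = 1 − Σp²` and the effective allele number
  `Ne = 1/Σp²` are computed from the same frequency vector, so the
  identity `D = 1 − 1/Ne` holds to machine precision — a property the
  tests assert and that also holds (to printed precision) in the survey's
  published panel.
* Expected heterozygosity uses the small-sample correction
  `He = 2n/(2n−1) · D` with the per-locus *n*. The survey's printed He/D
  ratios vary slightly by locus, consistent with per-locus *n* varying
  through missing bands but not exactly recoverable from the printed
  table; the convention here is documented, not fitted to those values.
* The Shannon index uses natural logarithms.
* PIC is the Botstein form `1 − Σp² − Σ_{i<j} 2p²_i p²_j`, computed via
  power sums (`PIC = D − (S₂² − S₄)`, `S_k = Σp^k`) for numerical economy.
  `PIC ≤ D` always.
* Text outputs round to 4 decimals; internal values are never rounded.

For a biallelic locus the printed gene diversity alone determines the
frequency pair (solve `p(1−p) = D/2`); `biallelic_freqs_from_diversity`
exposes that back-solve, which is what lets the acceptance script
recompute the published biallelic marker's PIC and Shannon index from
first principles.

## Distances and clustering

Individual-level clustering uses the shared-allele distance
`d(i,j) = 1 − mean_l(shared_l/2)` over loci typed in both accessions
(pairwise deletion). Nei's 1972 standard distance is defined on
population frequency vectors and degenerates for single diploids (it is
zero only for identical frequency vectors and blows up on disjoint
support), so it is provided for collection-level comparisons only;
disjoint support returns an infinite-distance flag that must be resolved
before tree building rather than silently truncated.

UPGMA merges the closest pair, updating distances by the size-weighted
arithmetic mean, node height = merge distance / 2. Ties are broken on the
lowest (row, column) index pair of the current matrix, with the merged
cluster occupying the lower slot; this makes every tree deterministic for
a fixed input order. Note the flip side: on tie-heavy matrices (few loci,
coarse distance values) two input orders can legitimately give different
topologies, so the order-invariance property is only asserted for generic
(tie-free) matrices. Ultrametricity is exact up to floating error
(asserted at 1e−9), and on already-ultrametric inputs the cophenetic
distances reproduce the input exactly.

Newick branch lengths are parent-height minus child-height. Rendering is
delegated to external viewers; the Newick string is the contract.

## Identity cards and marker selection

The fixed, global code map: homozygotes `A/A…D/D` → `1…4` (continuing
`5…9` for later homozygotes), the six heterozygotes among `A–D` in the
order A/B, A/C, A/D, B/C, B/D, C/D → `A…F`, missing → `0`. Heterozygote
pairs involving `E` or later letters are appended after `F` in
lexicographic pair order (`G`, `H`, …, continuing into lowercase), so the
published assignments are never disturbed and encode/decode is a bijection
over the whole representable alphabet (tested exhaustively).

Marker selection is greedy: rank markers by PIC descending (ties keep
input order) and grow the prefix until all identity strings are pairwise
distinct. Missing-data `0` characters *do* count as distinguishing
characters — two accessions differing only in which loci failed are
treated as distinguishable, which matches the structure of the published
cards (several differ only via `0` positions) though the original
authors' choice on this point is not stated. If the full marker set still
leaves collisions (true duplicates), the full set is returned along with
the colliding groups; collisions are a report, not an error. No attempt
is made at exact minimal-subset search; the greedy PIC order is the
method.

## Stepwise core collection

One round: compute shared-allele distances on the current set, build the
UPGMA tree, list its cherries (two-leaf internal nodes — the groups whose
within-group difference is smallest), and remove one member of each
cherry uniformly at random; accessions not in any cherry pass through.
Survivors are re-clustered (the tree is rebuilt every round, not reused)
and rounds repeat until the target size is reached. When a full round
would overshoot, only the lowest cherries — the most redundant pairs,
height ties resolved by position — are processed, so the final size is
hit *exactly*. Exact duplicates sit in height-0 cherries and are pruned
first.

The stopping rule is an exact target size, given directly or as
`ceil(fraction · N)`. The published core (164 of 955) is reported as
"17.2%", but `ceil(0.172 · 955) = 165`; reproducing 164 requires passing
the size directly. An optional retention floor (e.g. refuse to fall below
90% of the full collection's mean allele count) can stop selection early;
it is a guard, not a second selection algorithm, and when it fires the
result is flagged and larger than the target.

Every run logs, per round, the set size, cherry count and removed ids;
replaying the log reproduces the selection, and the same seed reproduces
it from scratch.

### Validation against pseudo-cores

A collection is summarised by its per-locus Na, Ho, Nei's D and PIC
panel. The comparison treats collections as groups and loci as
replicates: a one-way ANOVA on each statistic, plus a permutation test
that shuffles collection labels *within* each locus (≥ 9999 permutations,
add-one p-value). The permutation design respects the locus pairing —
loci differ enormously in diversity, so the paired test is far more
powerful than the unpaired ANOVA on the same data, and on simulated
surveys it is the permutation p that flags the core's excess diversity.
Both are reported. A degenerate comparison (identical collections) yields
F = 0 and permutation p = 1 by construction.

## Synthetic populations

The generator draws, per locus, ancestral frequencies from a symmetric
Dirichlet and subpopulation frequencies from the Balding–Nichols F-model
(Dirichlet with concentration `p·(1−Fst)/Fst` — the "correlated allele
frequencies" model that STRUCTURE assumes). Accessions are assigned to
subpopulations by fixed mixture weights; a genotype is autozygous with
probability Fis (one allele drawn and duplicated), otherwise two
independent draws from the subpopulation frequencies; cells go missing
independently at a uniform rate. Allele labels are assigned in decreasing
ancestral-frequency order, since gel-weight order is arbitrary.

The packaged survey profile (`akebia_profile`) uses the published
panel's exact allele-count spectrum (19 four-allele loci, 7 three-allele,
one biallelic, one five-allele; 104 alleles over 28 loci), N = 955, four
subpopulations at the published cluster proportions
(25.03/18.32/17.07/39.58%). The remaining constants were calibrated once
against the published panel means — `fst = 0.08` (weak structure),
`fis = 0.46`, `dirichlet_concentration = 0.5` — which puts the expected
mean observed heterozygosity near 0.238 and mean gene diversity near
0.460; the missing-band rate 0.08 is a documented guess, as the survey
reports none (its printed identity cards suggest the 11 card markers had
substantially higher missingness than a uniform 8%, but those 11 are not
a random sample of the panel).

What the simulator does **not** emulate: mutation processes (no stepwise
mutation model), linkage between loci, locus-specific missingness or
null alleles, family structure beyond a single inbreeding coefficient,
and selection. Consequently, passing pipeline tests on synthetic data
demonstrates the *procedures* behave as specified under the assumed
model — exact target sizes, seed reproducibility, diversity retention
above random cores — not that real *A. trifoliata* data would yield the
published per-locus values, which depend on the undeposited raw matrix.

## Problem sizes and determinism

All stochastic components take explicit seeds (`numpy.random.default_rng`);
identical (config, seed) pairs give identical matrices, cores and
permutation p-values. The test suite's heaviest check runs the full
955-accession stepwise selection against random cores over 20 seeds
(~15 s); simulator recovery checks use N = 1000 accessions and 28 loci,
where the across-locus standard error of `1 − Ho/He` is ≈ 0.006, small
enough to detect a mis-specified Fis. The brute-force UPGMA oracle runs
at n ≤ 7 leaves, where hand-checkable enumeration is feasible; scipy's
average-linkage implementation provides an independent cross-check at
larger n.

## Known limitations

* Pseudo-core ANOVA treats loci as independent replicates; loci on the
  same chromosome violate that silently.
* The greedy marker panel is minimal *for the greedy order*, not globally
  minimal.
* Retention percentages above 100% (possible for D and PIC, since a core
  can be more diverse per accession than its source) read oddly as
  "retention" but follow the field's convention of reporting
  `100 · core mean / full mean`.
* With heavy missingness the pairwise-deletion distance can rest on very
  few loci for some pairs; a pair sharing no typed locus is an error by
  design rather than an imputed value.
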