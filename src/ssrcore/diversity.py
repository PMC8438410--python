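"""Per-locus diversity statistics for codominant SSR data.

For allele frequencies :math:`p_i` at a locus the panel comprises

* ``Na`` — observed allele count,
* ``Ne`` — effective allele number :math:`1/\\sum p_i^2`,
* ``Ho`` — observed heterozygosity (fraction of heterozygous genotypes),
* ``He`` — unbiased expected heterozygosity :math:`\\frac{2n}{2n-1}(1-\\sum p_i^2)`
  with :math:`n` the non-missing sample size at the locus,
* ``D``  — Nei's gene diversity :math:`1-\\sum p_i^2` (so ``D == 1 - 1/Ne``),
* ``I``  — Shannon information index :math:`-\\sum p_i \\ln p_i` (nats),
* ``PIC`` — polymorphic information content (Botstein form)
  :math:`1-\\sum p_i^2-\\sum_{i<j} 2 p_i^2 p_j^2`.

Frequencies are counted over gene copies (a heterozygote contributes one
copy of each allele); missing cells are excluded listwise per locus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AllMissingLocusError
from .genotypes import ALLELE_LETTERS, GenotypeMatrix

__all__ = [
    "AlleleFrequencies",
    "allele_freqs",
    "nei_gene_diversity",
    "effective_alleles",
    "observed_heterozygosity",
    "expected_het_unbiased",
    "shannon_index",
    "pic",
    "locus_stats_table",
    "biallelic_freqs_from_diversity",
]


@dataclass
class AlleleFrequencies:
    """Allele frequencies at one locus, restricted to observed alleles."""

    locus: str
    labels: tuple[str, ...]
    p: np.ndarray
    n: int  # non-missing genotyped individuals

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if self.n > 0:
            if np.any(self.p < 0) or abs(self.p.sum() - 1.0) > 1e-12:
                raise ValueError(f"locus {self.locus!r}: invalid frequency simplex")


def allele_freqs(matrix: GenotypeMatrix, locus: str) -> AlleleFrequencies:
    """Gene-copy allele frequencies at ``locus``, missing cells excluded."""
    j = matrix.locus_index(locus)
    a1, a2 = matrix.a1[:, j], matrix.a2[:, j]
    ok = a1 >= 0
    n = int(ok.sum())
    if n == 0:
        raise AllMissingLocusError(f"locus {locus!r} has no non-missing genotype")
    k = matrix.markers[j].n_alleles
    counts = np.bincount(a1[ok], minlength=k) + np.bincount(a2[ok], minlength=k)
    observed = counts > 0
    labels = tuple(ALLELE_LETTERS[i] for i in range(k) if observed[i])
    p = counts[observed] / (2 * n)
    return AlleleFrequencies(locus, labels, p, n)


def nei_gene_diversity(p: np.ndarray) -> float:
    """Nei's gene diversity D = 1 - sum(p^2)."""
    p = np.asarray(p, dtype=float)
    return float(1.0 - np.sum(p**2))


def effective_alleles(p: np.ndarray) -> float:
    """Effective allele number Ne = 1 / sum(p^2)."""
    p = np.asarray(p, dtype=float)
    return float(1.0 / np.sum(p**2))


def observed_heterozygosity(matrix: GenotypeMatrix, locus: str) -> float:
    """Fraction of non-missing genotypes whose two alleles differ."""
    j = matrix.locus_index(locus)
    a1, a2 = matrix.a1[:, j], matrix.a2[:, j]
    ok = a1 >= 0
    n = int(ok.sum())
    if n == 0:
        raise AllMissingLocusError(f"locus {locus!r} has no non-missing genotype")
    return float(np.sum(a1[ok] != a2[ok]) / n)


def expected_het_unbiased(d: float, n: int) -> float:
    """Small-sample corrected expected heterozygosity, He = 2n/(2n-1) * D."""
    if n < 1:
        raise AllMissingLocusError("expected heterozygosity undefined for n = 0")
    return float(2 * n / (2 * n - 1) * d)


def shannon_index(p: np.ndarray) -> float:
    """Shannon information index I = -sum(p ln p) in nats; 0 ln 0 := 0."""
    p = np.asarray(p, dtype=float)
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


def pic(p: np.ndarray) -> float:
    """Polymorphic information content, 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2."""
    p = np.asarray(p, dtype=float)
    s2 = float(np.sum(p**2))
    s4 = float(np.sum(p**4))
    return 1.0 - s2 - (s2 * s2 - s4)


def biallelic_freqs_from_diversity(d: float) -> np.ndarray:
    """Back-solve the two allele frequencies of a biallelic locus from D.

    For two alleles, D = 2pq; solving p(1-p) = D/2 gives the (major, minor)
    frequency pair.  Only defined for 0 <= D <= 0.5.
    """
    if not 0.0 <= d <= 0.5:
        raise ValueError(f"biallelic gene diversity must lie in [0, 0.5], got {d}")
    disc = np.sqrt(1.0 - 2.0 * d)
    p = (1.0 + disc) / 2.0
    return np.array([p, 1.0 - p])


def locus_stats_table(matrix: GenotypeMatrix, mean_row: bool = True) -> pd.DataFrame:
    """Per-locus diversity panel with an arithmetic 'Mean' row.

    Columns: Na, Ne, Ho, He, Nei, I, PIC (Nei = gene diversity D).
    """
    rows = {}
    for m in matrix.markers:
        fr = allele_freqs(matrix, m.id)
        d = nei_gene_diversity(fr.p)
        rows[m.id] = {
            "Na": float(len(fr.p)),
            "Ne": effective_alleles(fr.p),
            "Ho": observed_heterozygosity(matrix, m.id),
            "He": expected_het_unbiased(d, fr.n),
            "Nei": d,
            "I": shannon_index(fr.p),
            "PIC": pic(fr.p),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    if mean_row:
        table.loc["Mean"] = table.mean(axis=0)
    table.index.name = "Marker"
    return table
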