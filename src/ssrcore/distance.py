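"""Genetic distances for individuals and populations.

Individual accessions are compared by the allele-sharing distance
``d(i, j) = 1 - mean_l(shared_l / 2)`` over loci typed in both accessions
(pairwise deletion), where ``shared_l`` is the size of the multiset
intersection of the two allele pairs (0, 1 or 2).  This is the standard
shared-allele distance for codominant markers and is the distance used for
individual-level clustering here, because the population-level Nei (1972)
standard distance degenerates when a "population" is a single diploid.

:func:`nei_1972_distance` implements Nei's standard distance for
frequency-characterised collections,

.. math:: D = -\\ln \\frac{\\sum_l \\sum_i p_{xi} p_{yi}}
                        {\\sqrt{\\sum_l \\sum_i p_{xi}^2 \\; \\sum_l \\sum_i p_{yi}^2}}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .diversity import AlleleFrequencies
from .errors import NoSharedLociError, ValidationError
from .genotypes import GenotypeMatrix

__all__ = ["DistanceMatrix", "allele_sharing_distance", "nei_1972_distance"]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with labelled rows."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValidationError(f"distance matrix must be {n}x{n}")
        if np.any(np.diag(self.d) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        finite = np.isfinite(self.d)
        if np.any(self.d[finite] < 0):
            raise ValidationError("distances must be non-negative")
        if not np.allclose(self.d, self.d.T, atol=1e-12, equal_nan=True):
            raise ValidationError("distance matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def value(self, a: str, b: str) -> float:
        return float(self.d[self.ids.index(a), self.ids.index(b)])


def _locus_share_table(k: int) -> np.ndarray:
    """Shared-allele counts between all genotype states of a k-allele locus.

    Genotype states are ordered pairs (a1 <= a2) enumerated as
    ``state = a1 * k + a2``; the table maps (state, state) -> multiset
    intersection size in {0, 1, 2}.
    """
    states = [(a, b) for a in range(k) for b in range(a, k)]
    n_codes = k * k
    table = np.zeros((n_codes, n_codes), dtype=np.int8)
    for a1, a2 in states:
        for b1, b2 in states:
            s = 0
            pool = [b1, b2]
            for x in (a1, a2):
                if x in pool:
                    pool.remove(x)
                    s += 1
            table[a1 * k + a2, b1 * k + b2] = s
    return table


def allele_sharing_distance(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise allele-sharing distance among all accessions.

    Loci missing in either accession of a pair are dropped for that pair;
    a pair with no commonly typed locus raises :class:`NoSharedLociError`.
    """
    n = matrix.n_accessions
    if n < 2:
        raise ValidationError("need at least two accessions for a distance matrix")
    shared_sum = np.zeros((n, n))
    typed = np.zeros((n, n), dtype=int)
    present = ~matrix.missing_mask()
    for j, marker in enumerate(matrix.markers):
        k = marker.n_alleles
        table = _locus_share_table(k)
        state = matrix.a1[:, j].astype(np.intp) * k + matrix.a2[:, j].astype(np.intp)
        state[~present[:, j]] = 0  # placeholder; masked out below
        both = np.outer(present[:, j], present[:, j])
        shared_sum += np.where(both, table[np.ix_(state, state)], 0)
        typed += both
    if np.any(typed == 0):
        i, j = np.argwhere(typed == 0)[0]
        raise NoSharedLociError(
            f"accessions {matrix.accession_ids[i]!r} and "
            f"{matrix.accession_ids[j]!r} share no typed locus"
        )
    d = 1.0 - shared_sum / (2.0 * typed)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # exact symmetry
    return DistanceMatrix(list(matrix.accession_ids), d)


def nei_1972_distance(
    fx: Sequence[AlleleFrequencies], fy: Sequence[AlleleFrequencies]
) -> float:
    """Nei's (1972) standard genetic distance between two collections.

    ``fx`` and ``fy`` are per-locus frequency sets over the same loci.
    Returns ``math.inf`` when the collections share no allele at all
    (zero cross-identity), which callers must resolve before clustering.
    """
    if [f.locus for f in fx] != [f.locus for f in fy]:
        raise ValidationError("Nei distance requires the same locus set in order")
    jxy = jx = jy = 0.0
    for a, b in zip(fx, fy):
        # align on the union of observed alleles
        labels = sorted(set(a.labels) | set(b.labels))
        pa = np.array([a.p[a.labels.index(l)] if l in a.labels else 0.0 for l in labels])
        pb = np.array([b.p[b.labels.index(l)] if l in b.labels else 0.0 for l in labels])
        jxy += float(pa @ pb)
        jx += float(pa @ pa)
        jy += float(pb @ pb)
    if jxy == 0.0:
        return math.inf
    return float(-math.log(jxy / math.sqrt(jx * jy)))
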