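import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from ssrcore import GenotypeMatrix

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("det")


@st.composite
def genotype_matrices(
    draw, min_n=2, max_n=8, max_loci=5, max_alleles=4, missing_rate=0.15
):
    """Random valid genotype matrices built from letter-pair cells."""
    n = draw(st.integers(min_n, max_n))
    L = draw(st.integers(1, max_loci))
    counts = [draw(st.integers(1, max_alleles)) for _ in range(L)]
    cells = []
    for i in range(n):
        row = []
        for k in counts:
            if draw(st.floats(0, 1)) < missing_rate:
                row.append(None)
            else:
                a = draw(st.integers(0, k - 1))
                b = draw(st.integers(0, k - 1))
                row.append(chr(ord("A") + min(a, b)) + chr(ord("A") + max(a, b)))
        cells.append(row)
    return GenotypeMatrix.from_cells(
        [f"A{i}" for i in range(n)], [f"L{j}" for j in range(L)], cells
    )


@pytest.fixture
def toy_matrix():
    """3 accessions x 2 loci with one missing cell."""
    return GenotypeMatrix.from_cells(
        ["x", "y", "z"],
        ["s1", "s2"],
        [["AA", "AB"], ["AB", None], ["BB", "AA"]],
    )


def naive_upgma_heights(ids, d):
    """Brute-force UPGMA oracle: plain-Python merging, returns cophenetic dict.

    Clusters live in slots; a merge reuses the lower slot, ties go to the
    lowest (row, column) pair — the same contract as the package, coded
    independently with dictionaries and loops.
    """
    d = {(i, j): float(d[i][j]) for i in range(len(ids)) for j in range(len(ids))}
    slots = {i: [i] for i in range(len(ids))}
    sizes = {i: 1 for i in range(len(ids))}
    heights = {}
    while len(slots) > 1:
        keys = sorted(slots)
        best = None
        for ai, i in enumerate(keys):
            for j in keys[ai + 1 :]:
                if best is None or d[(i, j)] < best[0]:
                    best = (d[(i, j)], i, j)
        dist, i, j = best
        for a in slots[i]:
            for b in slots[j]:
                heights[(min(ids[a], ids[b]), max(ids[a], ids[b]))] = dist / 2.0
        for k in keys:
            if k in (i, j):
                continue
            new = (sizes[i] * d[(i, k)] + sizes[j] * d[(j, k)]) / (sizes[i] + sizes[j])
            d[(i, k)] = d[(k, i)] = new
        slots[i] = slots[i] + slots[j]
        sizes[i] += sizes[j]
        del slots[j], sizes[j]
    return heights
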