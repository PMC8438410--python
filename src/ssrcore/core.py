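"""Core-collection extraction by stepwise clustering, with validation.

The selection rule: compute allele-sharing distances on the current set,
build the UPGMA dendrogram, find the cherries (two-leaf groups at the
lowest level of the tree, where within-group differences are smallest),
and discard one member of each cherry uniformly at random; singletons pass
through untouched.  The survivors are re-clustered and the round repeats
until the target size is reached.  When a full round would overshoot the
target (remove too many), only the lowest cherries — the most redundant
pairs — are processed, so the final size is hit exactly.

Validation compares the core's per-locus diversity panel against equal-size
random ("pseudo-core") collections: panel means, retention percentages
relative to the full collection, and a one-way ANOVA across collections
with loci as the replicate unit, backed by a within-locus permutation test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .distance import allele_sharing_distance
from .diversity import locus_stats_table
from .errors import ComputationError, ValidationError
from .genotypes import GenotypeMatrix
from .tree import upgma

__all__ = [
    "CoreCollection",
    "ComparisonReport",
    "stepwise_core",
    "random_cores",
    "retention",
    "collection_panel",
    "compare_collections",
]

#: Panel statistics used to judge a collection (as in the survey's tables).
PANEL_STATS = ("Na", "Ho", "Nei", "PIC")


@dataclass
class CoreCollection:
    """Result of a stepwise selection run."""

    selected_ids: list[str]
    target_size: int
    target_fraction: float | None
    seed: int | None
    rounds: list[dict] = field(default_factory=list)
    stats: pd.DataFrame | None = None  # per-locus panel of the core subset
    retention: dict[str, float] | None = None  # % of the full collection's means
    stopped_by_floor: bool = False

    @property
    def size(self) -> int:
        return len(self.selected_ids)


def collection_panel(matrix: GenotypeMatrix, ids=None) -> pd.DataFrame:
    """Per-locus Na/Ho/Nei/PIC panel of a subset (or the whole matrix)."""
    sub = matrix if ids is None else matrix.subset(ids)
    return locus_stats_table(sub, mean_row=False)[list(PANEL_STATS)]


def retention(core_means: pd.Series, full_means: pd.Series) -> dict[str, float]:
    """Percentage of each full-collection panel mean retained by the core, 1 dp."""
    out = {}
    for stat in core_means.index:
        full = float(full_means[stat])
        if full == 0.0:
            raise ComputationError(f"retention undefined: full-collection {stat} mean is 0")
        out[stat] = round(100.0 * float(core_means[stat]) / full, 1)
    return out


def _cherry_sort_key(cherry, position):
    # lowest height first; ties resolved by leaf position in the current set
    return (cherry.height, position)


def stepwise_core(
    matrix: GenotypeMatrix,
    target_fraction: float | None = None,
    size: int | None = None,
    seed: int | None = None,
    min_na_retention: float | None = None,
) -> CoreCollection:
    """Extract a core collection of exactly the target size.

    Exactly one of ``target_fraction`` (size = ``ceil(fraction * N)``) or
    ``size`` must be given.  ``min_na_retention`` is an optional guard (in
    percent): if a round would push the subset's mean allele count below
    that share of the full collection's, selection stops early with
    ``stopped_by_floor`` set and a larger-than-target core.
    """
    N = matrix.n_accessions
    if (target_fraction is None) == (size is None):
        raise ValidationError("give exactly one of target_fraction or size")
    if size is None:
        if not 0.0 < target_fraction <= 1.0:
            raise ValidationError("target_fraction must lie in (0, 1]")
        size = math.ceil(target_fraction * N)
    if not 1 <= size <= N:
        raise ValidationError(f"target size {size} outside 1..{N}")

    rng = np.random.default_rng(seed)
    current = list(matrix.accession_ids)
    rounds: list[dict] = []
    full_panel_means = collection_panel(matrix).mean(axis=0)

    while len(current) > size:
        sub = matrix.subset(current)
        pos = {acc: k for k, acc in enumerate(current)}
        tree = upgma(allele_sharing_distance(sub))
        cherries = tree.cherries()
        excess = len(current) - size
        if len(cherries) > excess:
            cherries = sorted(
                cherries,
                key=lambda c: _cherry_sort_key(c, min(pos[l.label] for l in c.leaves())),
            )[:excess]
        removed = []
        for cherry in cherries:
            leaves = [l.label for l in cherry.leaves()]
            removed.append(leaves[rng.integers(len(leaves))])
        survivors = [a for a in current if a not in set(removed)]
        if min_na_retention is not None:
            na_pct = 100.0 * collection_panel(matrix, survivors)["Na"].mean() / full_panel_means["Na"]
            if na_pct < min_na_retention:
                return _finalise(
                    matrix, current, size, target_fraction, seed, rounds,
                    full_panel_means, stopped_by_floor=True,
                )
        rounds.append(
            {
                "n_before": len(current),
                "n_cherries": len(cherries),
                "removed": removed,
                "n_after": len(survivors),
            }
        )
        current = survivors

    return _finalise(
        matrix, current, size, target_fraction, seed, rounds, full_panel_means,
        stopped_by_floor=False,
    )


def _finalise(matrix, selected, size, fraction, seed, rounds, full_means, stopped_by_floor):
    panel = collection_panel(matrix, selected)
    core = CoreCollection(
        selected_ids=selected,
        target_size=size,
        target_fraction=fraction,
        seed=seed,
        rounds=rounds,
        stats=panel,
        retention=retention(panel.mean(axis=0), full_means),
        stopped_by_floor=stopped_by_floor,
    )
    return core


def random_cores(
    matrix: GenotypeMatrix, size: int, reps: int, seed: int | None = None
) -> list[list[str]]:
    """Pseudo-cores: uniform samples without replacement, seed-reproducible."""
    if size > matrix.n_accessions:
        raise ValidationError(f"size {size} exceeds {matrix.n_accessions} accessions")
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    ids = np.asarray(matrix.accession_ids, dtype=object)
    return [list(rng.choice(ids, size=size, replace=False)) for _ in range(reps)]


@dataclass
class ComparisonReport:
    """Core vs pseudo-core diversity comparison.

    ``means``: collection x statistic panel means.  ``tests``: per statistic
    the one-way ANOVA F and p across collections (loci as replicates) and a
    within-locus permutation p-value for the same F statistic.
    """

    means: pd.DataFrame
    tests: pd.DataFrame
    per_locus: dict[str, pd.DataFrame]
    n_permutations: int


def compare_collections(
    matrix: GenotypeMatrix,
    collections: dict[str, list[str]],
    n_permutations: int = 9999,
    seed: int | None = None,
) -> ComparisonReport:
    """Compare panel statistics across collections of accessions.

    Each statistic's observations are its per-locus values in each
    collection; the ANOVA treats collections as groups and loci as
    replicates, and the permutation test shuffles collection labels within
    each locus (preserving locus pairing) ``n_permutations`` times.
    """
    if len(collections) < 2:
        raise ValidationError("need at least two collections to compare")
    if matrix.n_loci < 2:
        raise ValidationError("need at least two loci for a collection comparison")
    panels = {name: collection_panel(matrix, ids) for name, ids in collections.items()}
    names = list(panels)
    means = pd.DataFrame({name: p.mean(axis=0) for name, p in panels.items()}).T
    means.index.name = "Collection"

    rng = np.random.default_rng(seed)
    rows = []
    per_locus = {}
    for stat in PANEL_STATS:
        data = np.column_stack([panels[name][stat].to_numpy() for name in names])
        per_locus[stat] = pd.DataFrame(data, index=panels[names[0]].index, columns=names)
        f_obs = _f_statistic(data)
        df_b = data.shape[1] - 1
        df_w = data.size - data.shape[1]
        p_anova = 1.0 if f_obs == 0.0 else float(sps.f.sf(f_obs, df_b, df_w))
        p_perm = _permutation_p(data, f_obs, n_permutations, rng)
        rows.append({"stat": stat, "F": f_obs, "p_anova": p_anova, "p_perm": p_perm})
    tests = pd.DataFrame(rows).set_index("stat")
    return ComparisonReport(means=means, tests=tests, per_locus=per_locus,
                            n_permutations=n_permutations)


def _f_statistic(data: np.ndarray) -> float:
    # one-way ANOVA F for an (n_loci, n_groups) layout; 0 when degenerate
    col_means = data.mean(axis=0)
    if np.ptp(col_means) == 0.0:  # identical group means, incl. all-equal data
        return 0.0
    grand = data.mean()
    nl = data.shape[0]
    between = nl * np.sum((col_means - grand) ** 2)
    within = np.sum((data - data.mean(axis=0)) ** 2)
    df_b = data.shape[1] - 1
    df_w = data.size - data.shape[1]
    if within == 0.0:
        return 0.0 if between == 0.0 else np.inf
    return float((between / df_b) / (within / df_w))


def _permutation_p(
    data: np.ndarray, f_obs: float, n_permutations: int, rng: np.random.Generator
) -> float:
    if n_permutations < 1:
        return float("nan")
    count = 0
    work = data.copy()
    for _ in range(n_permutations):
        perm = rng.permuted(work, axis=1)
        if _f_statistic(perm) >= f_obs - 1e-12:
            count += 1
    return (1 + count) / (n_permutations + 1)
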