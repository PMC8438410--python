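"""Stepwise core-collection extraction, retention and pseudo-core comparison."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ssrcore import (
    GenotypeMatrix,
    compare_collections,
    collection_panel,
    random_cores,
    retention,
    simulate,
    stepwise_core,
    SimulationConfig,
)
from ssrcore.errors import ComputationError, ValidationError

from conftest import genotype_matrices


def _sim(n=40, seed=0, **kw):
    cfg = SimulationConfig(
        n_accessions=n,
        locus_allele_counts=(4, 3, 2, 4, 3),
        dirichlet_concentration=0.8,
        **kw,
    )
    return simulate(cfg, seed=seed)[0]


class TestStepwiseCore:
    def test_full_fraction_returns_everything(self):
        m = _sim(10)
        core = stepwise_core(m, target_fraction=1.0, seed=1)
        assert core.selected_ids == m.accession_ids
        assert core.rounds == []

    def test_duplicate_pairs_are_pruned_first(self):
        # two exact duplicate pairs; target half -> one of each pair kept
        m = GenotypeMatrix.from_cells(
            ["a1", "a2", "b1", "b2"],
            ["L1", "L2"],
            [["AA", "AB"], ["AA", "AB"], ["BB", "CC"], ["BB", "CC"]],
        )
        core = stepwise_core(m, target_fraction=0.5, seed=3)
        kept = set(core.selected_ids)
        assert len(kept & {"a1", "a2"}) == 1
        assert len(kept & {"b1", "b2"}) == 1

    def test_headline_size_arithmetic(self):
        # ceil(0.172 * 955) = 165; an exact 164 needs size=164
        assert math.ceil(0.172 * 955) == 165
        m = _sim(50)
        core = stepwise_core(m, target_fraction=0.172, seed=1)
        assert core.size == math.ceil(0.172 * 50)

    def test_exact_size_and_seed_reproducibility(self):
        m = _sim(40, seed=2)
        c1 = stepwise_core(m, size=13, seed=42)
        c2 = stepwise_core(m, size=13, seed=42)
        assert c1.selected_ids == c2.selected_ids
        assert c1.rounds == c2.rounds
        assert c1.size == 13

    def test_rounds_strictly_shrink_and_log_replays(self):
        m = _sim(40, seed=3)
        core = stepwise_core(m, size=11, seed=7)
        sizes = [r["n_before"] for r in core.rounds] + [core.size]
        assert all(a > b for a, b in zip(sizes, sizes[1:]))
        # replaying the removal log reproduces the selection
        current = list(m.accession_ids)
        for r in core.rounds:
            assert len(current) == r["n_before"]
            current = [a for a in current if a not in set(r["removed"])]
        assert current == core.selected_ids

    @given(st.integers(0, 50), st.floats(0.2, 1.0))
    def test_target_size_is_ceiling_of_fraction(self, seed, fraction):
        m = _sim(23, seed=seed % 5)
        core = stepwise_core(m, target_fraction=fraction, seed=seed)
        assert core.size == math.ceil(fraction * 23)

    def test_bad_targets_rejected(self):
        m = _sim(10)
        with pytest.raises(ValidationError):
            stepwise_core(m, target_fraction=0.5, size=5, seed=1)
        with pytest.raises(ValidationError):
            stepwise_core(m, size=11, seed=1)
        with pytest.raises(ValidationError):
            stepwise_core(m, seed=1)

    def test_retention_floor_guard_stops_early(self):
        m = _sim(40, seed=4)
        guarded = stepwise_core(m, size=2, seed=1, min_na_retention=99.0)
        assert guarded.stopped_by_floor
        assert guarded.size > 2
        assert guarded.retention["Na"] >= 99.0


class TestRandomCores:
    def test_distinct_subsets_reproducible_under_seed(self):
        m = _sim(30)
        r1 = random_cores(m, size=10, reps=3, seed=9)
        r2 = random_cores(m, size=10, reps=3, seed=9)
        assert r1 == r2
        assert len({tuple(sorted(ids)) for ids in r1}) == 3
        assert all(len(set(ids)) == 10 for ids in r1)

    def test_full_size_returns_every_accession(self):
        m = _sim(12)
        (ids,) = random_cores(m, size=12, reps=1, seed=0)
        assert sorted(ids) == sorted(m.accession_ids)

    def test_oversized_request_rejected(self):
        m = _sim(5)
        with pytest.raises(ValidationError):
            random_cores(m, size=6, reps=1, seed=0)


class TestRetention:
    def test_published_core_percentages(self):
        full = pd.Series({"Na": 3.7143, "Ho": 0.2382, "Nei": 0.4600})
        core = pd.Series({"Na": 3.5000, "Ho": 0.2351, "Nei": 0.5356})
        pct = retention(core, full)
        assert pct == {"Na": 94.2, "Ho": 98.7, "Nei": 116.4}

    def test_identical_collections_retain_everything(self):
        means = pd.Series({"Na": 3.0, "PIC": 0.4})
        assert retention(means, means) == {"Na": 100.0, "PIC": 100.0}

    def test_zero_full_mean_is_undefined(self):
        with pytest.raises(ComputationError):
            retention(pd.Series({"Ho": 0.1}), pd.Series({"Ho": 0.0}))


class TestComparison:
    def test_identical_collections_give_flat_test(self):
        m = _sim(30, seed=5)
        ids = list(m.accession_ids[:10])
        report = compare_collections(
            m, {"a": ids, "b": ids, "c": ids}, n_permutations=199, seed=1
        )
        assert (report.tests["F"] == 0.0).all()
        assert (report.tests["p_perm"] == 1.0).all()

    def test_dominant_collection_detected(self):
        # one collection strictly more diverse at every one of six loci
        hi_row = ["AB", "CD", "AC", "BD", "AD", "BC"]
        cells_hi = [hi_row, ["CD", "AB", "BD", "AC", "BC", "AD"],
                    ["AC", "BD", "AB", "CD", "BC", "AD"],
                    ["BD", "AC", "CD", "AB", "AD", "BC"]]
        cells_lo = [["AA"] * 6] * 4
        m = GenotypeMatrix.from_cells(
            [f"h{i}" for i in range(4)] + [f"l{i}" for i in range(4)],
            [f"L{j}" for j in range(1, 7)],
            cells_hi + cells_lo,
        )
        hi = [f"h{i}" for i in range(4)]
        lo = [f"l{i}" for i in range(4)]
        report = compare_collections(m, {"hi": hi, "lo": lo}, n_permutations=999, seed=2)
        assert report.means.loc["hi", "PIC"] > report.means.loc["lo", "PIC"]
        assert report.tests.loc["PIC", "p_perm"] < 0.05

    def test_needs_two_collections_and_two_loci(self):
        m = _sim(10)
        with pytest.raises(ValidationError):
            compare_collections(m, {"only": list(m.accession_ids)})
        m1 = GenotypeMatrix.from_cells(["a", "b"], ["L1"], [["AA"], ["AB"]])
        with pytest.raises(ValidationError):
            compare_collections(m1, {"a": ["a"], "b": ["b"]})
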