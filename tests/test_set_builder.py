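"""Sextuplet construction, family decomposition and the ds filter."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dupaccel import decompose_family, filter_ds, find_sextuplets, ng86_dnds, simulate_family
from dupaccel.set_builder import FILTER_COMPARISONS, FamilyCluster, SextupletSet
from dupaccel.simulate import make_homology_fixture


def _make_set(set_id: str) -> SextupletSet:
    return SextupletSet(
        genes={r: f"{set_id}_{r}" for r in ("C", "D", "M1", "M2", "R1", "R2")},
        source_cluster=set_id,
    )


class TestFindSextuplets:
    def test_single_valid_pattern(self):
        table, _ = make_homology_fixture(n_valid=1, seed=0)
        sets, clusters = find_sextuplets(table)
        assert len(sets) == 1 and not clusters
        assert set(sets[0].genes) == {"C", "D", "M1", "M2", "R1", "R2"}

    def test_valid_and_invalid_patterns(self):
        table, truth = make_homology_fixture(n_valid=10, n_dogcow_many=3, n_missing_rat=2, seed=7)
        sets, clusters = find_sextuplets(table)
        assert len(sets) == 10
        assert {s.genes["D"] for s in sets} == set(truth["valid_dog_genes"])

    def test_missing_rat_ortholog_yields_no_set(self):
        table, _ = make_homology_fixture(n_valid=0, n_missing_rat=1, seed=1)
        sets, clusters = find_sextuplets(table)
        assert not sets and not clusters

    def test_multi_paralog_families_passed_to_decomposition(self):
        table, truth = make_homology_fixture(n_valid=2, n_multi=3, paralogs_per_multi=4, seed=2)
        sets, clusters = find_sextuplets(table)
        assert len(sets) == 2
        assert {c.dog for c in clusters} == set(truth["multi_dog_genes"])
        assert all(len(c.pairs) == 4 for c in clusters)

    def test_malformed_relation_rejected(self):
        table, _ = make_homology_fixture(n_valid=1, seed=0)
        table.loc[0, "relation"] = "sort-of-orthologous"
        with pytest.raises(ValueError, match="relation"):
            find_sextuplets(table)


def _cluster(paralogs):
    return FamilyCluster(
        dog="dogX", cow="cowX", pairs=[(p, f"rat_{p}") for p in paralogs]
    )


class TestDecomposeFamily:
    def test_two_paralogs_one_set(self):
        out = decompose_family(_cluster(["ma", "mb"]), {frozenset(("ma", "mb")): 0.2})
        assert len(out) == 1
        assert out[0].duplication_rank == 1

    def test_smallest_ds_pair_first(self):
        ds = {
            frozenset(("ma", "mb")): 0.1,
            frozenset(("ma", "mc")): 0.4,
            frozenset(("mb", "mc")): 0.45,
        }
        out = decompose_family(_cluster(["ma", "mb", "mc"]), ds, seed=0)
        assert {out[0].genes["M1"], out[0].genes["M2"]} == {"ma", "mb"}
        assert len(out) == 2

    @pytest.mark.parametrize("k", [2, 3, 4, 5, 6])
    def test_k_paralogs_emit_k_minus_1_sets(self, k):
        paralogs = [f"m{i}" for i in range(k)]
        rng = np.random.default_rng(k)
        ds = {
            frozenset(pair): float(rng.uniform(0.05, 0.9))
            for pair in itertools.combinations(paralogs, 2)
        }
        out = decompose_family(_cluster(paralogs), ds, seed=1)
        assert len(out) == k - 1
        assert [s.duplication_rank for s in out] == list(range(1, k))

    def test_removal_is_seed_reproducible(self):
        paralogs = ["ma", "mb", "mc", "md"]
        ds = {
            frozenset(p): 0.1 * (i + 1)
            for i, p in enumerate(itertools.combinations(paralogs, 2))
        }
        a = decompose_family(_cluster(paralogs), ds, seed=42)
        b = decompose_family(_cluster(paralogs), ds, seed=42)
        assert [s.genes for s in a] == [s.genes for s in b]

    def test_ties_broken_lexicographically(self, caplog):
        ds = {
            frozenset(("ma", "mb")): 0.2,
            frozenset(("ma", "mc")): 0.2,
            frozenset(("mb", "mc")): 0.2,
        }
        with caplog.at_level("INFO"):
            out = decompose_family(_cluster(["ma", "mb", "mc"]), ds, seed=0)
        assert {out[0].genes["M1"], out[0].genes["M2"]} == {"ma", "mb"}
        assert any("tie" in rec.message for rec in caplog.records)

    def test_recovers_simulated_duplication_order(self):
        """End-to-end: ds measured on simulated nested duplications recovers
        the construction's most recent pair."""
        seqs, truth = simulate_family(3, [0.1, 0.4], seed=9, n_codons=400)
        ds = {
            frozenset((a, b)): ng86_dnds(seqs[a], seqs[b]).ds
            for a, b in itertools.combinations(sorted(seqs), 2)
        }
        cluster = FamilyCluster(
            dog="dogX", cow="cowX", pairs=[(p, f"rat_{p}") for p in sorted(seqs)]
        )
        out = decompose_family(cluster, ds, seed=0)
        assert {out[0].genes["M1"], out[0].genes["M2"]} == set(truth["most_recent_pair"])


class TestFilterDs:
    def _ds(self, set_id, **overrides):
        base = {c: 0.3 for c in FILTER_COMPARISONS}
        base.update(overrides)
        return {f"{set_id}.1": base}

    def test_excess_paralog_ds_removed(self):
        s = _make_set("a")
        kept, log = filter_ds([s], self._ds("a", **{"M1-M2": 1.2}))
        assert not kept
        assert log.iloc[0]["reason"] == "ds_above_threshold"
        assert log.iloc[0]["comparison"] == "M1-M2"

    def test_zero_divergence_retained(self):
        s = _make_set("b")
        kept, _ = filter_ds([s], {f"b.1": {c: 0.0 for c in FILTER_COMPARISONS}})
        assert kept == [s]

    def test_boundary_value_retained(self):
        s = _make_set("c")
        kept, _ = filter_ds([s], self._ds("c", **{"C-D": 1.0}))
        assert kept == [s]  # strict inequality: ds == threshold passes

    def test_missing_comparison_rejected_as_incomplete(self):
        s = _make_set("d")
        ds = self._ds("d")
        del ds["d.1"]["R1-R2"]
        kept, log = filter_ds([s], ds)
        assert not kept
        assert log.iloc[0]["reason"] == "incomplete"

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0.0, 2.0), min_size=5, max_size=5), st.permutations(range(4)))
    def test_idempotent_and_order_independent(self, values, order):
        sets = [_make_set(f"s{i}") for i in range(4)]
        ds = {
            s.set_id: dict(zip(FILTER_COMPARISONS, np.roll(values, i)))
            for i, s in enumerate(sets)
        }
        kept1, _ = filter_ds(sets, ds)
        kept_again, _ = filter_ds(kept1, ds)
        assert kept_again == kept1
        shuffled = [sets[i] for i in order]
        kept2, _ = filter_ds(shuffled, ds)
        assert {s.set_id for s in kept2} == {s.set_id for s in kept1}
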