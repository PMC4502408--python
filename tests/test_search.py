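"""Block-wise consistency search and DE-gene merging."""

import random

import pytest

from bruteforce import block_search_literal, random_ranked_duo
from repde import (
    RankedList,
    SearchParams,
    block_search,
    merge_de_sets,
    multi_pair_de,
    reproducible_de,
)
from repde.scores import RankedEntry
from repde.search import DEGeneSet


def ranked_from(entries, pair_id="p"):
    n = len(entries)
    return RankedList(pair_id, "PD", [
        RankedEntry(g, 1.0, float(n - i), d) for i, (g, d) in enumerate(entries)
    ])


class TestBlockSearch:
    def test_identical_lists_return_everything(self, rng):
        entries = [(f"g{i:04d}", rng.choice(["up", "down"])) for i in range(1000)]
        r = ranked_from(entries)
        out = block_search(r, r, SearchParams(ct=0.9, init_step=300))
        assert out == dict(entries)

    def test_disjoint_lists_return_nothing(self):
        a = ranked_from([(f"a{i}", "up") for i in range(40)])
        b = ranked_from([(f"b{i}", "up") for i in range(40)])
        assert block_search(a, b, SearchParams(ct=0.9, init_step=10)) == {}

    def test_engineered_halving_recovers_top_of_failed_block(self):
        # identical rankings; agreement engineered per gene so that with
        # k=10 block 1 passes (1.0), block 2 fails (0.8), the lookahead
        # block also fails, and halving to k=5 recovers genes 10-14
        agree = [True] * 15 + [True, True, True, False, False] \
            + [True] * 8 + [False] * 2 + [False] * 10
        a_entries = [(f"g{i:02d}", "up") for i in range(40)]
        b_entries = [(f"g{i:02d}", "up" if agree[i] else "down") for i in range(40)]
        a, b = ranked_from(a_entries), ranked_from(b_entries)
        params = SearchParams(ct=0.9, init_step=10)
        out = block_search(a, b, params)
        oracle = block_search_literal(a_entries, b_entries, 0.9, 10, 1)
        assert out == oracle
        assert {f"g{i:02d}" for i in range(15)} <= set(out)  # block 1 + recovered half
        # bottom of the failed block stays out, even its agreeing genes
        assert not {f"g{i:02d}" for i in range(15, 20)} & set(out)

    def test_lookahead_does_not_admit_failed_block(self):
        # block 2 fails, block 3 passes: block 2's agreeing genes must not
        # be admitted wholesale on the lookahead resume
        agree = [True] * 10 + [True] * 5 + [False] * 5 + [True] * 10 + [False] * 10
        a_entries = [(f"g{i:02d}", "up") for i in range(40)]
        b_entries = [(f"g{i:02d}", "up" if agree[i] else "down") for i in range(40)]
        a, b = ranked_from(a_entries), ranked_from(b_entries)
        out = block_search(a, b, SearchParams(ct=0.9, init_step=10, min_step=10))
        # with halving disabled (min_step=10) the failed block is skipped
        assert {f"g{i:02d}" for i in range(10)} <= set(out)
        assert {f"g{i:02d}" for i in range(20, 30)} <= set(out)
        assert not {f"g{i:02d}" for i in range(10, 20)} & set(out)
        assert out == block_search_literal(a_entries, b_entries, 0.9, 10, 10)

    @pytest.mark.parametrize("trial_block", range(4))
    def test_matches_literal_transcription_on_random_instances(self, trial_block):
        # 4 x 50 random instances against the literal step-by-step oracle
        rng = random.Random(1000 + trial_block)
        for _ in range(50):
            n = rng.randint(4, 60)
            k = rng.randint(2, 10)
            ct = rng.choice([0.6, 0.7, 0.8, 0.9, 0.95])
            share = rng.uniform(0.2, 1.0)
            a_entries, b_entries = random_ranked_duo(rng, n, share)
            got = block_search(
                ranked_from(a_entries), ranked_from(b_entries),
                SearchParams(ct=ct, init_step=k),
            )
            want = block_search_literal(a_entries, b_entries, ct, k)
            assert got == want, (n, k, ct, share)

    def test_output_genes_lie_in_both_lists_with_agreeing_direction(self):
        rng = random.Random(99)
        a_entries, b_entries = random_ranked_duo(rng, 50, 0.7)
        out = block_search(
            ranked_from(a_entries), ranked_from(b_entries),
            SearchParams(ct=0.6, init_step=8),
        )
        da, db = dict(a_entries), dict(b_entries)
        for g, d in out.items():
            assert da[g] == db[g] == d

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SearchParams(ct=0.4)
        with pytest.raises(ValueError):
            SearchParams(init_step=1)

    def test_empty_list_rejected(self):
        r = ranked_from([("g", "up")])
        with pytest.raises(ValueError):
            block_search(RankedList("q", "PD", []), r)


class TestReproducibleDE:
    def test_identical_lists(self, rng):
        entries = [(f"g{i}", rng.choice(["up", "down"])) for i in range(600)]
        r = ranked_from(entries, "A")
        de = reproducible_de(r, ranked_from(entries, "B"))
        assert de.genes == dict(entries)
        assert de.dropped_conflicts == []

    def test_union_covers_both_search_directions(self):
        rng = random.Random(7)
        a_entries, b_entries = random_ranked_duo(rng, 60, 0.8)
        a, b = ranked_from(a_entries, "A"), ranked_from(b_entries, "B")
        params = SearchParams(ct=0.6, init_step=10)
        de = reproducible_de(a, b, params)
        ab = block_search(a, b, params)
        ba = block_search(b, a, params)
        assert set(de.genes) == set(ab) | set(ba)

    def test_random_directions_admit_almost_nothing(self):
        # 50% direction noise: the first block fails and halving exhausts
        rng = random.Random(13)
        sizes = []
        for _ in range(40):
            a_entries, b_entries = random_ranked_duo(rng, 400, 1.0)
            de = reproducible_de(
                ranked_from(a_entries, "A"), ranked_from(b_entries, "B"),
                SearchParams(ct=0.9, init_step=100),
            )
            sizes.append(len(de))
        assert sum(sizes) / len(sizes) < 10


class TestMultiPairMerge:
    def test_three_identical_lists(self, rng):
        entries = [(f"g{i}", rng.choice(["up", "down"])) for i in range(500)]
        lists = [ranked_from(entries, p) for p in "ABC"]
        de = multi_pair_de(lists, SearchParams(ct=0.9, init_step=100))
        assert de.genes == dict(entries)
        assert de.dropped_conflicts == []

    def test_direction_conflict_dropped(self):
        one = DEGeneSet(genes={"g1": "up", "g2": "up"},
                        provenance={"g1": ["A~B"], "g2": ["A~B"]})
        two = DEGeneSet(genes={"g1": "down", "g3": "down"},
                        provenance={"g1": ["A~C"], "g3": ["A~C"]})
        merged = merge_de_sets([one, two])
        assert merged.dropped_conflicts == ["g1"]
        assert set(merged.genes) == {"g2", "g3"}

    def test_fewer_than_two_lists_rejected(self):
        r = ranked_from([("g", "up")])
        with pytest.raises(ValueError):
            multi_pair_de([r])
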