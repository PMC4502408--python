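"""Block-wise consistency search for reproducible DE genes.

Given two ranked gene lists from independent sample pairs (list A and
list B, each sorted by descending PD or PFC magnitude), the search walks
list A block by block and admits a block's genes when the dysregulation
directions of the genes it shares with the *cumulative top prefix* of
list B agree at or above the consistency threshold CT.  On a failing
block it first looks one block ahead (a short block may fail only because
it shares too few genes to give a stable score); if the lookahead also
fails, the step is halved and the tail of both lists is re-partitioned at
the finer granularity from the failed block onward, recovering the
higher-ranked part of the failed block.  The search exits when the step
can no longer be halved or a failing block shares no genes with the
prefix.

Running the search in both directions (A against B's prefix, B against
A's prefix) and merging the two results gives the reproducible DE genes
of the pair-duo; across several duos, genes whose directions conflict
between any two duo results are deleted from the final merge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import pandas as pd

from .scores import RankedList

DEFAULT_CT = 0.90
DEFAULT_INIT_STEP = 300


@dataclass(frozen=True)
class SearchParams:
    """Tuning knobs of the block search.

    ct
        Consistency threshold in (0.5, 1]; a block is accepted when the
        direction-agreement fraction of its shared genes is >= ct.
    init_step
        Initial block size (genes per block), >= 2.
    min_step
        Smallest usable block size; halving stops once the step would
        fall below max(min_step, 2).
    """

    ct: float = DEFAULT_CT
    init_step: int = DEFAULT_INIT_STEP
    min_step: int = 1

    def __post_init__(self) -> None:
        if not 0.5 < self.ct <= 1.0:
            raise ValueError(f"ct must lie in (0.5, 1], got {self.ct}")
        if self.init_step < 2:
            raise ValueError(f"init_step must be >= 2, got {self.init_step}")
        if self.min_step < 1:
            raise ValueError(f"min_step must be >= 1, got {self.min_step}")


@dataclass
class BlockDecision:
    """One audit-log row: what the search did at one block evaluation."""

    a_start: int  # 0-based rank of the block's first gene in list A
    a_end: int
    step: int
    k_shared: int
    s_same: int
    score: float | None
    action: str  # accept | lookahead-accept | fail | halve | exit-no-overlap | exit-min-step


@dataclass
class DEGeneSet:
    """Reproducible DE genes, each with a single consistent direction."""

    genes: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, list[str]] = field(default_factory=dict)
    dropped_conflicts: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": list(self.genes),
                "direction": [self.genes[g] for g in self.genes],
                "n_supporting_comparisons": [
                    len(self.provenance.get(g, [])) for g in self.genes
                ],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _block_consistency(dir_a_order: list[tuple[str, str]],
                       dir_b: dict[str, str],
                       a_start: int, a_end: int, b_end: int,
                       b_rank: dict[str, int]) -> tuple[list[str], int]:
    """Shared same-direction genes and shared count for A[a_start:a_end] vs B[:b_end]."""
    same: list[str] = []
    k = 0
    for g, d in dir_a_order[a_start:a_end]:
        rb = b_rank.get(g)
        if rb is None or rb >= b_end:
            continue
        k += 1
        if dir_b[g] == d:
            same.append(g)
    return same, k


def block_search(list_a: RankedList, list_b: RankedList,
                 params: SearchParams = SearchParams(),
                 log: list[BlockDecision] | None = None) -> dict[str, str]:
    """Genes of list A reproducible in the top-ranked prefix of list B (degAB).

    Returns a mapping gene -> direction covering every accepted block's
    shared, direction-concordant genes.  ``log`` (if given) collects one
    :class:`BlockDecision` per block evaluation for auditability.
    """
    if len(list_a) == 0 or len(list_b) == 0:
        raise ValueError("both ranked lists must be non-empty")
    a_entries = [(e.gene_id, e.direction) for e in list_a]
    dir_b = list_b.directions()
    b_rank = {e.gene_id: i for i, e in enumerate(list_b)}
    n = len(a_entries)

    accepted: dict[str, str] = {}
    dir_a = dict(a_entries)
    pos = 0
    k = params.init_step
    min_usable = max(params.min_step, 2)

    def record(a_start, a_end, shared_k, same, action):
        if log is not None:
            score = len(same) / shared_k if shared_k else None
            log.append(BlockDecision(a_start, a_end, k, shared_k,
                                     len(same), score, action))

    while pos < n:
        end = min(pos + k, n)
        same, shared_k = _block_consistency(a_entries, dir_b, pos, end, end, b_rank)
        if shared_k and len(same) / shared_k >= params.ct:
            record(pos, end, shared_k, same, "accept")
            for g in same:
                accepted[g] = dir_a[g]
            pos = end
            continue
        record(pos, end, shared_k, same, "fail")

        # lookahead one block: a failing block may merely be too sparse
        la_start, la_end = end, min(end + k, n)
        if la_start < n:
            la_same, la_k = _block_consistency(
                a_entries, dir_b, la_start, la_end, la_end, b_rank
            )
            if la_k and len(la_same) / la_k >= params.ct:
                # resume from the lookahead block; the failed block itself
                # is NOT admitted (its genes may return via step-halving)
                record(la_start, la_end, la_k, la_same, "lookahead-accept")
                for g in la_same:
                    accepted[g] = dir_a[g]
                pos = la_end
                continue
            record(la_start, la_end, la_k, la_same, "fail")

        if shared_k == 0:
            record(pos, end, 0, [], "exit-no-overlap")
            break
        if k // 2 < min_usable:
            record(pos, end, shared_k, same, "exit-min-step")
            break
        k //= 2
        record(pos, min(pos + k, n), shared_k, same, "halve")
        # re-partition the tails of both lists from the failed block onward

    return accepted


def reproducible_de(list_a: RankedList, list_b: RankedList,
                    params: SearchParams = SearchParams(),
                    log: list[BlockDecision] | None = None) -> DEGeneSet:
    """Merge degAB and degBA into the pair-duo's reproducible DE gene set."""
    deg_ab = block_search(list_a, list_b, params, log=log)
    deg_ba = block_search(list_b, list_a, params, log=log)
    merged = dict(deg_ab)
    for g, d in deg_ba.items():
        if g in merged and merged[g] != d:  # impossible: membership needs agreement
            raise AssertionError(f"direction conflict within a pair-duo for {g}")
        merged[g] = d
    label = f"{list_a.pair_id} ~ {list_b.pair_id}"
    return DEGeneSet(
        genes=merged,
        provenance={g: [label] for g in merged},
    )


def multi_pair_de(ranked_lists: list[RankedList],
                  params: SearchParams = SearchParams()) -> DEGeneSet:
    """Reproducible DE genes across every duo of independent sample pairs.

    Runs the two-way block search on every unordered duo and merges the
    duo results, deleting any gene whose direction differs between two
    duo results.
    """
    if len(ranked_lists) < 2:
        raise ValueError("need ranked lists from at least two sample pairs")
    duo_sets = [
        reproducible_de(a, b, params) for a, b in combinations(ranked_lists, 2)
    ]
    return merge_de_sets(duo_sets)


def merge_de_sets(de_sets: list[DEGeneSet]) -> DEGeneSet:
    """Union of DE sets with deletion of direction-conflicted genes."""
    direction: dict[str, str] = {}
    provenance: dict[str, list[str]] = {}
    conflicted: set[str] = set()
    for ds in de_sets:
        for g, d in ds.genes.items():
            if g in direction and direction[g] != d:
                conflicted.add(g)
            direction.setdefault(g, d)
            provenance.setdefault(g, []).extend(ds.provenance.get(g, []))
    for g in conflicted:
        direction.pop(g, None)
        provenance.pop(g, None)
    return DEGeneSet(
        genes=direction,
        provenance=provenance,
        dropped_conflicts=sorted(conflicted),
    )


def decisions_frame(log: list[BlockDecision]) -> pd.DataFrame:
    """Audit log as a table (one row per block decision)."""
    return pd.DataFrame([vars(d) for d in log])


def significance_of_threshold(ct: float, k: int, p_e: float = 0.5) -> float:
    """Binomial tail log-p of just meeting CT on a k-gene block (diagnostic)."""
    from .consistency import binom_tail_logp

    return binom_tail_logp(math.ceil(ct * k), k, p_e)
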