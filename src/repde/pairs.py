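"""Enumeration and reproducibility-based selection of independent sample pairs.

With r resistant and s sensitive technical replicates there are r*s
resistant-sensitive pairs; two pairs are *independent* when they share no
sample.  Selection proceeds in three steps: rank genes within every pair,
seed with the independent pair-duo whose top-n direction consistency is
most significant, then admit remaining pairs one by one while they are
independent of every selected pair and significantly consistent
(p < 0.01) with at least one of them.  Pairs left over are reported with
an exclusion reason, which flags replicates carrying unreliable
measurements.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .consistency import REPRODUCIBILITY_ALPHA, ConsistencyResult, topn_consistency
from .matrix import ExpressionMatrix
from .scores import PD_RULE, PFC_RULE, RankedList, SamplePair, pd_scores, pfc_scores

logger = logging.getLogger(__name__)

DEFAULT_TOP_N = 300


@dataclass
class PairSelectionResult:
    selected_pairs: list[SamplePair]
    excluded_pairs: list[tuple[SamplePair, str]]
    comparisons: list[tuple[str, str, ConsistencyResult]]
    top_n: int
    ranked_lists: dict[str, RankedList] = field(default_factory=dict)

    def report_frame(self) -> pd.DataFrame:
        """Per-comparison report with the k/s/score/p columns of the run log."""
        rows = []
        by_id = {p.pair_id: p for p in self.selected_pairs}
        by_id.update({p.pair_id: p for p, _ in self.excluded_pairs})
        for id_a, id_b, res in self.comparisons:
            rows.append(
                {
                    "pair_a": id_a,
                    "pair_b": id_b,
                    "K": res.k,
                    "S": res.s,
                    "S/K(%)": res.score_display(),
                    "p": res.p_display(),
                    "selected_a": id_a in {p.pair_id for p in self.selected_pairs},
                    "selected_b": id_b in {p.pair_id for p in self.selected_pairs},
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.report_frame().to_csv(path, sep="\t", index=False)


def enumerate_pairs(m: ExpressionMatrix) -> list[SamplePair]:
    """All r*s resistant-sensitive pairs, in R-sample x S-sample order."""
    r_ids, s_ids = m.samples_of("R"), m.samples_of("S")
    if not r_ids or not s_ids:
        raise ValueError("both phenotypes need at least one sample")
    pairs = [SamplePair(r, s) for r in r_ids for s in s_ids]
    if len(pairs) == 1:
        logger.warning("only one sample pair exists; no independent comparison possible")
    return pairs


def independent(pair_a: SamplePair, pair_b: SamplePair) -> bool:
    """True iff the two pairs share no sample (four distinct sample IDs)."""
    return not pair_a.overlaps(pair_b)


def rank_all_pairs(m: ExpressionMatrix, score_rule: str) -> dict[str, RankedList]:
    """Ranked gene list for every enumerated pair under the given score rule."""
    if score_rule == PD_RULE:
        scorer = pd_scores
    elif score_rule == PFC_RULE:
        scorer = pfc_scores
    else:
        raise ValueError(f"score_rule must be {PD_RULE!r} or {PFC_RULE!r}")
    return {p.pair_id: scorer(m, p) for p in enumerate_pairs(m)}


def _duo_sort_key(res: ConsistencyResult, id_a: str, id_b: str):
    # most significant p first; ties by higher score, then lexicographic ids
    score = res.score if res.evaluable else -1.0
    return (res.log_p, -score, id_a, id_b)


def select_reproducible_pairs(
    m: ExpressionMatrix,
    score_rule: str = PD_RULE,
    top_n: int = DEFAULT_TOP_N,
    alpha: float = REPRODUCIBILITY_ALPHA,
) -> PairSelectionResult:
    """Select the subset of mutually independent, reproducible sample pairs.

    The seed duo is the independent pair-duo with the most significant
    top-``top_n`` consistency p-value; further pairs are admitted greedily
    (most significant qualifying candidate first) while independent of all
    selected pairs and consistent (p < ``alpha``) with at least one.
    """
    pairs = enumerate_pairs(m)
    ranked = rank_all_pairs(m, score_rule)
    by_id = {p.pair_id: p for p in pairs}

    duos: dict[tuple[str, str], ConsistencyResult] = {}
    for i, pa in enumerate(pairs):
        for pb in pairs[i + 1:]:
            if independent(pa, pb):
                duos[(pa.pair_id, pb.pair_id)] = topn_consistency(
                    ranked[pa.pair_id], ranked[pb.pair_id], top_n
                )
    if not duos:
        raise ValueError(
            "insufficient replicates: no two independent sample pairs exist"
        )

    comparisons = [(a, b, res) for (a, b), res in duos.items()]
    seed_a, seed_b = min(duos, key=lambda ab: _duo_sort_key(duos[ab], *ab))
    selected = [by_id[seed_a], by_id[seed_b]]

    def duo_result(id_a: str, id_b: str) -> ConsistencyResult | None:
        return duos.get((id_a, id_b)) or duos.get((id_b, id_a))

    remaining = [p for p in pairs if p.pair_id not in (seed_a, seed_b)]
    while True:
        candidates = []
        for p in remaining:
            if any(p.overlaps(q) for q in selected):
                continue
            results = [duo_result(p.pair_id, q.pair_id) for q in selected]
            results = [r for r in results if r is not None]
            qualifying = [r for r in results
                          if r.evaluable and r.log_p < math.log(alpha)]
            if qualifying:
                best = min(qualifying, key=lambda r: r.log_p)
                candidates.append((best, p))
        if not candidates:
            break
        best_res, best_pair = min(
            candidates, key=lambda t: _duo_sort_key(t[0], t[1].pair_id, "")
        )
        if any(
            r is not None and (not r.evaluable or r.log_p >= math.log(alpha))
            for r in (duo_result(best_pair.pair_id, q.pair_id) for q in selected)
        ):
            logger.warning(
                "pair %s admitted though inconsistent with some selected pair",
                best_pair.pair_id,
            )
        selected.append(best_pair)
        remaining = [p for p in remaining if p.pair_id != best_pair.pair_id]

    excluded = []
    for p in remaining:
        reason = (
            "not-independent"
            if any(p.overlaps(q) for q in selected)
            else "inconsistent"
        )
        excluded.append((p, reason))

    return PairSelectionResult(
        selected_pairs=selected,
        excluded_pairs=excluded,
        comparisons=comparisons,
        top_n=top_n,
        ranked_lists=ranked,
    )
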