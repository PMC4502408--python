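"""Per-pair gene scoring: pairwise difference (PD) and pairwise fold change (PFC).

A *sample pair* couples one drug-resistant (R) replicate with one
drug-sensitive (S) replicate and is treated as one experiment.  For each
gene the pair yields either

* ``PD  = E_R - E_S``  (linear-scale difference), direction up iff PD > 0, or
* ``PFC = E_R / E_S``  (linear-scale ratio), direction up iff PFC > 1,

and genes are ranked by descending score magnitude.  For PFC the ranking
magnitude is the symmetric fold change ``max(PFC, 1/PFC)`` so that a 4-fold
drop ranks level with a 4-fold rise.  Genes with PD = 0 (or PFC = 1) carry
no direction and are excluded from the ranked list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

UP = "up"
DOWN = "down"

PD_RULE = "PD"
PFC_RULE = "PFC"


@dataclass(frozen=True)
class SamplePair:
    """One resistant replicate paired with one sensitive replicate."""

    r_sample: str
    s_sample: str
    pair_id: str = ""

    def __post_init__(self) -> None:
        if self.r_sample == self.s_sample:
            raise ValueError("a pair must couple two distinct samples")
        if not self.pair_id:
            object.__setattr__(self, "pair_id", f"{self.r_sample} VS {self.s_sample}")

    @property
    def samples(self) -> frozenset[str]:
        return frozenset((self.r_sample, self.s_sample))

    def overlaps(self, other: "SamplePair") -> bool:
        return bool(self.samples & other.samples)


@dataclass(frozen=True)
class RankedEntry:
    gene_id: str
    score: float
    magnitude: float
    direction: str


@dataclass
class RankedList:
    """Genes of one pair sorted by descending score magnitude.

    Entries are strictly ordered by ``(-magnitude, gene_id)``; ties in
    magnitude are broken by lexicographic gene ID for determinism.
    """

    pair_id: str
    score_rule: str
    entries: list[RankedEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[RankedEntry]:
        return iter(self.entries)

    def top(self, n: int) -> "RankedList":
        if n < 1:
            raise ValueError("n must be >= 1")
        return RankedList(self.pair_id, self.score_rule, self.entries[:n])

    def directions(self) -> dict[str, str]:
        """Gene -> dysregulation direction, in rank order."""
        return {e.gene_id: e.direction for e in self.entries}

    def gene_ids(self) -> list[str]:
        return [e.gene_id for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "rank": np.arange(1, len(self.entries) + 1),
                "gene_id": [e.gene_id for e in self.entries],
                "score": [e.score for e in self.entries],
                "magnitude": [e.magnitude for e in self.entries],
                "direction": [e.direction for e in self.entries],
            }
        )
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _ranked(genes: np.ndarray, score: np.ndarray, magnitude: np.ndarray,
            up_mask: np.ndarray, keep: np.ndarray,
            pair_id: str, rule: str) -> RankedList:
    genes, score, magnitude, up_mask = (a[keep] for a in (genes, score, magnitude, up_mask))
    # sort by magnitude descending, then gene_id ascending (deterministic ties)
    order = sorted(range(len(genes)), key=lambda i: (-magnitude[i], genes[i]))
    entries = [
        RankedEntry(str(genes[i]), float(score[i]), float(magnitude[i]),
                    UP if up_mask[i] else DOWN)
        for i in order
    ]
    return RankedList(pair_id, rule, entries)


def pd_scores(m: ExpressionMatrix, pair: SamplePair) -> RankedList:
    """Rank genes of one pair by absolute pairwise difference ``E_R - E_S``."""
    er = m.column(pair.r_sample).to_numpy(dtype=float)
    es = m.column(pair.s_sample).to_numpy(dtype=float)
    genes = np.asarray(m.gene_ids, dtype=object)
    score = er - es
    return _ranked(genes, score, np.abs(score), score > 0, score != 0,
                   pair.pair_id, PD_RULE)


def pfc_scores(m: ExpressionMatrix, pair: SamplePair) -> RankedList:
    """Rank genes of one pair by symmetric pairwise fold change ``E_R / E_S``."""
    er = m.column(pair.r_sample).to_numpy(dtype=float)
    es = m.column(pair.s_sample).to_numpy(dtype=float)
    genes = np.asarray(m.gene_ids, dtype=object)
    for vals, sid in ((er, pair.r_sample), (es, pair.s_sample)):
        if (vals <= 0).any():
            bad = genes[vals <= 0][0]
            raise ValueError(
                f"non-positive intensity for gene {bad!r} in sample {sid!r}; "
                "apply floor_values first"
            )
    score = er / es
    magnitude = np.maximum(score, 1.0 / score)
    return _ranked(genes, score, magnitude, score > 1, score != 1,
                   pair.pair_id, PFC_RULE)


def fc_baseline(m: ExpressionMatrix) -> RankedList:
    """Conventional fold-change ranking: mean(R samples) / mean(S samples).

    Provided as a comparison baseline only; it has no reproducibility
    control and is biased toward genes with low expression in both groups.
    """
    r_ids, s_ids = m.samples_of("R"), m.samples_of("S")
    if not r_ids or not s_ids:
        raise ValueError("need at least one sample per phenotype")
    er = m.values[r_ids].mean(axis=1).to_numpy(dtype=float)
    es = m.values[s_ids].mean(axis=1).to_numpy(dtype=float)
    genes = np.asarray(m.gene_ids, dtype=object)
    if (er <= 0).any() or (es <= 0).any():
        bad = genes[(er <= 0) | (es <= 0)][0]
        raise ValueError(f"non-positive mean intensity for gene {bad!r}")
    score = er / es
    magnitude = np.maximum(score, 1.0 / score)
    return _ranked(genes, score, magnitude, score > 1, score != 1,
                   "FC", "FC")
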