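"""Hypergeometric gene-set over-representation with BH FDR control.

For a DE list of K genes drawn from a universe of N measured genes, the
chance of seeing at least X of them inside a gene set of size M is the
upper tail of the hypergeometric distribution,

    P(count >= X) = 1 - sum_{i<X} C(M, i) C(N-M, K-i) / C(N, K),

one p per gene set, adjusted across sets by the Benjamini-Hochberg
step-up procedure at a 5% false-discovery-rate level by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .search import DEGeneSet

logger = logging.getLogger(__name__)

DEFAULT_FDR_LEVEL = 0.05


@dataclass
class GeneSetCollection:
    """Named gene sets over a background universe of measured genes."""

    sets: dict[str, tuple[str, frozenset[str]]]  # set_id -> (name, members)
    universe: frozenset[str]

    def __post_init__(self) -> None:
        self.universe = frozenset(self.universe)
        restricted = {}
        for set_id, (name, members) in self.sets.items():
            kept = frozenset(members) & self.universe
            if kept:
                restricted[set_id] = (name, kept)
        self.sets = restricted

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path, universe: set[str] | None = None) -> GeneSetCollection:
    """Read a GMT file (set_id TAB description TAB member genes...).

    When ``universe`` is None the union of all set members is used as the
    background; pass the measured genes of the dataset for a proper test.
    """
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            set_id, name, members = parts[0], parts[1], frozenset(
                g for g in parts[2:] if g
            )
            if members:
                sets[set_id] = (name, members)
    if not sets:
        raise ValueError(f"{path}: no gene sets parsed")
    if universe is None:
        universe = set().union(*(m for _, m in sets.values()))
    return GeneSetCollection(sets=sets, universe=frozenset(universe))


def write_gmt(gsc: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_id, (name, members) in gsc.sets.items():
            fh.write("\t".join([set_id, name, *sorted(members)]) + "\n")


def hypergeom_test(x: int, m: int, k: int, n: int) -> float:
    """Upper-tail hypergeometric p-value P(count >= x).

    x DE genes inside a set of m genes, with a DE list of k genes drawn
    from a universe of n genes.
    """
    if not (0 <= x <= min(m, k)) or m > n or k > n or min(m, k, n) < 0:
        raise ValueError(f"inconsistent counts: X={x}, M={m}, K={k}, N={n}")
    if x == 0:
        return 1.0
    return float(stats.hypergeom.sf(x - 1, n, m, k))


@dataclass
class EnrichmentRow:
    set_id: str
    name: str
    x: int  # DE genes inside the set
    m: int  # set size (within universe)
    k: int  # DE list size (within universe)
    n: int  # universe size
    p_value: float
    fdr: float = field(default=float("nan"))
    significant: bool = False


def enrich(de: DEGeneSet | set[str], gsc: GeneSetCollection,
           fdr_level: float = DEFAULT_FDR_LEVEL) -> list[EnrichmentRow]:
    """Test every gene set for over-representation of the DE genes.

    Returns one row per set with at least one DE member, sorted by p.  BH
    adjustment uses every set with >= 1 universe member as a test.
    """
    if len(gsc) == 0:
        raise ValueError("empty gene-set collection")
    de_genes = set(de.genes) if isinstance(de, DEGeneSet) else set(de)
    outside = de_genes - gsc.universe
    if outside:
        logger.warning("dropping %d DE genes outside the universe", len(outside))
        de_genes -= outside
    n = len(gsc.universe)
    k = len(de_genes)

    rows: list[EnrichmentRow] = []
    pvals: list[float] = []
    for set_id, (name, members) in gsc.sets.items():
        m = len(members)
        x = len(members & de_genes)
        p = hypergeom_test(x, m, k, n)
        pvals.append(p)
        if x >= 1:
            rows.append(EnrichmentRow(set_id, name, x, m, k, n, p))

    if pvals:
        reject, fdr, _, _ = multipletests(pvals, alpha=fdr_level, method="fdr_bh")
        by_p = {}
        for (set_id, _), q, rej in zip(gsc.sets.items(), fdr, reject):
            by_p[set_id] = (float(q), bool(rej))
        for row in rows:
            row.fdr, row.significant = by_p[row.set_id]
    rows.sort(key=lambda r: (r.p_value, r.set_id))
    return rows


def enrichment_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set_id": r.set_id,
                "name": r.name,
                "X": r.x,
                "M": r.m,
                "K": r.k,
                "N": r.n,
                "p": r.p_value,
                "FDR": r.fdr,
                "significant": r.significant,
            }
            for r in rows
        ]
    )
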