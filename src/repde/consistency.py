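"""Direction-concordance scoring between two gene lists.

Two ranked or DE gene lists sharing ``k`` genes, of which ``s`` carry the
same dysregulation direction, get the consistency score ``s/k``.  Its
significance is the upper tail of a Binomial(k, p_e) at ``s``,

    P(X >= s) = sum_{i=s}^{k} C(k, i) p_e^i (1 - p_e)^(k - i),

with ``p_e = 0.5`` under the null that each shared gene agrees in
direction by coin flip.  A comparison is significantly reproducible when
this p-value falls below 0.01.

Tail probabilities far below the float64 range (they reach ~1e-900 for
k = s = 3000) are kept in log space; ``p_value`` underflows gracefully to
0.0 while ``log10_p`` stays exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from scipy import special, stats

REPRODUCIBILITY_ALPHA = 0.01  # significance rule for "reproducible"

DirectionList = Mapping[str, str] | Iterable[tuple[str, str]]

_VALID_DIRECTIONS = {"up", "down"}


def _as_direction_map(lst: DirectionList) -> dict[str, str]:
    d = dict(lst)
    bad = {g: v for g, v in d.items() if v not in _VALID_DIRECTIONS}
    if bad:
        raise ValueError(f"invalid dysregulation direction(s): {bad}")
    return d


@dataclass(frozen=True)
class ConsistencyResult:
    """Outcome of comparing dysregulation directions of two gene lists.

    ``k`` shared genes, ``s`` of them direction-concordant; ``score`` is
    s/k (None when k = 0: a comparison with no shared genes is
    *not evaluable*, never scored as 0).
    """

    k: int
    s: int
    p_e: float = 0.5
    log_p: float = 0.0  # natural log of the upper-tail binomial p

    @property
    def evaluable(self) -> bool:
        return self.k > 0

    @property
    def score(self) -> float | None:
        return self.s / self.k if self.k > 0 else None

    @property
    def p_value(self) -> float:
        """Upper-tail binomial p; may underflow to 0.0 (see ``log10_p``)."""
        return math.exp(self.log_p) if self.log_p > -745 else 0.0

    @property
    def log10_p(self) -> float:
        return self.log_p / math.log(10.0)

    @property
    def significant(self) -> bool:
        """Reproducible under the p < 0.01 rule (False when not evaluable)."""
        return self.evaluable and self.log_p < math.log(REPRODUCIBILITY_ALPHA)

    def p_display(self) -> str:
        """p formatted for reports; values below 2.2e-16 print as '<2.2E-16'."""
        if not self.evaluable:
            return "NA"
        p = self.p_value
        return "<2.2E-16" if p < 2.2e-16 else f"{p:.3G}"

    def score_display(self) -> str:
        return "NA" if not self.evaluable else f"{100.0 * self.score:.2f}%"


def binom_tail_logp(s: int, k: int, p_e: float = 0.5) -> float:
    """Natural log of ``P(Binomial(k, p_e) >= s)``, numerically stable.

    Exact 0 log (p = 1) for s <= 0.  Uses the log-survival of the binomial
    via a log-sum-exp over log pmf terms, which stays accurate when the
    tail is far below the smallest positive float.
    """
    if not 0 < p_e < 1:
        raise ValueError(f"p_e must lie in (0, 1), got {p_e}")
    if k < 0 or s > k:
        raise ValueError(f"need 0 <= s <= k, got s={s}, k={k}")
    if s <= 0:
        return 0.0
    logpmf = stats.binom.logpmf(range(s, k + 1), k, p_e)
    return float(special.logsumexp(logpmf))


def consistency(list_a: DirectionList, list_b: DirectionList,
                p_e: float = 0.5) -> ConsistencyResult:
    """Direction concordance of the genes shared by two lists.

    Symmetric in its arguments.  Lists may be given as mappings
    ``gene -> direction`` or iterables of ``(gene, direction)`` pairs with
    direction in {"up", "down"}.
    """
    a = _as_direction_map(list_a)
    b = _as_direction_map(list_b)
    shared = a.keys() & b.keys()
    k = len(shared)
    if k == 0:
        return ConsistencyResult(k=0, s=0, p_e=p_e, log_p=0.0)
    s = sum(1 for g in shared if a[g] == b[g])
    return ConsistencyResult(k=k, s=s, p_e=p_e, log_p=binom_tail_logp(s, k, p_e))


def topn_consistency(ranked_a, ranked_b, n: int,
                     p_e: float = 0.5) -> ConsistencyResult:
    """Consistency of the top ``n`` entries of two ranked lists."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(ranked_a) == 0 or len(ranked_b) == 0:
        return ConsistencyResult(k=0, s=0, p_e=p_e, log_p=0.0)
    return consistency(ranked_a.top(n).directions(),
                       ranked_b.top(n).directions(), p_e=p_e)
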