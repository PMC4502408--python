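"""Naive reference implementations used as test oracles.

These transcribe the published procedures literally (explicit block
lists, recursion, exact rational arithmetic) with no optimisation, and
stay independent of the package's own code paths.
"""

from __future__ import annotations

import math
from fractions import Fraction


def exact_binom_tail(s: int, k: int, p_e: Fraction = Fraction(1, 2)) -> Fraction:
    """Exact upper-tail binomial probability by term-wise rational summation."""
    if s <= 0:
        return Fraction(1)
    total = Fraction(0)
    for i in range(s, k + 1):
        total += math.comb(k, i) * p_e**i * (1 - p_e) ** (k - i)
    return total


def exact_log_binom_tail(s: int, k: int, p_e: Fraction = Fraction(1, 2)) -> float:
    """Natural log of the exact tail (math.log handles big integers exactly)."""
    frac = exact_binom_tail(s, k, p_e)
    return math.log(frac.numerator) - math.log(frac.denominator)


def block_search_literal(list_a, list_b, ct, init_step, min_step=1):
    """Literal transcription of the block-wise search, steps (i)-(iv).

    ``list_a``/``list_b`` are sequences of (gene, direction) in rank
    order.  Returns the accepted {gene: direction} mapping.
    """
    n = len(list_a)
    dir_a = dict(list_a)
    dir_b = dict(list_b)
    b_position = {g: i for i, (g, _) in enumerate(list_b)}

    def divide(offset, k):
        # step (i): explicit consecutive blocks of k genes from `offset`
        blocks = []
        i = offset
        while i < n:
            blocks.append((i, min(i + k, n)))
            i += k
        return blocks

    def evaluate(block):
        # overlap of an A block with the cumulative B prefix B(1)~B(i),
        # whose end coincides with the block's end under synchronous division
        start, end = block
        shared = [g for g, _ in list_a[start:end]
                  if g in b_position and b_position[g] < end]
        same = [g for g in shared if dir_a[g] == dir_b[g]]
        return shared, same

    accepted: dict[str, str] = {}

    def run(offset, k):
        blocks = divide(offset, k)
        j = 0
        while j < len(blocks):
            shared, same = evaluate(blocks[j])  # step (ii)
            if shared and len(same) / len(shared) >= ct:
                for g in same:
                    accepted[g] = dir_a[g]
                j += 1
                continue
            # step (iii): look one more block ahead
            if j + 1 < len(blocks):
                shared2, same2 = evaluate(blocks[j + 1])
                if shared2 and len(same2) / len(shared2) >= ct:
                    for g in same2:
                        accepted[g] = dir_a[g]
                    j += 2
                    continue
            # step (iv): halve the step and re-divide from the failed block
            if not shared:
                return  # no overlapping genes can be found
            if k // 2 < max(min_step, 2):
                return
            run(blocks[j][0], k // 2)
            return

    run(0, init_step)
    return accepted


def random_ranked_duo(rng, n_genes, shared_fraction=0.8):
    """Two random direction-annotated rankings over a partly shared universe."""
    universe = [f"g{i}" for i in range(n_genes)]
    n_shared = int(n_genes * shared_fraction)
    shared = universe[:n_shared]

    def one_list(private_tag):
        genes = shared + [f"{private_tag}{i}" for i in range(n_genes - n_shared)]
        order = list(genes)
        rng.shuffle(order)
        return [(g, rng.choice(["up", "down"])) for g in order]

    return one_list("a"), one_list("b")
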