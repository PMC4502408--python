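"""Synthetic technical-replicate expression data.

The generator emulates the structure of small drug-resistant vs
drug-sensitive cell-line experiments: a handful of technical replicates
per phenotype around a single clonal expression profile (no biological
variance), with intensity-dependent technical noise on the log2 scale
whose standard deviation shrinks as intensity grows,

    sd_log2(mu) = a + b / sqrt(mu),

so low-intensity genes have unstable fold changes while high-intensity
genes measure precisely.  Differential expression is planted in two
regimes: *high-expression* genes separated by a large additive
(linear-scale) shift that yields a modest fold change, and
*low-expression* genes separated by a large fold change that yields a
small absolute difference.  These two regimes are exactly the genes the
PD and the PFC rankings are each designed to catch.

Optionally, whole samples can be corrupted (their values re-drawn from an
independent random profile) to emulate a failed array that the
reproducible-pair selection should exclude.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; the defaults mirror a 3 vs 3 replicate design
    of ~2000 measured genes with 200 planted DE genes."""

    n_genes: int = 2000
    n_rep_r: int = 3
    n_rep_s: int = 3
    seed: int = 0
    # null gene baselines (log2 intensity)
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 2.0
    # technical noise: sd_log2(mu) = noise_a + noise_b / sqrt(mu)
    noise_a: float = 0.1
    noise_b: float = 2.0
    # planted high-expression genes: additive linear shift at high baseline
    n_planted_high: int = 100
    high_baseline_log2_mean: float = 11.0
    high_baseline_log2_sd: float = 0.5
    high_effect: float = 1000.0
    # planted low-expression genes: fold effect at low baseline
    n_planted_low: int = 100
    low_baseline_log2_mean: float = 4.5
    low_baseline_log2_sd: float = 0.5
    low_effect_fold: float = 8.0
    corrupt_samples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_planted_high + self.n_planted_low > self.n_genes:
            raise ValueError("more planted genes than genes")
        if self.n_genes < 1 or self.n_rep_r < 1 or self.n_rep_s < 1:
            raise ValueError("n_genes and replicate counts must be >= 1")
        if self.high_effect < 0 or self.low_effect_fold < 1:
            raise ValueError("effect sizes must be positive (fold >= 1)")
        if self.noise_a < 0 or self.noise_b < 0:
            raise ValueError("noise coefficients must be non-negative")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class SimTruth:
    """Ground truth of a simulation: per-gene direction and planting regime."""

    direction: dict[str, str]  # gene -> up | down | null
    planted_high: list[str] = field(default_factory=list)
    planted_low: list[str] = field(default_factory=list)

    def __getitem__(self, gene: str) -> str:
        return self.direction[gene]

    def to_frame(self) -> pd.DataFrame:
        high, low = set(self.planted_high), set(self.planted_low)
        return pd.DataFrame(
            {
                "gene_id": list(self.direction),
                "direction": list(self.direction.values()),
                "regime": [
                    "high" if g in high else "low" if g in low else "null"
                    for g in self.direction
                ],
            }
        )


def _noise_sd(mu: np.ndarray, cfg: SimConfig) -> np.ndarray:
    return cfg.noise_a + cfg.noise_b / np.sqrt(mu)


def simulate(config: SimConfig = SimConfig()) -> tuple[ExpressionMatrix, SimTruth]:
    """Draw one synthetic experiment; identical seeds give identical output."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]
    r_ids = [f"R{i + 1}" for i in range(cfg.n_rep_r)]
    s_ids = [f"S{i + 1}" for i in range(cfg.n_rep_s)]
    unknown = set(cfg.corrupt_samples) - set(r_ids) - set(s_ids)
    if unknown:
        raise ValueError(f"corrupt_samples names unknown samples: {sorted(unknown)}")

    planted = rng.choice(cfg.n_genes, size=cfg.n_planted_high + cfg.n_planted_low,
                         replace=False)
    high_idx = planted[: cfg.n_planted_high]
    low_idx = planted[cfg.n_planted_high:]

    base_log2 = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, cfg.n_genes)
    base_log2[high_idx] = rng.normal(
        cfg.high_baseline_log2_mean, cfg.high_baseline_log2_sd, len(high_idx)
    )
    base_log2[low_idx] = rng.normal(
        cfg.low_baseline_log2_mean, cfg.low_baseline_log2_sd, len(low_idx)
    )
    base = 2.0 ** base_log2

    sign = np.zeros(cfg.n_genes)
    sign[high_idx] = rng.choice([-1.0, 1.0], len(high_idx))
    sign[low_idx] = rng.choice([-1.0, 1.0], len(low_idx))

    # the sensitive parental line is the reference profile; dysregulation
    # is modelled in the resistant derivative only
    mu_r = base.copy()
    mu_s = base.copy()
    mu_r[high_idx] = np.maximum(base[high_idx] + sign[high_idx] * cfg.high_effect, 1.0)
    mu_r[low_idx] = base[low_idx] * cfg.low_effect_fold ** sign[low_idx]

    cols = {}
    for sid, mu in [(s, mu_r) for s in r_ids] + [(s, mu_s) for s in s_ids]:
        if sid in cfg.corrupt_samples:
            # failed array: an independent random profile, no planted signal
            bad_log2 = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd,
                                  cfg.n_genes)
            bad_mu = 2.0 ** bad_log2
            noisy = bad_log2 + rng.normal(0.0, _noise_sd(bad_mu, cfg), cfg.n_genes)
        else:
            noisy = np.log2(mu) + rng.normal(0.0, _noise_sd(mu, cfg), cfg.n_genes)
        cols[sid] = 2.0 ** noisy

    values = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    phenotype = {s: "R" for s in r_ids} | {s: "S" for s in s_ids}

    direction = {g: "null" for g in genes}
    for idx in (*high_idx, *low_idx):
        direction[genes[idx]] = "up" if sign[idx] > 0 else "down"
    truth = SimTruth(
        direction=direction,
        planted_high=[genes[i] for i in sorted(high_idx)],
        planted_low=[genes[i] for i in sorted(low_idx)],
    )
    return ExpressionMatrix(values, phenotype), truth


# Published worked examples of the consistency evaluation: (dataset,
# comparison, K shared genes, S same-direction genes, score as printed).
TABLE1_ROWS: tuple[tuple[str, str, int, int, str], ...] = (
    ("CP70/A2780", "pair1-2", 267, 267, "100.00"),
    ("CP70/A2780", "pair1-3", 151, 142, "94.04"),
    ("CP70/A2780", "pair2-3", 155, 146, "94.19"),
    ("MDA-MB-231", "pair1-2", 200, 194, "97.00"),
    ("MDA-MB-231", "pair1-3", 186, 174, "93.55"),
    ("MDA-MB-231", "pair2-3", 179, 167, "93.30"),
    ("LCC2/MCF7", "pair1-2", 196, 190, "96.94"),
    ("HCT116", "pair1-2", 147, 136, "92.52"),
)


def make_direction_lists(k: int, s: int, n_private: int = 10
                         ) -> tuple[dict[str, str], dict[str, str]]:
    """Two direction-annotated lists sharing exactly ``k`` genes, ``s`` of
    them with identical direction; each list also carries ``n_private``
    unshared genes."""
    if not 0 <= s <= k:
        raise ValueError("need 0 <= s <= k")
    list_a: dict[str, str] = {}
    list_b: dict[str, str] = {}
    for i in range(k):
        g = f"shared{i:04d}"
        list_a[g] = "up" if i % 2 == 0 else "down"
        list_b[g] = list_a[g] if i < s else ("down" if list_a[g] == "up" else "up")
    for i in range(n_private):
        list_a[f"onlyA{i:03d}"] = "up"
        list_b[f"onlyB{i:03d}"] = "down"
    return list_a, list_b


def make_table1_fixture() -> dict[str, tuple[dict[str, str], dict[str, str], int, int, str]]:
    """Direction-annotated list duos reproducing every published (K, S) row.

    Keys are "<dataset> <comparison>"; values are
    (list_a, list_b, k, s, printed_score_percent).
    """
    out = {}
    for dataset, comparison, k, s, printed in TABLE1_ROWS:
        la, lb = make_direction_lists(k, s)
        out[f"{dataset} {comparison}"] = (la, lb, k, s, printed)
    return out
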