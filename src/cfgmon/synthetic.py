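"""Synthetic molecule streams with controlled group enrichment.

The enrichment monitor is validated against streams whose ground truth
is known exactly: molecules are drawn from small labelled pools (one
pool per monitored group plus a pool of negatives matching no group),
so the per-index occurrence probability of each group is an input, not
an estimate. A trend maps stream index to occurrence probability, which
lets tests inject the step- and ramp-shaped strategy changes a real
generator exhibits — e.g. a quinone pool whose probability rises
partway through the run — and check that the windowed P_E trajectory
recovers the injected ratio p(t)/q within binomial error.

Default stream sizes are scaled about 20x down from a full production
run (2,000 molecules instead of ~45,000) so validation runs in seconds.

At each index the pool is chosen categorically: group g with
probability trend_g(t), the negatives pool with the remainder. If the
trend probabilities at an index sum past 1, mass is allocated in
trends-list order (earlier trends win); this is the documented priority
rule for conflicting trends. Per-group occurrence equals the injected
probability exactly when pools are exclusive with respect to the
monitored groups; chemically nested groups (a quinone necessarily
contains a ketone) share occurrences as real molecules would.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrendSpec",
    "constant_trend",
    "step_trend",
    "ramp_trend",
    "builtin_pools",
    "make_training_set",
    "make_stream",
]


@dataclass(frozen=True)
class TrendSpec:
    """Occurrence-probability trajectory p(t) for one group's pool."""

    group_name: str
    trajectory: Callable[[int], float]

    def probability(self, t: int) -> float:
        p = float(self.trajectory(t))
        if not 0.0 <= p <= 1.0:
            raise ValueError(
                f"trend for {self.group_name!r} gives p({t}) = {p} outside [0, 1]"
            )
        return p


def constant_trend(p: float) -> Callable[[int], float]:
    return lambda t: p


def step_trend(p_before: float, p_after: float, t_step: int) -> Callable[[int], float]:
    """p_before for t < t_step, p_after from t_step on."""
    return lambda t: p_after if t >= t_step else p_before


def ramp_trend(
    p_start: float, p_end: float, t_start: int, t_end: int
) -> Callable[[int], float]:
    """Linear rise from p_start to p_end over [t_start, t_end]."""

    def fn(t: int) -> float:
        if t <= t_start:
            return p_start
        if t >= t_end:
            return p_end
        frac = (t - t_start) / (t_end - t_start)
        return p_start + frac * (p_end - p_start)

    return fn


# Labelled pools, one per default-catalog group plus negatives. Every
# member is verified against the catalog SMARTS by the test suite.
_POOLS: dict[str, list[str]] = {
    "ketone": [
        "CC(C)=O",
        "CCC(C)=O",
        "CCCC(C)=O",
        "O=C1CCCCC1",
        "CC(=O)c1ccccc1",
        "CCC(=O)CC",
    ],
    "diketone": [
        "CC(=O)C(C)=O",
        "CCC(=O)C(=O)CC",
        "O=C1CCCCC1=O",
        "O=C(c1ccccc1)C(=O)c1ccccc1",
        "CC(=O)C(=O)c1ccccc1",
    ],
    "aniline": [
        "Nc1ccccc1",
        "CNc1ccccc1",
        "CCNc1ccccc1",
        "Cc1ccccc1N",
        "Nc1ccc(O)cc1",
        "Nc1ccc(C)cc1",
    ],
    "azo": [
        "CN=NC",
        "CCN=NCC",
        "CN=Nc1ccccc1",
        "c1ccc(N=Nc2ccccc2)cc1",
        "CC(C)N=NC(C)C",
    ],
    "1,2-quinone": [
        "O=C1C(=O)C=CC=C1",
        "CC1=CC(=O)C(=O)C=C1",
        "CC1=CC(=O)C(=O)C(C)=C1",
        "OC1=CC(=O)C(=O)C=C1",
        "CCC1=CC(=O)C(=O)C=C1",
    ],
    "1,4-quinone": [
        "O=C1C=CC(=O)C=C1",
        "CC1=CC(=O)C=CC1=O",
        "CC1=CC(=O)C(C)=CC1=O",
        "CC1=C(C)C(=O)C(C)=C(C)C1=O",
        "OC1=CC(=O)C=CC1=O",
    ],
    "1,2-naphthoquinone": [
        "O=C1C(=O)c2ccccc2C=C1",
        "O=C1C(=O)c2ccc(C)cc2C=C1",
        "O=C1C(=O)c2cc(C)ccc2C=C1",
        "O=C1C(=O)c2ccc(O)cc2C=C1",
        "O=C1C(=O)c2ccccc2C=C1c1ccccc1",
    ],
    "1,4-naphthoquinone": [
        "O=C1c2ccccc2C(=O)C=C1",
        "CC1=CC(=O)c2ccccc2C1=O",
        "O=C1C=CC(=O)c2ccc(C)cc12",
        "O=C1C=CC(=O)c2cc(C)ccc12",
        "O=C1C=CC(=O)c2ccc(O)cc12",
    ],
    "negative": [
        "CCCC",
        "CCCCC",
        "CCCCCC",
        "CC(C)C",
        "CCOCC",
        "CCO",
        "COC",
        "C1CCCCC1",
        "CCCO",
        "CC(C)O",
    ],
}


def builtin_pools() -> dict[str, list[str]]:
    """Labelled SMILES pools per default-catalog group, plus negatives."""
    return {name: list(pool) for name, pool in _POOLS.items()}


def _draw(pool: Sequence[str], rng: np.random.Generator) -> str:
    if not pool:
        raise ValueError("empty pool")
    return pool[rng.integers(len(pool))]


def make_training_set(
    group_fractions: Mapping[str, float],
    n: int,
    seed: int = 0,
    pools: Mapping[str, Sequence[str]] | None = None,
) -> list[str]:
    """Draw ``n`` molecules with expected per-group fraction ``q``.

    Each index independently picks group g's pool with probability
    ``group_fractions[g]`` and the negatives pool otherwise; the
    fractions must sum to at most 1.
    """
    trends = [
        TrendSpec(g, constant_trend(q)) for g, q in group_fractions.items()
    ]
    stream, _ = make_stream(trends, n, seed=seed, pools=pools)
    return stream


def make_stream(
    trends: Sequence[TrendSpec],
    n: int,
    seed: int = 0,
    pools: Mapping[str, Sequence[str]] | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Sample a stream of ``n`` molecules following the injected trends.

    Returns the SMILES list and a ground-truth table with one row per
    molecule: index, smiles, the pool it was drawn from, and the
    injected probability of every trend group at that index.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    pools = pools if pools is not None else builtin_pools()
    if "negative" not in pools or not pools["negative"]:
        raise ValueError("pools must include a non-empty 'negative' pool")
    for trend in trends:
        if trend.group_name not in pools or not pools[trend.group_name]:
            raise ValueError(f"empty or missing pool for {trend.group_name!r}")

    rng = np.random.default_rng(seed)
    smiles: list[str] = []
    rows = []
    for t in range(n):
        probs = []
        remaining = 1.0
        for trend in trends:  # earlier trends take priority if mass runs out
            p = min(trend.probability(t), remaining)
            probs.append(p)
            remaining -= p
        u = rng.random()
        source = "negative"
        acc = 0.0
        for trend, p in zip(trends, probs):
            acc += p
            if u < acc:
                source = trend.group_name
                break
        smi = _draw(pools[source], rng)
        smiles.append(smi)
        row = {"index": t, "smiles": smi, "source": source}
        for trend, p in zip(trends, probs):
            row[f"p_{trend.group_name}"] = p
        rows.append(row)
    return smiles, pd.DataFrame(rows)
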