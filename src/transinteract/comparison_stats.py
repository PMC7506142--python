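"""Group-level inference across spatial scenarios.

If overlapping regulator pairs interact more than independent ones, the
interaction p-values of the overlapping group should be collectively
smaller. That is tested with a one-sided two-sample Kolmogorov-Smirnov
statistic D+ = sup_t (ECDF_x(t) - ECDF_y(t)): D+ near 1 means group x's
p-values sit far below group y's. Recurrence of significant pairs across
conditions is assessed with one-sided Fisher (hypergeometric) tests.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .interaction_model import InteractionFit, adjust_bh

SCENARIO_ORDER = ("overlapping", "neighboring", "independent")


@dataclass
class GroupComparison:
    """One-sided KS comparison of two scenario groups' p-values."""

    condition_label: str
    group_x: str
    group_y: str
    n_x: int
    n_y: int
    d_plus: float
    p_ks: float

    @property
    def available(self) -> bool:
        return not math.isnan(self.d_plus)


@dataclass
class RecurrenceResult:
    """Enrichment of one regulator pair among significant trios."""

    pair_id: tuple[str, str]
    condition_label: str
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_fisher: float
    q_fisher: float | None = None


def d_plus_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """sup_t (ECDF_x(t) - ECDF_y(t)) over the pooled sample points."""
    grid = np.concatenate([x, y])
    ecdf_x = np.searchsorted(np.sort(x), grid, side="right") / x.size
    ecdf_y = np.searchsorted(np.sort(y), grid, side="right") / y.size
    return float(np.max(ecdf_x - ecdf_y))


def ks_greater(
    x: Sequence[float],
    y: Sequence[float],
    condition_label: str = "",
    group_x: str = "x",
    group_y: str = "y",
    exact: bool | None = None,
    n_permutations: int = 20000,
    seed: int = 0,
) -> GroupComparison:
    """One-sided KS test that sample x is stochastically smaller than... not.

    Rejects the null when x's ECDF rises above y's, i.e. when x's values
    are collectively smaller. The p-value is the asymptotic one-sided
    expression exp(-2 d+^2 n_x n_y / (n_x + n_y)), capped at 1; for tiny
    samples (n_x + n_y <= 20, or ``exact=True``) a permutation p-value is
    computed instead.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    d = d_plus_statistic(x, y)
    use_exact = exact if exact is not None else (x.size + y.size <= 20)
    if use_exact:
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([x, y])
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            if d_plus_statistic(perm[: x.size], perm[x.size:]) >= d - 1e-12:
                count += 1
        p = (count + 1) / (n_permutations + 1)
    else:
        n_eff = x.size * y.size / (x.size + y.size)
        p = min(1.0, math.exp(-2.0 * d * d * n_eff))
    return GroupComparison(condition_label, group_x, group_y,
                           int(x.size), int(y.size), d, float(p))


def compare_scenarios(
    fits: Iterable[InteractionFit],
    condition_label: str | None = None,
) -> list[GroupComparison]:
    """The three ordered scenario comparisons for one condition.

    Compares the interaction p-value distributions of (overlapping vs
    neighboring, overlapping vs independent, neighboring vs independent),
    excluding degenerate fits. A scenario with zero usable fits yields an
    unavailable comparison (NaN statistic) rather than an error.
    """
    groups: dict[str, list[float]] = {s: [] for s in SCENARIO_ORDER}
    label = condition_label
    for f in fits:
        if label is None:
            label = f.condition_label
        if f.degenerate or f.p_a3 is None:
            continue
        if f.scenario in groups:
            groups[f.scenario].append(f.p_a3)
    out = []
    for gx, gy in itertools.combinations(SCENARIO_ORDER, 2):
        # sorted inputs keep the (permutation-based) small-sample branch
        # invariant to fit ordering
        x, y = sorted(groups[gx]), sorted(groups[gy])
        if not x or not y:
            out.append(GroupComparison(label or "", gx, gy, len(x), len(y),
                                       float("nan"), float("nan")))
        else:
            out.append(ks_greater(x, y, label or "", gx, gy))
    return out


def comparisons_to_frame(comparisons: Iterable[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.condition_label, c.group_x, c.group_y, c.n_x, c.n_y, c.d_plus, c.p_ks)
         for c in comparisons],
        columns=["condition", "group_x", "group_y", "n_x", "n_y",
                 "d_plus", "p_ks"],
    )


def fisher_enrichment_p(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """One-sided (enrichment) Fisher exact test on a 2x2 table.

    Returns (odds_ratio, p). p = P[X >= a] under the hypergeometric null
    with a = table[0][0], margins fixed.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be non-negative")
    n = a + b + c + d
    p = float(stats.hypergeom.sf(a - 1, n, a + b, a + c))
    odds = (a * d) / (b * c) if b * c > 0 else math.inf
    return odds, min(p, 1.0)


def fisher_recurrence(
    fits: Iterable[InteractionFit],
    alpha_q: float = 0.05,
) -> list[RecurrenceResult]:
    """Per pair per condition: is the pair enriched among significant trios?

    Each fitted trio is called significant when q < ``alpha_q``. For every
    pair the 2x2 table crosses significance with pair membership over all
    trios of the same condition; the one-sided hypergeometric p is
    BH-adjusted across pairs within each condition.
    """
    fits = [f for f in fits if f.q_a3 is not None and f.trio is not None]
    results: list[RecurrenceResult] = []
    for cond in sorted({f.condition_label for f in fits}):
        cond_fits = [f for f in fits if f.condition_label == cond]
        sig = np.array([f.q_a3 < alpha_q for f in cond_fits])
        pair_ids = [f.trio.pair_id for f in cond_fits]
        cond_results = []
        for pair in sorted(set(pair_ids)):
            member = np.array([p == pair for p in pair_ids])
            a = int(np.sum(sig & member))
            b = int(np.sum(sig & ~member))
            c = int(np.sum(~sig & member))
            d = int(np.sum(~sig & ~member))
            odds, p = fisher_enrichment_p([[a, b], [c, d]])
            cond_results.append(
                RecurrenceResult(pair, cond, ((a, b), (c, d)), odds, p)
            )
        qs = adjust_bh([r.p_fisher for r in cond_results])
        for r, q in zip(cond_results, qs):
            r.q_fisher = float(q)
        results.extend(cond_results)
    return results


def recurrent_pairs(
    results: Iterable[RecurrenceResult], alpha_q: float = 0.05, min_conditions: int = 2
) -> pd.DataFrame:
    """Pairs significantly enriched in at least ``min_conditions`` conditions."""
    df = pd.DataFrame(
        [(r.pair_id[0], r.pair_id[1], r.condition_label, r.p_fisher, r.q_fisher)
         for r in results],
        columns=["regulator_a", "regulator_b", "condition", "p_fisher", "q_fisher"],
    )
    sig = df[df["q_fisher"] < alpha_q]
    counts = (
        sig.groupby(["regulator_a", "regulator_b"])
        .agg(n_conditions=("condition", "nunique"))
        .reset_index()
    )
    return counts[counts["n_conditions"] >= min_conditions].reset_index(drop=True)
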