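"""Interaction regression for regulator pairs on a shared target.

For a trio (regulator x1, regulator x2, target y) the model

    y = a1*x1 + a2*x2 + a3*x1*x2 + a4

is fitted by ordinary least squares (a4 is the intercept; the residual
captures regulation by other factors). A significant interaction
coefficient a3 — two-sided t-test of a3 = 0 — signals a competitive or
cooperative effect between the two regulators on that target. P-values
are adjusted within families by Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression_prep import ExpressionMatrix
from .overlap_engine import TrioRecord
from .site_catalog import SiteCatalog

logger = logging.getLogger(__name__)

MIN_SAMPLES = 5  # 4 parameters need n >= 5 for a positive-df t-test


@dataclass
class InteractionFit:
    """One fitted trio in one condition."""

    trio: TrioRecord | None
    condition_label: str
    a1: float
    a2: float
    a3: float
    a4: float
    se_a3: float
    p_a3: float | None
    n_samples: int
    degenerate: bool = False
    degeneracy_reason: str = ""
    q_a3: float | None = None

    @property
    def scenario(self) -> str:
        return self.trio.scenario if self.trio is not None else "unlabeled"


def fit_eq1(
    y: Sequence[float],
    x1: Sequence[float],
    x2: Sequence[float],
    trio: TrioRecord | None = None,
    condition_label: str = "pooled",
) -> InteractionFit:
    """OLS fit of y on [1, x1, x2, x1*x2] with a t-test on the interaction.

    Standard errors use the unbiased residual variance (df = n - 4); the
    p-value for a3 is two-sided. A rank-deficient design (e.g., a constant
    regulator) is flagged degenerate with a missing p-value; an exact fit
    (zero residual variance with a nonzero a3) is flagged with p = 0.
    """
    y = np.asarray(y, float)
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    n = len(y)
    if not (len(x1) == len(x2) == n):
        raise ValueError("y, x1, x2 must have equal length")
    if n < MIN_SAMPLES:
        raise ValueError(f"need at least {MIN_SAMPLES} samples, got {n}")
    if np.isnan(y).any() or np.isnan(x1).any() or np.isnan(x2).any():
        raise ValueError("missing values must be imputed before fitting")

    X = np.column_stack([np.ones(n), x1, x2, x1 * x2])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    a4, a1, a2, a3 = beta
    if rank < 4:
        return InteractionFit(trio, condition_label, a1, a2, a3, a4,
                              float("nan"), None, n, degenerate=True,
                              degeneracy_reason="rank-deficient design")
    resid = y - X @ beta
    df = n - 4
    rss = float(resid @ resid)
    # machine-precision exact fits count as zero residual variance
    if rss <= 1e-24 * max(float(y @ y), 1.0):
        rss = 0.0
    sigma2 = rss / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se_a3 = math.sqrt(max(sigma2 * xtx_inv[3, 3], 0.0))
    if se_a3 == 0.0:
        # exact algebraic fit: interaction is either absent or certain
        p = 0.0 if abs(a3) > 1e-12 else 1.0
        return InteractionFit(trio, condition_label, a1, a2, a3, a4,
                              0.0, p, n, degenerate=True,
                              degeneracy_reason="zero residual variance")
    t = a3 / se_a3
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return InteractionFit(trio, condition_label, a1, a2, a3, a4, se_a3, p, n)


def fit_all_trios(
    trios: Iterable[TrioRecord],
    regulator_expr: ExpressionMatrix,
    gene_expr: ExpressionMatrix,
    condition_label: str | None = None,
) -> tuple[list[InteractionFit], int]:
    """Fit every resolvable trio; returns (fits, n_skipped).

    A trio is skipped (and counted) when any of its three feature ids is
    absent from the matrices. Scenario labels travel with each fit.
    """
    label = condition_label or gene_expr.condition_label
    reg = regulator_expr.data
    genes = gene_expr.data
    if not reg.index.equals(genes.index):
        shared = reg.index.intersection(genes.index)
        if len(shared) < MIN_SAMPLES:
            raise ValueError("regulator and gene matrices share too few samples")
        reg, genes = reg.loc[shared], genes.loc[shared]
    fits: list[InteractionFit] = []
    n_skipped = 0
    for trio in trios:
        ra, rb = trio.regulator_a[0], trio.regulator_b[0]
        if ra not in reg.columns or rb not in reg.columns or trio.gene_id not in genes.columns:
            n_skipped += 1
            continue
        fits.append(
            fit_eq1(genes[trio.gene_id].to_numpy(),
                    reg[ra].to_numpy(), reg[rb].to_numpy(),
                    trio=trio, condition_label=label)
        )
    if n_skipped:
        logger.info("fit_all_trios skipped %d unresolvable trios", n_skipped)
    return fits, n_skipped


def build_independent_trios(
    catalog: SiteCatalog,
    trios: Sequence[TrioRecord],
    pair_summary: pd.DataFrame,
    seed: int = 0,
) -> list[TrioRecord]:
    """Construct target trios for pairs that share no gene.

    An independent pair has no shared target, so no natural y exists. For
    each such pair we sample (reproducibly, from ``seed``) genes targeted
    by exactly one member of the pair, drawing per-pair trio counts from
    the empirical count distribution of the overlapping group so that the
    three scenario groups have comparable sizes downstream.
    """
    rng = np.random.default_rng(seed)
    overlap_counts: dict[tuple[str, str], int] = {}
    for t in trios:
        if t.scenario == "overlapping":
            overlap_counts[t.pair_id] = overlap_counts.get(t.pair_id, 0) + 1
    count_pool = sorted(overlap_counts.values()) or [1]

    targets_of: dict[str, set[str]] = {}
    for s in catalog.sites:
        targets_of.setdefault(s.regulator_id, set()).add(s.gene_id)
    classes = {rid: cls for rid, cls in catalog.regulators}

    indep = pair_summary[pair_summary["pair_label"] == "independent"]
    out: list[TrioRecord] = []
    for _, row in indep.sort_values(["regulator_a", "regulator_b"]).iterrows():
        ra, rb = row["regulator_a"], row["regulator_b"]
        eligible = sorted(
            targets_of.get(ra, set()) ^ targets_of.get(rb, set())
        )
        if not eligible:
            continue
        want = int(rng.choice(count_pool))
        picked = rng.choice(eligible, size=min(want, len(eligible)), replace=False)
        for gene in sorted(picked):
            out.append(
                TrioRecord((ra, classes[ra]), (rb, classes[rb]), str(gene),
                           "independent", 0)
            )
    return out


def adjust_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, preserving input order.

    q_(i) = min_{j>=i} m * p_(j) / j, capped at 1. NaN entries are passed
    through untouched and do not count toward m.
    """
    p = np.asarray(p_values, float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0,1]")
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.empty(m)
    qv[order] = np.minimum(ranked, 1.0)
    q[ok] = qv
    return q


def attach_qvalues(fits: list[InteractionFit]) -> list[InteractionFit]:
    """BH-adjust within each (condition, class combination, scenario) family."""
    def family(f: InteractionFit):
        classes = ("?", "?")
        if f.trio is not None:
            classes = tuple(sorted((f.trio.regulator_a[1], f.trio.regulator_b[1])))
        return (f.condition_label, classes, f.scenario)

    groups: dict[tuple, list[int]] = {}
    for i, f in enumerate(fits):
        groups.setdefault(family(f), []).append(i)
    out = list(fits)
    for idx in groups.values():
        ps = [fits[i].p_a3 if fits[i].p_a3 is not None else float("nan")
              for i in idx]
        qs = adjust_bh(ps)
        for i, qv in zip(idx, qs):
            out[i] = replace(fits[i], q_a3=None if np.isnan(qv) else float(qv))
    return out


def fits_to_frame(fits: Iterable[InteractionFit]) -> pd.DataFrame:
    rows = []
    for f in fits:
        t = f.trio
        rows.append(
            ((t.regulator_a[0] if t else ""), (t.regulator_b[0] if t else ""),
             (t.gene_id if t else ""), f.scenario, f.condition_label,
             f.a1, f.a2, f.a3, f.a4, f.p_a3, f.q_a3, f.n_samples,
             f.degenerate, f.degeneracy_reason)
        )
    return pd.DataFrame(
        rows,
        columns=["regulator_a", "regulator_b", "gene_id", "scenario",
                 "condition", "a1", "a2", "a3", "a4", "p_a3", "q_a3",
                 "n_samples", "degenerate", "degeneracy_reason"],
    )
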