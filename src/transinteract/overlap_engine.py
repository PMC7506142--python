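"""Spatial classification of regulator pairs and randomization nulls.

Two trans regulators sharing a target mRNA fall into one of three
scenarios: *overlapping* (their 3'UTR sites intersect by at least one
nucleotide), *neighboring* (both bind the UTR but never overlap), or
*independent* (no shared target). The enrichment of observed overlap over
chance is assessed by re-distributing each site uniformly on its own UTR
and recomputing overlap frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .site_catalog import BindingSite, SiteCatalog

Scenario = Literal["overlapping", "neighboring", "independent"]

_CLASS_FILTERS = {
    "RBP-RBP": ("RBP", "RBP"),
    "miRNA-miRNA": ("miRNA", "miRNA"),
    "RBP-miRNA": ("RBP", "miRNA"),
}


@dataclass(frozen=True)
class TrioRecord:
    """A (regulator pair, target gene) unit with its spatial scenario."""

    regulator_a: tuple[str, str]  # (id, class), canonical sorted-id order
    regulator_b: tuple[str, str]
    gene_id: str
    scenario: Scenario
    n_overlapping_site_pairs: int = 0

    def __post_init__(self) -> None:
        if self.regulator_a[0] == self.regulator_b[0]:
            raise ValueError("a pair needs two distinct regulators")
        if self.regulator_a[0] > self.regulator_b[0]:
            raise ValueError("pair must be in canonical (sorted-id) order")
        if self.scenario == "overlapping" and self.n_overlapping_site_pairs < 1:
            raise ValueError("overlapping trio needs >= 1 overlapping site pair")
        if self.scenario == "neighboring" and self.n_overlapping_site_pairs != 0:
            raise ValueError("neighboring trio cannot have overlapping site pairs")

    @property
    def pair_id(self) -> tuple[str, str]:
        return (self.regulator_a[0], self.regulator_b[0])


@dataclass
class OverlapNull:
    """Monte-Carlo null for the overlapped-site fraction."""

    n_rounds: int
    observed_overlap_fraction: float
    null_overlap_fractions: np.ndarray
    seed: int

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_overlap_fractions))


def sites_overlap(s1: BindingSite, s2: BindingSite, max_gap: int = 0) -> bool:
    """True iff the two sites intersect, or their gap is < ``max_gap``.

    With the default ``max_gap=0`` this is overlap by at least one
    nucleotide on half-open intervals; ``max_gap=5`` reproduces the
    relaxed "distance less than 5 nt" sensitivity variant.
    """
    if s1.gene_id != s2.gene_id:
        raise ValueError("cannot compare sites on different genes")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    return s1.start < s2.end + max_gap and s2.start < s1.end + max_gap


def _canonical(a: tuple[str, str], b: tuple[str, str]):
    return (a, b) if a[0] < b[0] else (b, a)


def _pair_matches_filter(cls_a: str, cls_b: str, class_filter: str) -> bool:
    if class_filter == "all":
        return True
    want = _CLASS_FILTERS[class_filter]
    return tuple(sorted((cls_a, cls_b))) == tuple(sorted(want))


def classify_pairs(
    catalog: SiteCatalog,
    class_filter: Literal["RBP-RBP", "miRNA-miRNA", "RBP-miRNA", "all"] = "all",
    max_gap: int = 0,
) -> tuple[list[TrioRecord], pd.DataFrame]:
    """Classify every regulator pair on every shared gene.

    For each unordered regulator pair (restricted by ``class_filter``) and
    each gene on which both have at least one site, the trio is
    *overlapping* when any cross-regulator site pair overlaps and
    *neighboring* otherwise. The pair-level summary counts genes per
    scenario and total overlapping site pairs, and flags pairs that share
    no gene at all as *independent*.
    """
    trios: list[TrioRecord] = []
    pair_stats: dict[tuple, dict] = {}

    def stats_for(reg_a, reg_b):
        key = _canonical(reg_a, reg_b)
        return pair_stats.setdefault(
            key,
            {"n_overlapping_site_pairs": 0, "n_genes_overlapping": 0,
             "n_genes_neighboring": 0, "n_genes_shared": 0},
        )

    for gene_id, gene_sites in catalog.sites_by_gene().items():
        by_reg: dict[tuple[str, str], list[BindingSite]] = {}
        for s in gene_sites:
            by_reg.setdefault((s.regulator_id, s.regulator_class), []).append(s)
        regs = sorted(by_reg)
        for i in range(len(regs)):
            for j in range(i + 1, len(regs)):
                reg_a, reg_b = regs[i], regs[j]
                if not _pair_matches_filter(reg_a[1], reg_b[1], class_filter):
                    continue
                n_over = sum(
                    sites_overlap(sa, sb, max_gap)
                    for sa in by_reg[reg_a]
                    for sb in by_reg[reg_b]
                )
                scenario: Scenario = "overlapping" if n_over else "neighboring"
                trios.append(TrioRecord(reg_a, reg_b, gene_id, scenario, n_over))
                st = stats_for(reg_a, reg_b)
                st["n_genes_shared"] += 1
                st["n_overlapping_site_pairs"] += n_over
                st["n_genes_overlapping" if n_over else "n_genes_neighboring"] += 1

    # pairs with no shared gene are independent at pair level
    all_regs = sorted(catalog.regulators)
    rows = []
    for i in range(len(all_regs)):
        for j in range(i + 1, len(all_regs)):
            reg_a, reg_b = _canonical(all_regs[i], all_regs[j])
            if not _pair_matches_filter(reg_a[1], reg_b[1], class_filter):
                continue
            st = pair_stats.get((reg_a, reg_b))
            if st is None:
                rows.append((reg_a[0], reg_b[0], reg_a[1], reg_b[1],
                             0, 0, 0, 0, "independent"))
            else:
                label = ("overlapping" if st["n_genes_overlapping"]
                         else "neighboring")
                rows.append((reg_a[0], reg_b[0], reg_a[1], reg_b[1],
                             st["n_overlapping_site_pairs"],
                             st["n_genes_overlapping"],
                             st["n_genes_neighboring"],
                             st["n_genes_shared"], label))
    summary = pd.DataFrame(
        rows,
        columns=["regulator_a", "regulator_b", "class_a", "class_b",
                 "n_overlapping_site_pairs", "n_genes_overlapping",
                 "n_genes_neighboring", "n_genes_shared", "pair_label"],
    )
    trios.sort(key=lambda t: (t.regulator_a[0], t.regulator_b[0], t.gene_id))
    return trios, summary


def fraction_sites_overlapped(
    catalog: SiteCatalog,
    by: Literal["any-RBP", "any-miRNA", "any"] = "any",
    max_gap: int = 0,
) -> tuple[pd.DataFrame, float]:
    """For each site, whether another regulator's site overlaps it.

    ``by`` restricts the class of the *other* site ("any-RBP": overlapped
    by at least one RBP site of a different regulator). Returns the
    per-site table and the overlapped fraction.
    """
    want_class = {"any": None, "any-RBP": "RBP", "any-miRNA": "miRNA"}[by]
    rows = []
    for gene_id, gene_sites in catalog.sites_by_gene().items():
        for s in gene_sites:
            hit = any(
                o.regulator_id != s.regulator_id
                and (want_class is None or o.regulator_class == want_class)
                and sites_overlap(s, o, max_gap)
                for o in gene_sites
            )
            rows.append((s.regulator_id, s.regulator_class, gene_id,
                         s.start, s.end, hit))
    table = pd.DataFrame(
        rows, columns=["regulator_id", "regulator_class", "gene_id",
                       "start", "end", "overlapped"],
    )
    frac = float(table["overlapped"].mean()) if len(table) else 0.0
    return table, frac


def randomized_placement(
    catalog: SiteCatalog,
    sites: Sequence[BindingSite],
    rng: np.random.Generator,
) -> list[BindingSite]:
    """One randomization round: uniform random start for each site on its
    own gene, preserving site count, length, and gene assignment."""
    placed = []
    for s in sites:
        utr_len = catalog.utrs[s.gene_id].length
        start = int(rng.integers(0, utr_len - s.length + 1))
        placed.append(BindingSite(s.regulator_id, s.regulator_class,
                                  s.gene_id, start, start + s.length))
    return placed


def randomize_sites(
    catalog: SiteCatalog,
    n_rounds: int = 10,
    seed: int = 0,
    scope: Literal["all", "RBP", "miRNA"] = "all",
    by: Literal["any-RBP", "any-miRNA", "any"] = "any",
    max_gap: int = 0,
) -> OverlapNull:
    """Monte-Carlo null for the overlapped-site fraction.

    Each round independently re-places every site (of the ``scope`` class)
    uniformly at random on its own gene's UTR, preserving the site count,
    each site's length, and the gene assignment, then recomputes the
    fraction of sites overlapped by another regulator's site. Per-round
    random streams are derived from ``seed`` and the round index, so runs
    are reproducible and parallelizable.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    sites = [s for s in catalog.sites
             if scope == "all" or s.regulator_class == scope]
    scoped = SiteCatalog(utrs=catalog.utrs, sites=sites)
    for s in sites:
        if s.length > catalog.utrs[s.gene_id].length:
            raise ValueError(
                f"site {s.regulator_id}:[{s.start},{s.end}) longer than the "
                f"UTR of {s.gene_id}"
            )
    _, observed = fraction_sites_overlapped(scoped, by=by, max_gap=max_gap)
    fractions = np.empty(n_rounds)
    for r in range(n_rounds):
        rng = np.random.default_rng(np.random.SeedSequence((seed, r)))
        placed = randomized_placement(catalog, sites, rng)
        _, frac = fraction_sites_overlapped(
            SiteCatalog(utrs=catalog.utrs, sites=placed), by=by, max_gap=max_gap
        )
        fractions[r] = frac
    return OverlapNull(n_rounds, observed, fractions, seed)


def trios_to_frame(trios: Iterable[TrioRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (t.regulator_a[0], t.regulator_a[1], t.regulator_b[0],
             t.regulator_b[1], t.gene_id, t.scenario,
             t.n_overlapping_site_pairs)
            for t in trios
        ],
        columns=["regulator_a", "class_a", "regulator_b", "class_b",
                 "gene_id", "scenario", "n_overlapping_site_pairs"],
    )
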