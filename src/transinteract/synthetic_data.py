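"""Synthetic inputs with a known ground truth for every pipeline stage.

The generator emulates the statistical shape of the real inputs — a 3'UTR
annotation, RBP interval catalogs, mature microRNA sequences whose seed
motifs are physically planted in the UTR sequences, per-nucleotide
accessibility tracks, and tumor/normal expression matrices generated from
the interaction model itself — while recording everything it planted in a
:class:`GroundTruthLedger` so that recovery can be asserted exactly.

Scenario planting: each *overlapping* pair receives, on each of its
assigned genes, a microRNA seed site and an RBP site intersecting it by at
least one nucleotide; each *neighboring* pair receives the two sites well
separated on the same UTR; remaining regulator pairs never co-occur on a
gene and are therefore *independent*. Genes not assigned to any pair carry
a single regulator's site, providing targets for independent-pair trios.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .accessibility import AccessibilityTrack, write_tracks_tsv
from .expression_prep import ExpressionMatrix, write_expression_tsv
from .seed_targeting import MatureMirna, SEED_LENGTH, seed_of, target_motif
from .site_catalog import BindingSite, UtrModel

_BASES = np.array(list("ACGU"))


@dataclass
class SimConfig:
    """Study conditions for the synthetic benchmark.

    Defaults are desk-scale: 300 genes, 10 RBPs, 10 microRNAs, 100 samples
    per condition. Regulator pairs are RBP-microRNA (the primary analysis)
    unless no microRNAs are requested, in which case RBP-RBP pairs are
    planted.
    """

    n_genes: int = 300
    utr_length_range: tuple[int, int] = (200, 1000)
    n_rbps: int = 10
    n_mirnas: int = 10
    rbp_site_length_range: tuple[int, int] = (10, 30)
    n_overlapping_pairs: int = 15
    n_neighboring_pairs: int = 15
    genes_per_pair: int = 5
    neighbor_gap_min: int = 10  # keeps neighboring pairs neighboring even at max_gap=5
    decoy_inaccessible_fraction: float = 0.0
    accessibility_beta: tuple[float, float] = (8.0, 2.0)
    n_samples_per_condition: int = 100
    a1_range: tuple[float, float] = (0.3, 0.8)
    a2_range: tuple[float, float] = (0.3, 0.8)
    a3_range_overlapping: tuple[float, float] = (0.5, 1.0)
    a3_range_neighboring: tuple[float, float] = (0.2, 0.5)
    noise_sigma: float = 1.0
    missing_rate: float = 0.0
    seed: int = 42

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_rbps, self.n_samples_per_condition) <= 0:
            raise ValueError("counts must be positive")
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be > 0")
        if not 0 <= self.decoy_inaccessible_fraction < 1:
            raise ValueError("decoy fraction must be in [0,1)")
        n_pairs = self.n_overlapping_pairs + self.n_neighboring_pairs
        n_combos = (
            self.n_rbps * self.n_mirnas
            if self.n_mirnas > 0
            else self.n_rbps * (self.n_rbps - 1) // 2
        )
        if n_pairs > n_combos:
            raise ValueError(
                f"quota of {n_pairs} planted pairs exceeds the "
                f"{n_combos} available regulator pairs"
            )
        if n_pairs * self.genes_per_pair > self.n_genes:
            raise ValueError("planted-pair quota exceeds the gene count")
        if self.utr_length_range[0] < 4 * self.rbp_site_length_range[1]:
            raise ValueError("UTRs too short for the configured site lengths")

    @classmethod
    def small(cls, **overrides) -> "SimConfig":
        """A reduced configuration for replicate-heavy calibration runs."""
        defaults = dict(
            n_genes=60, n_rbps=5, n_mirnas=5, n_overlapping_pairs=6,
            n_neighboring_pairs=6, genes_per_pair=3,
            n_samples_per_condition=40,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class PlantedSite:
    regulator_id: str
    regulator_class: str
    gene_id: str
    start: int
    end: int
    decoy: bool = False  # planted below the accessibility threshold


@dataclass
class GroundTruthLedger:
    """Everything the generator planted, for exact round-trip checks."""

    config: SimConfig
    pair_scenarios: dict[tuple[str, str], str] = field(default_factory=dict)
    pair_genes: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    planted_sites: list[PlantedSite] = field(default_factory=list)
    gene_lengths: dict[str, int] = field(default_factory=dict)
    mirna_sequences: dict[str, str] = field(default_factory=dict)
    singleton_regulator: dict[str, str] = field(default_factory=dict)
    trio_coefficients: dict[str, dict] = field(default_factory=dict)
    missing_cells: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    @property
    def overlapping_pairs(self) -> set[tuple[str, str]]:
        return {p for p, s in self.pair_scenarios.items() if s == "overlapping"}

    @property
    def neighboring_pairs(self) -> set[tuple[str, str]]:
        return {p for p, s in self.pair_scenarios.items() if s == "neighboring"}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": dataclasses.asdict(self.config),
            "pair_scenarios": {
                f"{a}|{b}": s for (a, b), s in self.pair_scenarios.items()
            },
            "pair_genes": {
                f"{a}|{b}": genes for (a, b), genes in self.pair_genes.items()
            },
            "planted_sites": [dataclasses.asdict(s) for s in self.planted_sites],
            "gene_lengths": self.gene_lengths,
            "mirna_sequences": self.mirna_sequences,
            "singleton_regulator": self.singleton_regulator,
            "trio_coefficients": self.trio_coefficients,
            "missing_cells": self.missing_cells,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class SyntheticCatalog:
    """In-memory bundle of everything :func:`simulate_catalog` emits."""

    utrs: dict[str, UtrModel]  # with sequences attached
    sites: list[BindingSite]
    tracks: dict[str, AccessibilityTrack]
    mirnas: list[MatureMirna]
    ledger: GroundTruthLedger

    def write(self, outdir: str | Path) -> None:
        """Write the exact text formats the reading modules consume."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "annotation.tsv", "w") as fh:
            for g in sorted(self.utrs):
                u = self.utrs[g]
                for b in u.blocks:
                    fh.write(f"{g}\t{u.transcript_id}\t{u.chrom}\t{b[0]}\t{b[1]}\t{u.strand}\n")
        with open(outdir / "utrs.fasta", "w") as fh:
            for g in sorted(self.utrs):
                fh.write(f">{g}\n{self.utrs[g].sequence}\n")
        with open(outdir / "sites.bed", "w") as fh:
            for s in sorted(self.sites):
                fh.write(f"{s.gene_id}\t{s.start}\t{s.end}\t{s.regulator_id}\t0\t+\n")
        with open(outdir / "mirnas.fasta", "w") as fh:
            for m in self.mirnas:
                fh.write(f">{m.mirna_id}\n{m.sequence}\n")
        write_tracks_tsv(self.tracks, outdir / "accessibility.tsv")
        self.ledger.to_json(outdir / "ledger.json")


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, n)]


def _distinct_mirnas(rng: np.random.Generator, n: int) -> list[MatureMirna]:
    """Random 22-nt matures with pairwise-distinct seeds."""
    mirnas: list[MatureMirna] = []
    seeds: set[str] = set()
    while len(mirnas) < n:
        seq = "".join(_random_seq(rng, 22))
        if seed_of(seq) in seeds:
            continue
        seeds.add(seed_of(seq))
        mirnas.append(MatureMirna(f"miR-{len(mirnas) + 1:03d}", seq))
    return mirnas


def _scrub_unplanted_motifs(
    seq: np.ndarray,
    motifs: dict[str, str],
    planted_at: set[tuple[str, int]],
    protected: np.ndarray,
    rng: np.random.Generator,
    max_iter: int = 200,
) -> np.ndarray:
    """Mutate away motif occurrences the generator did not plant.

    ``planted_at`` holds (motif, start) positions that must survive;
    ``protected`` marks bases inside planted seed sites that may not be
    touched. Spurious occurrences necessarily contain at least one
    unprotected base (two distinct planted sites never tile a third
    occurrence here because planted sites are kept non-adjacent).
    """
    for _ in range(max_iter):
        dirty = False
        s = "".join(seq)
        for motif in motifs.values():
            pos = s.find(motif)
            while pos != -1:
                if (motif, pos) not in planted_at:
                    free = [i for i in range(pos, pos + SEED_LENGTH)
                            if not protected[i]]
                    if not free:
                        raise RuntimeError("cannot scrub fully protected motif")
                    i = int(rng.choice(free))
                    choices = [b for b in "ACGU" if b != seq[i]]
                    seq[i] = rng.choice(choices)
                    dirty = True
                    break
                pos = s.find(motif, pos + 1)
            if dirty:
                break
        if not dirty:
            return seq
    raise RuntimeError("motif scrubbing did not converge")


def simulate_catalog(config: SimConfig) -> SyntheticCatalog:
    """Generate annotation, sequences, sites, and accessibility tracks.

    Deterministic given ``config.seed``. The returned ledger records the
    scenario of every planted pair, every planted site (with its decoy
    flag), and the microRNA sequences, so downstream recovery can be
    checked against it exactly.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.utr_length_range
    gene_ids = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    ledger = GroundTruthLedger(config=config)
    ledger.gene_lengths = {g: int(n) for g, n in zip(gene_ids, lengths)}

    rbp_ids = [f"RBP{i + 1:02d}" for i in range(config.n_rbps)]
    mirnas = _distinct_mirnas(rng, config.n_mirnas)
    ledger.mirna_sequences = {m.mirna_id: m.sequence for m in mirnas}
    motifs = {m.mirna_id: target_motif(seed_of(m)) for m in mirnas}

    # --- choose planted pairs -------------------------------------------
    if config.n_mirnas > 0:
        combos = [(r, m.mirna_id) for r in rbp_ids for m in mirnas]
    else:
        combos = [(a, b) for i, a in enumerate(rbp_ids) for b in rbp_ids[i + 1:]]
    rng.shuffle(combos)
    planted_pairs = combos[: config.n_overlapping_pairs + config.n_neighboring_pairs]
    for i, pair in enumerate(planted_pairs):
        key = tuple(sorted(pair))
        scenario = "overlapping" if i < config.n_overlapping_pairs else "neighboring"
        ledger.pair_scenarios[key] = scenario

    # --- assign genes ----------------------------------------------------
    shuffled_genes = list(gene_ids)
    rng.shuffle(shuffled_genes)
    cursor = 0
    class_of = {r: "RBP" for r in rbp_ids}
    class_of.update({m.mirna_id: "miRNA" for m in mirnas})

    def plant(reg: str, gene: str, start: int, end: int) -> None:
        ledger.planted_sites.append(
            PlantedSite(reg, class_of[reg], gene, int(start), int(end))
        )

    for pair in planted_pairs:
        key = tuple(sorted(pair))
        scenario = ledger.pair_scenarios[key]
        genes = shuffled_genes[cursor: cursor + config.genes_per_pair]
        cursor += config.genes_per_pair
        ledger.pair_genes[key] = genes
        reg_a, reg_b = pair
        for gene in genes:
            utr_len = ledger.gene_lengths[gene]
            rbp_len = int(rng.integers(*config.rbp_site_length_range))
            if config.n_mirnas > 0:
                rbp_reg, seed_reg = reg_a, reg_b
                seed_len = SEED_LENGTH
            else:
                rbp_reg, seed_reg = reg_a, reg_b
                seed_len = int(rng.integers(*config.rbp_site_length_range))
            if scenario == "overlapping":
                # seed site in the middle region, RBP site intersecting it
                p = int(rng.integers(rbp_len + 1, utr_len - seed_len - rbp_len - 1))
                s_lo = max(0, p - rbp_len + 1)
                s_hi = min(utr_len - rbp_len, p + seed_len - 1)
                start = int(rng.integers(s_lo, s_hi + 1))
                plant(seed_reg, gene, p, p + seed_len)
                plant(rbp_reg, gene, start, start + rbp_len)
            else:
                gap = config.neighbor_gap_min
                p = int(rng.integers(1, utr_len - seed_len - rbp_len - gap - 2))
                start = int(
                    rng.integers(p + seed_len + gap, utr_len - rbp_len + 1)
                )
                plant(seed_reg, gene, p, p + seed_len)
                plant(rbp_reg, gene, start, start + rbp_len)

    all_regs = rbp_ids + [m.mirna_id for m in mirnas]
    for i, gene in enumerate(shuffled_genes[cursor:]):
        reg = all_regs[i % len(all_regs)]
        utr_len = ledger.gene_lengths[gene]
        if class_of[reg] == "miRNA":
            p = int(rng.integers(1, utr_len - SEED_LENGTH - 1))
            plant(reg, gene, p, p + SEED_LENGTH)
        else:
            n = int(rng.integers(*config.rbp_site_length_range))
            p = int(rng.integers(0, utr_len - n + 1))
            plant(reg, gene, p, p + n)
        ledger.singleton_regulator[gene] = reg

    # --- mark decoys (only on sites whose footprint is private) ----------
    if config.decoy_inaccessible_fraction > 0:
        private = []
        for i, s in enumerate(ledger.planted_sites):
            alone = all(
                o is s or o.gene_id != s.gene_id
                or o.end <= s.start or s.end <= o.start
                for o in ledger.planted_sites
            )
            if alone:
                private.append(i)
        n_decoys = int(round(config.decoy_inaccessible_fraction
                             * len(ledger.planted_sites)))
        for i in rng.choice(private, size=min(n_decoys, len(private)),
                            replace=False):
            ledger.planted_sites[i].decoy = True

    # --- sequences: plant seed motifs, scrub spurious occurrences --------
    utrs: dict[str, UtrModel] = {}
    tracks: dict[str, AccessibilityTrack] = {}
    planted_by_gene: dict[str, list[PlantedSite]] = {}
    for s in ledger.planted_sites:
        planted_by_gene.setdefault(s.gene_id, []).append(s)
    offset = 0
    a_beta, b_beta = config.accessibility_beta
    for gene in gene_ids:
        utr_len = ledger.gene_lengths[gene]
        seq = _random_seq(rng, utr_len)
        protected = np.zeros(utr_len, bool)
        planted_at: set[tuple[str, int]] = set()
        for s in planted_by_gene.get(gene, []):
            if s.regulator_class == "miRNA":
                motif = motifs[s.regulator_id]
                seq[s.start:s.end] = list(motif)
                protected[s.start:s.end] = True
                planted_at.add((motif, s.start))
        if config.n_mirnas > 0:
            seq = _scrub_unplanted_motifs(seq, motifs, planted_at, protected, rng)
        utrs[gene] = UtrModel(
            gene_id=gene, transcript_id=f"T-{gene}", strand="+",
            blocks=((offset, offset + utr_len),), chrom="chr1",
            sequence="".join(seq),
        )
        offset += utr_len + 100
        probs = rng.beta(a_beta, b_beta, utr_len)
        for s in planted_by_gene.get(gene, []):
            if s.decoy:
                probs[s.start:s.end] = rng.uniform(0.0, 0.1, s.end - s.start)
            else:
                probs[s.start:s.end] = rng.uniform(0.85, 1.0, s.end - s.start)
        tracks[gene] = AccessibilityTrack(gene, probs)

    sites = [
        BindingSite(s.regulator_id, s.regulator_class, s.gene_id, s.start, s.end)
        for s in ledger.planted_sites
    ]
    sites.sort()
    return SyntheticCatalog(utrs=utrs, sites=sites, tracks=tracks,
                            mirnas=mirnas, ledger=ledger)


def simulate_expression(
    config: SimConfig,
    ledger: GroundTruthLedger,
    force_null: bool = False,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Generate tumor and normal expression from the interaction model.

    Regulator expression is i.i.d. standard normal. Each pair-assigned
    gene's expression is a1*x1 + a2*x2 + a3*x1*x2 + noise with the trio's
    true coefficients (a3 = 0 for every trio when ``force_null`` is on —
    the calibration configuration); singleton genes follow a1*x + noise.
    Coefficients are shared between the two conditions; samples are not.
    The true coefficients are appended to the ledger. Missing values are
    injected completely at random at ``config.missing_rate`` and recorded.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 7001)))
    rbp_ids = [f"RBP{i + 1:02d}" for i in range(config.n_rbps)]
    mirna_ids = list(ledger.mirna_sequences)
    regulators = rbp_ids + mirna_ids
    genes = list(ledger.gene_lengths)

    def draw(rng_, rng_range):
        mag = rng_.uniform(*rng_range)
        return float(mag * rng_.choice([-1.0, 1.0]))

    for (a, b), scenario in ledger.pair_scenarios.items():
        for gene in ledger.pair_genes[(a, b)]:
            a3_range = (config.a3_range_overlapping if scenario == "overlapping"
                        else config.a3_range_neighboring)
            ledger.trio_coefficients[gene] = {
                "regulators": [a, b],
                "scenario": scenario,
                "a1": draw(rng, config.a1_range),
                "a2": draw(rng, config.a2_range),
                "a3": 0.0 if force_null else draw(rng, a3_range),
            }
    for gene, reg in ledger.singleton_regulator.items():
        ledger.trio_coefficients[gene] = {
            "regulators": [reg], "scenario": "singleton",
            "a1": draw(rng, config.a1_range), "a2": 0.0, "a3": 0.0,
        }

    matrices = []
    for cond in ("tumor", "normal"):
        n = config.n_samples_per_condition
        sample_ids = [f"{cond}_{i + 1:03d}" for i in range(n)]
        reg_x = pd.DataFrame(rng.standard_normal((n, len(regulators))),
                             index=sample_ids, columns=regulators)
        gene_y = pd.DataFrame(0.0, index=sample_ids, columns=genes)
        for gene, truth in ledger.trio_coefficients.items():
            regs = truth["regulators"]
            x1 = reg_x[regs[0]].to_numpy()
            y = truth["a1"] * x1
            if len(regs) == 2:
                x2 = reg_x[regs[1]].to_numpy()
                y = y + truth["a2"] * x2 + truth["a3"] * x1 * x2
            gene_y[gene] = y + rng.normal(0.0, config.noise_sigma, n)
        data = pd.concat([reg_x, gene_y], axis=1)
        if config.missing_rate > 0:
            mask = rng.random(data.shape) < config.missing_rate
            cells = [
                (data.index[i], data.columns[j])
                for i, j in zip(*np.nonzero(mask))
            ]
            ledger.missing_cells[cond] = cells
            data = data.mask(mask)
        matrices.append(ExpressionMatrix(data, cond))
    return matrices[0], matrices[1]
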