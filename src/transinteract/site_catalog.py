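"""Per-gene 3'UTR site catalog.

Builds the data structure the rest of the pipeline operates on: for each
gene, one representative 3'UTR (the longest one among its annotated
transcripts), and all regulator binding sites expressed in UTR-local
coordinates (0-based, half-open, position 0 = 5'-most UTR base).

Binding sites come from CLIP-seq-style interval catalogs (RBPs) or from
seed matching (microRNAs); both are normalized into :class:`BindingSite`
records and pooled into a :class:`SiteCatalog`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

RegulatorClass = Literal["RBP", "miRNA"]

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def _normalize_rna(seq: str) -> str:
    """Uppercase and convert T to U; validates the alphabet."""
    s = seq.upper().replace("T", "U")
    if not set(s) <= set("ACGU"):
        bad = sorted(set(s) - set("ACGU"))
        raise ValueError(f"non-RNA characters in sequence: {bad}")
    return s


@dataclass(frozen=True)
class UtrModel:
    """A gene's chosen (longest) 3'UTR.

    ``blocks`` are genomic 0-based half-open intervals, stored in
    transcript (5'->3') order: ascending genomic coordinates on the +
    strand, descending on the - strand, so that local coordinate 0 always
    corresponds to the 5'-most UTR base.
    """

    gene_id: str
    transcript_id: str
    strand: str
    blocks: tuple[tuple[int, int], ...]
    chrom: str = ""
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for start, end in self.blocks:
            if end <= start:
                raise ValueError(
                    f"malformed block [{start},{end}) on {self.transcript_id}"
                )
        if self.length <= 0:
            raise ValueError(f"UTR of {self.gene_id} has zero length")
        if self.sequence is not None:
            seq = _normalize_rna(self.sequence)
            if len(seq) != self.length:
                raise ValueError(
                    f"sequence length {len(seq)} != UTR length {self.length} "
                    f"for {self.gene_id}"
                )
            object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return sum(end - start for start, end in self.blocks)


@dataclass(frozen=True, order=True)
class BindingSite:
    """One regulator's interval on a gene's 3'UTR, in local coordinates."""

    regulator_id: str
    regulator_class: str
    gene_id: str
    start: int
    end: int
    source_study: str = ""

    def __post_init__(self) -> None:
        if self.regulator_class not in ("RBP", "miRNA"):
            raise ValueError(f"unknown regulator class {self.regulator_class!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid site interval [{self.start},{self.end}) "
                f"for {self.regulator_id} on {self.gene_id}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SiteCatalog:
    """Pooled binding sites on per-gene 3'UTR models."""

    utrs: dict[str, UtrModel]
    sites: list[BindingSite] = field(default_factory=list)

    @property
    def regulators(self) -> set[tuple[str, str]]:
        return {(s.regulator_id, s.regulator_class) for s in self.sites}

    def sites_by_gene(self) -> dict[str, list[BindingSite]]:
        out: dict[str, list[BindingSite]] = {}
        for s in self.sites:
            out.setdefault(s.gene_id, []).append(s)
        return out

    def validate(self) -> None:
        for s in self.sites:
            utr = self.utrs.get(s.gene_id)
            if utr is None:
                raise ValueError(f"site on unknown gene {s.gene_id}")
            if s.end > utr.length:
                raise ValueError(
                    f"site [{s.start},{s.end}) of {s.regulator_id} exceeds "
                    f"UTR length {utr.length} of {s.gene_id}"
                )


# ---------------------------------------------------------------------------
# Longest-UTR selection
# ---------------------------------------------------------------------------

def select_longest_utr(
    annotation: Mapping[str, Sequence[UtrModel]] | Iterable[UtrModel],
) -> dict[str, UtrModel]:
    """Pick, per gene, the transcript with the longest total 3'UTR.

    Ties are broken by the lexicographically smallest transcript id, so the
    result is deterministic under input reordering. Genes whose transcripts
    all have zero-length UTRs are dropped (a UtrModel cannot have length 0,
    so such transcripts never reach this function; absent genes simply have
    no entry).
    """
    if isinstance(annotation, Mapping):
        models: list[UtrModel] = [m for ms in annotation.values() for m in ms]
    else:
        models = list(annotation)
    chosen: dict[str, UtrModel] = {}
    for m in models:
        cur = chosen.get(m.gene_id)
        if (
            cur is None
            or m.length > cur.length
            or (m.length == cur.length and m.transcript_id < cur.transcript_id)
        ):
            chosen[m.gene_id] = m
    return chosen


# ---------------------------------------------------------------------------
# Coordinate conversion
# ---------------------------------------------------------------------------

def genomic_to_local(
    interval: tuple[int, int], utr: UtrModel
) -> tuple[int, int] | None:
    """Map a genomic 0-based half-open interval onto UTR-local coordinates.

    Walks blocks in transcript order (reverse genomic order on the -
    strand). Returns the one contiguous local interval covering the union
    of the per-block intersections, or None if the interval misses the UTR
    entirely. A site spanning a block junction therefore maps to a single
    local interval; a site extending past the UTR edge is clipped.
    """
    g_start, g_end = interval
    if g_end <= g_start:
        raise ValueError(f"malformed genomic interval [{g_start},{g_end})")
    lo: int | None = None
    hi: int | None = None
    offset = 0
    for b_start, b_end in utr.blocks:
        inter_lo = max(g_start, b_start)
        inter_hi = min(g_end, b_end)
        if inter_lo < inter_hi:
            if utr.strand == "+":
                loc_lo = offset + (inter_lo - b_start)
                loc_hi = offset + (inter_hi - b_start)
            else:
                # on - strand local 0 is the highest genomic coordinate
                loc_lo = offset + (b_end - inter_hi)
                loc_hi = offset + (b_end - inter_lo)
            lo = loc_lo if lo is None else min(lo, loc_lo)
            hi = loc_hi if hi is None else max(hi, loc_hi)
        offset += b_end - b_start
    if lo is None:
        return None
    return lo, hi


def local_to_genomic(interval: tuple[int, int], utr: UtrModel) -> tuple[int, int]:
    """Inverse of :func:`genomic_to_local` for single-block UTRs."""
    if len(utr.blocks) != 1:
        raise ValueError("local_to_genomic supports single-block UTRs only")
    (b_start, b_end), (lo, hi) = utr.blocks[0], interval
    if utr.strand == "+":
        return b_start + lo, b_start + hi
    return b_end - hi, b_end - lo


# ---------------------------------------------------------------------------
# Pooling
# ---------------------------------------------------------------------------

def _merge_intervals(
    intervals: list[tuple[int, int]], book_ended: bool = True
) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and (start <= merged[-1][1] if book_ended else start < merged[-1][1]):
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def pool_sites(
    utrs: dict[str, UtrModel],
    sites: Iterable[BindingSite],
    merge_same_regulator: bool = True,
) -> SiteCatalog:
    """Pool binding sites into a catalog, deduplicating exact duplicates.

    Sites from separate studies of the same regulator are collapsed:
    identical records become one, and — when ``merge_same_regulator`` is on
    (the default, because broad CLIP peaks are typically unions of several
    binding events) — overlapping or book-ended intervals of one regulator
    on one gene are merged into their union. Sites on unknown genes or
    exceeding the UTR are rejected with a logged validation error.
    """
    by_key: dict[tuple[str, str, str], list[tuple[int, int]]] = {}
    classes: dict[str, str] = {}
    n_rejected = 0
    for s in sites:
        utr = utrs.get(s.gene_id)
        if utr is None or s.end > utr.length:
            logger.warning("rejecting site %s: gene missing or exceeds UTR", s)
            n_rejected += 1
            continue
        classes[s.regulator_id] = s.regulator_class
        by_key.setdefault((s.regulator_id, s.regulator_class, s.gene_id), []).append(
            (s.start, s.end)
        )
    pooled: list[BindingSite] = []
    for (reg, cls, gene), intervals in by_key.items():
        if merge_same_regulator:
            kept = _merge_intervals(intervals)
        else:
            kept = sorted(set(intervals))
        pooled.extend(
            BindingSite(reg, cls, gene, start, end) for start, end in kept
        )
    if n_rejected:
        logger.warning("pool_sites rejected %d invalid sites", n_rejected)
    pooled.sort()
    return SiteCatalog(utrs=dict(utrs), sites=pooled)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def summarize_catalog(
    catalog: SiteCatalog,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, float]]:
    """Per-regulator and per-gene summary tables plus catalog-wide stats.

    Returns ``(per_regulator, per_gene, overall)`` where ``overall`` holds
    the mean/median number of sites and of distinct regulators per gene —
    the usual "a typical regulator binds N genes" summary surface.
    """
    rows = [
        (s.regulator_id, s.regulator_class, s.gene_id) for s in catalog.sites
    ]
    if not rows:
        return (
            pd.DataFrame(
                columns=["regulator_id", "regulator_class", "n_target_genes",
                         "n_sites", "mean_sites_per_gene"]
            ),
            pd.DataFrame(columns=["gene_id", "n_sites", "n_regulators"]),
            {},
        )
    df = pd.DataFrame(rows, columns=["regulator_id", "regulator_class", "gene_id"])
    per_reg = (
        df.groupby(["regulator_id", "regulator_class"])
        .agg(n_target_genes=("gene_id", "nunique"), n_sites=("gene_id", "size"))
        .reset_index()
    )
    per_reg["mean_sites_per_gene"] = per_reg["n_sites"] / per_reg["n_target_genes"]
    per_gene = (
        df.groupby("gene_id")
        .agg(n_sites=("regulator_id", "size"), n_regulators=("regulator_id", "nunique"))
        .reset_index()
    )
    overall = {
        "mean_sites_per_gene": float(per_gene["n_sites"].mean()),
        "median_sites_per_gene": float(per_gene["n_sites"].median()),
        "mean_regulators_per_gene": float(per_gene["n_regulators"].mean()),
        "median_regulators_per_gene": float(per_gene["n_regulators"].median()),
        "n_sites_total": int(len(df)),
        "n_genes": int(per_gene.shape[0]),
        "n_regulators": int(per_reg.shape[0]),
    }
    return per_reg, per_gene, overall


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def read_annotation_gtf(path: str | Path) -> list[UtrModel]:
    """Read ``three_prime_utr`` features from a GTF file into UtrModels.

    Blocks of one transcript are grouped and ordered 5'->3'. This is a
    minimal reader for the GTF subset the pipeline consumes, not a general
    GTF parser. Malformed records are skipped with a logged parse error.
    """
    per_tx: dict[tuple[str, str], dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "three_prime_utr":
                continue
            chrom, start1, end, strand, attrs = (
                fields[0], fields[3], fields[4], fields[6], fields[8],
            )
            try:
                start0, end0 = int(start1) - 1, int(end)  # GTF is 1-based closed
                if end0 <= start0:
                    raise ValueError("end <= start")
            except ValueError as exc:
                logger.warning("%s:%d skipped (%s)", path, lineno, exc)
                continue
            attr = dict(_GTF_ATTR.findall(attrs))
            gene, tx = attr.get("gene_id"), attr.get("transcript_id")
            if not gene or not tx:
                logger.warning("%s:%d missing gene_id/transcript_id", path, lineno)
                continue
            rec = per_tx.setdefault(
                (gene, tx), {"chrom": chrom, "strand": strand, "blocks": []}
            )
            rec["blocks"].append((start0, end0))
    models = []
    for (gene, tx), rec in per_tx.items():
        blocks = sorted(rec["blocks"], reverse=(rec["strand"] == "-"))
        models.append(
            UtrModel(gene, tx, rec["strand"], tuple(blocks), chrom=rec["chrom"])
        )
    return models


def read_annotation_tsv(path: str | Path, one_based: bool = False) -> list[UtrModel]:
    """Read a 6-column annotation TSV (gene, transcript, chrom, start, end, strand).

    Set ``one_based`` for 1-based inclusive coordinates; the default is
    0-based half-open. Multiple rows of one transcript become blocks.
    """
    df = pd.read_csv(
        path, sep="\t",
        names=["gene_id", "transcript_id", "chrom", "start", "end", "strand"],
        comment="#",
    )
    models = []
    for (gene, tx), grp in df.groupby(["gene_id", "transcript_id"], sort=True):
        strand = grp["strand"].iloc[0]
        blocks = []
        for _, row in grp.iterrows():
            start, end = int(row["start"]), int(row["end"])
            if one_based:
                start -= 1
            if end <= start:
                logger.warning("skipping malformed block %s on %s", (start, end), tx)
                continue
            blocks.append((start, end))
        if not blocks:
            continue
        blocks.sort(reverse=(strand == "-"))
        models.append(
            UtrModel(str(gene), str(tx), strand, tuple(blocks),
                     chrom=str(grp["chrom"].iloc[0]))
        )
    return models


def read_sites_bed(
    path: str | Path,
    utrs: Mapping[str, UtrModel],
    coords: Literal["local", "genomic"] = "local",
    regulator_class: str = "RBP",
) -> list[BindingSite]:
    """Read BED6 binding sites (name column = regulator id).

    In ``local`` mode the chrom column holds the gene id and intervals are
    UTR-local already; in ``genomic`` mode the chrom column is a genomic
    chromosome and each interval is mapped through every UTR on that
    chromosome (strand must match), clipping to the UTR.
    """
    bed = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    sites: list[BindingSite] = []
    if coords == "local":
        for _, row in bed.iterrows():
            gene = str(row["chrom"])
            utr = utrs.get(gene)
            if utr is None:
                logger.warning("site on unknown gene %s skipped", gene)
                continue
            start, end = int(row["start"]), int(row["end"])
            start, end = max(0, start), min(utr.length, end)  # clip to UTR
            if end <= start:
                continue
            sites.append(BindingSite(str(row["name"]), regulator_class, gene, start, end))
    else:
        by_chrom: dict[str, list[UtrModel]] = {}
        for utr in utrs.values():
            by_chrom.setdefault(utr.chrom, []).append(utr)
        for _, row in bed.iterrows():
            for utr in by_chrom.get(str(row["chrom"]), []):
                if str(row["strand"]) not in (".", utr.strand):
                    continue
                local = genomic_to_local((int(row["start"]), int(row["end"])), utr)
                if local is not None:
                    sites.append(
                        BindingSite(str(row["name"]), regulator_class,
                                    utr.gene_id, local[0], local[1])
                    )
    return sites


def read_utr_fasta(path: str | Path, utrs: dict[str, UtrModel]) -> dict[str, UtrModel]:
    """Attach UTR sequences from a FASTA keyed by gene id (T normalized to U)."""
    from Bio import SeqIO

    out = dict(utrs)
    for rec in SeqIO.parse(str(path), "fasta"):
        gene = rec.id
        if gene in out:
            out[gene] = replace(out[gene], sequence=_normalize_rna(str(rec.seq)))
    return out


def write_catalog_tsv(catalog: SiteCatalog, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (s.gene_id, s.start, s.end, s.regulator_id, s.regulator_class)
            for s in catalog.sites
        ],
        columns=["gene_id", "start", "end", "regulator_id", "regulator_class"],
    )
    df.to_csv(path, sep="\t", index=False)
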