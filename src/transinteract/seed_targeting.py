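"""MicroRNA seed-match target prediction.

A mature microRNA pairs with its mRNA target chiefly through the *seed
region*, nucleotides 2-8 of the mature sequence. The canonical target
site on the mRNA is the reverse complement of that 7-mer. This module
extracts seeds, derives target motifs, and scans 3'UTR sequences for
exact motif occurrences — a deliberately simple stand-in for full
context-scored target prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .site_catalog import BindingSite, UtrModel, _RNA_COMPLEMENT, _normalize_rna

SEED_LENGTH = 7


@dataclass(frozen=True)
class MatureMirna:
    """A mature microRNA sequence, 5'->3', RNA alphabet."""

    mirna_id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _normalize_rna(self.sequence))
        if len(self.sequence) < 8:
            raise ValueError(
                f"mature sequence of {self.mirna_id} is shorter than 8 nt"
            )


@dataclass(frozen=True)
class SeedMatch:
    """One exact seed-complement occurrence on a UTR (local, half-open)."""

    mirna_id: str
    gene_id: str
    start: int
    end: int
    site_motif: str

    def __post_init__(self) -> None:
        if self.end - self.start != SEED_LENGTH:
            raise ValueError("seed match must span exactly 7 nt")


def seed_of(mirna: MatureMirna | str) -> str:
    """Seed region: nucleotides 2-8 (1-based) of the mature sequence."""
    seq = mirna.sequence if isinstance(mirna, MatureMirna) else _normalize_rna(mirna)
    if len(seq) < 8:
        raise ValueError("mature sequence shorter than 8 nt has no seed")
    return seq[1:8]


def target_motif(seed: str) -> str:
    """Reverse complement of the seed in the RNA alphabet: the mRNA site."""
    seed = _normalize_rna(seed)
    return seed.translate(_RNA_COMPLEMENT)[::-1]


def scan_utr(mirna: MatureMirna, utr: UtrModel) -> list[SeedMatch]:
    """All exact target-motif occurrences in the UTR sequence, sorted by start.

    Occurrences may overlap each other (a motif with internal periodicity
    can match at adjacent offsets).
    """
    if utr.sequence is None:
        raise ValueError(f"UTR of {utr.gene_id} has no sequence to scan")
    motif = target_motif(seed_of(mirna))
    matches = []
    pos = utr.sequence.find(motif)
    while pos != -1:
        matches.append(
            SeedMatch(mirna.mirna_id, utr.gene_id, pos, pos + SEED_LENGTH, motif)
        )
        pos = utr.sequence.find(motif, pos + 1)
    return matches


def scan_catalog(
    mirnas: Iterable[MatureMirna], utrs: dict[str, UtrModel]
) -> list[BindingSite]:
    """Scan every UTR with every miRNA; matches become miRNA BindingSites.

    Homologous family members sharing a seed are scanned independently and
    yield coincident sites — they are treated as independent regulators.
    """
    sites = []
    for mirna in mirnas:
        for utr in utrs.values():
            if utr.sequence is None:
                continue
            for m in scan_utr(mirna, utr):
                sites.append(
                    BindingSite(m.mirna_id, "miRNA", m.gene_id, m.start, m.end)
                )
    return sites


def read_mirna_fasta(path: str | Path) -> list[MatureMirna]:
    from Bio import SeqIO

    return [
        MatureMirna(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_matches_bed(matches: Iterable[SeedMatch], path: str | Path) -> None:
    """BED6 output (chrom = gene id, name = mirna id), ingestible as sites."""
    with open(path, "w") as fh:
        for m in matches:
            fh.write(f"{m.gene_id}\t{m.start}\t{m.end}\t{m.mirna_id}\t0\t+\n")
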