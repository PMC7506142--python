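"""Local RNA-structure accessibility filter.

Single-strand-binding RBPs require their site to be accessible (unpaired).
This module consumes per-nucleotide unpaired-probability tracks — the
``_lunp`` output dialect of RNAplfold (typically computed with window
W = 80 and span L = 40) or a plain TSV — and keeps a binding site when the
mean unpaired probability over the site reaches a threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .site_catalog import BindingSite

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.5


@dataclass
class AccessibilityTrack:
    """Per-nucleotide unpaired probabilities for one gene's 3'UTR."""

    gene_id: str
    probs: np.ndarray
    window_w: int = 80
    span_l: int = 40

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 1:
            raise ValueError("probs must be a 1-D vector")
        if ((self.probs < 0) | (self.probs > 1)).any():
            raise ValueError(f"probabilities outside [0,1] for {self.gene_id}")

    def __len__(self) -> int:
        return len(self.probs)


def read_lunp(path: str | Path, gene_id: str | None = None,
              length: int | None = None) -> AccessibilityTrack:
    """Read a ``_lunp``-style file: position (1-based) and P(unpaired).

    Only the single-nucleotide column (the first probability column) is
    consumed. Comment lines start with '#'. Missing positions are filled
    with 0 and counted in a warning.
    """
    path = Path(path)
    if gene_id is None:
        gene_id = path.name.removesuffix("_lunp").removesuffix(".lunp")
    entries: dict[int, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            try:
                pos = int(fields[0])
                prob = float(fields[1])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: unparseable row ({exc})")
            if not 0.0 <= prob <= 1.0:
                raise ValueError(
                    f"{path}:{lineno}: probability {prob} outside [0,1]"
                )
            entries[pos] = prob
    n = length if length is not None else (max(entries) if entries else 0)
    probs = np.zeros(n)
    missing = 0
    for i in range(1, n + 1):
        if i in entries:
            probs[i - 1] = entries[i]
        else:
            missing += 1
    if missing:
        logger.warning("%s: %d positions missing, filled with 0", path, missing)
    return AccessibilityTrack(gene_id, probs)


def read_tracks_tsv(path: str | Path) -> dict[str, AccessibilityTrack]:
    """Read a 3-column TSV (gene_id, pos 1-based, prob) into tracks."""
    df = pd.read_csv(path, sep="\t", names=["gene_id", "pos", "prob"], comment="#")
    if ((df["prob"] < 0) | (df["prob"] > 1)).any():
        raise ValueError(f"{path}: probability outside [0,1]")
    tracks = {}
    for gene, grp in df.groupby("gene_id", sort=True):
        n = int(grp["pos"].max())
        probs = np.zeros(n)
        probs[grp["pos"].to_numpy(int) - 1] = grp["prob"].to_numpy()
        tracks[str(gene)] = AccessibilityTrack(str(gene), probs)
    return tracks


def write_tracks_tsv(tracks: Mapping[str, AccessibilityTrack], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(tracks):
            for i, p in enumerate(tracks[gene].probs, start=1):
                fh.write(f"{gene}\t{i}\t{p:.6g}\n")


def site_accessibility(site: BindingSite, track: AccessibilityTrack) -> float:
    """Mean single-nucleotide unpaired probability over the site."""
    return float(track.probs[site.start:site.end].mean())


def filter_accessible(
    sites: Iterable[BindingSite],
    tracks: Mapping[str, AccessibilityTrack],
    min_mean_access: float = DEFAULT_THRESHOLD,
    strict: bool = True,
) -> tuple[list[BindingSite], list[BindingSite]]:
    """Partition sites into (kept, dropped) by mean accessibility.

    A site is kept iff its mean unpaired probability is >= the threshold
    (boundary inclusive). A missing track is an error in strict mode; in
    lenient mode the site is kept and the omission logged.
    """
    kept: list[BindingSite] = []
    dropped: list[BindingSite] = []
    n_untracked = 0
    for site in sites:
        track = tracks.get(site.gene_id)
        if track is None:
            if strict:
                raise KeyError(f"no accessibility track for gene {site.gene_id}")
            n_untracked += 1
            kept.append(site)
            continue
        if site.end > len(track):
            raise ValueError(
                f"site [{site.start},{site.end}) exceeds track length "
                f"{len(track)} on {site.gene_id}"
            )
        (kept if site_accessibility(site, track) >= min_mean_access else dropped).append(site)
    if n_untracked:
        logger.warning("%d sites kept without an accessibility track", n_untracked)
    return kept, dropped
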