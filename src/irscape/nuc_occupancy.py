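"""Normalized nucleosome-occupancy (nNuOc) metaprofiles around IR centers.

Nucleosome calls arrive as genomic intervals (BED-like; MNase-seq- or
chemical-cleavage-derived, both consumed identically).  A base is occupied
(value 1) when at least one call covers it, otherwise 0.  Each IR-centered
window of the binary track is divided by its chromosome's mean occupancy —
so a flat, fully tiled chromosome profiles at exactly 1.0 — oriented so
positive offsets run downstream in the owning gene's direction, and the
windows are averaged per offset across IRs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome_partition import GeneModel, Region, convergent_gene_ids


@dataclass
class OccupancyTrack:
    """Per-bp binary occupancy over one chromosome."""

    values: np.ndarray  # uint8 0/1
    chrom_mean: float


def build_track(
    calls: Iterable[tuple[int, int]], chrom_length: int
) -> OccupancyTrack:
    """Union coverage of (possibly overlapping) nucleosome intervals.

    Intervals are 0-based half-open; an interval outside [0, chrom_length)
    or with negative length is an error naming the interval.
    """
    delta = np.zeros(chrom_length + 1, dtype=np.int64)
    for s, e in calls:
        if e < s or s < 0 or e > chrom_length:
            raise ValueError(
                f"nucleosome interval [{s}, {e}) outside chromosome of "
                f"length {chrom_length}"
            )
        delta[s] += 1
        delta[e] -= 1
    cov = np.cumsum(delta[:-1])
    values = (cov > 0).astype(np.uint8)
    return OccupancyTrack(values=values, chrom_mean=float(values.mean()))


def build_tracks(
    callset: dict[str, list[tuple[int, int]]], chrom_lengths: dict[str, int]
) -> dict[str, OccupancyTrack]:
    return {
        chrom: build_track(callset.get(chrom, []), length)
        for chrom, length in chrom_lengths.items()
    }


@dataclass
class NnuocProfile:
    """Average normalized occupancy per offset around IR centers."""

    offsets: np.ndarray  # -flank .. +flank
    values: np.ndarray
    n_irs: int
    n_skipped: int = 0  # IR windows dropped (chromosome edge or empty track)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "mean_nnuoc": self.values, "n": self.n_irs}
        )


def select_ir_windows(
    irs: pd.DataFrame,
    regions: Sequence[Region],
    genes: dict[str, GeneModel],
    kinds: Sequence[str] = ("UTR3",),
    convergent_only: bool = False,
) -> list[tuple[str, int, str]]:
    """Oriented (chrom, center, strand) windows for IRs inside genic regions.

    Keeps IRs whose center falls inside a region of one of ``kinds``; the
    window strand is the owning gene's.  ``convergent_only`` restricts to
    genes flanking a CON intergenic region (avoiding the nucleosome-depleted
    promoter of a downstream tandem gene in the averaged profile).  Any
    additional filtering (by type, arm length, Q group) is done on ``irs``
    by the caller beforehand.
    """
    conv = convergent_gene_ids(regions) if convergent_only else None
    by_chrom: dict[str, np.ndarray] = {}
    for chrom, sub in irs.groupby("chrom"):
        by_chrom[chrom] = np.sort(sub["center"].to_numpy(dtype=np.int64))
    windows: list[tuple[str, int, str]] = []
    for region in regions:
        if region.kind not in kinds or not region.genes:
            continue
        gid = region.genes[0]
        if conv is not None and gid not in conv:
            continue
        centers = by_chrom.get(region.chrom)
        if centers is None:
            continue
        i0 = np.searchsorted(centers, region.start, side="left")
        i1 = np.searchsorted(centers, region.end, side="left")
        strand = genes[gid].strand
        windows.extend(
            (region.chrom, int(c), strand) for c in centers[i0:i1]
        )
    return windows


def nnuoc_profile(
    tracks: dict[str, OccupancyTrack],
    windows: Sequence[tuple[str, int, str]],
    flank: int = 200,
) -> NnuocProfile:
    """Average normalized occupancy around a set of oriented centers.

    ``windows`` holds (chrom, center, strand) triples — typically IR centers
    with the strand of the owning gene, so upstream/downstream asymmetry is
    meaningful after averaging.  Windows truncated by a chromosome end, or
    on a chromosome with zero mean occupancy (normalization undefined), are
    skipped and counted in ``n_skipped``.
    """
    if not windows:
        raise ValueError("no IR windows to profile")
    width = 2 * flank + 1
    acc = np.zeros(width, dtype=float)
    n = 0
    skipped = 0
    for chrom, center, strand in windows:
        track = tracks.get(chrom)
        if track is None or track.chrom_mean == 0.0:
            skipped += 1
            continue
        lo, hi = center - flank, center + flank + 1
        if lo < 0 or hi > track.values.size:
            skipped += 1
            continue
        win = track.values[lo:hi].astype(float)
        if strand == "-":
            win = win[::-1]
        acc += win / track.chrom_mean
        n += 1
    if n == 0:
        raise ValueError("every IR window was skipped; nothing to average")
    return NnuocProfile(
        offsets=np.arange(-flank, flank + 1),
        values=acc / n,
        n_irs=n,
        n_skipped=skipped,
    )
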