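"""Detection of maximal perfect inverted repeats (IRs).

An inverted repeat is two perfectly complementary arms ("repeat units") of
length ``R`` separated by a spacer of length ``S``; read 5'->3' it is
identical on both strands and can extrude into a cruciform under negative
supercoiling.  The scanner reports every IR with ``R >= 5``, ``S <= 8`` and
total length ``2R + S >= 13`` — the sequence requirements for cruciform
competence used throughout the package — after pruning IRs nested inside
larger ones.

Coordinates are 0-based half-open.  Each IR is mapped to a single ``center``
coordinate, the left-of-middle base of its span.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .alphabet import COMPLEMENT, decode, encode

MIN_ARM = 5
MAX_SPACER = 8
MIN_TOTAL = 13


@dataclass(frozen=True)
class IRecord:
    """One detected perfect inverted repeat.

    ``arm_len`` is the repeat-unit length R, ``spacer_len`` the spacer S;
    the conventional name of the motif class is ``R{arm_len}S{spacer_len}``.
    """

    chrom: str
    start: int
    end: int
    arm_len: int
    spacer_len: int
    left_arm_seq: str = field(compare=False, default="")

    @property
    def center(self) -> int:
        """Genomic position of the central base (left-of-middle when the
        total length is even)."""
        return self.start + (self.end - self.start - 1) // 2

    @property
    def name(self) -> str:
        return f"R{self.arm_len}S{self.spacer_len}"

    def __post_init__(self) -> None:
        if self.end - self.start != 2 * self.arm_len + self.spacer_len:
            raise ValueError("interval length inconsistent with R and S")


def _scan_arrays(
    codes: np.ndarray,
    min_arm: int = MIN_ARM,
    max_spacer: int = MAX_SPACER,
    min_total: int = MIN_TOTAL,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Core scan on a coded sequence.

    For every gap position and spacer size the two arms are extended
    outward until the next base pair fails to be Watson-Crick complementary
    (or the sequence ends), so every emitted candidate is maximal for its
    (gap, spacer).  Returns parallel arrays (start, arm_len, spacer_len)
    before containment pruning.
    """
    L = len(codes)
    cseq = COMPLEMENT[codes]
    starts: list[np.ndarray] = []
    arms: list[np.ndarray] = []
    spacers: list[np.ndarray] = []

    def flush(gaps: np.ndarray, r: int, s: int) -> None:
        if gaps.size and r >= min_arm and 2 * r + s >= min_total:
            starts.append(gaps - r)
            arms.append(np.full(gaps.size, r, dtype=np.int64))
            spacers.append(np.full(gaps.size, s, dtype=np.int64))

    for s in range(max_spacer + 1):
        # gap position m: spacer occupies [m, m+s); innermost pair (m-1, m+s)
        if L < s + 2:
            continue
        gaps = np.arange(1, L - s, dtype=np.int64)
        k = 0
        while gaps.size:
            left = gaps - 1 - k
            right = gaps + s + k
            inb = (left >= 0) & (right < L)
            flush(gaps[~inb], k, s)
            gaps, left, right = gaps[inb], left[inb], right[inb]
            if not gaps.size:
                break
            match = codes[left] == cseq[right]
            flush(gaps[~match], k, s)
            gaps = gaps[match]
            k += 1

    if not starts:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty.copy(), empty.copy()
    return (
        np.concatenate(starts),
        np.concatenate(arms),
        np.concatenate(spacers),
    )


def _prune_arrays(
    start: np.ndarray, arm: np.ndarray, spacer: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Containment pruning on parallel candidate arrays.

    Drops any candidate whose interval is a proper sub-interval of another
    candidate; among identical intervals keeps a single record with the
    largest arm (ties: smallest spacer) — the decomposition with the most
    paired bases, which dominates cruciform stem energetics.
    """
    if start.size == 0:
        return start, arm, spacer
    end = start + 2 * arm + spacer

    # deduplicate identical intervals: keep max arm, then min spacer
    order = np.lexsort((spacer, -arm, end, start))
    start, arm, spacer, end = start[order], arm[order], spacer[order], end[order]
    first = np.ones(start.size, dtype=bool)
    first[1:] = (start[1:] != start[:-1]) | (end[1:] != end[:-1])
    start, arm, spacer, end = start[first], arm[first], spacer[first], end[first]

    # containment sweep: sort by (start asc, end desc); an interval is
    # contained iff some earlier interval in this order reaches at least as
    # far right.
    order = np.lexsort((-end, start))
    start, arm, spacer, end = start[order], arm[order], spacer[order], end[order]
    keep = np.ones(start.size, dtype=bool)
    if start.size > 1:
        running = np.maximum.accumulate(end)
        keep[1:] = end[1:] > running[:-1]
    start, arm, spacer, end = start[keep], arm[keep], spacer[keep], end[keep]

    order = np.lexsort((end, start))
    return start[order], arm[order], spacer[order]


def _records(
    codes: np.ndarray,
    chrom: str,
    start: np.ndarray,
    arm: np.ndarray,
    spacer: np.ndarray,
) -> list[IRecord]:
    return [
        IRecord(
            chrom=chrom,
            start=int(a),
            end=int(a + 2 * r + s),
            arm_len=int(r),
            spacer_len=int(s),
            left_arm_seq=decode(codes[a : a + r]),
        )
        for a, r, s in zip(start, arm, spacer)
    ]


def find_maximal_irs(
    seq: "str | np.ndarray",
    chrom: str = "chr",
    min_arm: int = MIN_ARM,
    max_spacer: int = MAX_SPACER,
    min_total: int = MIN_TOTAL,
) -> list[IRecord]:
    """Find all maximal, containment-pruned perfect IRs in a sequence.

    ``seq`` may be a nucleotide string over {A,C,G,T,N} (case folded) or an
    already-encoded uint8 array.  Records are sorted by start coordinate.
    Sequences with characters outside the alphabet raise ``ValueError``.
    """
    codes = encode(seq) if isinstance(seq, str) else np.asarray(seq, dtype=np.uint8)
    start, arm, spacer = _scan_arrays(codes, min_arm, max_spacer, min_total)
    start, arm, spacer = _prune_arrays(start, arm, spacer)
    return _records(codes, chrom, start, arm, spacer)


def prune_contained(candidates: Sequence[IRecord]) -> list[IRecord]:
    """Containment pruning over IRecord objects (see ``_prune_arrays``)."""
    if not candidates:
        return []
    by_chrom: dict[str, list[IRecord]] = {}
    for rec in candidates:
        by_chrom.setdefault(rec.chrom, []).append(rec)
    out: list[IRecord] = []
    for chrom in sorted(by_chrom):
        recs = by_chrom[chrom]
        start = np.array([r.start for r in recs], dtype=np.int64)
        arm = np.array([r.arm_len for r in recs], dtype=np.int64)
        spacer = np.array([r.spacer_len for r in recs], dtype=np.int64)
        ks, ka, kp = _prune_arrays(start, arm, spacer)
        kept = {(int(a), int(r), int(s)) for a, r, s in zip(ks, ka, kp)}
        chosen = [
            rec for rec in recs if (rec.start, rec.arm_len, rec.spacer_len) in kept
        ]
        chosen.sort(key=lambda r: (r.start, r.end))
        out.extend(chosen)
    return out


def scan_genome(
    genome: "dict[str, np.ndarray]",
    min_arm: int = MIN_ARM,
    max_spacer: int = MAX_SPACER,
    min_total: int = MIN_TOTAL,
) -> list[IRecord]:
    """Run the scanner over every chromosome of a coded genome."""
    out: list[IRecord] = []
    for chrom in genome:
        out.extend(
            find_maximal_irs(genome[chrom], chrom, min_arm, max_spacer, min_total)
        )
    return out


def centers_by_chrom(irs: Iterable[IRecord]) -> dict[str, np.ndarray]:
    """Sorted IR-center coordinates per chromosome (for fast interval queries)."""
    acc: dict[str, list[int]] = {}
    for rec in irs:
        acc.setdefault(rec.chrom, []).append(rec.center)
    return {c: np.sort(np.array(v, dtype=np.int64)) for c, v in acc.items()}
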