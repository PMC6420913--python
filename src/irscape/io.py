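"""File-format plumbing: FASTA, BED, GFF3 and the package's TSV tables.

Coordinates follow the usual conventions: BED and internal intervals are
0-based half-open, GFF3 is 1-based inclusive, and annotation TSVs carry
1-based anchor positions.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import decode, encode
from .ir_scan import IRecord


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: "str | Path") -> dict[str, np.ndarray]:
    """Read a (multi-record) FASTA into coded uint8 arrays, folding case."""
    genome: dict[str, np.ndarray] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        genome[record.id] = encode(str(record.seq))
    if not genome:
        raise ValueError(f"no FASTA records in {path}")
    return genome


def write_fasta(genome: dict[str, np.ndarray], path: "str | Path") -> None:
    records = [
        SeqRecord(Seq(decode(codes)), id=chrom, description="")
        for chrom, codes in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# IR tables
# ---------------------------------------------------------------------------

IR_COLUMNS = ["chrom", "start", "end", "arm_len", "spacer_len", "center", "left_arm_seq"]


def irs_to_frame(irs: Sequence[IRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "arm_len": r.arm_len,
                "spacer_len": r.spacer_len,
                "center": r.center,
                "left_arm_seq": r.left_arm_seq,
            }
            for r in irs
        ],
        columns=IR_COLUMNS,
    )


def frame_to_irs(frame: pd.DataFrame) -> list[IRecord]:
    return [
        IRecord(
            chrom=str(row.chrom),
            start=int(row.start),
            end=int(row.end),
            arm_len=int(row.arm_len),
            spacer_len=int(row.spacer_len),
            left_arm_seq=str(row.left_arm_seq),
        )
        for row in frame.itertuples()
    ]


def write_ir_tsv(irs: Sequence[IRecord], path: "str | Path") -> None:
    irs_to_frame(irs).to_csv(path, sep="\t", index=False)


def read_ir_tsv(path: "str | Path") -> list[IRecord]:
    return frame_to_irs(pd.read_csv(path, sep="\t"))


def write_ir_bed(irs: Sequence[IRecord], path: "str | Path") -> None:
    """BED6: name R{arm}S{spacer}, score = arm length, strand '.' (an IR
    reads identically on both strands)."""
    with open(path, "w") as fh:
        for r in irs:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.arm_len}\t.\n"
            )


def write_ir_gff3(irs: Sequence[IRecord], path: "str | Path") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, r in enumerate(irs):
            attrs = (
                f"ID=ir{i};Name={r.name};arm_len={r.arm_len};"
                f"spacer_len={r.spacer_len};center={r.center + 1};"
                f"left_arm_seq={r.left_arm_seq}"
            )
            fh.write(
                f"{r.chrom}\tirscape\tinverted_repeat\t{r.start + 1}\t{r.end}\t"
                f"{r.arm_len}\t.\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# BED intervals (nucleosome calls, excluded features)
# ---------------------------------------------------------------------------

def read_bed_intervals(path: "str | Path") -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{line_no}: fewer than 3 BED fields")
            chrom, s, e = fields[0], int(fields[1]), int(fields[2])
            out.setdefault(chrom, []).append((s, e))
    return out


def write_bed_intervals(
    intervals: dict[str, list[tuple[int, int]]], path: "str | Path", name: str = "."
) -> None:
    with open(path, "w") as fh:
        for chrom in intervals:
            for s, e in intervals[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")


# ---------------------------------------------------------------------------
# annotation tables
# ---------------------------------------------------------------------------

GENE_COLUMNS = [
    "gene_id", "chrom", "strand", "tss", "start_codon", "stop_codon", "polya_site",
]


def read_gene_table(path: "str | Path") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})


def write_gene_table(frame: pd.DataFrame, path: "str | Path") -> None:
    frame.to_csv(path, sep="\t", index=False)
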