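"""Gene models and partitioning of the genome into region classes.

A protein-coding gene is reduced to four anchors: the transcription start
site (TSS), the first nucleotide of the start codon, the third nucleotide
of the stop codon, and the poly(A) site.  Anchors are stored as 0-based
genomic positions of single bases; annotation tables carry them 1-based.

From the anchors the genome is partitioned into

* genic regions per gene — 5'-UTR ``[tss, start_codon)``, ORF
  ``[start_codon, stop_codon]`` and 3'-UTR ``(stop_codon, polya]`` in the
  gene's transcriptional orientation (the 3'-UTR includes the poly(A)-site
  base and excludes the stop codon's third base);
* overlap regions OUR-1/2/3 where the UTRs of adjacent genes overlap
  (5'/5', 3'/5' and 3'/3' overlaps respectively);
* intergenic regions between adjacent genes with clear transcript ends,
  labelled TAN (tandem), DIV (divergent) or CON (convergent) by the strands
  of the flanking genes.  Intergenic intervals exclude both bounding anchor
  bases, which belong to the flanking UTRs.

Genes missing a TSS or poly(A) site ("no clear ends") keep their ORF region
but are excluded from UTR profiling and from intergenic construction, and
any intergenic stretch that overlaps an excluded feature (pseudogene,
tRNA/rRNA gene, ...) is dropped entirely.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

GENIC_KINDS = ("UTR5", "ORF", "UTR3")
OUR_KINDS = ("OUR1", "OUR2", "OUR3")
INTERGENIC_KINDS = ("TAN", "DIV", "CON")
REGION_KINDS = GENIC_KINDS + OUR_KINDS + INTERGENIC_KINDS

ANCHOR_KINDS = ("tss", "start_codon", "stop_codon", "polya")


@dataclass(frozen=True)
class GeneModel:
    """Anchor-level model of one protein-coding gene (0-based positions)."""

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    start_codon: int
    stop_codon: int
    tss: Optional[int] = None
    polya: Optional[int] = None

    @property
    def clear_ends(self) -> bool:
        """True when both transcript ends (TSS and poly(A) site) are known."""
        return self.tss is not None and self.polya is not None

    def anchor(self, kind: str) -> int:
        if kind not in ANCHOR_KINDS:
            raise ValueError(f"unknown anchor kind {kind!r}")
        value = getattr(self, "polya" if kind == "polya" else kind)
        if value is None:
            raise ValueError(f"gene {self.gene_id} has no {kind} annotation")
        return value

    # --- genomic half-open intervals -------------------------------------
    def orf_interval(self) -> tuple[int, int]:
        if self.strand == "+":
            return self.start_codon, self.stop_codon + 1
        return self.stop_codon, self.start_codon + 1

    def utr5_interval(self) -> tuple[int, int]:
        if self.tss is None:
            raise ValueError(f"gene {self.gene_id} has no TSS")
        if self.strand == "+":
            return self.tss, self.start_codon
        return self.start_codon + 1, self.tss + 1

    def utr3_interval(self) -> tuple[int, int]:
        if self.polya is None:
            raise ValueError(f"gene {self.gene_id} has no poly(A) site")
        if self.strand == "+":
            return self.stop_codon + 1, self.polya + 1
        return self.polya, self.stop_codon

    def transcript_interval(self) -> tuple[int, int]:
        """Genomic span [TSS, poly(A)] inclusive of both anchor bases; falls
        back to the ORF span when an end is missing."""
        lo, hi = self.orf_interval()
        if self.tss is not None:
            lo, hi = min(lo, self.tss), max(hi, self.tss + 1)
        if self.polya is not None:
            lo, hi = min(lo, self.polya), max(hi, self.polya + 1)
        return lo, hi


@dataclass(frozen=True)
class Region:
    """A labelled genomic segment (0-based half-open interval)."""

    kind: str
    chrom: str
    start: int
    end: int
    #: (anchor_kind, gene_id) of the genomically left / right bounding anchor
    left_anchor: Optional[tuple[str, str]] = None
    right_anchor: Optional[tuple[str, str]] = None
    genes: tuple[str, ...] = ()

    @property
    def length(self) -> int:
        return self.end - self.start


def build_gene_models(table: pd.DataFrame) -> list[GeneModel]:
    """Build gene models from an annotation table.

    Expects columns gene_id, chrom, strand, tss, start_codon, stop_codon,
    polya_site with 1-based positions (tss/polya_site may be missing/NaN);
    emits 0-based models.  Rows violating the anchor ordering for their
    strand are rejected with the offending row index; duplicate gene ids
    are an error.
    """
    required = {"gene_id", "chrom", "strand", "start_codon", "stop_codon"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"annotation table lacks columns: {sorted(missing)}")

    genes: list[GeneModel] = []
    seen: set[str] = set()
    errors: list[str] = []
    for idx, row in table.iterrows():
        gid = str(row["gene_id"])
        if gid in seen:
            raise ValueError(f"duplicate gene id {gid!r} (row {idx})")
        seen.add(gid)
        strand = str(row["strand"])
        try:
            if strand not in "+-":
                raise ValueError(f"bad strand {strand!r}")
            start_codon = int(row["start_codon"]) - 1
            stop_codon = int(row["stop_codon"]) - 1
            tss = _opt_pos(row.get("tss"))
            polya = _opt_pos(row.get("polya_site"))
            _check_order(strand, tss, start_codon, stop_codon, polya)
        except (ValueError, TypeError) as exc:
            errors.append(f"row {idx} (gene {gid}): {exc}")
            continue
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=str(row["chrom"]),
                strand=strand,
                start_codon=start_codon,
                stop_codon=stop_codon,
                tss=tss,
                polya=polya,
            )
        )
    if errors:
        raise ValueError("malformed annotation rows:\n" + "\n".join(errors))
    return genes


def _opt_pos(value) -> Optional[int]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() in ("", ".", "NA"):
        return None
    return int(value) - 1


def _check_order(strand, tss, start_codon, stop_codon, polya) -> None:
    if strand == "+":
        ok = start_codon < stop_codon
        if tss is not None:
            ok &= tss <= start_codon
        if polya is not None:
            ok &= stop_codon <= polya
    else:
        ok = stop_codon < start_codon
        if tss is not None:
            ok &= start_codon <= tss
        if polya is not None:
            ok &= polya <= stop_codon
    if not ok:
        raise ValueError("anchor ordering violates strand orientation")


def relative_offset(pos: int, anchor_kind: str, gene: GeneModel) -> int:
    """Signed offset of a genomic position from a gene anchor.

    Positive offsets are downstream in the gene's transcriptional
    orientation; the anchor base itself is offset 0.
    """
    anchor = gene.anchor(anchor_kind)
    return pos - anchor if gene.strand == "+" else anchor - pos


def partition(
    genes: Sequence[GeneModel],
    excluded_features: Iterable[tuple[str, int, int]] = (),
) -> list[Region]:
    """Partition the genome into genic, overlap and intergenic regions."""
    excluded: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in excluded_features:
        excluded.setdefault(chrom, []).append((int(s), int(e)))

    regions: list[Region] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    for chrom in sorted(by_chrom):
        chrom_genes = sorted(by_chrom[chrom], key=lambda g: g.transcript_interval())
        genic, trims = _genic_regions(chrom_genes)
        regions.extend(_apply_trims(genic, trims))
        regions.extend(_our_regions(chrom_genes))
        regions.extend(_intergenic_regions(chrom_genes, excluded.get(chrom, [])))
    regions.sort(key=lambda r: (r.chrom, r.start, r.end))
    return regions


def _genic_regions(chrom_genes: Sequence[GeneModel]):
    out: list[Region] = []
    for g in chrom_genes:
        s, e = g.orf_interval()
        lo_kind, hi_kind = (
            ("start_codon", "stop_codon") if g.strand == "+" else ("stop_codon", "start_codon")
        )
        out.append(
            Region("ORF", g.chrom, s, e, (lo_kind, g.gene_id), (hi_kind, g.gene_id), (g.gene_id,))
        )
        if g.tss is not None:
            s, e = g.utr5_interval()
            if e > s:
                anchors = (
                    (("tss", g.gene_id), ("start_codon", g.gene_id))
                    if g.strand == "+"
                    else (("start_codon", g.gene_id), ("tss", g.gene_id))
                )
                out.append(Region("UTR5", g.chrom, s, e, anchors[0], anchors[1], (g.gene_id,)))
        if g.polya is not None:
            s, e = g.utr3_interval()
            if e > s:
                anchors = (
                    (("stop_codon", g.gene_id), ("polya", g.gene_id))
                    if g.strand == "+"
                    else (("polya", g.gene_id), ("stop_codon", g.gene_id))
                )
                out.append(Region("UTR3", g.chrom, s, e, anchors[0], anchors[1], (g.gene_id,)))
    return out, _utr_overlaps(chrom_genes)


def _utr_intervals(g: GeneModel):
    pairs = []
    if g.tss is not None:
        s, e = g.utr5_interval()
        if e > s:
            pairs.append(("UTR5", s, e))
    if g.polya is not None:
        s, e = g.utr3_interval()
        if e > s:
            pairs.append(("UTR3", s, e))
    return pairs


def _utr_overlaps(chrom_genes: Sequence[GeneModel]):
    """All pairwise UTR-UTR overlap intervals between distinct genes."""
    hits = []
    for i, ga in enumerate(chrom_genes):
        for gb in chrom_genes[i + 1 :]:
            if gb.transcript_interval()[0] >= ga.transcript_interval()[1]:
                break
            for kind_a, sa, ea in _utr_intervals(ga):
                for kind_b, sb, eb in _utr_intervals(gb):
                    lo, hi = max(sa, sb), min(ea, eb)
                    if hi > lo:
                        hits.append((ga, kind_a, gb, kind_b, lo, hi))
    return hits


_OUR_CASE = {
    frozenset(["UTR5"]): "OUR1",
    frozenset(["UTR5", "UTR3"]): "OUR2",
    frozenset(["UTR3"]): "OUR3",
}


def _our_regions(chrom_genes: Sequence[GeneModel]) -> list[Region]:
    out = []
    for ga, kind_a, gb, kind_b, lo, hi in _utr_overlaps(chrom_genes):
        kind = _OUR_CASE[frozenset([kind_a, kind_b])]
        out.append(
            Region(kind, ga.chrom, lo, hi, None, None, (ga.gene_id, gb.gene_id))
        )
    return out


def _apply_trims(genic: list[Region], overlaps) -> list[Region]:
    """Trim plain UTR regions so OUR segments replace the overlapped parts."""
    if not overlaps:
        return genic
    cuts: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for ga, kind_a, gb, kind_b, lo, hi in overlaps:
        cuts.setdefault((ga.gene_id, kind_a), []).append((lo, hi))
        cuts.setdefault((gb.gene_id, kind_b), []).append((lo, hi))
    out = []
    for reg in genic:
        key = (reg.genes[0], reg.kind) if reg.genes else None
        if reg.kind not in ("UTR5", "UTR3") or key not in cuts:
            out.append(reg)
            continue
        pieces = [(reg.start, reg.end)]
        for lo, hi in cuts[key]:
            nxt = []
            for s, e in pieces:
                if hi <= s or lo >= e:
                    nxt.append((s, e))
                else:
                    if s < lo:
                        nxt.append((s, lo))
                    if hi < e:
                        nxt.append((hi, e))
            pieces = nxt
        for s, e in pieces:
            out.append(
                Region(reg.kind, reg.chrom, s, e, reg.left_anchor, reg.right_anchor, reg.genes)
            )
    return out


def _facing_anchor(gene: GeneModel, side: str) -> tuple[str, int]:
    """Anchor kind/position of the transcript end facing an intergenic gap.

    ``side='right'`` is the gene's genomically right transcript end.
    """
    if side == "right":
        kind = "polya" if gene.strand == "+" else "tss"
    else:
        kind = "tss" if gene.strand == "+" else "polya"
    return kind, gene.anchor(kind)


_ORIENT = {("+", "+"): "TAN", ("-", "-"): "TAN", ("+", "-"): "CON", ("-", "+"): "DIV"}


def _intergenic_regions(
    chrom_genes: Sequence[GeneModel], excluded: list[tuple[int, int]]
) -> list[Region]:
    clear = [g for g in chrom_genes if g.clear_ends]
    out = []
    for ga, gb in zip(clear, clear[1:]):
        kind_a, pos_a = _facing_anchor(ga, "right")
        kind_b, pos_b = _facing_anchor(gb, "left")
        start, end = pos_a + 1, pos_b  # both anchor bases excluded
        if end <= start:
            continue  # overlapping transcripts: handled as OUR, not intergenic
        if any(lo < end and hi > start for lo, hi in excluded):
            continue
        out.append(
            Region(
                _ORIENT[(ga.strand, gb.strand)],
                ga.chrom,
                start,
                end,
                (kind_a, ga.gene_id),
                (kind_b, gb.gene_id),
                (ga.gene_id, gb.gene_id),
            )
        )
    return out


@dataclass(frozen=True)
class LengthGroup:
    name: str
    regions: tuple[Region, ...]
    min_length: int
    max_length: int


def length_groups(regions: Sequence[Region], k: int = 5) -> list[LengthGroup]:
    """Sort regions by length into ``k`` equal-count groups, drop the
    shortest group and name the rest Q1 (shortest retained) .. Q(k-1).

    The remainder of an uneven split is spread over the shortest groups.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(regions) < k:
        raise ValueError(f"need at least {k} regions, got {len(regions)}")
    ordered = sorted(regions, key=lambda r: (r.length, r.chrom, r.start))
    n = len(ordered)
    base, rem = divmod(n, k)
    sizes = [base + (1 if i < rem else 0) for i in range(k)]
    groups: list[LengthGroup] = []
    pos = sizes[0]  # discard the shortest group
    for i, size in enumerate(sizes[1:], start=1):
        chunk = ordered[pos : pos + size]
        pos += size
        groups.append(
            LengthGroup(
                name=f"Q{i}",
                regions=tuple(chunk),
                min_length=chunk[0].length,
                max_length=chunk[-1].length,
            )
        )
    return groups


def convergent_gene_ids(regions: Sequence[Region]) -> set[str]:
    """Gene ids flanking a convergent (CON) intergenic region."""
    out: set[str] = set()
    for r in regions:
        if r.kind == "CON":
            out.update(r.genes)
    return out


def regions_to_frame(regions: Sequence[Region]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "kind": r.kind,
                "genes": ",".join(r.genes),
            }
            for r in regions
        ],
        columns=["chrom", "start", "end", "kind", "genes"],
    )
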