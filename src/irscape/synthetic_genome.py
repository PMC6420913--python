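"""Seed-reproducible synthetic genomes with planted, typed inverted repeats.

The generator emulates the statistical structure the analysis assumes — a
multi-gene genome with UTRs, the three intergenic orientations, an i.i.d.
background of tunable AT fraction, IRs of chosen type/arm/spacer planted at
chosen anchor offsets, and nucleosome interval sets with depletion windows —
so every pipeline stage is testable without external downloads.

Planted IRs are written so the scanner must recover them exactly:

* the flanking bases just outside the IR are redrawn until non-complementary,
  which makes the planted arms outward-maximal;
* the outermost spacer bases are redrawn until non-complementary, which
  blocks any alternative same-interval decomposition with a longer arm;
* each planted locus is then re-scanned locally, and the surrounding
  background redrawn (a bounded number of times) in the rare case a chance
  background IR would contain the plant.

Arms are constructed per type from simple recipes and validated against the
classifier at generation time, so declared type labels are guaranteed
independent of classifier edge cases.  Some (type, arm length) combinations
are arithmetically impossible (e.g. a 5-bp type I arm cannot hold both a
>=3 A/T-tract and a >=4-bp alternating stretch at >=0.5 occupancy each);
those raise ``ValueError`` up front.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .alphabet import A, C, G, T, COMPLEMENT, decode, encode, revcomp
from .genome_partition import GeneModel
from .ir_classify import ClassifierThresholds, classify_arm
from .ir_scan import find_maximal_irs
from . import io as _io


@dataclass(frozen=True)
class LengthDist:
    """Truncated-normal length distribution (bp)."""

    mean: float
    sd: float
    min: int

    def draw(self, rng: np.random.Generator) -> int:
        return max(self.min, int(round(rng.normal(self.mean, self.sd))))


@dataclass(frozen=True)
class PlantSpec:
    """One planted-IR recipe: where and how often to insert IRs of a type."""

    type_id: str
    arm_len: int
    spacer_len: int
    anchor: str  # tss | start_codon | stop_codon | polya
    offset_min: int
    offset_max: int  # inclusive; offsets are gene-oriented (downstream > 0)
    prob: float = 1.0


@dataclass(frozen=True)
class DepletionSpec:
    """Nucleosome-free window specification.

    ``mode='planted'`` centres the window on every planted IR (gene
    oriented); ``mode='anchor'`` places it relative to a gene anchor for
    every clear-ended gene.
    """

    mode: str = "planted"
    window: tuple[int, int] = (-40, 40)  # inclusive, relative offsets
    prob: float = 0.9
    anchor: str = "polya"  # used in 'anchor' mode
    #: in 'planted' mode, restrict to planted IRs of these types (None = all)
    types: Optional[tuple[str, ...]] = None


@dataclass(frozen=True)
class NucleosomeSpec:
    width: int = 147
    linker: int = 20
    jitter_sd: float = 3.0
    conditions: tuple[str, ...] = ("mnase", "chemical")
    depletion: tuple[DepletionSpec, ...] = ()


@dataclass(frozen=True)
class SynthConfig:
    """Full recipe for one synthetic genome + annotations + nucleosome calls.

    Defaults give ~1 Mb over 2 chromosomes and 200 genes with yeast-like
    gene architecture (mean ORF 1536 bp, mean 3'-UTR 120 bp, background AT
    fraction 0.62).
    """

    n_chromosomes: int = 2
    genes_per_chrom: int = 100
    at_fraction: float = 0.62
    utr5: LengthDist = LengthDist(70, 20, 25)
    orf: LengthDist = LengthDist(1536, 400, 300)
    utr3: LengthDist = LengthDist(120, 35, 70)
    intergenic: LengthDist = LengthDist(2800, 700, 400)
    margin: int = 500
    #: relative weights of tandem / divergent / convergent junctions
    orientation: tuple[float, float, float] = (0.5, 0.25, 0.25)
    plants: tuple[PlantSpec, ...] = ()
    nucleosomes: NucleosomeSpec = NucleosomeSpec()
    seed: int = 0

    def __post_init__(self):
        for p in (self.at_fraction, *self.orientation):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for spec in self.plants:
            if not 0.0 <= spec.prob <= 1.0:
                raise ValueError("plant probability outside [0, 1]")
            if (
                spec.arm_len < 5
                or not 0 <= spec.spacer_len <= 8
                or 2 * spec.arm_len + spec.spacer_len < 13
            ):
                raise ValueError(
                    "planted IR violates the scanner thresholds "
                    "(R >= 5, 0 <= S <= 8, 2R+S >= 13)"
                )


@dataclass
class SynthResult:
    genome: dict[str, np.ndarray]
    genes: list[GeneModel]
    nucleosome_calls: dict[str, dict[str, list[tuple[int, int]]]]
    truth_irs: pd.DataFrame
    truth_depletion: pd.DataFrame
    config: SynthConfig

    def gene_table(self) -> pd.DataFrame:
        rows = []
        for g in self.genes:
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "chrom": g.chrom,
                    "strand": g.strand,
                    "tss": g.tss + 1 if g.tss is not None else "",
                    "start_codon": g.start_codon + 1,
                    "stop_codon": g.stop_codon + 1,
                    "polya_site": g.polya + 1 if g.polya is not None else "",
                }
            )
        return pd.DataFrame(rows, columns=_io.GENE_COLUMNS)

    def write(self, outdir: "str | Path") -> dict[str, str]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fasta",
            "genes": outdir / "genes.tsv",
            "truth_irs": outdir / "truth_irs.tsv",
            "truth_depletion": outdir / "truth_depletion.tsv",
        }
        _io.write_fasta(self.genome, paths["genome"])
        _io.write_gene_table(self.gene_table(), paths["genes"])
        self.truth_irs.to_csv(paths["truth_irs"], sep="\t", index=False)
        self.truth_depletion.to_csv(paths["truth_depletion"], sep="\t", index=False)
        for cond, calls in self.nucleosome_calls.items():
            p = outdir / f"nucleosomes_{cond}.bed"
            _io.write_bed_intervals(calls, p, name="nuc")
            paths[f"nucleosomes_{cond}"] = p
        return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# arm construction per type
# ---------------------------------------------------------------------------

def make_arm(
    type_id: str,
    arm_len: int,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> str:
    """Deterministic arm sequence of the requested type and length.

    Raises ``ValueError`` when no recipe yields the requested type at that
    length (arithmetically infeasible combinations).
    """
    r = arm_len
    candidates: list[str] = []
    if type_id == "I":
        for a in range(3, r):
            tail = "".join("TA"[i % 2] for i in range(r - a))
            candidates.append("A" * a + tail)
    elif type_id == "II":
        candidates.append("A" * r)
    elif type_id == "III":
        candidates.append("".join("AT"[i % 2] for i in range(r)))
    elif type_id == "IV":
        candidates.append(("AATC" * r)[:r])
    elif type_id == "V":
        for a in range(3, r):
            candidates.append("A" * a + ("GC" * r)[: r - a])
    elif type_id == "VI":
        for a in range(2, r, 2):
            alt = "".join("AT"[i % 2] for i in range(a))
            candidates.append(alt + ("GC" * r)[: r - a])
    elif type_id == "VII":
        candidates.append(("GACGTC" * r)[:r])
    else:
        raise ValueError(f"unknown IR type {type_id!r}")
    for arm in candidates:
        if classify_arm(arm, thresholds).type_id == type_id:
            return arm
    raise ValueError(f"cannot construct a type {type_id} arm of length {arm_len}")


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _base_probs(at: float) -> np.ndarray:
    return np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])


_NEXT_STRAND = {
    # previous strand -> [(relation, next_strand), ...]
    "+": [("TAN", "+"), ("CON", "-")],
    "-": [("DIV", "+"), ("TAN", "-")],
}
_REL_INDEX = {"TAN": 0, "DIV": 1, "CON": 2}


def _layout_chromosome(
    cfg: SynthConfig, chrom: str, gene_start_index: int, rng: np.random.Generator
) -> tuple[int, list[GeneModel]]:
    genes: list[GeneModel] = []
    cursor = cfg.margin
    prev_strand: Optional[str] = None
    for i in range(cfg.genes_per_chrom):
        if prev_strand is None:
            strand = "+" if rng.random() < 0.5 else "-"
        else:
            options = _NEXT_STRAND[prev_strand]
            weights = np.array(
                [cfg.orientation[_REL_INDEX[rel]] for rel, _ in options], dtype=float
            )
            if weights.sum() == 0:
                weights[:] = 1.0
            strand = options[rng.choice(len(options), p=weights / weights.sum())][1]
        u5, orf, u3 = cfg.utr5.draw(rng), cfg.orf.draw(rng), cfg.utr3.draw(rng)
        gap = cfg.intergenic.draw(rng)
        start = cursor + gap
        span = u5 + orf + u3
        if strand == "+":
            tss = start
            start_codon = start + u5
            stop_codon = start + u5 + orf - 1
            polya = start + span - 1
        else:
            polya = start
            stop_codon = start + u3
            start_codon = start + u3 + orf - 1
            tss = start + span - 1
        genes.append(
            GeneModel(
                gene_id=f"g{gene_start_index + i:04d}",
                chrom=chrom,
                strand=strand,
                start_codon=start_codon,
                stop_codon=stop_codon,
                tss=tss,
                polya=polya,
            )
        )
        cursor = start + span
        prev_strand = strand
    return cursor + cfg.margin, genes


def _feasible_offset(spec: PlantSpec, u5: int, orf: int, u3: int) -> tuple[int, int]:
    """Offset bounds keeping the planted center inside the anchor's region."""
    if spec.anchor == "polya":
        lo, hi = -(u3 - 1), 0
    elif spec.anchor == "stop_codon":
        lo, hi = 1, u3
    elif spec.anchor == "start_codon":
        lo, hi = 0, orf - 1
    elif spec.anchor == "tss":
        lo, hi = 0, u5 - 1
    else:
        raise ValueError(f"unknown anchor {spec.anchor!r}")
    return max(lo, spec.offset_min), min(hi, spec.offset_max)


def _plant_one(
    seq: np.ndarray,
    gene: GeneModel,
    spec: PlantSpec,
    occupied: list[tuple[int, int]],
    rng: np.random.Generator,
    probs: np.ndarray,
) -> Optional[dict]:
    u5 = gene.utr5_interval()[1] - gene.utr5_interval()[0]
    u3 = gene.utr3_interval()[1] - gene.utr3_interval()[0]
    orf = gene.orf_interval()[1] - gene.orf_interval()[0]
    lo, hi = _feasible_offset(spec, u5, orf, u3)
    if hi < lo:
        return None
    offset = int(rng.integers(lo, hi + 1))
    anchor = gene.anchor(spec.anchor)
    center = anchor + offset if gene.strand == "+" else anchor - offset
    total = 2 * spec.arm_len + spec.spacer_len
    start = center - (total - 1) // 2
    end = start + total
    guard = 90  # keep planted loci far enough apart to verify independently
    if start - guard < 0 or end + guard > len(seq):
        return None
    if any(s < end + guard and e > start - guard for s, e in occupied):
        return None

    arm = make_arm(spec.type_id, spec.arm_len)
    arm_codes = encode(arm)
    rc_codes = encode(revcomp(arm))
    window = 40

    # homopolymer arms merge with a chance adjacent A/T into a containing IR
    # roughly half the time, so the redraw loop needs generous headroom
    for _attempt in range(60):
        seq[start : start + spec.arm_len] = arm_codes
        if spec.spacer_len:
            spacer = rng.choice(4, size=spec.spacer_len, p=probs).astype(np.uint8)
            while (
                spec.spacer_len >= 2
                and spacer[-1] == COMPLEMENT[spacer[0]]
            ):
                spacer[-1] = rng.choice(4, p=probs)
            seq[start + spec.arm_len : end - spec.arm_len] = spacer
        seq[end - spec.arm_len : end] = rc_codes
        # block outward extension so the planted arms are maximal
        while seq[end] == COMPLEMENT[seq[start - 1]]:
            seq[end] = rng.choice(4, p=probs)
        # local verification: the plant must survive scanning + pruning
        w0 = max(0, start - window)
        found = find_maximal_irs(seq[w0 : end + window], chrom="w")
        ok = any(
            w0 + rec.start == start
            and w0 + rec.end == end
            and rec.arm_len == spec.arm_len
            for rec in found
        )
        if ok:
            occupied.append((start, end))
            return {
                "chrom": gene.chrom,
                "start": start,
                "end": end,
                "arm_len": spec.arm_len,
                "spacer_len": spec.spacer_len,
                "center": center,
                "left_arm_seq": arm,
                "type_id": spec.type_id,
                "gene_id": gene.gene_id,
                "anchor": spec.anchor,
                "offset": offset,
            }
        # a chance background IR interferes: redraw the local flanks
        for a, b in ((w0, start), (end, min(len(seq), end + window))):
            if b > a:
                seq[a:b] = rng.choice(4, size=b - a, p=probs).astype(np.uint8)
    raise RuntimeError(
        f"could not realize planted IR near {gene.gene_id} after 60 attempts"
    )


def _depletion_windows(
    cfg: SynthConfig,
    genes: Sequence[GeneModel],
    truth_rows: Sequence[dict],
) -> list[dict]:
    windows: list[dict] = []
    for spec in cfg.nucleosomes.depletion:
        lo, hi = spec.window
        if spec.mode == "planted":
            for row in truth_rows:
                if spec.types is not None and row["type_id"] not in spec.types:
                    continue
                gene = next(g for g in genes if g.gene_id == row["gene_id"])
                c = row["center"]
                if gene.strand == "+":
                    s, e = c + lo, c + hi + 1
                else:
                    s, e = c - hi, c - lo + 1
                windows.append(
                    {"chrom": row["chrom"], "start": s, "end": e,
                     "gene_id": row["gene_id"], "prob": spec.prob}
                )
        elif spec.mode == "anchor":
            for gene in genes:
                if not gene.clear_ends:
                    continue
                a = gene.anchor(spec.anchor)
                if gene.strand == "+":
                    s, e = a + lo, a + hi + 1
                else:
                    s, e = a - hi, a - lo + 1
                windows.append(
                    {"chrom": gene.chrom, "start": s, "end": e,
                     "gene_id": gene.gene_id, "prob": spec.prob}
                )
        else:
            raise ValueError(f"unknown depletion mode {spec.mode!r}")
    return windows


def _nucleosome_calls(
    cfg: SynthConfig,
    chrom_lengths: dict[str, int],
    windows: Sequence[dict],
    rng: np.random.Generator,
) -> tuple[dict[str, dict[str, list[tuple[int, int]]]], pd.DataFrame]:
    nuc = cfg.nucleosomes
    period = nuc.width + nuc.linker
    phases = {chrom: int(rng.integers(0, period)) for chrom in chrom_lengths}
    calls: dict[str, dict[str, list[tuple[int, int]]]] = {}
    realized_cols: dict[str, list[bool]] = {}
    for cond in nuc.conditions:
        realized = [bool(rng.random() < w["prob"]) for w in windows]
        realized_cols[cond] = realized
        cond_calls: dict[str, list[tuple[int, int]]] = {}
        for chrom, length in chrom_lengths.items():
            chrom_windows = [
                (w["start"], w["end"])
                for w, r in zip(windows, realized)
                if r and w["chrom"] == chrom
            ]
            out = []
            pos = phases[chrom]
            while pos + nuc.width <= length:
                p = pos + int(round(rng.normal(0, nuc.jitter_sd)))
                p = min(max(p, 0), length - nuc.width)
                if not any(p < e and p + nuc.width > s for s, e in chrom_windows):
                    out.append((p, p + nuc.width))
                pos += period
            cond_calls[chrom] = out
        calls[cond] = cond_calls
    truth = pd.DataFrame(
        [
            {
                "chrom": w["chrom"],
                "start": w["start"],
                "end": w["end"],
                "gene_id": w["gene_id"],
                **{f"realized_{cond}": realized_cols[cond][i] for cond in nuc.conditions},
            }
            for i, w in enumerate(windows)
        ],
        columns=["chrom", "start", "end", "gene_id"]
        + [f"realized_{c}" for c in nuc.conditions],
    )
    return calls, truth


#: Canonical planted-IR conditions: alternating-AT type III IRs ~30-60 bp
#: upstream of poly(A) sites in most genes, A/T-tract type II IRs in their
#: close vicinity (~10-20 bp upstream), and non-AT-rich type VII IRs
#: ~30-60 bp downstream of start codons — the positional/type structure the
#: analysis is designed to detect.
DEFAULT_PLANTS: tuple[PlantSpec, ...] = (
    PlantSpec("III", 8, 0, "polya", -60, -31, prob=0.7),
    PlantSpec("II", 7, 0, "polya", -20, -10, prob=0.5),
    PlantSpec("VII", 6, 3, "start_codon", 30, 60, prob=0.5),
)


def default_config(seed: int = 0) -> SynthConfig:
    """The default study conditions: a ~1 Mb, 200-gene genome with the
    canonical planted IRs and nucleosome depletion over the planted loci."""
    return SynthConfig(
        plants=DEFAULT_PLANTS,
        nucleosomes=NucleosomeSpec(
            depletion=(
                DepletionSpec(
                    mode="planted", window=(-40, 40), prob=0.9, types=("III", "II")
                ),
            )
        ),
        seed=seed,
    )


TRUTH_IR_COLUMNS = [
    "chrom", "start", "end", "arm_len", "spacer_len", "center",
    "left_arm_seq", "type_id", "gene_id", "anchor", "offset",
]


def generate(config: SynthConfig) -> SynthResult:
    """Generate a synthetic genome, annotations, nucleosome calls and truth
    tables from a config.  Identical config (incl. seed) gives byte-identical
    outputs."""
    rng = np.random.default_rng(config.seed)
    probs = _base_probs(config.at_fraction)

    genome: dict[str, np.ndarray] = {}
    genes: list[GeneModel] = []
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        length, chrom_genes = _layout_chromosome(
            config, chrom, len(genes), rng
        )
        genome[chrom] = rng.choice(4, size=length, p=probs).astype(np.uint8)
        genes.extend(chrom_genes)

    truth_rows: list[dict] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}
    for gene in genes:
        for spec in config.plants:
            if rng.random() >= spec.prob:
                continue
            row = _plant_one(
                genome[gene.chrom], gene, spec, occupied[gene.chrom], rng, probs
            )
            if row is not None:
                truth_rows.append(row)

    windows = _depletion_windows(config, genes, truth_rows)
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    calls, truth_depletion = _nucleosome_calls(config, chrom_lengths, windows, rng)

    truth_irs = pd.DataFrame(truth_rows, columns=TRUTH_IR_COLUMNS)
    return SynthResult(
        genome=genome,
        genes=genes,
        nucleosome_calls=calls,
        truth_irs=truth_irs,
        truth_depletion=truth_depletion,
        config=config,
    )
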