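"""Deterministic readers/writers for BED, bedGraph, GTF/BED12 and UCSC track lines.

All coordinates are 0-based half-open internally and in BED/bedGraph output;
human-readable reports use the 1-based inclusive ``chr4:81,122,001-81,124,000``
convention of the genome browser.  Writers are byte-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gffutils

from .density import Peak
from .errors import FormatError

_VISIBILITIES = ("dense", "pack", "full")


@dataclass(frozen=True)
class TrackSpec:
    """A UCSC custom-track header (``track name=... visibility=pack``)."""

    name: str
    description: str = ""
    track_type: str = "bed"
    visibility: str = "pack"
    color: str | None = None

    def __post_init__(self) -> None:
        if self.visibility not in _VISIBILITIES:
            raise ValueError(f"visibility must be one of {_VISIBILITIES}")
        if self.track_type not in ("bed", "bedGraph"):
            raise ValueError("track_type must be 'bed' or 'bedGraph'")

    def line(self) -> str:
        parts = ["track"]
        if self.track_type == "bedGraph":
            parts.append("type=bedGraph")
        parts.append(f'name="{self.name}"')
        if self.description:
            parts.append(f'description="{self.description}"')
        parts.append(f"visibility={self.visibility}")
        if self.color:
            parts.append(f"color={self.color}")
        return " ".join(parts)


@dataclass(frozen=True)
class BedInterval:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: int = 0
    strand: str = "."


# ---------------------------------------------------------------- regions


def format_region(chrom: str, start: int, end: int) -> str:
    """0-based half-open interval -> browser-style 1-based inclusive span."""
    return f"{chrom}:{start + 1:,}-{end:,}"


def parse_region(text: str) -> tuple[str, int, int]:
    """Parse ``chrom:start-end`` (1-based inclusive, commas allowed)."""
    try:
        chrom, span = text.rsplit(":", 1)
        lo, hi = span.replace(",", "").split("-")
        start1, end1 = int(lo), int(hi)
    except ValueError as exc:
        raise FormatError(f"cannot parse region {text!r} (expected chrom:start-end)") from exc
    if not 1 <= start1 <= end1:
        raise FormatError(f"invalid region span in {text!r}")
    return chrom, start1 - 1, end1


# -------------------------------------------------------------------- BED


def write_bed(
    intervals: Iterable[BedInterval],
    path: str | Path,
    track: TrackSpec | None = None,
    columns: int = 6,
) -> None:
    if columns not in (4, 6):
        raise ValueError("columns must be 4 or 6")
    lines = []
    if track is not None:
        lines.append(track.line())
    for iv in intervals:
        if iv.start < 0 or iv.start >= iv.end:
            raise FormatError(f"invalid interval {iv.chrom}:[{iv.start}, {iv.end})")
        fields = [iv.chrom, str(iv.start), str(iv.end), iv.name]
        if columns == 6:
            fields += [str(iv.score), iv.strand]
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n" if lines else "")


def read_bed(path: str | Path) -> tuple[list[BedInterval], str | None]:
    """Read BED4/BED6; returns (intervals, track line or None)."""
    path = Path(path)
    track_line = None
    out: list[BedInterval] = []
    for i, ln in enumerate(path.read_text().splitlines(), start=1):
        if not ln.strip() or ln.startswith(("#", "browser")):
            continue
        if ln.startswith("track"):
            track_line = ln
            continue
        f = ln.split("\t")
        if len(f) < 3:
            raise FormatError(f"{path}:{i}: fewer than 3 BED columns")
        try:
            start, end = int(f[1]), int(f[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{i}: non-integer coordinates") from exc
        if start < 0 or start >= end:
            raise FormatError(f"{path}:{i}: invalid interval [{start}, {end})")
        name = f[3] if len(f) > 3 else "."
        try:
            score = int(f[4]) if len(f) > 4 else 0
        except ValueError as exc:
            raise FormatError(f"{path}:{i}: non-integer score") from exc
        strand = f[5] if len(f) > 5 else "."
        out.append(BedInterval(f[0], start, end, name, score, strand))
    return out, track_line


def peaks_to_bed(peaks: Sequence[Peak]) -> list[BedInterval]:
    """Peak list -> BED6 rows: name = class, score = max-within-window count."""
    return [
        BedInterval(p.chrom, p.start, p.end, p.peak_class, p.max_window_count, "+")
        for p in peaks
    ]


# --------------------------------------------------------------- bedGraph


def write_bedgraph(
    profiles: dict[str, Sequence[tuple[int, int, int]]],
    path: str | Path,
    track: TrackSpec | None = None,
) -> None:
    """Write per-chromosome (start, end, value) runs as 4-column bedGraph.

    Adjacent equal-value runs are merged; zero-valued runs are omitted;
    overlapping runs are a validation error.
    """
    lines = []
    if track is not None:
        lines.append(track.line())
    for chrom in profiles:
        prev_end = -1
        merged: list[list[int]] = []
        for start, end, value in sorted(profiles[chrom]):
            if value < 0:
                raise FormatError(f"{chrom}: negative bedGraph value {value}")
            if start >= end:
                raise FormatError(f"{chrom}: empty run [{start}, {end})")
            if start < prev_end:
                raise FormatError(f"{chrom}: overlapping profile runs at {start}")
            prev_end = end
            if value == 0:
                continue
            if merged and merged[-1][1] == start and merged[-1][2] == value:
                merged[-1][1] = end
            else:
                merged.append([start, end, value])
        lines += [f"{chrom}\t{s}\t{e}\t{v}" for s, e, v in merged]
    Path(path).write_text("\n".join(lines) + "\n" if lines else "")


def read_bedgraph(path: str | Path) -> tuple[dict[str, list[tuple[int, int, int]]], str | None]:
    path = Path(path)
    track_line = None
    out: dict[str, list[tuple[int, int, int]]] = {}
    for i, ln in enumerate(path.read_text().splitlines(), start=1):
        if not ln.strip() or ln.startswith(("#", "browser")):
            continue
        if ln.startswith("track"):
            track_line = ln
            continue
        f = ln.split("\t")
        if len(f) != 4:
            raise FormatError(f"{path}:{i}: bedGraph needs 4 columns")
        out.setdefault(f[0], []).append((int(f[1]), int(f[2]), int(f[3])))
    return out, track_line


# ------------------------------------------------------------ gene models


@dataclass(frozen=True)
class Transcript:
    id: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...] = ()

    @property
    def tss(self) -> int:
        """TSS position: span start on '+', span end - 1 on '-'."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def first_exon(self) -> tuple[int, int] | None:
        if not self.exons:
            return None
        return self.exons[0] if self.strand == "+" else self.exons[-1]


@dataclass(frozen=True)
class GeneModel:
    name: str
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: tuple[Transcript, ...] = ()


def _genes_from_transcripts(
    per_gene: dict[tuple[str, str], list[Transcript]],
    strands: dict[tuple[str, str], str],
) -> list[GeneModel]:
    genes = []
    for (chrom, name), txs in per_gene.items():
        txs = sorted(txs, key=lambda t: (t.start, t.end, t.id))
        genes.append(
            GeneModel(
                name=name,
                chrom=chrom,
                strand=strands[(chrom, name)],
                start=min(t.start for t in txs),
                end=max(t.end for t in txs),
                transcripts=tuple(txs),
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start, g.name))
    return genes


def _read_bed12(path: Path) -> list[GeneModel]:
    per_gene: dict[tuple[str, str], list[Transcript]] = {}
    strands: dict[tuple[str, str], str] = {}
    for i, ln in enumerate(path.read_text().splitlines(), start=1):
        if not ln.strip() or ln.startswith(("#", "track", "browser")):
            continue
        f = ln.split("\t")
        if len(f) < 12:
            raise FormatError(f"{path}:{i}: BED12 needs 12 columns")
        chrom, start, end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
        if strand not in "+-":
            raise FormatError(f"{path}:{i}: unknown strand {strand!r}")
        n_blocks = int(f[9])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        offsets = [int(x) for x in f[11].rstrip(",").split(",")]
        if len(sizes) != n_blocks or len(offsets) != n_blocks:
            raise FormatError(f"{path}:{i}: block count mismatch")
        exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
        gene = name.split("|")[0]  # convention: gene|transcript, else name is both
        tx_id = name.split("|")[1] if "|" in name else name
        key = (chrom, gene)
        per_gene.setdefault(key, []).append(Transcript(tx_id, start, end, strand, exons))
        strands[key] = strand
    return _genes_from_transcripts(per_gene, strands)


def _read_gtf(path: Path) -> list[GeneModel]:
    import warnings

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    per_gene: dict[tuple[str, str], list[Transcript]] = {}
    strands: dict[tuple[str, str], str] = {}
    for tx in db.features_of_type("transcript", order_by=("seqid", "start")):
        if tx.strand not in "+-":
            raise FormatError(f"{path}: transcript {tx.id}: unknown strand {tx.strand!r}")
        gene = (tx.attributes.get("gene_name") or tx.attributes.get("gene_id") or ["?"])[0]
        tx_id = (tx.attributes.get("transcript_id") or [tx.id])[0]
        exons = tuple(
            sorted((e.start - 1, e.end) for e in db.children(tx, featuretype="exon"))
        )
        if not exons:
            warnings.warn(f"transcript {tx_id} has no exons; using its span")
        per_gene.setdefault((tx.seqid, gene), []).append(
            Transcript(tx_id, tx.start - 1, tx.end, tx.strand, exons)
        )
        strands[(tx.seqid, gene)] = tx.strand
    return _genes_from_transcripts(per_gene, strands)


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from GTF or BED12 (sniffed by content).

    GTF's 1-based inclusive coordinates are converted to 0-based half-open;
    transcripts are grouped by gene (GTF ``gene_name``/``gene_id``; BED12
    name, with an optional ``gene|transcript`` convention); TSS derived per
    strand.
    """
    path = Path(path)
    for ln in path.read_text().splitlines():
        if not ln.strip() or ln.startswith(("#", "track", "browser")):
            continue
        fields = ln.split("\t")
        is_gtf = len(fields) == 9 and fields[3].isdigit() and fields[6] in "+-."
        return _read_gtf(path) if is_gtf else _read_bed12(path)
    raise FormatError(f"{path}: no gene model records")
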