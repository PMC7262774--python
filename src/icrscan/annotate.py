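"""Localize density peaks against genes, TSSs and CpG islands.

ICR-associated CpG islands can be intergenic, span promoters/TSSs and first
exons, or sit inside gene bodies.  Each peak is classified (TSS-overlap >
intragenic > intergenic; TSS evidence outranks body overlap at overlapping-
gene loci), flagged for CpG-island overlap, and assigned a nearest gene
with a signed, strand-aware distance (negative = upstream of that gene's
TSS).  Robust peaks overlapping a gene or lying near one of its TSSs
nominate it as a candidate imprinted gene; peaks of exactly two sites are
reported separately as true-or-false-positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .density import AMBIGUOUS, ROBUST, Peak
from .errors import IcrScanError
from .track_io import BedInterval, GeneModel, format_region

TSS_OVERLAP = "TSS-overlap"
INTRAGENIC = "intragenic"
INTERGENIC = "intergenic"


@dataclass(frozen=True)
class AnnotationRecord:
    peak: Peak
    location_class: str
    cgi_overlap: bool
    nearest_gene: str | None
    nearest_distance: int | None
    overlapping_tss: tuple[str, ...] = ()
    exon_overlap: bool = False


@dataclass(frozen=True)
class Nomination:
    gene: str
    peak: Peak
    reason: str  # intragenic | promoter | TSS-overlap
    flagged: bool  # True for ambiguous (2-site) peaks: true or false positive

    def span(self) -> str:
        return format_region(self.peak.chrom, self.peak.start, self.peak.end)


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def _interval_distance(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    if _overlap(a_start, a_end, b_start, b_end):
        return 0
    return b_start - a_end if a_end <= b_start else a_start - b_end


def _signed_distance(peak: Peak, gene: GeneModel) -> int:
    """Distance in bases; 0 if overlapping; negative = peak upstream of gene."""
    d = _interval_distance(peak.start, peak.end, gene.start, gene.end)
    if d == 0:
        return 0
    peak_before = peak.end <= gene.start
    upstream = peak_before if gene.strand == "+" else not peak_before
    return -d if upstream else d


def classify_location(
    peak: Peak,
    genes: Sequence[GeneModel],
    cgis: Sequence[BedInterval] = (),
) -> AnnotationRecord:
    """Classify one peak as TSS-overlap / intragenic / intergenic.

    TSS-overlap when the peak interval contains any transcript TSS; else
    intragenic when it overlaps any gene span; else intergenic.  Nearest
    gene by minimal interval distance, ties broken by smaller gene start
    then lexicographic name.  ``exon_overlap`` notes overlap with any exon
    of a same-chromosome transcript (intragenic CpG islands in terminal
    exons are reported this way, not as a separate class).
    """
    chrom_genes = [g for g in genes if g.chrom == peak.chrom]
    tss_hits = []
    intragenic = False
    exon_overlap = False
    for g in chrom_genes:
        for t in g.transcripts:
            if peak.start <= t.tss < peak.end:
                tss_hits.append(t.id)
            if any(_overlap(peak.start, peak.end, es, ee) for es, ee in t.exons):
                exon_overlap = True
        if _overlap(peak.start, peak.end, g.start, g.end):
            intragenic = True

    if tss_hits:
        loc = TSS_OVERLAP
    elif intragenic:
        loc = INTRAGENIC
    else:
        loc = INTERGENIC

    nearest: GeneModel | None = None
    nearest_d: int | None = None
    for g in sorted(chrom_genes, key=lambda g: (g.start, g.name)):
        d = _interval_distance(peak.start, peak.end, g.start, g.end)
        if nearest_d is None or d < nearest_d:
            nearest, nearest_d = g, d

    cgi = any(
        c.chrom == peak.chrom and _overlap(peak.start, peak.end, c.start, c.end)
        for c in cgis
    )
    return AnnotationRecord(
        peak=peak,
        location_class=loc,
        cgi_overlap=cgi,
        nearest_gene=nearest.name if nearest else None,
        nearest_distance=_signed_distance(peak, nearest) if nearest else None,
        overlapping_tss=tuple(sorted(tss_hits)),
        exon_overlap=exon_overlap,
    )


def annotate_peaks(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    cgis: Sequence[BedInterval] = (),
) -> list[AnnotationRecord]:
    return [classify_location(p, genes, cgis) for p in peaks]


def nominate_candidates(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    promoter_margin: int = 2000,
) -> list[Nomination]:
    """Nominate candidate imprinted genes from peak positions.

    A gene is nominated when a peak overlaps its span (reason intragenic;
    TSS-overlap when the peak contains one of its TSSs) or lies within
    ``promoter_margin`` bases of any of its TSSs (reason promoter).  Robust
    peaks nominate outright; ambiguous peaks produce flagged nominations
    ("could be a true or a false positive").  Sorted by (gene, peak start);
    one record per (gene, peak).
    """
    if promoter_margin < 0:
        raise ValueError("promoter_margin must be >= 0")
    noms: list[Nomination] = []
    for g in genes:
        for p in peaks:
            if p.chrom != g.chrom:
                continue
            if any(p.start <= t.tss < p.end for t in g.transcripts):
                reason = TSS_OVERLAP
            elif _overlap(p.start, p.end, g.start, g.end):
                reason = INTRAGENIC
            elif any(
                _interval_distance(p.start, p.end, t.tss, t.tss + 1) <= promoter_margin
                for t in g.transcripts
            ):
                reason = "promoter"
            else:
                continue
            noms.append(
                Nomination(gene=g.name, peak=p, reason=reason, flagged=p.peak_class != ROBUST)
            )
    noms.sort(key=lambda n: (n.gene, n.peak.chrom, n.peak.start))
    return noms


def annotation_table(records: Sequence[AnnotationRecord]) -> str:
    """TSV report of annotated peaks; spans printed 1-based inclusive."""
    lines = [
        "span\tclass\tlocation\tcgi_overlap\tnearest_gene\tdistance\ttss\texon_overlap"
    ]
    for r in records:
        p = r.peak
        lines.append(
            "\t".join(
                [
                    format_region(p.chrom, p.start, p.end),
                    p.peak_class,
                    r.location_class,
                    "yes" if r.cgi_overlap else "no",
                    r.nearest_gene or ".",
                    str(r.nearest_distance) if r.nearest_distance is not None else ".",
                    ",".join(r.overlapping_tss) or ".",
                    "yes" if r.exon_overlap else "no",
                ]
            )
        )
    return "\n".join(lines) + "\n"


def nomination_table(nominations: Sequence[Nomination]) -> str:
    """TSV of nominated genes; ambiguous-peak rows carry the caveat flag."""
    lines = ["gene\tpeak_span\treason\tpeak_class\tnote"]
    for n in nominations:
        note = "true or false positive" if n.flagged else "."
        lines.append(
            f"{n.gene}\t{n.span()}\t{n.reason}\t{n.peak.peak_class}\t{note}"
        )
    return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class RecoveryReport:
    statuses: tuple[tuple[str, bool], ...]  # (ICR label, hit?)
    fraction: float

    @property
    def n_hit(self) -> int:
        return sum(1 for _, hit in self.statuses if hit)


def evaluate_recovery(
    peaks: Sequence[Peak],
    known_icrs: Sequence[BedInterval],
    include_ambiguous: bool = False,
    chroms: Sequence[str] | None = None,
) -> RecoveryReport:
    """Fraction of known ICRs intersected by a robust peak.

    ``include_ambiguous`` also credits 2-site peaks.  When ``chroms`` is
    given (e.g. the scanned chromosome names), ICR entries on unknown
    chromosomes raise an error listing the unmatched names.
    """
    if chroms is not None:
        unmatched = sorted({i.chrom for i in known_icrs} - set(chroms))
        if unmatched:
            raise IcrScanError(f"known-ICR chromosomes not in genome: {unmatched}")
    usable = [
        p for p in peaks if p.peak_class == ROBUST or (include_ambiguous and p.peak_class == AMBIGUOUS)
    ]
    statuses = []
    for icr in known_icrs:
        label = icr.name if icr.name != "." else format_region(icr.chrom, icr.start, icr.end)
        hit = any(
            p.chrom == icr.chrom and _overlap(p.start, p.end, icr.start, icr.end)
            for p in usable
        )
        statuses.append((label, hit))
    fraction = (sum(h for _, h in statuses) / len(statuses)) if statuses else 0.0
    return RecoveryReport(statuses=tuple(statuses), fraction=fraction)
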