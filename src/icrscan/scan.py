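"""Exact-word scanning of genomic DNA on both strands.

Finds every occurrence of each motif-set member (forward strand) and of its
reverse complement (reported as strand '-') in soft-masked FASTA
chromosomes.  Matching is case-insensitive; windows containing N never
match; a palindromic motif is reported once, on '+'.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .errors import AlphabetError, FormatError, IcrScanError
from .motifs import MotifSet, reverse_complement

_GENOME_ALPHABET = frozenset("ACGTNacgtn")


@dataclass(frozen=True)
class SiteHit:
    """One genomic occurrence of a motif (0-based half-open interval)."""

    chrom: str
    start: int
    end: int
    strand: str
    motif_id: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def sort_key(self) -> tuple:
        return (self.start, self.end, self.motif_id, self.strand)


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    """Yield every (overlapping) occurrence start of needle in haystack."""
    pos = haystack.find(needle)
    while pos != -1:
        yield pos
        pos = haystack.find(needle, pos + 1)


def scan_sequence(sequence: str, motifs: MotifSet, chrom: str = "seq") -> list[SiteHit]:
    """All exact occurrences of the motif set on both strands of one sequence.

    Soft-masking (lowercase) is ignored; N aborts any candidate match (motifs
    are pure ACGT, so a window containing N can never match).  Output is
    sorted by (start, end, motif_id, strand); identical tuples are reported
    once; palindromic motifs yield a single '+' hit per position.
    """
    if len(motifs) == 0:
        raise ValueError("motif set is empty")
    if not sequence:
        return []
    bad = set(sequence) - _GENOME_ALPHABET
    if bad:
        raise AlphabetError(f"{chrom}: non-genomic characters {sorted(bad)!r}")
    seq = sequence.upper()

    hits: set[tuple[int, int, str, str]] = set()
    for m in motifs:
        word = m.sequence
        for pos in _find_all(seq, word):
            hits.add((pos, pos + len(word), m.id, "+"))
        rc = reverse_complement(word)
        if rc == word:  # palindrome: one '+' report only
            continue
        for pos in _find_all(seq, rc):
            hits.add((pos, pos + len(word), m.id, "-"))
    return sorted(
        (SiteHit(chrom, s, e, strand, mid) for (s, e, mid, strand) in hits),
        key=lambda h: h.sort_key,
    )


def scan_genome(fasta_path: str | Path, motifs: MotifSet) -> dict[str, list[SiteHit]]:
    """Scan every record of a FASTA file; returns {record name: hits}.

    Record order follows the FASTA; records without hits map to empty lists.
    """
    fasta_path = Path(fasta_path)
    results: dict[str, list[SiteHit]] = {}
    try:
        records = list(SeqIO.parse(str(fasta_path), "fasta"))
    except (OSError, ValueError) as exc:
        raise IcrScanError(f"cannot read FASTA {fasta_path}: {exc}") from exc
    if not records:
        raise FormatError(f"{fasta_path}: no FASTA records")
    for rec in records:
        if rec.id in results:
            raise FormatError(f"{fasta_path}: duplicate record name {rec.id!r}")
        results[rec.id] = scan_sequence(str(rec.seq), motifs, chrom=rec.id)
    return results
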