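"""Composite DNA motifs: the ZFP57 core, MLL1 morphemes, and their overlaps.

ZFP57 binds the CpG-methylated hexamer TGCCGC inside imprinting control
regions.  Because the hexamer alone is too short to be specific genome-wide,
it is extended into composite elements in which the hexamer overlaps a
CpG-rich MLL1 morpheme (the shortest DNA words selectively bound by the
MLL1/MLL2 MT domain).  This module represents those motifs, enumerates
composites from a morpheme list, and reads/writes motif-set files.

The published composite set is distributed as deposited data files and is
not shipped here; :func:`synthetic_motif_set` provides a clearly labeled
synthetic stand-in for testing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .errors import AlphabetError, FormatError

log = logging.getLogger(__name__)

#: Canonical ZFP57 binding hexamer.
ZFP57_CORE = "TGCCGC"

_DNA = frozenset("ACGT")
_RC_TABLE = str.maketrans("ACGTN", "TGCAN")


def _check_dna(sequence: str, *, what: str = "sequence", allow_n: bool = False) -> str:
    seq = sequence.upper()
    allowed = _DNA | {"N"} if allow_n else _DNA
    bad = set(seq) - allowed
    if not seq:
        raise AlphabetError(f"{what} is empty")
    if bad:
        raise AlphabetError(
            f"{what} contains non-DNA characters: {sorted(bad)!r} in {sequence!r}"
        )
    return seq


def reverse_complement(sequence: str) -> str:
    """Watson-Crick reverse complement of an uppercase ACGTN string.

    >>> reverse_complement("TGCCGC")
    'GCGGCA'
    """
    seq = _check_dna(sequence, what="sequence", allow_n=True)
    return seq.translate(_RC_TABLE)[::-1]


@dataclass(frozen=True)
class Motif:
    """One exact DNA word scanned for.

    Parameters
    ----------
    id
        Short unique label (used as BED name field).
    sequence
        Uppercase word over {A, C, G, T}.
    provenance
        ``core`` (the ZFP57 hexamer), ``morpheme`` (an MLL1 word), or
        ``composite`` (core overlapping a morpheme).
    core_offset
        For composites, 0-based offset of the core within the sequence.
    morpheme
        For composites, the source morpheme.
    """

    id: str
    sequence: str
    provenance: str = "composite"
    core_offset: int | None = None
    morpheme: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _check_dna(self.sequence, what=f"motif {self.id!r}"))
        if self.provenance not in ("core", "morpheme", "composite"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class MotifSet:
    """An ordered, duplicate-free collection of motifs sharing one core."""

    motifs: list[Motif] = field(default_factory=list)
    core: str = ZFP57_CORE

    def __post_init__(self) -> None:
        self.core = _check_dna(self.core, what="core")
        seen_ids: set[str] = set()
        seen_seqs: set[str] = set()
        for m in self.motifs:
            if m.id in seen_ids:
                raise FormatError(f"duplicate motif id {m.id!r}")
            if m.sequence in seen_seqs:
                raise FormatError(f"duplicate motif sequence {m.sequence!r} ({m.id!r})")
            seen_ids.add(m.id)
            seen_seqs.add(m.sequence)
            if m.provenance == "composite":
                self._check_composite(m)

    def _check_composite(self, m: Motif) -> None:
        if m.core_offset is None:
            raise FormatError(f"composite {m.id!r} lacks core_offset")
        if m.sequence[m.core_offset : m.core_offset + len(self.core)] != self.core:
            raise FormatError(
                f"composite {m.id!r}: core {self.core} absent at offset {m.core_offset}"
            )
        if m.morpheme is not None:
            if m.morpheme not in m.sequence:
                raise FormatError(f"composite {m.id!r}: morpheme {m.morpheme} not a substring")
            if len(m.sequence) > len(self.core) + len(m.morpheme) - 1:
                raise FormatError(f"composite {m.id!r} longer than core+morpheme-1")

    def __iter__(self) -> Iterator[Motif]:
        return iter(self.motifs)

    def __len__(self) -> int:
        return len(self.motifs)

    def __getitem__(self, motif_id: str) -> Motif:
        for m in self.motifs:
            if m.id == motif_id:
                return m
        raise KeyError(motif_id)

    def sequences(self) -> list[str]:
        return [m.sequence for m in self.motifs]


def _merge_at_offset(core: str, morpheme: str, offset: int) -> str | None:
    """Overlay ``morpheme`` starting at ``offset`` relative to the core start.

    Returns the merged word when every overlapped base agrees, else None.
    """
    lo = min(0, offset)
    hi = max(len(core), offset + len(morpheme))
    out = []
    for pos in range(lo, hi):
        c = core[pos] if 0 <= pos < len(core) else None
        m = morpheme[pos - offset] if 0 <= pos - offset < len(morpheme) else None
        if c is not None and m is not None and c != m:
            return None
        out.append(c if c is not None else m)
    return "".join(out)  # type: ignore[arg-type]


def enumerate_overlaps(
    core: str,
    morphemes: Iterable[str],
    min_overlap: int = 2,
) -> MotifSet:
    """Enumerate every composite formable by overlapping a morpheme with the core.

    The morpheme may sit on either side of the core; the overlapped region
    (>= ``min_overlap`` bases) must be base-identical.  Full containment of
    one word in the other collapses to the longer word.  Composites record
    their source morpheme and the core's offset within the merged word.

    Duplicate merged sequences are removed; output order is deterministic
    (sorted by sequence) and invariant to morpheme list order/duplication.
    """
    core = _check_dna(core, what="core")
    morpheme_list = sorted({_check_dna(m, what="morpheme") for m in morphemes})
    if not morpheme_list:
        warnings.warn("empty morpheme list: composite set is empty", stacklevel=2)
        return MotifSet([], core=core)
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")

    merged: dict[str, tuple[str, int]] = {}  # sequence -> (morpheme, core_offset)
    for morpheme in morpheme_list:
        if min_overlap > min(len(core), len(morpheme)):
            raise ValueError(
                f"min_overlap={min_overlap} exceeds min(len(core), len({morpheme!r}))"
            )
        for offset in range(-(len(morpheme) - 1), len(core)):
            ov = min(len(core), offset + len(morpheme)) - max(0, offset)
            if ov < min_overlap:
                continue
            word = _merge_at_offset(core, morpheme, offset)
            if word is None:
                continue
            merged.setdefault(word, (morpheme, max(0, -offset)))

    motifs = []
    for i, (seq, (morpheme, core_offset)) in enumerate(sorted(merged.items()), start=1):
        if seq == core:
            motifs.append(Motif(id="core", sequence=seq, provenance="core"))
        else:
            motifs.append(
                Motif(
                    id=f"ov{i:02d}",
                    sequence=seq,
                    provenance="composite",
                    core_offset=core_offset,
                    morpheme=morpheme,
                )
            )
    return MotifSet(motifs, core=core)


# --------------------------------------------------------------------------
# Motif-set files: TSV (id<TAB>sequence, '#' comments) or FASTA.


def load_motif_file(path: str | Path, core: str = ZFP57_CORE) -> MotifSet:
    """Read a motif set from a TSV (``id<TAB>sequence``) or FASTA file.

    Lowercase sequences are accepted, uppercased, and logged.  Composites
    are recognized by the core occurring as a substring; their core_offset
    is the first occurrence.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    records: list[tuple[str, str, int]] = []  # id, sequence, line number
    if any(ln.startswith(">") for ln in lines):
        name = None
        chunks: list[str] = []
        start_line = 0
        for i, ln in enumerate(lines, start=1):
            if ln.startswith(">"):
                if name is not None:
                    records.append((name, "".join(chunks), start_line))
                name = ln[1:].split()[0] if len(ln) > 1 else ""
                chunks, start_line = [], i
            elif ln.strip() and not ln.startswith("#"):
                chunks.append(ln.strip())
        if name is not None:
            records.append((name, "".join(chunks), start_line))
    else:
        for i, ln in enumerate(lines, start=1):
            if not ln.strip() or ln.startswith("#"):
                continue
            parts = ln.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{i}: expected 'id<TAB>sequence', got {ln!r}")
            records.append((parts[0], parts[1], i))
    if not records:
        raise FormatError(f"{path}: empty motif file")

    core = _check_dna(core, what="core")
    motifs = []
    seen_ids: dict[str, int] = {}
    seen_seqs: dict[str, int] = {}
    for name, seq, lineno in records:
        if seq != seq.upper():
            log.warning("%s:%d: lowercase sequence %r uppercased", path, lineno, seq)
        try:
            seq = _check_dna(seq, what=f"motif {name!r}")
        except AlphabetError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        if name in seen_ids:
            raise FormatError(f"{path}:{lineno}: duplicate id {name!r} (first at line {seen_ids[name]})")
        if seq in seen_seqs:
            raise FormatError(
                f"{path}:{lineno}: duplicate sequence {seq!r} (first at line {seen_seqs[seq]})"
            )
        seen_ids[name], seen_seqs[seq] = lineno, lineno
        if seq == core:
            motifs.append(Motif(id=name, sequence=seq, provenance="core"))
        elif core in seq:
            motifs.append(
                Motif(id=name, sequence=seq, provenance="composite", core_offset=seq.index(core))
            )
        else:
            motifs.append(Motif(id=name, sequence=seq, provenance="morpheme"))
    return MotifSet(motifs, core=core)


def save_motif_file(motif_set: MotifSet, path: str | Path, fmt: str = "tsv") -> None:
    """Write a motif set as TSV (default) or FASTA; round-trip stable."""
    path = Path(path)
    if fmt == "tsv":
        lines = ["# icrscan motif set: id<TAB>sequence"]
        lines += [f"{m.id}\t{m.sequence}" for m in motif_set]
    elif fmt == "fasta":
        lines = []
        for m in motif_set:
            lines += [f">{m.id}", m.sequence]
    else:
        raise ValueError(f"unknown motif file format {fmt!r}")
    path.write_text("\n".join(lines) + "\n")


def synthetic_motif_set(min_overlap: int = 2) -> MotifSet:
    """A small SYNTHETIC composite set for tests and demos.

    The morphemes below are invented CpG-rich hexamers standing in for the
    published MLL1 morpheme list, which is distributed as deposited data
    files and NOT reproduced here.  Composites are enumerated against the
    real ZFP57 core (TGCCGC).
    """
    morphemes = ["CGCACG", "GCGGCG", "CCGCCA", "ACGCGT", "CGCCGT", "CCTGCC", "GCGCTG"]
    return enumerate_overlaps(ZFP57_CORE, morphemes, min_overlap=min_overlap)
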