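"""Synthetic genomes with planted motif clusters and truth labels.

Generates i.i.d. background DNA at a chosen GC fraction (default 0.41,
human-like) and overwrites it with planted motif sites at specified
spacings.  In motif-free mode the background is rejection-cleaned until no
motif-set member occurs (either strand) outside the planted regions, so
the pipeline's peaks can be compared exactly against geometric truth.
Truth clusters and their expected robust/ambiguous class are derived from
the planted site geometry by the density module's own definitions.

Background realism is deliberately minimal: composition is i.i.d., so CpG
depletion of real vertebrate DNA is not modeled (a dinucleotide shuffle
mode is available for null-model work on real sequence).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .density import Peak, ScanParams, Site, call_peaks, collapse_sites
from .errors import SpecError
from .motifs import MotifSet, reverse_complement
from .scan import scan_sequence
from .track_io import BedInterval, write_bed

_MAX_CLEAN_ROUNDS = 200


@dataclass(frozen=True)
class PlantSpec:
    """One planted run of motif sites.

    ``gaps`` are the bases *between* consecutive sites (end to next start),
    one fewer than ``motif_ids``; ``strands`` gives the planted orientation
    per site ('-' plants the reverse complement).
    """

    position: int
    motif_ids: tuple[str, ...]
    gaps: tuple[int, ...] = ()
    strands: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.position < 0:
            raise SpecError("plant position must be >= 0")
        if len(self.gaps) != max(0, len(self.motif_ids) - 1):
            raise SpecError("need len(gaps) == n_sites - 1")
        if any(g < 0 for g in self.gaps):
            raise SpecError("gaps must be >= 0")
        if self.strands is not None and len(self.strands) != len(self.motif_ids):
            raise SpecError("strands must match motif_ids")

    @property
    def n_sites(self) -> int:
        return len(self.motif_ids)

    def site_intervals(self, motifs: MotifSet) -> list[tuple[int, int, str, str]]:
        """Expand to (start, end, motif_id, strand) tuples."""
        out = []
        pos = self.position
        strands = self.strands or ("+",) * self.n_sites
        for i, mid in enumerate(self.motif_ids):
            length = len(motifs[mid])
            out.append((pos, pos + length, mid, strands[i]))
            if i < len(self.gaps):
                pos += length + self.gaps[i]
        return out


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """A reproducible synthetic chromosome: same spec + seed => same bytes."""

    length: int
    seed: int
    gc: float = 0.41
    motif_free: bool = True
    plants: tuple[PlantSpec, ...] = ()
    chrom: str = "chrS"

    def __post_init__(self) -> None:
        if self.length < 1:
            raise SpecError("length must be >= 1")
        if not 0.0 < self.gc < 1.0:
            raise SpecError("gc must be in (0, 1)")


@dataclass(frozen=True)
class TruthCluster:
    chrom: str
    start: int
    end: int
    n_sites: int
    max_window_count: int
    peak_class: str


@dataclass
class SyntheticGenome:
    spec: SyntheticGenomeSpec
    sequence: str
    planted_sites: list[Site]
    truth: list[TruthCluster]

    def write_fasta(self, path: str | Path) -> None:
        lines = [f">{self.spec.chrom}"]
        lines += [self.sequence[i : i + 70] for i in range(0, len(self.sequence), 70)]
        Path(path).write_text("\n".join(lines) + "\n")

    def write_truth_bed(self, path: str | Path) -> None:
        rows = [
            BedInterval(t.chrom, t.start, t.end, f"{t.peak_class};n={t.n_sites}", t.max_window_count, "+")
            for t in self.truth
        ]
        write_bed(rows, path)


def _draw_background(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=probs)


def generate(
    spec: SyntheticGenomeSpec, motifs: MotifSet, params: ScanParams | None = None
) -> SyntheticGenome:
    """Build the synthetic chromosome and its truth labels.

    Truth = peaks called on the planted sites themselves (collapsed) with
    default :class:`ScanParams`; singleton plants therefore yield no truth
    cluster (suppressed as isolated occurrences).  In motif-free mode the
    assembled sequence is re-scanned and any stray motif occurrence outside
    the planted intervals has its background bases redrawn, up to a bounded
    number of rounds.
    """
    planted: list[tuple[int, int, str, str]] = []
    for p in spec.plants:
        planted.extend(p.site_intervals(motifs))
    planted.sort()
    for (s1, e1, *_), (s2, e2, *_) in zip(planted, planted[1:]):
        if s2 < e1:
            raise SpecError(f"plants overlap after expansion at [{s2}, {e1})")
    if planted and planted[-1][1] > spec.length:
        raise SpecError("planted sites extend past sequence end")

    rng = np.random.default_rng(spec.seed)
    arr = _draw_background(rng, spec.length, spec.gc)
    for start, end, mid, strand in planted:
        word = motifs[mid].sequence
        if strand == "-":
            word = reverse_complement(word)
        arr[start:end] = np.frombuffer(word.encode(), dtype="S1")

    planted_ivals = [(s, e) for s, e, _, _ in planted]

    def stray_hits(seq: str) -> list[tuple[int, int]]:
        strays = []
        for h in scan_sequence(seq, motifs, chrom=spec.chrom):
            inside = any(s <= h.start and h.end <= e for s, e in planted_ivals)
            if not inside:
                strays.append((h.start, h.end))
        return strays

    sequence = arr.tobytes().decode()
    if spec.motif_free:
        for _ in range(_MAX_CLEAN_ROUNDS):
            strays = stray_hits(sequence)
            if not strays:
                break
            for s, e in strays:
                for i in range(s, e):
                    if not any(ps <= i < pe for ps, pe in planted_ivals):
                        arr[i] = _draw_background(rng, 1, spec.gc)[0]
            sequence = arr.tobytes().decode()
        else:
            raise SpecError(
                "motif-free cleaning failed: planted junctions keep spawning motif hits"
            )

    sites = collapse_sites(
        [Site(spec.chrom, s, e) for s, e in planted_ivals]
    )
    params = params or ScanParams()
    truth = [
        TruthCluster(p.chrom, p.start, p.end, p.n_sites, p.max_window_count, p.peak_class)
        for p in call_peaks(sites, params)
    ] if sites else []
    return SyntheticGenome(spec=spec, sequence=sequence, planted_sites=sites, truth=truth)


# ----------------------------------------------------------------- shuffle


def shuffle_background(sequence: str, seed: int, dinucleotide: bool = False) -> str:
    """Composition-preserving shuffle (null model for false-peak studies).

    Mononucleotide mode permutes bases (exact composition preserved);
    dinucleotide mode walks a random Eulerian path on the dinucleotide
    transition multigraph (Altschul–Erikson), preserving all dinucleotide
    counts and the first/last base.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    if not dinucleotide:
        arr = np.frombuffer(sequence.encode(), dtype="S1").copy()
        rng.shuffle(arr)
        return arr.tobytes().decode()

    if len(sequence) < 3:
        return sequence
    # Altschul-Erikson: pick random last-edges into the terminal vertex to
    # guarantee an Eulerian path, then random-walk the remaining edges.
    edges: dict[str, list[str]] = {}
    for a, b in zip(sequence, sequence[1:]):
        edges.setdefault(a, []).append(b)
    last = sequence[-1]
    for _ in range(10_000):
        trial = {a: list(bs) for a, bs in edges.items()}
        for a in trial:
            rng.shuffle(trial[a])
        # walk from the first base, always consuming the next edge
        out = [sequence[0]]
        cur = sequence[0]
        ok = True
        for _step in range(len(sequence) - 1):
            if not trial.get(cur):
                ok = False
                break
            nxt = trial[cur].pop()
            out.append(nxt)
            cur = nxt
        if ok and cur == last:
            return "".join(out)
    raise SpecError("dinucleotide shuffle failed to find an Eulerian arrangement")


# -------------------------------------------------------------- spec files


def load_spec(path: str | Path) -> SyntheticGenomeSpec:
    """Read a genome spec from YAML (see ``save_spec`` for the layout)."""
    data = yaml.safe_load(Path(path).read_text())
    plants = tuple(
        PlantSpec(
            position=p["position"],
            motif_ids=tuple(p["motif_ids"]),
            gaps=tuple(p.get("gaps", ())),
            strands=tuple(p["strands"]) if "strands" in p else None,
        )
        for p in data.get("plants", [])
    )
    return SyntheticGenomeSpec(
        length=data["length"],
        seed=data["seed"],
        gc=data.get("gc", 0.41),
        motif_free=data.get("motif_free", True),
        plants=plants,
        chrom=data.get("chrom", "chrS"),
    )


def save_spec(spec: SyntheticGenomeSpec, path: str | Path) -> None:
    data = {
        "length": spec.length,
        "seed": spec.seed,
        "gc": spec.gc,
        "motif_free": spec.motif_free,
        "chrom": spec.chrom,
        "plants": [
            {
                "position": p.position,
                "motif_ids": list(p.motif_ids),
                "gaps": list(p.gaps),
                **({"strands": list(p.strands)} if p.strands else {}),
            }
            for p in spec.plants
        ],
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
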