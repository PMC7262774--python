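# Methods

## Model

The predictor rests on one empirical regularity: imprinting control regions
(ICRs/gDMRs) contain *clusters* of composite DNA elements in which the
ZFP57-bound hexamer TGCCGC overlaps a CpG-rich MLL1 morpheme, whereas random
occurrences of these composites are sparse and isolated. The statistic is
deliberately simple — no positional weights, no significance model — because
the unit being counted is an exact word whose clustering, not its individual
occurrence, carries the signal.

For a chromosome with collapsed site starts `s_1 < s_2 < …` and window
length `W`, the density at anchor `x` is

    d(x) = |{ i : x ≤ s_i < x + W }|,   with d(x) := 0 whenever d(x) ≤ 1.

The zeroing step is the background-noise suppression: a window containing a
single composite is indistinguishable from a random occurrence. The profile
is defined over *every* anchor (step-free); the implementation is
event-driven — each site contributes the anchor interval
`[max(0, s_i − W + 1), s_i]` and a sweep over the ±1 events reproduces the
all-anchor evaluation exactly, which the tests verify against a brute-force
oracle.

Peaks are maximal single-linkage chains of sites with start-to-start gap
≤ `chain_gap`. A chain of ≥ `min_cluster_count` sites becomes one peak
spanning first site start → last site end (so a peak may exceed `W`;
reported candidate spans of real ICRs range roughly 0.6–2.5 kb). Its class
is decided by `max_window_count` — the largest number of member sites inside
any single window, computed only at windows flush with a site start, where
the maximum must be attained:

- `max_window_count ≥ 3` → **robust** (the candidate-ICR call),
- `= 2` → **ambiguous** (a true or a false positive).

Classification uses the within-window maximum rather than the chain size:
three sites spread over 2.4 kb never co-occupy one 850-base window and stay
ambiguous, while three sites within one window are robust even inside a
longer chain.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `window_length` | 850 | bases | Tuned by trial and error in the source method: narrower windows fragment real clusters into spikes, wider ones merge neighboring clusters into false peaks. The window-size study in the acceptance suite reproduces both failure modes (425 splits, 1700 merges). |
| `min_cluster_count` | 2 | sites | Clusters of ≥ 2 composites are the weakest reportable signal. |
| `robust_threshold` | 3 | sites/window | ≥ 3 composites per window proved reliable; 2 is true-or-false-positive. |
| `chain_gap` | = `window_length` | bases | The smallest gap guaranteeing that any pair counted together by some window lies in one chain; doublet ICRs stay one peak while the bedGraph profile still shows both maxima. |
| `collapse_overlapping_hits` | on | — | Two composites sharing one genomic TGCCGC are one physical ZFP57 site; counting both would inflate density. Disable to compare with externally produced position files. |
| `promoter_margin` | 2000 | bases | "Vicinity of a TSS" for gene nomination; the conventional promoter window. Nomination is monotone in this margin. |

Counting unit: a site is *in* a window when its **start** is (not interval
overlap). The alternatives differ only at window edges, below the
biological resolution of the method.

## Coordinates

Internal and BED/bedGraph coordinates are 0-based half-open; human-readable
reports print 1-based inclusive spans with thousands separators
(`chr4:81,122,001-81,124,000`), matching genome-browser conventions.
Chromosome names pass through verbatim. Nearest-gene distances are signed:
negative = upstream of the gene (strand-aware), 0 = overlapping.

## Scanning

Both strands are scanned by searching each motif and its reverse complement
on the forward sequence; a palindromic motif is reported once, on '+'.
Soft-masking is uppercased away (hit sets are case-invariant); any N aborts
a match — there is no wildcard matching, and no approximate matching at all:
the composites are exact words by construction. Overlapping occurrences of
*different* motifs are reported separately in BED output and collapsed
before counting (see above).

## Annotation semantics

`TSS-overlap` (peak contains a transcript TSS) outranks `intragenic` (peak
overlaps a gene span) outranks `intergenic`. The ranking reflects how
candidate ICRs are described: TSS relationship first, even at
overlapping-gene loci where a peak sits in one gene's body and the other
gene's promoter. Intragenic is defined on the gene span (union of
transcripts); overlap with an exon (e.g. an intragenic CpG island in a
terminal exon) is reported as a note, not a class. Nearest-gene ties break
deterministically by smaller gene start, then name.

`evaluate_recovery` scores a known-ICR catalog as hit/miss by robust-peak
intersection (optionally crediting ambiguous peaks) and reports the overall
fraction.

## Synthetic genomes

The generator emulates the *geometry* of the signal, not the sequence
landscape of real DNA: background is i.i.d. at GC 0.41 (human-like), and
planted sites are exact motif copies at specified spacings and strands. In
motif-free mode the background is rejection-cleaned — the assembled sequence
is re-scanned and any stray motif occurrence outside a planted interval has
its background bases redrawn (bounded rounds; a junction that keeps
spawning hits is an error). Truth clusters and their classes are derived
from the planted geometry by the density module's own definitions, so
pipeline-vs-truth comparisons are exact.

What a green planted-recovery test does **not** establish: performance on
real chromatin. i.i.d. background has no CpG depletion, so CpG-rich motifs
occur *more* often by chance than in real vertebrate DNA, and there are no
CpG islands, repeats, or isochores; the false-positive behavior of the
method on hg19 cannot be inferred from these tests. A mononucleotide
shuffle (exact composition preserved) and an Altschul–Erikson dinucleotide
shuffle (all dinucleotide counts preserved) are provided for null-model
work on real sequence.

## Numerical / degenerate-input choices

- Suppression is applied after window evaluation (anchors with count ≤ 1
  emit 0). The alternative — deleting singleton sites before evaluation —
  differs only in profile display, never in peak calls of ≥ 2 sites.
- Composite enumeration requires an overlap of ≥ 2 identical bases
  (`min_overlap=2`); single-base "overlaps" would mostly be concatenations.
  Full containment collapses to the longer word. Enumeration is invariant
  to morpheme order and duplication; morphemes are matched on the given
  strand only, since the scanner handles the minus strand genome-wide
  (enumerating against the reverse-complement core would double count).
- Collapsing merges strictly overlapping intervals; book-ended (touching)
  sites remain distinct. Collapsing is idempotent.
- Empty inputs: empty sequence → no hits; empty gene set → all peaks
  intergenic with no nearest gene; empty ICR catalog → recovery fraction 0.
- bedGraph output merges adjacent equal-value runs, omits zero runs, and
  rejects overlapping runs; all writers are byte-deterministic.

## Known limitations

- Exact matching only: no PWMs or IUPAC degeneracy (the method's unit is an
  exact composite word).
- No statistical calibration of peaks (no p-values/FDR): classes are count
  thresholds, as defined.
- Whether a composite containing two core instances deserves special
  treatment is unspecified upstream; here it is one motif, one hit per
  occurrence, collapsed like any other overlap.
- Cross-gene attribution of far-upstream peaks beyond `promoter_margin` is
  not attempted.
- Chromosomes are processed one at a time in memory (~1 byte/base plus
  overhead); genome-scale runs are minutes per human chromosome on one CPU.
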