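# icrscan

Genome-wide prediction of **imprinting control regions (ICRs)** from the
local density of composite DNA elements in which the ZFP57 binding hexamer
overlaps CpG-rich MLL1 morphemes.

## The problem

Genomic imprinting — parent-of-origin-specific monoallelic expression — is
governed by ICRs / germline differentially methylated regions (gDMRs). The
KRAB zinc-finger protein ZFP57 maintains methylation imprints by binding the
CpG-methylated hexamer **TGCCGC**, but that word is too short to be specific
across a mammalian genome. Specificity improves when the hexamer is extended
into *composite* elements that overlap **MLL1 morphemes** — the shortest
CpG-rich words selectively bound by the MT domain of MLL1/MLL2 (ZFBS-morph
overlaps). Within true ICRs these composites occur in tight clusters, while
random occurrences are scattered.

`icrscan` turns that observation into a predictor, for epigenomics and
regulatory-genomics researchers who want candidate ICRs (and hence candidate
imprinted genes) directly from chromosome sequence:

1. **Scan** both strands of FASTA chromosomes for every exact occurrence of a
   composite-motif set; overlapping hits are collapsed — they share one
   physical ZFP57 core.
2. **Density statistic** — for every anchor *x* along the chromosome, count
   collapsed sites with start in *[x, x + W)*, with window length
   **W = 850 b**. Anchors covering at most one site report **0**: isolated
   occurrences are background noise and suppressed.
3. **Peak calling** — chain nearby sites (start-to-start gap ≤ W) into
   clusters; clusters of ≥ 2 sites become peaks. A peak is **robust** when
   some 850-base window holds **≥ 3** sites (the candidate-ICR call) and
   **ambiguous** at exactly 2 ("could be a true or a false positive").
4. **Annotate** peaks against gene models (GTF/BED12) and CpG islands (BED):
   TSS-overlap / intragenic / intergenic, nearest gene with signed
   strand-aware distance, candidate-gene nomination, and recovery scoring
   against a known-ICR catalog.
5. **Export** UCSC custom tracks: BED6 hits and peaks, bedGraph density.

A synthetic-genome module generates test chromosomes with controlled GC
content and planted motif clusters carrying truth labels, so the entire
pipeline is testable without downloading any reference data. The shipped
motif set is likewise synthetic — the published composite set is distributed
as deposited data files and is *not* reproduced here; pass your own motif
file for real analyses.

## Worked example

```python
from icrscan import *

ms = synthetic_motif_set()                      # synthetic stand-in set
spec = SyntheticGenomeSpec(
    length=50_000, seed=7,
    plants=(PlantSpec(8_000,  ("ov01", "ov03", "ov07"), (150, 400)),
            PlantSpec(30_000, ("ov02", "ov05"), (500,)),
            PlantSpec(44_000, ("ov04",))),      # a lone site
)
genome = generate(spec, ms)
sites = collapse_sites(scan_sequence(genome.sequence, ms, chrom="chrS"))
print(f"{len(sites)} collapsed sites")
for p in call_peaks(sites, ScanParams()):
    print(f"{format_region(p.chrom, p.start, p.end)}  class={p.peak_class}  "
          f"sites={p.n_sites}  max_in_window={p.max_window_count}")
```

prints

```
6 collapsed sites
chrS:8,001-8,577  class=robust  sites=3  max_in_window=3
chrS:30,001-30,519  class=ambiguous  sites=2  max_in_window=2
```

The three-site plant becomes a robust peak (3 sites inside one 850-base
window), the pair is called but flagged ambiguous, and the planted singleton
is suppressed as background — the method's three regimes. Spans are printed
1-based inclusive, browser style.

The same workflow is available from the shell:

```sh
icrscan simulate --spec genome.yaml --motifs motifs.tsv \
    --out-fasta genome.fa --out-truth truth.bed
icrscan run-all --fasta genome.fa --motifs motifs.tsv \
    --genes genes.gtf --cgi cgi.bed --outdir out/
icrscan evaluate --peaks out/peaks.bed --icrs truth.bed
```

`run-all` writes `sites.bed`, `density.bedGraph`, `peaks.bed`,
`annotation.tsv` and `nominations.tsv`, each with a JSON run manifest
(parameters, input checksums, version). All defaults mirror the method:
`--window 850 --min-cluster 2 --robust 3`.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from scratch on a ~1 Mb motif-free synthetic
chromosome with ~40 planted clusters: scan → density → peak calling →
annotation → recovery of the planted robust clusters, printing the counts it
measures and checking that called peaks equal the planted truth in position
and class.

## Layout

- `src/icrscan/motifs.py` — motif model, composite enumeration, motif files
- `src/icrscan/scan.py` — both-strand exact scanning of FASTA chromosomes
- `src/icrscan/density.py` — window counts, suppression, peak calling/classes
- `src/icrscan/annotate.py` — localization, nomination, ICR recovery
- `src/icrscan/track_io.py` — BED/bedGraph/GTF/BED12 + UCSC track lines
- `src/icrscan/synthetic.py` — planted-cluster genome generator, shuffles
- `src/icrscan/cli.py` — `icrscan` subcommands

See `docs/methods.md` for the model, parameter rationale, and limitations.
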