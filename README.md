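# hrdscar

Automated **homologous recombination deficiency (HRD) scar scoring** from
structural-variant (SV), copy-number (CNV/AOH) and aneuploidy call files.

HR-deficient tumors cannot repair double-strand breaks through the
homologous-recombination pathway, and the resulting genomic instability
leaves quantifiable scars. `hrdscar` classifies called variants into the
three canonical scar signatures — loss of heterozygosity (**LOH**, >15 Mb
and smaller than a chromosome), telomeric allelic imbalance (**TAI**,
imbalance reaching the sub-telomere), and large-scale state transitions
(**LST**, chromosome breaks >10 Mb) — and sums fixed per-class point
weights into per-chromosome and genome-wide HRD scores. It is aimed at
cytogenetics/oncology analysts working with optical-genome-mapping (OGM)
rare-variant output, and at methodologists comparing platforms: a
**CNA-only mode** restricts scoring to copy-number/AOH evidence, emulating
what a chromosomal microarray or NGS gene panel can see.

## The scoring scheme

After filtering (per-type SV confidence floors, control-database frequency
= 0, ≥5 supporting molecules, CNV confidence ≥0.99) and stitching of
same-state CNV fragments within 500 kbp, each segment is classified:

| class | definition | points |
|---|---|---|
| TAI-0 | terminal gain/loss/AOH > 3 Mb, < 10 Mb | 1 |
| TAI-1 | terminal gain/loss/AOH > 10 Mb | 2 |
| TAI-LOH-1 | terminal loss/AOH > 15 Mb | 3 |
| LOH-0 | interstitial loss/AOH > 15 Mb, 0 breakpoints | 1 |
| LOH-1 | interstitial loss/AOH > 15 Mb, 1 breakpoint | 2 |
| LOH-2 | interstitial loss/AOH > 15 Mb, 2 breakpoints | 3 |
| LST-1 | interstitial event > 10 Mb, 1 breakpoint | 1 |
| LST-2 | interstitial event > 10 Mb, 2 breakpoints (incl. >10 Mb inversions) | 2 |
| LST-3 | insertion > 10 Mb (3 anticipated breakpoints) | 3 |

Whole-chromosome events (trisomies, whole-chromosome AOH) score 0.
Breakpoints are segment ends that are neither telomeric nor inside the
(mask-extended) centromeric region. On top of the copy-number base class,
each segment end coinciding (±500 kbp) with a retained translocation
junction earns a **+1 rearrangement bonus**, and retained interchromosomal
translocations not consumed this way score 1 LST point each — the mechanism
by which full SV visibility outscores CNA-only platforms on identical
copy-number input. Chromosomes with >15 intrachromosomal fusion events are
flagged as possible chromothripsis and can optionally be excluded.

## Worked example

A 5.3 Mb interstitial deletion is below every size threshold, but when both
of its ends are explained by t(16;19) translocation junctions it still
scores — with SV evidence only:

```python
from hrdscar import CNVSegment, SVCall, compute_hrd, load_genome

genome = load_genome("GRCh38")
deletion = CNVSegment(chrom="16", start=60_000_000, end=65_299_999,
                      state="loss", confidence=0.995, id="del")
junctions = [
    SVCall(id="t1", chrom_a="16", pos_a=60_000_000, chrom_b="19",
           pos_b=40_000_000, sv_type="translocation", size=0,
           confidence=0.5, molecule_support=10, control_frequency=0.0),
    SVCall(id="t2", chrom_a="16", pos_a=65_299_999, chrom_b="19",
           pos_b=45_000_000, sv_type="translocation", size=0,
           confidence=0.5, molecule_support=10, control_frequency=0.0),
]
for mode in ("ogm", "cna"):
    result = compute_hrd(junctions, [deletion], [], genome, mode=mode)
    print(mode, result.total, result.signature_totals)
```

prints

```
ogm 2 {'LOH': 0, 'TAI': 0, 'LST': 2}
cna 0 {'LOH': 0, 'TAI': 0, 'LST': 0}
```

— 2 points in full-evidence mode (one LST-class scar carrying two bonus
points from the matched junctions), 0 in CNA-only mode where the deletion
is invisible to scoring.

The same pipeline is available from the shell:

```
hrd score --sv sv.tsv --cnv cnv.tsv --aneuploidy an.tsv \
    --genome GRCh38 --mode ogm --out result.json
hrd simulate --spec case.yaml --seed 17 --out-dir fixtures/
hrd report --result result.json
```

`hrd simulate` generates synthetic SV/CNV/aneuploidy call sets with planted
scars, decoys and fragmentation, together with the ground-truth result —
every pipeline stage is testable without any external data.

## Input formats

* SV TSV: `id chrom_a pos_a chrom_b pos_b sv_type size confidence
  molecule_support control_frequency` (SMAP-like; foreign headers can be
  aliased). SV VCF 4.2 with `SVTYPE`/`END`/BND records is also accepted.
* CNV TSV: `chrom start end state confidence [copy_number]` with state
  `gain|loss|aoh`; aneuploidy TSV: `chrom event fraction`.
* Genome annotation: bundled GRCh38 (lengths, centromeres, telomeric
  masks), overridable with a TSV (`chrom length cen_start cen_end` rows plus
  optional `chrom mask_start mask_end` rows).

All coordinates are 1-based closed intervals.

`hrdscar` reports scores only: it deliberately does not apply an
HR-deficient/HR-proficient cutoff (published cutoffs disagree), and it does
not call variants, genotypes or BRCA/HRR mutations.
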