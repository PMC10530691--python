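# Methods

## Model

`hrdscar` implements a deterministic scar-counting procedure, not a fitted
statistical model. The quantity it reports — the HRD score — is a weighted
count of genomic scars attributable to defective double-strand-break
repair, built from three signatures: LOH (large loss/copy-neutral AOH
regions), TAI (allelic imbalance reaching a telomere), and LST (large-scale
state transitions, i.e. chromosome breaks >10 Mb). The nine scored classes
and their 1/2/3-point weights are listed in the README; they are treated as
a fixed, immutable rule table.

The pipeline is: **filter → stitch → geometry → classify → bonus →
chromothripsis flag → aggregate**. Every stage is a pure function of its
inputs; identical inputs give byte-identical JSON output.

## Assumptions

* Variant calls are taken at face value: no re-calling, no genotype or
  B-allele-frequency computation; AOH is whatever the upstream caller
  labelled `aoh`.
* Coordinates are 1-based closed intervals on a single build (bundled
  GRCh38). No liftover, no sequence handling.
* A segment "reaches" a telomere or centromere if it overlaps the
  *effective* region (below) — endpoint equality is deliberately not
  required, because mosaic and mask-shortened calls rarely hit base 1.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| SV confidence floors | ins 0, del 0, inv 0.01, dup −1, transloc 0 | platform-recommended per-type minimums (inclusive) |
| `cnv_confidence` | 0.99 | CNV retention floor; the upstream platform also documents a permissive "low stringency = 0" reading, selectable via config |
| `max_control_frequency` | 0 | keep only variants absent from the control database |
| `min_molecule_support` | 5 | molecules spanning the SV breakpoints |
| `stitch_max_gap` | 500 kbp | max gap for merging same-state CNV fragments; also the mask-extension adjacency |
| `tai_min` / `tai0_max` | 3 / 10 Mb | TAI floor and TAI-0/TAI-1 split |
| `loh_min` | 15 Mb | LOH floor |
| `lst_min` / `lst_exclusion` | 10 / 3 Mb | LST floor; nothing below 3 Mb ever scores |
| `breakpoint_match_tolerance` | 500 kbp | segment-end vs translocation-junction match radius (reuses the one stated adjacency constant rather than introducing a second) |
| `chromothripsis_threshold` | 15 | flag chromosomes with **more than** this many intrachromosomal fusions |
| `exclude_chromothripsis` | off | flagged chromosomes are reported, not excluded, by default |

All size comparisons are strict (`>` / `<`) as printed in the scheme: a
segment of exactly 10 Mb is neither TAI-0 nor TAI-1. All filter
comparisons are inclusive at the printed thresholds, keeping variants at
exactly the recommended confidence.

## Geometry

Copy-number callers lose sensitivity in masked regions, so the telomeric
and centromeric anchors are extended through any masked region chained to
them by gaps ≤ the stitch distance ("effective" terminal/centromeric
regions). A segment end is a **chromosome breakpoint** iff it is neither
inside its arm's effective terminal region nor inside the effective
centromeric region — centromeric breaks are not counted. Whole-chromosome
detection is geometric (terminal on both arms), never fraction-of-length
based; whole-chromosome events score 0 in every mode.

The bundled GRCh38 annotation uses assembly-exact chromosome lengths,
cytoband-level centromere approximations, and the 10 kb telomeric assembly
gaps as masked regions. Acrocentric p-arms are intentionally *not* masked:
masking them would fuse the p-terminal and centromeric effective regions
and make centromere-bounded interstitial segments on 13/14/15/21/22
unclassifiable. The masked-region catalog is an implementer-supplied
approximation and fully user-overridable via the annotation TSV.

Stitching may bridge the centromere: only gap size and state matter.

## Rearrangement bonus and SV scars

The bonus rule — +1 point per segment end whose position coincides with a
retained translocation junction, on top of the copy-number base class — is
the minimal rule consistent with the two benchmark configurations (a 5.3 Mb
deletion with both ends translocated: 0 base + 2 = 2; a >15 Mb LOH-2
deletion with one translocated end: 3 + 1 = 4). Design choices around it:

* Matching is greedy nearest-first; each translocation supports at most one
  segment end and each end is matched at most once.
* Only genuine breakpoint ends are matchable — a telomeric or centromeric
  end is not a rearrangement junction. Totals are unaffected (an
  unconsumed translocation scores 1 under LST anyway); attribution is
  cleaner.
* A segment below the 3 Mb exclusion emits nothing, bonus included; its
  flanking translocations then score as unmatched events, keeping the total
  monotone in evidence.
* Retained interchromosomal translocations not consumed as bonus evidence
  score 1 point each, accounted under LST with the LST-1 class label and
  attributed to their first chromosome. This is required for
  rearrangement-dominated genomes and is config-switchable
  (`score_unmatched_translocations`), as is the bonus itself
  (`rearrangement_bonus`).
* Duplication *segments* are scored like gains; duplication SV records do
  not score on their own (their copy-number footprint does).
* Intrachromosomal fusions/inversions spanning >10 Mb score LST-2;
  insertions >10 Mb score LST-3.

Because per-signature totals can be read either as point sums or event
counts, the result carries both (`signature_totals`, `signature_counts`).

## CNA-only mode

`mode="cna"` ignores the SV input entirely — no bonus, no SV scars, no
chromothripsis flags — emulating microarray / NGS-panel visibility for
platform comparison. For identical CNV/AOH input the full-evidence total is
always ≥ the CNA-only total.

## Synthetic data generator

`generate_case` plants scars by class on real (or toy) chromosome
geometry and returns call sets plus the ground-truth result computed from
the planting plan alone, independent of the scoring pipeline. It emulates:

* fragmented CNV calls (pieces with gaps < 500 kbp, exercising stitching);
* decoys that each fail exactly one retention rule — sub-3 Mb segments,
  below-threshold confidence (kept >1e-6 clear of the boundary to avoid
  flakiness), control-database frequency >0, molecule support <5;
* translocation-evidenced segment ends (partner breakpoints are placed in
  the partner chromosome's centromere, where they can never be mistaken
  for copy-number break ends);
* trisomy "fracture" (`degrade_to_cna_platform`), reproducing the
  false-positive mechanism by which a mosaic trisomy under limited
  coverage appears as two scoring segmental gains.

It does **not** simulate molecule-level noise, tumor purity, breakpoint
imprecision beyond the match tolerance, overlapping same-state calls, or a
realistic genome-wide background of benign CNVs. Passing tests therefore
demonstrate the correctness of the scoring logic on well-formed call sets,
not robustness to caller artifacts beyond the modelled decoy classes.
Placement uses one explicitly passed seeded generator; same seed, same
bytes. LOH-0 (interstitial >15 Mb with zero breakpoints) is geometrically
impossible on the bundled GRCh38 annotation — it needs an effective
centromeric region wider than 15 Mb — so the generator refuses it there and
it is exercised on a toy genome with wide centromere-flanking masks.

## Numerical and degenerate-input choices

* Gap between closed intervals = bases strictly between (b.start − a.end −
  1); merge iff gap ≤ 500 000, so a 500 kbp gap merges and 501 kbp does not.
* Stitched confidence is the minimum of the parts; copy number is kept only
  if all parts agree.
* AOH segments with no reported confidence pass the CNV filter (no AOH
  confidence scale is defined upstream); logged when it happens.
* Intrachromosomal SV rows with reversed breakpoints are canonicalized by
  swapping; readers otherwise fail loudly with the offending line number,
  and never silently drop rows.
* VCF input lacking molecule support / control frequency defaults those
  fields to pass-through values with a logged warning.
* Segment processing order (chromosome, start) is canonical, so greedy
  bonus consumption is deterministic and input-order independent.
* The library's `write_result` JSON is byte-deterministic; the CLI
  additionally embeds a run manifest whose timestamp lives only in that
  manifest block.

## Problem sizes

Tests run on single cases of a handful of variants each; the generator
round-trip property uses 200 random case specs of 1–4 planted scars with
decoys and fragmentation, which completes in a few seconds. The acceptance
script scores nine constructed configurations of 1–3 records each.

## Known limitations

* Centromere coordinates and the mask catalog are approximations; users
  with a platform-specific catalog should supply their own annotation TSV.
* No HR-deficient/proficient dichotomization is offered — published
  cutoffs disagree — and no cohort-level statistics are computed.
* The bonus rule is an inference from two published configurations; other
  readings (e.g. bonus capped by base class) are possible and can be
  explored via the config switches.
* Balanced-event scars other than translocations/inversions/insertions
  (e.g. complex derivative chromosomes) are only scored insofar as they
  surface as those call types.
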