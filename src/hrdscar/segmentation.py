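"""From filtered CNV/AOH calls to analysis-ready segments.

Copy-number callers fragment long events, especially across regions of
reduced sensitivity, so same-state fragments separated by small gaps
(default 500 kbp) are stitched back together before classification.
Geometry is then resolved against the genome model: which segment ends are
telomeric, which fall inside the effective centromeric region, and which
remain as genuine chromosome breakpoints — the quantity the LOH/LST classes
condition on.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome import (
    DEFAULT_STITCH_GAP,
    ChromAnnotation,
    GenomeBuild,
    effective_centromeric_region,
    effective_terminal_region,
    interval_gap,
    intervals_overlap,
)
from .variant_io import AneuploidyCall, CNVSegment

_CHROM_ORDER = {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24}


def chrom_sort_key(name: str) -> tuple[int, str]:
    return (_CHROM_ORDER.get(name, 99), name)


@dataclass(frozen=True)
class SegmentGeometry:
    """Placement of a segment within its chromosome.

    ``cn_breakpoints`` counts the segment ends that are genuine chromosome
    breaks: neither inside the effective terminal region of their arm nor
    inside the effective centromeric region (centromeric breaks are not
    counted as breakpoints).
    """

    terminal_p: bool
    terminal_q: bool
    spans_centromere: bool
    whole_chromosome: bool
    cn_breakpoints: int
    start_is_break: bool = False
    end_is_break: bool = False

    @property
    def terminal(self) -> bool:
        return self.terminal_p or self.terminal_q


def classify_geometry(segment: CNVSegment, genome: GenomeBuild,
                      max_gap: int = DEFAULT_STITCH_GAP) -> SegmentGeometry:
    """Resolve terminal/centromeric/whole-chromosome flags and breakpoints.

    A segment is terminal on an arm iff it overlaps that arm's effective
    terminal region (overlap, not endpoint equality: mask-shortened calls
    rarely hit base 1). Whole-chromosome means terminal on both arms.
    """
    if segment.chrom not in genome:
        raise KeyError(f"chromosome {segment.chrom!r} not in genome build")
    ann: ChromAnnotation = genome[segment.chrom]
    if segment.end > ann.length:
        raise ValueError(
            f"segment {segment.chrom}:{segment.start}-{segment.end} "
            f"exceeds chromosome length {ann.length}")
    p_term = effective_terminal_region(ann, "p", max_gap)
    q_term = effective_terminal_region(ann, "q", max_gap)
    cen = effective_centromeric_region(ann, max_gap)
    iv = segment.interval
    terminal_p = intervals_overlap(iv, p_term)
    terminal_q = intervals_overlap(iv, q_term)
    spans_cen = intervals_overlap(iv, cen)
    whole = terminal_p and terminal_q

    def _is_break(pos: int, term: tuple[int, int]) -> bool:
        in_term = term[0] <= pos <= term[1]
        in_cen = cen[0] <= pos <= cen[1]
        return not (in_term or in_cen)

    start_break = _is_break(segment.start, p_term)
    end_break = _is_break(segment.end, q_term)
    return SegmentGeometry(
        terminal_p=terminal_p, terminal_q=terminal_q,
        spans_centromere=spans_cen, whole_chromosome=whole,
        cn_breakpoints=int(start_break) + int(end_break),
        start_is_break=start_break, end_is_break=end_break,
    )


def stitch_segments(cnvs: list[CNVSegment],
                    max_gap: int = DEFAULT_STITCH_GAP) -> list[CNVSegment]:
    """Merge same-chromosome, same-state segments with gaps <= ``max_gap``.

    Merging is transitive; merged confidence is the minimum of the parts and
    the copy number is kept only when all parts agree. Different states never
    merge. Output is canonically sorted (chromosome, start), so stitching is
    independent of input order.
    """
    groups: dict[tuple[str, str], list[CNVSegment]] = {}
    for seg in cnvs:
        groups.setdefault((seg.chrom, seg.state), []).append(seg)
    out: list[CNVSegment] = []
    for (chrom, state), members in groups.items():
        members = sorted(members, key=lambda s: (s.start, s.end))
        cluster: list[CNVSegment] = []
        for seg in members:
            if cluster and interval_gap((cluster[-1].start, max(m.end for m in cluster)),
                                        seg.interval) <= max_gap:
                cluster.append(seg)
            else:
                if cluster:
                    out.append(_merge_cluster(cluster))
                cluster = [seg]
        if cluster:
            out.append(_merge_cluster(cluster))
    out.sort(key=lambda s: (chrom_sort_key(s.chrom), s.start, s.end, s.state))
    return out


def _merge_cluster(cluster: list[CNVSegment]) -> CNVSegment:
    if len(cluster) == 1:
        return cluster[0]
    confs = [s.confidence for s in cluster]
    conf = None if any(c is None for c in confs) else min(confs)
    cns = {s.copy_number for s in cluster}
    return CNVSegment(
        chrom=cluster[0].chrom,
        start=min(s.start for s in cluster),
        end=max(s.end for s in cluster),
        state=cluster[0].state,
        confidence=conf,
        copy_number=cns.pop() if len(cns) == 1 else None,
        id="+".join(s.id for s in cluster if s.id),
        from_aneuploidy=all(s.from_aneuploidy for s in cluster),
    )


_EVENT_STATE = {"gain": "gain", "loss": "loss", "whole_chrom_aoh": "aoh"}


def aneuploidy_to_segments(calls: list[AneuploidyCall],
                           genome: GenomeBuild) -> list[CNVSegment]:
    """Whole-chromosome segments for aneuploidy calls.

    These span base 1 to the chromosome end, classify as whole-chromosome,
    and therefore never contribute scar points.
    """
    out: list[CNVSegment] = []
    for call in calls:
        if call.chrom not in genome:
            raise KeyError(f"aneuploidy chromosome {call.chrom!r} not in genome build")
        ann = genome[call.chrom]
        out.append(CNVSegment(
            chrom=ann.name, start=1, end=ann.length,
            state=_EVENT_STATE[call.event],
            confidence=None, id=f"aneuploidy_{call.event}_{ann.name}",
            from_aneuploidy=True,
        ))
    return out
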