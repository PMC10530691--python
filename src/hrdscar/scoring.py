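"""HRD scar classification and score aggregation.

Each qualifying copy-number/AOH segment (never a whole chromosome) is
assigned one of nine scar classes built from three genomic-instability
signatures, each with a fixed point weight:

======== ======================================================== ======
class    definition                                               points
======== ======================================================== ======
TAI-0    terminal gain/loss/AOH  > 3 Mb, < 10 Mb                     1
TAI-1    terminal gain/loss/AOH  > 10 Mb                             2
TAI-LOH-1 terminal loss/AOH > 15 Mb (meets both TAI and LOH)         3
LOH-0    interstitial loss/AOH > 15 Mb, 0 chromosome breakpoints     1
LOH-1    interstitial loss/AOH > 15 Mb, 1 chromosome breakpoint      2
LOH-2    interstitial loss/AOH > 15 Mb, 2 chromosome breakpoints     3
LST-1    interstitial gain/loss/AOH > 10 Mb, 1 breakpoint            1
LST-2    interstitial event > 10 Mb, 2 breakpoints (incl. large      2
         inversions / intrachromosomal rearrangements)
LST-3    insertion > 10 Mb, 3 anticipated breakpoints                3
======== ======================================================== ======

Segments shorter than 3 Mb never score. On top of the copy-number base
class, each segment end whose position coincides (within a tolerance) with a
retained translocation junction earns a +1 rearrangement bonus — the
mechanism by which a platform that sees translocations outscores a
CNA-only platform on identical copy-number input. Retained interchromosomal
translocations not consumed as bonus evidence score 1 point each under the
LST signature. Chromosomes with more than 15 intrachromosomal fusion events
are flagged as possible chromothripsis and can optionally be excluded from
the totals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Sequence

from .filtering import FilterConfig, apply_mask_filter, filter_cnvs, filter_svs
from .genome import DEFAULT_STITCH_GAP, GenomeBuild
from .segmentation import (
    SegmentGeometry,
    aneuploidy_to_segments,
    chrom_sort_key,
    classify_geometry,
    stitch_segments,
)
from .variant_io import AneuploidyCall, CNVSegment, SVCall

MODE_OGM = "ogm"
MODE_CNA = "cna"

SIGNATURES = ("LOH", "TAI", "LST")


@dataclass(frozen=True)
class ScarClass:
    name: str
    weight: int
    signature: str


#: The fixed scar taxonomy; weights and signature membership are immutable.
#: TAI-LOH-1 meets both definitions and is accounted under TAI.
SCAR_CLASSES: dict[str, ScarClass] = {c.name: c for c in (
    ScarClass("TAI-0", 1, "TAI"),
    ScarClass("TAI-1", 2, "TAI"),
    ScarClass("TAI-LOH-1", 3, "TAI"),
    ScarClass("LOH-0", 1, "LOH"),
    ScarClass("LOH-1", 2, "LOH"),
    ScarClass("LOH-2", 3, "LOH"),
    ScarClass("LST-1", 1, "LST"),
    ScarClass("LST-2", 2, "LST"),
    ScarClass("LST-3", 3, "LST"),
)}

_LOSS_LIKE = frozenset({"loss", "aoh"})


@dataclass(frozen=True)
class ScoreConfig:
    """Size thresholds (bp) and behaviour switches for scar scoring.

    Sizes default to the published scheme: TAI floor 3 Mb, TAI-0/TAI-1 split
    10 Mb, LOH floor 15 Mb, LST floor 10 Mb, and a 3 Mb exclusion below which
    nothing scores. Comparisons are strict (> / <) as printed: a segment of
    exactly 10 Mb is neither TAI-0 nor TAI-1.
    """

    tai_min: int = 3_000_000
    tai0_max: int = 10_000_000
    loh_min: int = 15_000_000
    lst_min: int = 10_000_000
    lst_exclusion: int = 3_000_000
    breakpoint_match_tolerance: int = 500_000
    chromothripsis_threshold: int = 15
    exclude_chromothripsis: bool = False
    stitch_max_gap: int = DEFAULT_STITCH_GAP
    #: +1 per translocation-evidenced segment end (the worked-example rule).
    rearrangement_bonus: bool = True
    #: 1 LST point per retained interchromosomal translocation not consumed
    #: as bonus evidence.
    score_unmatched_translocations: bool = True

    def __post_init__(self) -> None:
        for name in ("tai_min", "tai0_max", "loh_min", "lst_min", "lst_exclusion",
                     "breakpoint_match_tolerance", "stitch_max_gap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.chromothripsis_threshold < 0:
            raise ValueError("chromothripsis_threshold must be >= 0")

    def merged(self, **overrides) -> "ScoreConfig":
        return replace(self, **overrides)


@dataclass(frozen=True)
class ScarCall:
    """One classified scar: class, location, evidence and points."""

    scar_class: ScarClass
    chrom: str
    interval: tuple[int, int]
    base_points: int
    bonus_points: int = 0
    evidence: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.bonus_points < 0:
            raise ValueError("bonus_points must be >= 0")

    @property
    def total_points(self) -> int:
        return self.base_points + self.bonus_points

    def to_dict(self) -> dict:
        return {
            "scar_class": self.scar_class.name,
            "signature": self.scar_class.signature,
            "chrom": self.chrom,
            "start": self.interval[0],
            "end": self.interval[1],
            "base_points": self.base_points,
            "bonus_points": self.bonus_points,
            "total_points": self.total_points,
            "evidence": list(self.evidence),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScarCall":
        return cls(
            scar_class=SCAR_CLASSES[d["scar_class"]],
            chrom=d["chrom"],
            interval=(d["start"], d["end"]),
            base_points=d["base_points"],
            bonus_points=d["bonus_points"],
            evidence=tuple(d["evidence"]),
        )


@dataclass(frozen=True)
class HRDResult:
    """Genome-wide scoring outcome.

    ``total`` sums scar points over non-excluded chromosomes and always
    equals both the per-chromosome and the per-signature sums.
    ``fusion_counts`` records intrachromosomal fusion events per chromosome;
    ``chromothripsis_chroms`` is the flagged subset, and ``excluded_chroms``
    the flagged chromosomes actually removed from the totals (only when
    exclusion is enabled).
    """

    scars: tuple[ScarCall, ...]
    per_chromosome: dict[str, int]
    signature_totals: dict[str, int]
    signature_counts: dict[str, int]
    total: int
    fusion_counts: dict[str, int]
    chromothripsis_chroms: frozenset[str]
    excluded_chroms: frozenset[str]
    mode: str

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "total": self.total,
            "per_chromosome": dict(sorted(self.per_chromosome.items(),
                                          key=lambda kv: chrom_sort_key(kv[0]))),
            "signature_totals": {s: self.signature_totals[s] for s in SIGNATURES},
            "signature_counts": {s: self.signature_counts[s] for s in SIGNATURES},
            "fusion_counts": dict(sorted(self.fusion_counts.items(),
                                         key=lambda kv: chrom_sort_key(kv[0]))),
            "chromothripsis_chroms": sorted(self.chromothripsis_chroms,
                                            key=chrom_sort_key),
            "excluded_chroms": sorted(self.excluded_chroms, key=chrom_sort_key),
            "scars": [s.to_dict() for s in self.scars],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "HRDResult":
        return cls(
            scars=tuple(ScarCall.from_dict(s) for s in d["scars"]),
            per_chromosome=dict(d["per_chromosome"]),
            signature_totals=dict(d["signature_totals"]),
            signature_counts=dict(d["signature_counts"]),
            total=d["total"],
            fusion_counts=dict(d["fusion_counts"]),
            chromothripsis_chroms=frozenset(d["chromothripsis_chroms"]),
            excluded_chroms=frozenset(d["excluded_chroms"]),
            mode=d["mode"],
        )


def classify_scar(segment: CNVSegment, geometry: SegmentGeometry,
                  config: ScoreConfig | None = None) -> ScarClass | None:
    """Assign a scar class to a segment, or None if it does not score.

    Decision order (first match wins) resolves the TAI/LOH overlap in favour
    of TAI-LOH-1 so nothing is double counted:

    1. whole chromosome -> None
    2. terminal loss/AOH > 15 Mb -> TAI-LOH-1
    3. terminal > 10 Mb -> TAI-1
    4. terminal in (3 Mb, 10 Mb) -> TAI-0
    5. interstitial loss/AOH > 15 Mb -> LOH-{0,1,2} by breakpoint count
    6. interstitial > 10 Mb with 1 breakpoint -> LST-1
    7. interstitial > 10 Mb with 2 breakpoints -> LST-2
    """
    config = config or ScoreConfig()
    length = segment.length
    if geometry.whole_chromosome:
        return None
    if length < config.lst_exclusion:
        return None
    loss_like = segment.state in _LOSS_LIKE
    if geometry.terminal:
        if loss_like and length > config.loh_min:
            return SCAR_CLASSES["TAI-LOH-1"]
        if length > config.tai0_max:
            return SCAR_CLASSES["TAI-1"]
        if config.tai_min < length < config.tai0_max:
            return SCAR_CLASSES["TAI-0"]
        return None
    if loss_like and length > config.loh_min:
        if geometry.cn_breakpoints not in (0, 1, 2):
            raise ValueError(
                f"cn_breakpoints {geometry.cn_breakpoints} outside 0-2 for LOH candidate")
        return SCAR_CLASSES[f"LOH-{geometry.cn_breakpoints}"]
    if length > config.lst_min and geometry.cn_breakpoints == 1:
        return SCAR_CLASSES["LST-1"]
    if length > config.lst_min and geometry.cn_breakpoints == 2:
        return SCAR_CLASSES["LST-2"]
    return None


def classify_sv_scar(sv: SVCall, config: ScoreConfig | None = None) -> ScarClass | None:
    """Scar class of a standalone (unconsumed) structural variant.

    Large intrachromosomal rearrangements (inversions, intrachromosomal
    fusions) spanning > 10 Mb are two-breakpoint state transitions (LST-2);
    insertions > 10 Mb imply three breakpoints (LST-3); interchromosomal
    translocations not tied to a copy-number segment score 1 point under LST
    (recorded with the LST-1 class).
    """
    config = config or ScoreConfig()
    if sv.sv_type == "inversion" and sv.span > config.lst_min:
        return SCAR_CLASSES["LST-2"]
    if sv.sv_type == "translocation" and sv.intrachromosomal and sv.span > config.lst_min:
        return SCAR_CLASSES["LST-2"]
    if sv.sv_type == "insertion" and sv.size > config.lst_min:
        return SCAR_CLASSES["LST-3"]
    if (sv.sv_type == "translocation" and not sv.intrachromosomal
            and config.score_unmatched_translocations):
        return SCAR_CLASSES["LST-1"]
    return None


def _match_ends(segment: CNVSegment, svs: Sequence[SVCall], tolerance: int,
                geometry: SegmentGeometry | None = None) -> list[tuple[str, str]]:
    """Greedy nearest assignment of translocation junctions to segment ends.

    Returns (end_label, sv_id) pairs; each SV supports at most one end and
    each end is matched at most once. When geometry is supplied, only ends
    that are genuine chromosome breakpoints are matchable (a telomeric or
    centromeric end is not a rearrangement junction).
    """
    ends: dict[str, int] = {"start": segment.start, "end": segment.end}
    if geometry is not None:
        if not geometry.start_is_break:
            ends.pop("start")
        if not geometry.end_is_break:
            ends.pop("end")
    candidates: list[tuple[int, str, str]] = []
    for sv in svs:
        if sv.sv_type != "translocation":
            continue
        for chrom, pos in ((sv.chrom_a, sv.pos_a), (sv.chrom_b, sv.pos_b)):
            if chrom != segment.chrom:
                continue
            for label, end_pos in ends.items():
                dist = abs(pos - end_pos)
                if dist <= tolerance:
                    candidates.append((dist, sv.id, label))
    candidates.sort()
    used_svs: set[str] = set()
    used_ends: set[str] = set()
    matches: list[tuple[str, str]] = []
    for _, sv_id, label in candidates:
        if sv_id in used_svs or label in used_ends:
            continue
        used_svs.add(sv_id)
        used_ends.add(label)
        matches.append((label, sv_id))
    return matches


def match_rearrangement_breakpoints(segment: CNVSegment, svs: Sequence[SVCall],
                                    tolerance: int = 500_000) -> int:
    """Number of segment ends (0-2) coinciding with a translocation junction."""
    return len(_match_ends(segment, svs, tolerance))


def score_segment(segment: CNVSegment, geometry: SegmentGeometry,
                  svs: Sequence[SVCall] = (),
                  config: ScoreConfig | None = None,
                  mode: str = MODE_OGM) -> ScarCall | None:
    """Combine the copy-number base class with the rearrangement bonus.

    In CNA-only mode the bonus is always 0. A segment with no base class but
    translocation-evidenced ends still scores (class recorded as the nearest
    LST class, points = bonus) — how a sub-threshold deletion flanked by
    translocations enters the total. Whole-chromosome segments and segments
    below the 3 Mb exclusion never score.
    """
    config = config or ScoreConfig()
    if geometry.whole_chromosome or segment.length < config.lst_exclusion:
        return None
    base_class = classify_scar(segment, geometry, config)
    base = base_class.weight if base_class else 0
    matches: list[tuple[str, str]] = []
    if mode == MODE_OGM and config.rearrangement_bonus and svs:
        matches = _match_ends(segment, svs, config.breakpoint_match_tolerance,
                              geometry)
    bonus = len(matches)
    if base == 0 and bonus == 0:
        return None
    if base_class is None:
        base_class = SCAR_CLASSES["LST-1"] if bonus == 1 else SCAR_CLASSES["LST-2"]
    evidence = tuple(filter(None, [segment.id])) + tuple(sv_id for _, sv_id in matches)
    return ScarCall(
        scar_class=base_class, chrom=segment.chrom, interval=segment.interval,
        base_points=base, bonus_points=bonus, evidence=evidence,
    )


def detect_chromothripsis(svs: Sequence[SVCall],
                          config: ScoreConfig | None = None
                          ) -> tuple[dict[str, int], frozenset[str]]:
    """Count intrachromosomal fusion events; flag counts above the threshold.

    Returns (counts per chromosome, flagged chromosomes); flagging is strict:
    exactly `threshold` events do not flag.
    """
    config = config or ScoreConfig()
    counts: dict[str, int] = {}
    for sv in svs:
        if sv.sv_type == "translocation" and sv.intrachromosomal:
            counts[sv.chrom_a] = counts.get(sv.chrom_a, 0) + 1
    flagged = frozenset(c for c, n in counts.items()
                        if n > config.chromothripsis_threshold)
    return counts, flagged


def compute_hrd(svs: Sequence[SVCall] = (),
                cnvs: Sequence[CNVSegment] = (),
                aneuploidies: Sequence[AneuploidyCall] = (),
                genome: GenomeBuild | None = None,
                filter_config: FilterConfig | None = None,
                score_config: ScoreConfig | None = None,
                mode: str = MODE_OGM) -> HRDResult:
    """Full pipeline: filter, stitch, classify, score, flag, aggregate.

    ``mode`` is ``"ogm"`` (all evidence) or ``"cna"`` (CNA-only: SV input is
    ignored entirely, emulating microarray / NGS-panel visibility; no
    rearrangement bonus, no SV scars, no chromothripsis flags).
    """
    if genome is None:
        from .genome import load_genome
        genome = load_genome("GRCh38")
    mode = mode.lower().replace("-only", "")
    if mode not in (MODE_OGM, MODE_CNA):
        raise ValueError(f"mode must be 'ogm' or 'cna', got {mode!r}")
    filter_config = filter_config or FilterConfig()
    score_config = score_config or ScoreConfig()

    if mode == MODE_CNA:
        svs_f: list[SVCall] = []
    else:
        svs_f = filter_svs(list(svs), filter_config)
        if filter_config.apply_mask_filter:
            svs_f = apply_mask_filter(svs_f, genome)
        for sv in svs_f:
            for chrom, pos in ((sv.chrom_a, sv.pos_a), (sv.chrom_b, sv.pos_b)):
                if chrom not in genome:
                    raise KeyError(f"SV {sv.id}: chromosome {chrom!r} not in build")
                if not genome[chrom].contains(pos):
                    raise ValueError(f"SV {sv.id}: position {pos} outside {chrom}")

    cnvs_f = filter_cnvs(list(cnvs), filter_config)
    stitched = stitch_segments(cnvs_f, score_config.stitch_max_gap)
    segments = stitched + aneuploidy_to_segments(list(aneuploidies), genome)
    segments.sort(key=lambda s: (chrom_sort_key(s.chrom), s.start, s.end, s.state))

    scars: list[ScarCall] = []
    consumed: set[str] = set()
    for seg in segments:
        geom = classify_geometry(seg, genome, score_config.stitch_max_gap)
        available = [sv for sv in svs_f if sv.id not in consumed]
        scar = score_segment(seg, geom, available, score_config, mode)
        if scar is not None:
            scars.append(scar)
            consumed.update(set(scar.evidence) - {seg.id})
    if mode == MODE_OGM:
        for sv in svs_f:
            if sv.id in consumed:
                continue
            cls = classify_sv_scar(sv, score_config)
            if cls is None:
                continue
            iv = (sv.pos_a, sv.pos_b) if sv.intrachromosomal else (sv.pos_a, sv.pos_a)
            scars.append(ScarCall(
                scar_class=cls, chrom=sv.chrom_a, interval=iv,
                base_points=cls.weight, bonus_points=0, evidence=(sv.id,),
            ))

    fusion_counts, flagged = detect_chromothripsis(svs_f, score_config)
    excluded = flagged if score_config.exclude_chromothripsis else frozenset()

    per_chromosome = {ann.name: 0 for ann in genome}
    signature_totals = {s: 0 for s in SIGNATURES}
    signature_counts = {s: 0 for s in SIGNATURES}
    total = 0
    for scar in scars:
        if scar.chrom in excluded:
            continue
        per_chromosome[scar.chrom] = per_chromosome.get(scar.chrom, 0) + scar.total_points
        signature_totals[scar.scar_class.signature] += scar.total_points
        signature_counts[scar.scar_class.signature] += 1
        total += scar.total_points

    scars.sort(key=lambda s: (chrom_sort_key(s.chrom), s.interval, s.scar_class.name))
    return HRDResult(
        scars=tuple(scars),
        per_chromosome=per_chromosome,
        signature_totals=signature_totals,
        signature_counts=signature_counts,
        total=total,
        fusion_counts=fusion_counts,
        chromothripsis_chroms=flagged,
        excluded_chroms=excluded,
        mode=MODE_OGM if mode == MODE_OGM else "cna-only",
    )
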