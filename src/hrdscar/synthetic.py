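"""Synthetic call-set generator with planted scars and known ground truth.

Every pipeline stage is testable offline: a :class:`CaseSpec` names the scars
to plant (by class), decoy counts and a fragmentation probability; the
generator emits SV/CNV/aneuploidy call sets that parse through
:mod:`hrdscar.variant_io` together with the ground-truth
:class:`~hrdscar.scoring.HRDResult` the pipeline must reproduce.

Placement rules keep the planted events independent: same-state intervals
stay more than the stitch distance apart, bonus-translocation partner
breakpoints land in the partner chromosome's centromere (never matchable to
a copy-number break end), and decoys are constructed to fail exactly one
retention rule, so removing them never changes the computed score.

All randomness flows through one seeded ``random.Random``; identical seeds
give byte-identical emitted files.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .genome import (
    ChromAnnotation,
    GenomeBuild,
    effective_centromeric_region,
    effective_terminal_region,
    load_genome,
)
from .scoring import SCAR_CLASSES, SIGNATURES, HRDResult, ScarCall
from .segmentation import chrom_sort_key
from .variant_io import AneuploidyCall, CNVSegment, SVCall

MB = 1_000_000

#: margin kept between planted intervals / sensitive positions (> stitch gap
#: and > breakpoint-match tolerance, with headroom).
_MARGIN = 1_000_000
_BODY_BUFFER = 2_000_000

#: pseudo-class for a sub-threshold interstitial deletion that scores only
#: through translocation-evidenced ends.
BONUS_ONLY = "BONUS"

_PLANTABLE = set(SCAR_CLASSES) | {BONUS_ONLY}


@dataclass(frozen=True)
class PlantedScar:
    """One scar to plant: class name, chromosome, optional fixed interval.

    ``n_bonus_ends`` adds that many passing translocations whose junctions
    coincide with the segment's breakpoint ends. ``via`` selects the evidence
    route for LST-2 ("cnv" segment or "inversion" SV) and "cnv" elsewhere.
    """

    scar_class: str
    chrom: str
    interval: tuple[int, int] | None = None
    n_bonus_ends: int = 0
    state: str | None = None
    via: str = "cnv"

    def __post_init__(self) -> None:
        if self.scar_class not in _PLANTABLE:
            raise ValueError(f"unknown scar class {self.scar_class!r}")
        if self.n_bonus_ends not in (0, 1, 2):
            raise ValueError("n_bonus_ends must be 0, 1 or 2")
        if self.via not in ("cnv", "inversion"):
            raise ValueError("via must be 'cnv' or 'inversion'")
        if self.via == "inversion" and self.scar_class != "LST-2":
            raise ValueError("via='inversion' only applies to LST-2")


@dataclass(frozen=True)
class DecoyCounts:
    """Counts of planted non-events, each failing exactly one retention rule."""

    sub_threshold: int = 0      # CNV segments below the 3 Mb exclusion
    low_confidence: int = 0     # SVs below their type's confidence threshold
    polymorphic: int = 0        # SVs present in the control database
    low_support: int = 0        # SVs with fewer than 5 spanning molecules


@dataclass(frozen=True)
class CaseSpec:
    """Recipe for one synthetic case."""

    planted_scars: tuple[PlantedScar, ...] = ()
    aneuploidies: tuple[tuple[str, str], ...] = ()  # (chrom, event)
    decoys: DecoyCounts = field(default_factory=DecoyCounts)
    fragmentation: float = 0.0
    seed: int = 0
    genome: GenomeBuild | str = "GRCh38"

    def resolve_genome(self) -> GenomeBuild:
        return self.genome if isinstance(self.genome, GenomeBuild) else load_genome(self.genome)


class _Placer:
    """Collision-free interval placement on one genome."""

    def __init__(self, genome: GenomeBuild, rng: random.Random):
        self.genome = genome
        self.rng = rng
        self.occupied: dict[str, list[tuple[int, int]]] = {}

    def _free(self, chrom: str, iv: tuple[int, int]) -> bool:
        for lo, hi in self.occupied.get(chrom, []):
            if iv[0] <= hi + _MARGIN and lo <= iv[1] + _MARGIN:
                return False
        return True

    def claim(self, chrom: str, iv: tuple[int, int]) -> None:
        self.occupied.setdefault(chrom, []).append(iv)

    def q_body(self, ann: ChromAnnotation) -> tuple[int, int]:
        cen = effective_centromeric_region(ann)
        q_term = effective_terminal_region(ann, "q")
        return (cen[1] + _BODY_BUFFER, q_term[0] - _BODY_BUFFER)

    def place_interstitial(self, ann: ChromAnnotation, length: int,
                           start_in_cen: bool = False) -> tuple[int, int]:
        lo, hi = self.q_body(ann)
        cen = effective_centromeric_region(ann)
        for _ in range(200):
            if start_in_cen:
                start = self.rng.randint(cen[0], cen[1])
            else:
                if hi - length + 1 < lo:
                    break
                start = self.rng.randint(lo, hi - length + 1)
            iv = (start, start + length - 1)
            if iv[1] > hi:
                continue
            if self._free(ann.name, iv):
                self.claim(ann.name, iv)
                return iv
        raise ValueError(
            f"planted scar geometrically impossible on chromosome {ann.name} "
            f"(length {length} bp does not fit)")

    def place_terminal_q(self, ann: ChromAnnotation, length: int) -> tuple[int, int]:
        iv = (ann.length - length + 1, ann.length)
        cen = effective_centromeric_region(ann)
        if iv[0] <= cen[1] + _BODY_BUFFER or not self._free(ann.name, iv):
            raise ValueError(
                f"planted scar geometrically impossible on chromosome {ann.name} "
                f"(terminal {length} bp reaches the centromere or collides)")
        self.claim(ann.name, iv)
        return iv


def _pick_state(rng: random.Random, loss_like: bool, max_len_cap: bool) -> str:
    if loss_like:
        return rng.choice(["loss", "aoh"])
    return rng.choice(["gain", "loss", "aoh"]) if not max_len_cap else "gain"


def generate_case(spec: CaseSpec) -> tuple[
        list[SVCall], list[CNVSegment], list[AneuploidyCall], HRDResult]:
    """Emit (svs, cnvs, aneuploidies, truth) for a case spec.

    ``truth`` is built from the planting plan alone — independently of the
    scoring pipeline — and states the OGM-mode result: total = sum of planted
    class weights plus bonus points; aneuploidies contribute zero.
    """
    genome = spec.resolve_genome()
    rng = random.Random(spec.seed)
    placer = _Placer(genome, rng)
    svs: list[SVCall] = []
    cnvs: list[CNVSegment] = []
    truth_scars: list[ScarCall] = []
    sv_n = 0

    def next_sv_id(kind: str) -> str:
        nonlocal sv_n
        sv_n += 1
        return f"sv_{kind}_{sv_n}"

    def partner_site(exclude: str) -> tuple[str, int]:
        names = [c.name for c in genome if c.name != exclude]
        ann = genome[rng.choice(names)] if names else genome[exclude]
        cen = effective_centromeric_region(ann)
        return ann.name, (cen[0] + cen[1]) // 2

    for k, planted in enumerate(spec.planted_scars):
        ann = genome[planted.chrom]
        cls_name = planted.scar_class
        seg_id = f"plant_{k + 1}"

        if cls_name == "LST-2" and planted.via == "inversion":
            if planted.n_bonus_ends:
                raise ValueError("bonus ends need a copy-number segment")
            size = rng.randint(int(10.5 * MB), 20 * MB)
            iv = placer.place_interstitial(ann, size)
            svs.append(SVCall(
                id=next_sv_id("inv"), chrom_a=ann.name, pos_a=iv[0],
                chrom_b=ann.name, pos_b=iv[1], sv_type="inversion", size=size,
                confidence=0.5, molecule_support=10, control_frequency=0.0))
            truth_scars.append(ScarCall(SCAR_CLASSES["LST-2"], ann.name, iv,
                                        base_points=2))
            continue
        if cls_name == "LST-3":
            if planted.n_bonus_ends:
                raise ValueError("bonus ends need a copy-number segment")
            size = rng.randint(int(10.5 * MB), 15 * MB)
            iv = placer.place_interstitial(ann, 1)
            svs.append(SVCall(
                id=next_sv_id("ins"), chrom_a=ann.name, pos_a=iv[0],
                chrom_b=ann.name, pos_b=iv[0], sv_type="insertion", size=size,
                confidence=0.5, molecule_support=10, control_frequency=0.0))
            truth_scars.append(ScarCall(SCAR_CLASSES["LST-3"], ann.name, iv,
                                        base_points=3))
            continue

        # copy-number routes
        if planted.interval is not None:
            iv = planted.interval
            placer.claim(ann.name, iv)
            state = planted.state or "loss"
            bonus_ends = _bonus_ends_for(cls_name, planted.n_bonus_ends, iv)
        else:
            iv, state, bonus_ends = _plan_cnv_scar(cls_name, planted, ann, placer, rng)
        length = iv[1] - iv[0] + 1
        cnvs.extend(_emit_segment(seg_id, ann.name, iv, state, spec.fragmentation, rng))

        bonus_ids = []
        for pos in bonus_ends:
            pb_chrom, pb_pos = partner_site(ann.name)
            sid = next_sv_id("bonus")
            svs.append(SVCall(
                id=sid, chrom_a=ann.name, pos_a=pos, chrom_b=pb_chrom,
                pos_b=pb_pos, sv_type="translocation", size=0,
                confidence=0.5, molecule_support=10, control_frequency=0.0))
            bonus_ids.append(sid)

        if cls_name == BONUS_ONLY:
            if not bonus_ids:
                continue  # nothing scores
            cls = SCAR_CLASSES["LST-1"] if len(bonus_ids) == 1 else SCAR_CLASSES["LST-2"]
            truth_scars.append(ScarCall(cls, ann.name, iv, base_points=0,
                                        bonus_points=len(bonus_ids),
                                        evidence=tuple(bonus_ids)))
        else:
            truth_scars.append(ScarCall(SCAR_CLASSES[cls_name], ann.name, iv,
                                        base_points=SCAR_CLASSES[cls_name].weight,
                                        bonus_points=len(bonus_ids),
                                        evidence=tuple(bonus_ids)))

    aneuploidies = [AneuploidyCall(chrom=c, event=e) for c, e in spec.aneuploidies]
    _emit_decoys(spec.decoys, genome, placer, rng, svs, cnvs, next_sv_id)

    truth = _assemble_truth(truth_scars, genome)
    return svs, cnvs, aneuploidies, truth


def _bonus_ends_for(cls_name: str, n: int, iv: tuple[int, int]) -> list[int]:
    if n == 0:
        return []
    avail = _break_ends(cls_name, iv, start_in_cen=cls_name in ("LOH-1", "LST-1"))
    if n > len(avail):
        raise ValueError(
            f"{cls_name} has only {len(avail)} breakpoint end(s); cannot plant {n} bonuses")
    return avail[:n]


def _break_ends(cls_name: str, iv: tuple[int, int], start_in_cen: bool) -> list[int]:
    if cls_name in ("TAI-0", "TAI-1", "TAI-LOH-1"):
        return [iv[0]]            # q-terminal: only the interior end breaks
    if start_in_cen:
        return [iv[1]]            # centromere-anchored: only the distal end
    return [iv[1], iv[0]]


def _plan_cnv_scar(cls_name, planted, ann, placer, rng):
    loss_like_classes = {"TAI-LOH-1", "LOH-0", "LOH-1", "LOH-2"}
    start_in_cen = cls_name in ("LOH-1", "LST-1")
    if cls_name == "TAI-0":
        state = planted.state or rng.choice(["gain", "loss", "aoh"])
        iv = placer.place_terminal_q(ann, rng.randint(4 * MB, 9 * MB))
    elif cls_name == "TAI-1":
        state = planted.state or rng.choice(["gain", "loss", "aoh"])
        hi = 20 * MB if state == "gain" else int(14.5 * MB)
        iv = placer.place_terminal_q(ann, rng.randint(int(10.5 * MB), hi))
    elif cls_name == "TAI-LOH-1":
        state = planted.state or rng.choice(["loss", "aoh"])
        iv = placer.place_terminal_q(ann, rng.randint(int(15.5 * MB), 28 * MB))
    elif cls_name in ("LOH-1", "LOH-2"):
        state = planted.state or rng.choice(["loss", "aoh"])
        iv = placer.place_interstitial(ann, rng.randint(int(15.5 * MB), 25 * MB),
                                       start_in_cen=start_in_cen)
    elif cls_name == "LOH-0":
        state = planted.state or rng.choice(["loss", "aoh"])
        cen = effective_centromeric_region(ann)
        width = cen[1] - cen[0] + 1
        if width < int(15.5 * MB):
            raise ValueError(
                f"planted scar geometrically impossible: LOH-0 needs an effective "
                f"centromeric region > 15 Mb; chromosome {ann.name} has {width} bp")
        length = rng.randint(int(15.5 * MB), width)
        iv = (cen[0], cen[0] + length - 1)
        placer.claim(ann.name, iv)
    elif cls_name in ("LST-1", "LST-2"):
        state = planted.state
        if state is None:
            state = rng.choice(["gain", "loss", "aoh"])
        hi = 20 * MB if state == "gain" else int(14.5 * MB)
        iv = placer.place_interstitial(ann, rng.randint(int(10.5 * MB), hi),
                                       start_in_cen=start_in_cen)
    elif cls_name == BONUS_ONLY:
        state = planted.state or "loss"
        iv = placer.place_interstitial(ann, rng.randint(int(3.5 * MB), 9 * MB))
    else:  # pragma: no cover - guarded by PlantedScar validation
        raise ValueError(f"cannot plant class {cls_name!r}")
    bonus_ends = [] if planted.n_bonus_ends == 0 else \
        _break_ends(cls_name, iv, start_in_cen)[: planted.n_bonus_ends]
    if planted.n_bonus_ends > len(_break_ends(cls_name, iv, start_in_cen)):
        raise ValueError(
            f"{cls_name} has too few breakpoint ends for {planted.n_bonus_ends} bonuses")
    return iv, state, bonus_ends


def _emit_segment(seg_id: str, chrom: str, iv: tuple[int, int], state: str,
                  fragmentation: float, rng: random.Random) -> list[CNVSegment]:
    """Emit the planted interval, optionally as stitchable fragments."""
    conf = 0.995
    if rng.random() >= fragmentation:
        return [CNVSegment(chrom=chrom, start=iv[0], end=iv[1], state=state,
                           confidence=conf, id=seg_id)]
    n_parts = rng.randint(2, 3)
    length = iv[1] - iv[0] + 1
    if length < n_parts * MB:
        n_parts = 2
    cuts = sorted(rng.sample(range(iv[0] + length // 4, iv[1] - length // 4),
                             n_parts - 1))
    bounds = [iv[0], *cuts, iv[1]]
    parts = []
    prev_start = bounds[0]
    for i in range(n_parts):
        end = bounds[i + 1] if i == n_parts - 1 else bounds[i + 1] - rng.randint(50_000, 400_000)
        end = max(end, prev_start + 1)
        parts.append(CNVSegment(chrom=chrom, start=prev_start, end=end, state=state,
                                confidence=conf, id=f"{seg_id}.{i + 1}"))
        prev_start = bounds[i + 1]
    return parts


def _emit_decoys(decoys, genome, placer, rng, svs, cnvs, next_sv_id) -> None:
    names = [c.name for c in genome]

    def rand_pos(ann):
        return rng.randint(1, ann.length)

    for _ in range(decoys.sub_threshold):
        ann = genome[rng.choice(names)]
        length = rng.randint(200_000, 2 * MB)
        try:
            iv = placer.place_interstitial(ann, length)
        except ValueError:
            continue
        cnvs.append(CNVSegment(chrom=ann.name, start=iv[0], end=iv[1],
                               state=rng.choice(["gain", "loss", "aoh"]),
                               confidence=0.995, id=next_sv_id("decoycnv")))
    for _ in range(decoys.low_confidence):
        ann = genome[rng.choice(names)]
        pos = rand_pos(ann)
        size = rng.randint(11 * MB, 15 * MB)
        svs.append(SVCall(
            id=next_sv_id("lowconf"), chrom_a=ann.name, pos_a=pos,
            chrom_b=ann.name, pos_b=min(pos + size - 1, ann.length),
            sv_type="inversion", size=size,
            confidence=0.01 - 1e-6 - rng.random() * 0.005,
            molecule_support=10, control_frequency=0.0))
    for _ in range(decoys.polymorphic):
        a = genome[rng.choice(names)]
        b = genome[rng.choice(names)]
        svs.append(SVCall(
            id=next_sv_id("polymorphic"), chrom_a=a.name, pos_a=rand_pos(a),
            chrom_b=b.name, pos_b=rand_pos(b), sv_type="translocation", size=0,
            confidence=0.5, molecule_support=10,
            control_frequency=round(rng.uniform(0.01, 0.3), 4)))
    for _ in range(decoys.low_support):
        a = genome[rng.choice(names)]
        b = genome[rng.choice(names)]
        svs.append(SVCall(
            id=next_sv_id("lowsupport"), chrom_a=a.name, pos_a=rand_pos(a),
            chrom_b=b.name, pos_b=rand_pos(b), sv_type="translocation", size=0,
            confidence=0.5, molecule_support=rng.randint(0, 4),
            control_frequency=0.0))


def _assemble_truth(truth_scars: list[ScarCall], genome: GenomeBuild) -> HRDResult:
    per_chromosome = {ann.name: 0 for ann in genome}
    signature_totals = {s: 0 for s in SIGNATURES}
    signature_counts = {s: 0 for s in SIGNATURES}
    total = 0
    for scar in truth_scars:
        per_chromosome[scar.chrom] += scar.total_points
        signature_totals[scar.scar_class.signature] += scar.total_points
        signature_counts[scar.scar_class.signature] += 1
        total += scar.total_points
    scars = sorted(truth_scars,
                   key=lambda s: (chrom_sort_key(s.chrom), s.interval, s.scar_class.name))
    return HRDResult(
        scars=tuple(scars), per_chromosome=per_chromosome,
        signature_totals=signature_totals, signature_counts=signature_counts,
        total=total, fusion_counts={}, chromothripsis_chroms=frozenset(),
        excluded_chroms=frozenset(), mode="ogm")


def degrade_to_cna_platform(svs, cnvs, aneuploidies=(), genome=None,
                            fracture: bool = False, seed: int = 0
                            ) -> list[CNVSegment]:
    """CNA-only arm of a platform comparison: drop SVs, keep copy number.

    With ``fracture`` enabled, whole-chromosome gains (trisomies) are emitted
    as two segmental gains — one centromere-anchored interstitial piece and
    one q-terminal piece — reproducing the false-positive mechanism by which
    mosaic trisomies under limited coverage masquerade as scoring segments.
    """
    del svs  # a CNA platform never sees them
    genome = genome or load_genome("GRCh38")
    rng = random.Random(seed)
    from .segmentation import aneuploidy_to_segments

    out: list[CNVSegment] = list(cnvs)
    whole = aneuploidy_to_segments(list(aneuploidies), genome)
    for seg in whole:
        ann = genome[seg.chrom]
        if not (fracture and seg.state == "gain"):
            out.append(seg)
            continue
        cen = effective_centromeric_region(ann)
        q_term = effective_terminal_region(ann, "q")
        q_len = q_term[0] - cen[1]
        a_start = (cen[0] + cen[1]) // 2
        a_end = cen[1] + int(q_len * rng.uniform(0.30, 0.40))
        b_start = q_term[0] - int(q_len * rng.uniform(0.25, 0.35))
        out.append(CNVSegment(chrom=ann.name, start=a_start, end=a_end, state="gain",
                              confidence=0.995, id=f"fracture_{ann.name}_a"))
        out.append(CNVSegment(chrom=ann.name, start=b_start, end=ann.length,
                              state="gain", confidence=0.995,
                              id=f"fracture_{ann.name}_b"))
    return out
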