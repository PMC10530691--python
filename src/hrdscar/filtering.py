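"""Variant-retention rules applied before any scoring.

Three independent SV filters (caller confidence per SV type, control-database
frequency, molecule support) and one CNV confidence filter. All comparisons
are inclusive at the printed thresholds. The difficult-to-map-region mask
filter exists but is off by default: masked regions still shape geometry, but
SVs inside them are kept.

Every removal is logged with the rule that caused it, so a filtered run is
auditable variant by variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .genome import GenomeBuild
from .variant_io import CNVSegment, SVCall, SV_TYPES

logger = logging.getLogger(__name__)

#: Platform-recommended minimum confidence per SV type.
DEFAULT_CONFIDENCE_THRESHOLDS: dict[str, float] = {
    "insertion": 0.0,
    "deletion": 0.0,
    "inversion": 0.01,
    "duplication": -1.0,
    "translocation": 0.0,
}


@dataclass(frozen=True)
class FilterConfig:
    """Retention thresholds; defaults are the platform-recommended values.

    ``max_control_frequency`` = 0 keeps only variants absent from the control
    database; ``min_molecule_support`` = 5 requires five spanning molecules;
    ``cnv_confidence`` = 0.99 is the copy-number confidence floor (set it to
    0 for the low-stringency reading). ``apply_mask_filter`` is off by
    default: SVs in difficult-to-map regions are retained.
    """

    confidence_thresholds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONFIDENCE_THRESHOLDS))
    cnv_confidence: float = 0.99
    max_control_frequency: float = 0.0
    min_molecule_support: int = 5
    apply_mask_filter: bool = False

    def __post_init__(self) -> None:
        missing = SV_TYPES - set(self.confidence_thresholds)
        if missing:
            raise ValueError(
                f"confidence_thresholds missing sv_type(s): {', '.join(sorted(missing))}")
        if not 0.0 <= self.max_control_frequency <= 1.0:
            raise ValueError("max_control_frequency must lie in [0, 1]")
        if self.min_molecule_support < 0:
            raise ValueError("min_molecule_support must be >= 0")

    def merged(self, **overrides) -> "FilterConfig":
        return replace(self, **overrides)


def filter_svs(svs: list[SVCall], config: FilterConfig | None = None) -> list[SVCall]:
    """Keep SVs passing confidence, control-frequency and support rules.

    Order is preserved; each removal is logged with exactly one rule name
    (the first that fails, checked in the order confidence, frequency,
    support).
    """
    config = config or FilterConfig()
    kept: list[SVCall] = []
    for sv in svs:
        try:
            threshold = config.confidence_thresholds[sv.sv_type]
        except KeyError:
            raise ValueError(f"no confidence threshold configured for {sv.sv_type!r}")
        if sv.confidence < threshold:
            logger.info("filtered %s: confidence %.4g < %.4g [confidence]",
                        sv.id, sv.confidence, threshold)
        elif sv.control_frequency > config.max_control_frequency:
            logger.info("filtered %s: control_frequency %.4g > %.4g [control_frequency]",
                        sv.id, sv.control_frequency, config.max_control_frequency)
        elif sv.molecule_support < config.min_molecule_support:
            logger.info("filtered %s: molecule_support %d < %d [molecule_support]",
                        sv.id, sv.molecule_support, config.min_molecule_support)
        else:
            kept.append(sv)
    return kept


def filter_cnvs(cnvs: list[CNVSegment],
                config: FilterConfig | None = None) -> list[CNVSegment]:
    """Keep CNV/AOH segments with confidence >= the floor.

    AOH segments whose caller reports no confidence pass (logged): no AOH
    confidence scale is defined upstream.
    """
    config = config or FilterConfig()
    kept: list[CNVSegment] = []
    for seg in cnvs:
        if seg.confidence is None:
            if seg.state == "aoh" or seg.from_aneuploidy:
                logger.info("kept %s %s:%d-%d without confidence [aoh_no_confidence]",
                            seg.state, seg.chrom, seg.start, seg.end)
                kept.append(seg)
            else:
                logger.info("filtered %s %s:%d-%d: no confidence [cnv_confidence]",
                            seg.state, seg.chrom, seg.start, seg.end)
        elif seg.confidence >= config.cnv_confidence:
            kept.append(seg)
        else:
            logger.info("filtered %s %s:%d-%d: confidence %.4g < %.4g [cnv_confidence]",
                        seg.state, seg.chrom, seg.start, seg.end,
                        seg.confidence, config.cnv_confidence)
    return kept


def apply_mask_filter(svs: list[SVCall], genome: GenomeBuild) -> list[SVCall]:
    """Drop SVs with any breakpoint inside a masked region (opt-in filter)."""
    kept: list[SVCall] = []
    for sv in svs:
        masked = False
        for chrom, pos in ((sv.chrom_a, sv.pos_a), (sv.chrom_b, sv.pos_b)):
            if chrom in genome:
                for lo, hi in genome[chrom].masked_regions:
                    if lo <= pos <= hi:
                        masked = True
                        break
            if masked:
                break
        if masked:
            logger.info("filtered %s: breakpoint in masked region [mask]", sv.id)
        else:
            kept.append(sv)
    return kept
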