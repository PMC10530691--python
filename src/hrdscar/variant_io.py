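"""Readers and writers for SV, CNV and aneuploidy call files.

Input dialects
--------------
* SV TSV (SMAP-like): columns ``id chrom_a pos_a chrom_b pos_b sv_type size
  confidence molecule_support control_frequency``. Real SMAP headers can be
  aliased onto these names via a column-mapping dict.
* CNV TSV: ``chrom start end state confidence`` plus optional ``copy_number``.
* Aneuploidy TSV: ``chrom event fraction``.
* SV VCF 4.2 with SVTYPE/END/SVLEN INFO keys; BND mate pairs collapse to one
  translocation record. Fields a VCF cannot carry (molecule support, control
  database frequency) default to values that pass every filter, with a logged
  warning, so VCF input remains usable but is auditable as weaker-filtered.

Readers are strict: every data row is either parsed or the read fails naming
the offending line; rows are never silently dropped.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genome import normalize_chrom

logger = logging.getLogger(__name__)

SV_TYPES = frozenset({"insertion", "deletion", "duplication", "inversion", "translocation"})
CNV_STATES = frozenset({"gain", "loss", "aoh"})
ANEUPLOIDY_EVENTS = frozenset({"gain", "loss", "whole_chrom_aoh"})

#: Defaults for VCF records lacking OGM-specific annotations: chosen to pass
#: every filter (support and frequency filters cannot act without evidence).
VCF_PASS_CONFIDENCE = 1.0
VCF_PASS_SUPPORT = 999_999
VCF_PASS_FREQUENCY = 0.0

SV_COLUMNS = (
    "id", "chrom_a", "pos_a", "chrom_b", "pos_b", "sv_type",
    "size", "confidence", "molecule_support", "control_frequency",
)
CNV_COLUMNS = ("chrom", "start", "end", "state", "confidence")
ANEUPLOIDY_COLUMNS = ("chrom", "event", "fraction")


@dataclass(frozen=True)
class SVCall:
    """One structural-variant record (paired breakpoints).

    ``size`` is 0 for interchromosomal translocations; ``confidence`` is the
    caller's score in [-1, 1]; ``molecule_support`` counts molecules spanning
    the breakpoints; ``control_frequency`` is the fraction of a control
    database carrying the variant.
    """

    id: str
    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    sv_type: str
    size: int
    confidence: float
    molecule_support: int
    control_frequency: float

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        if self.pos_a < 1 or self.pos_b < 1:
            raise ValueError(f"SV {self.id}: positions must be >= 1")
        if not -1.0 <= self.confidence <= 1.0:
            raise ValueError(f"SV {self.id}: confidence {self.confidence} outside [-1, 1]")
        if not 0.0 <= self.control_frequency <= 1.0:
            raise ValueError(
                f"SV {self.id}: control_frequency {self.control_frequency} outside [0, 1]"
            )
        if self.molecule_support < 0:
            raise ValueError(f"SV {self.id}: negative molecule_support")
        if self.intrachromosomal and self.pos_a > self.pos_b:
            # canonicalize breakpoint order rather than reject
            a, b = self.pos_a, self.pos_b
            object.__setattr__(self, "pos_a", b)
            object.__setattr__(self, "pos_b", a)

    @property
    def intrachromosomal(self) -> bool:
        return self.chrom_a == self.chrom_b

    @property
    def span(self) -> int:
        """Genomic extent: reported size, else breakpoint distance (0 interchrom)."""
        if self.size > 0:
            return self.size
        if self.intrachromosomal:
            return self.pos_b - self.pos_a + 1
        return 0


@dataclass(frozen=True)
class CNVSegment:
    """One copy-number or AOH interval (1-based closed).

    ``confidence`` may be None for AOH calls whose caller reports none; such
    segments are treated as passing the CNV confidence filter (logged).
    """

    chrom: str
    start: int
    end: int
    state: str
    confidence: float | None = None
    copy_number: float | None = None
    id: str = ""
    from_aneuploidy: bool = False

    def __post_init__(self) -> None:
        if self.state not in CNV_STATES:
            raise ValueError(f"unknown CNV state {self.state!r}")
        if self.start < 1 or self.start > self.end:
            raise ValueError(
                f"CNV {self.chrom}:{self.start}-{self.end}: requires 1 <= start <= end"
            )
        if self.confidence is not None and not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"CNV confidence {self.confidence} outside [0, 1]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class AneuploidyCall:
    """Whole-chromosome event: gain, loss or whole-chromosome AOH."""

    chrom: str
    event: str
    fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.event not in ANEUPLOIDY_EVENTS:
            raise ValueError(f"unknown aneuploidy event {self.event!r}")
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError(f"aneuploidy fraction {self.fraction} outside (0, 1]")


def _read_table(path: str | Path, required: Sequence[str],
                aliases: Mapping[str, str] | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", skip_blank_lines=True)
    if aliases:
        df = df.rename(columns=dict(aliases))
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df


def _row_error(path: str | Path, idx: int, exc: Exception) -> ValueError:
    # pandas row idx 0 is file line 2 (header is line 1)
    return ValueError(f"{path}, line {idx + 2}: {exc}")


def read_sv_table(path: str | Path,
                  aliases: Mapping[str, str] | None = None) -> list[SVCall]:
    """Parse the SMAP-like SV TSV; ``aliases`` maps foreign headers to ours."""
    df = _read_table(path, SV_COLUMNS, aliases)
    calls: list[SVCall] = []
    for idx, row in df.iterrows():
        try:
            calls.append(SVCall(
                id=str(row["id"]),
                chrom_a=normalize_chrom(row["chrom_a"]),
                pos_a=int(row["pos_a"]),
                chrom_b=normalize_chrom(row["chrom_b"]),
                pos_b=int(row["pos_b"]),
                sv_type=str(row["sv_type"]).strip().lower(),
                size=int(float(row["size"])),
                confidence=float(row["confidence"]),
                molecule_support=int(float(row["molecule_support"])),
                control_frequency=float(row["control_frequency"]),
            ))
        except (ValueError, TypeError) as exc:
            raise _row_error(path, idx, exc) from None
    return calls


def read_cnv_table(path: str | Path,
                   aliases: Mapping[str, str] | None = None) -> list[CNVSegment]:
    df = _read_table(path, CNV_COLUMNS, aliases)
    segments: list[CNVSegment] = []
    for idx, row in df.iterrows():
        try:
            conf_raw = row["confidence"]
            confidence = None if (pd.isna(conf_raw) or str(conf_raw).upper() in ("NA", ""))\
                else float(conf_raw)
            copy_number = None
            if "copy_number" in df.columns and not pd.isna(row["copy_number"]):
                copy_number = float(row["copy_number"])
            segments.append(CNVSegment(
                chrom=normalize_chrom(row["chrom"]),
                start=int(row["start"]),
                end=int(row["end"]),
                state=str(row["state"]).strip().lower(),
                confidence=confidence,
                copy_number=copy_number,
                id=f"cnv_{idx + 1}",
            ))
        except (ValueError, TypeError) as exc:
            raise _row_error(path, idx, exc) from None
    return segments


def read_aneuploidy_table(path: str | Path) -> list[AneuploidyCall]:
    df = _read_table(path, ANEUPLOIDY_COLUMNS)
    calls: list[AneuploidyCall] = []
    for idx, row in df.iterrows():
        try:
            calls.append(AneuploidyCall(
                chrom=normalize_chrom(row["chrom"]),
                event=str(row["event"]).strip().lower(),
                fraction=float(row["fraction"]),
            ))
        except (ValueError, TypeError) as exc:
            raise _row_error(path, idx, exc) from None
    return calls


_BND_ALT = re.compile(r"[\[\]](?P<chrom>[^:\[\]]+):(?P<pos>\d+)[\[\]]")

_VCF_SVTYPE = {
    "DEL": "deletion", "INS": "insertion", "DUP": "duplication",
    "INV": "inversion", "TRA": "translocation", "BND": "translocation",
}


def read_sv_vcf(path: str | Path) -> list[SVCall]:
    """Read SV records from a VCF; BND mate pairs become one translocation.

    Confidence, molecule support and control frequency are not part of the
    VCF SV spec; absent fields default to pass-through values so that every
    record survives filtering (warning logged once).
    """
    import pysam

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    calls: list[SVCall] = []
    pending_bnds: dict[str, "pysam.VariantRecord"] = {}
    defaulted = False

    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            svtype = rec.info.get("SVTYPE")
            if svtype is None:
                raise ValueError(f"{path}: record {rec.id or rec.pos} lacks SVTYPE")
            svtype = str(svtype).upper()
            if svtype not in _VCF_SVTYPE:
                raise ValueError(f"{path}: unsupported SVTYPE {svtype!r}")
            defaulted = True
            if svtype == "BND":
                mate_id = rec.info.get("MATEID")
                if isinstance(mate_id, tuple):
                    mate_id = mate_id[0]
                key = str(mate_id) if mate_id else None
                if rec.id and rec.id in pending_bnds:
                    raise ValueError(f"{path}: duplicate BND id {rec.id!r}")
                # try to resolve against a pending mate
                mate = None
                if key and key in pending_bnds:
                    mate = pending_bnds.pop(key)
                else:
                    m = _BND_ALT.search(str(rec.alts[0]))
                    if m is None:
                        raise ValueError(f"{path}: BND {rec.id!r} has unparsable ALT")
                    for pid, prec in list(pending_bnds.items()):
                        if (normalize_chrom(prec.chrom) == normalize_chrom(m.group("chrom"))
                                and prec.pos == int(m.group("pos"))):
                            mate = pending_bnds.pop(pid)
                            break
                if mate is None:
                    pending_bnds[rec.id or f"bnd{len(pending_bnds)}"] = rec
                    continue
                ca, pa = normalize_chrom(mate.chrom), mate.pos
                cb, pb = normalize_chrom(rec.chrom), rec.pos
                calls.append(SVCall(
                    id=f"{mate.id or 'bnd'}|{rec.id or 'bnd'}",
                    chrom_a=ca, pos_a=pa, chrom_b=cb, pos_b=pb,
                    sv_type="translocation",
                    size=0 if ca != cb else abs(pb - pa),
                    confidence=VCF_PASS_CONFIDENCE,
                    molecule_support=VCF_PASS_SUPPORT,
                    control_frequency=VCF_PASS_FREQUENCY,
                ))
                continue
            end = rec.stop  # pysam resolves INFO/END
            svlen = rec.info.get("SVLEN")
            if isinstance(svlen, tuple):
                svlen = svlen[0]
            size = abs(int(svlen)) if svlen is not None else max(end - rec.pos, 1)
            calls.append(SVCall(
                id=rec.id or f"{svtype.lower()}_{rec.chrom}_{rec.pos}",
                chrom_a=normalize_chrom(rec.chrom), pos_a=rec.pos,
                chrom_b=normalize_chrom(rec.chrom), pos_b=max(end, rec.pos),
                sv_type=_VCF_SVTYPE[svtype],
                size=size,
                confidence=VCF_PASS_CONFIDENCE,
                molecule_support=VCF_PASS_SUPPORT,
                control_frequency=VCF_PASS_FREQUENCY,
            ))
    if pending_bnds:
        ids = ", ".join(sorted(str(k) for k in pending_bnds))
        raise ValueError(f"{path}: BND record(s) without mate: {ids}")
    if defaulted:
        logger.warning(
            "%s: VCF input carries no molecule support / control frequency; "
            "records default to pass-through values and skip those filters", path)
    return calls


def write_sv_table(svs: Iterable[SVCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SV_COLUMNS) + "\n")
        for sv in svs:
            fh.write("\t".join(str(x) for x in (
                sv.id, sv.chrom_a, sv.pos_a, sv.chrom_b, sv.pos_b, sv.sv_type,
                sv.size, sv.confidence, sv.molecule_support, sv.control_frequency,
            )) + "\n")


def write_cnv_table(cnvs: Iterable[CNVSegment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CNV_COLUMNS + ("copy_number",)) + "\n")
        for seg in cnvs:
            conf = "NA" if seg.confidence is None else seg.confidence
            cn = "" if seg.copy_number is None else seg.copy_number
            fh.write(f"{seg.chrom}\t{seg.start}\t{seg.end}\t{seg.state}\t{conf}\t{cn}\n")


def write_aneuploidy_table(calls: Iterable[AneuploidyCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ANEUPLOIDY_COLUMNS) + "\n")
        for c in calls:
            fh.write(f"{c.chrom}\t{c.event}\t{c.fraction}\n")


def write_result(result, path: str | Path, format: str = "json") -> None:
    """Serialize an HRDResult; the JSON form round-trips via ``read_result``."""
    from .scoring import HRDResult  # local import to avoid a cycle

    if not isinstance(result, HRDResult):
        raise TypeError("write_result expects an HRDResult")
    path = Path(path)
    if format == "json":
        path.write_text(result.to_json() + "\n")
    elif format == "tsv":
        lines = ["\t".join((
            "scar_class", "signature", "chrom", "start", "end",
            "base_points", "bonus_points", "total_points", "evidence"))]
        for scar in result.scars:
            lines.append("\t".join(str(x) for x in (
                scar.scar_class.name, scar.scar_class.signature, scar.chrom,
                scar.interval[0], scar.interval[1], scar.base_points,
                scar.bonus_points, scar.total_points, ",".join(scar.evidence))))
        lines.append("")
        lines.append(f"# mode\t{result.mode}")
        for sig in ("LOH", "TAI", "LST"):
            lines.append(f"# {sig}\t{result.signature_totals[sig]}")
        lines.append(f"# total\t{result.total}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown output format {format!r}")


def read_result(path: str | Path):
    """Load an HRDResult back from its JSON form."""
    from .scoring import HRDResult

    with open(path) as fh:
        return HRDResult.from_dict(json.load(fh))
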