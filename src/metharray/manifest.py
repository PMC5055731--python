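"""Probe data model, manifest I/O and platform-to-platform comparison.

Internal coordinates are 0-based half-open throughout the package; the
manifest CSV dialect carries 1-based target positions (``MAPINFO``) which
are converted at the I/O boundary.

Footprint geometry
------------------
``target_pos`` is the 0-based plus-strand position of the C of the target
CpG. For a plus-design probe the 50-base footprint is ``[p, p+50)``; for a
minus-design probe it is the mirrored interval ``[p-48, p+2)``. The probe
body excludes the target CpG dinucleotide for Type I probes (48 bases) and
the single-base-extension base for Type II probes (49 bases). The SBE base
sits immediately upstream of the CpG on the hybridised strand for Type I,
and on the target cytosine itself for Type II.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import CoordinateError, FormatError, IntegrityError

__all__ = [
    "ProbeRecord",
    "Manifest",
    "PlatformComparison",
    "compute_footprint",
    "read_manifest",
    "write_manifest",
    "footprints_to_bed",
    "compare_platforms",
    "odds_ratio",
]

PROBE_LEN = 50

MANIFEST_COLUMNS = [
    "IlmnID",
    "Infinium_Design_Type",
    "CHR",
    "MAPINFO",
    "Strand",
    "AlleleA_ProbeSeq",
    "AlleleB_ProbeSeq",
]

_SEQ_ALPHABET = frozenset("ACGTR")
_STRAND_ALIASES = {"+": "+", "-": "-", "F": "+", "R": "-"}


def compute_footprint(
    infinium_type: str, target_pos: int, design_strand: str
) -> tuple[tuple[int, int], int, tuple[tuple[int, int], ...]]:
    """Footprint interval, SBE position and body interval(s) for a probe.

    Returns ``(footprint, sbe_pos, body_intervals)`` with the footprint as
    a 0-based half-open plus-strand interval of length 50. Body lengths are
    48 for Type I and 49 for Type II by construction.
    """
    p = int(target_pos)
    if design_strand == "+":
        footprint = (p, p + PROBE_LEN)
        if infinium_type == "I":
            sbe, body = p - 1, ((p + 2, p + PROBE_LEN),)
        else:
            sbe, body = p, ((p + 1, p + PROBE_LEN),)
    elif design_strand == "-":
        footprint = (p + 2 - PROBE_LEN, p + 2)
        if infinium_type == "I":
            sbe, body = p + 2, ((p + 2 - PROBE_LEN, p),)
        else:
            sbe, body = p + 1, ((p + 2 - PROBE_LEN, p + 1),)
    else:
        raise FormatError(f"unknown design strand {design_strand!r}")
    return footprint, sbe, body


@dataclass
class ProbeRecord:
    """One array probe with its derived genomic geometry."""

    probe_id: str
    infinium_type: str
    chrom: str
    target_pos: int
    design_strand: str
    sequence_u: str
    sequence_m: str | None = None
    footprint: tuple[int, int] = field(init=False)
    sbe_pos: int = field(init=False)
    body_intervals: tuple[tuple[int, int], ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.infinium_type not in ("I", "II"):
            raise FormatError(
                f"probe {self.probe_id}: bad Infinium type {self.infinium_type!r}"
            )
        if len(self.sequence_u) != PROBE_LEN:
            raise FormatError(
                f"probe {self.probe_id}: sequence length {len(self.sequence_u)} != {PROBE_LEN}"
            )
        if not set(self.sequence_u) <= _SEQ_ALPHABET:
            raise FormatError(f"probe {self.probe_id}: invalid sequence characters")
        if self.infinium_type == "I":
            if self.sequence_m is None:
                raise FormatError(
                    f"probe {self.probe_id}: Type I requires both allele sequences"
                )
            if len(self.sequence_m) != PROBE_LEN:
                raise FormatError(
                    f"probe {self.probe_id}: allele B sequence length != {PROBE_LEN}"
                )
            if "R" in self.sequence_u or "R" in self.sequence_m:
                raise FormatError(
                    f"probe {self.probe_id}: Type I sequences must not contain R"
                )
        elif self.sequence_m is not None:
            raise FormatError(
                f"probe {self.probe_id}: Type II must not carry an allele B sequence"
            )
        self.footprint, self.sbe_pos, self.body_intervals = compute_footprint(
            self.infinium_type, self.target_pos, self.design_strand
        )

    @property
    def probe_class(self) -> str:
        """``cg`` (CpG), ``ch`` (CNG) or ``rs`` (SNP) by id prefix."""
        return self.probe_id[:2]

    @property
    def body_length(self) -> int:
        return sum(e - s for s, e in self.body_intervals)

    def check_bounds(self, chrom_length: int) -> None:
        s, e = self.footprint
        lo = min(s, self.sbe_pos)
        hi = max(e, self.sbe_pos + 1)
        if lo < 0 or hi > chrom_length:
            raise CoordinateError(
                f"probe {self.probe_id}: footprint [{s}, {e}) with SBE at "
                f"{self.sbe_pos} exceeds chromosome bounds [0, {chrom_length})"
            )


@dataclass
class Manifest:
    platform_name: str
    probes: dict[str, ProbeRecord]

    def __len__(self) -> int:
        return len(self.probes)

    @property
    def counts(self) -> dict[str, int]:
        c = {"cg": 0, "ch": 0, "rs": 0, "other": 0, "I": 0, "II": 0}
        for p in self.probes.values():
            c[p.probe_class if p.probe_class in ("cg", "ch", "rs") else "other"] += 1
            c[p.infinium_type] += 1
        return c

    def ids(self, probe_class: str | None = "cg") -> set[str]:
        if probe_class is None:
            return set(self.probes)
        return {pid for pid, p in self.probes.items() if p.probe_class == probe_class}


@dataclass
class PlatformComparison:
    platform_a: str
    platform_b: str
    shared_ids: set[str]
    unique_to_a: set[str]
    unique_to_b: set[str]
    odds_ratio: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    table: tuple[int, int, int, int] | None = None


def read_manifest(path, platform_name: str) -> Manifest:
    """Read a manifest CSV into a :class:`Manifest`.

    ``MAPINFO`` (1-based position of the target C) is converted to the
    0-based ``target_pos``. Malformed rows raise :class:`FormatError` with
    the offending 1-based data row number; duplicate probe ids raise
    :class:`IntegrityError`.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise FormatError(f"manifest missing required columns: {missing}")
    has_b = "AlleleB_ProbeSeq" in df.columns
    probes: dict[str, ProbeRecord] = {}
    problems: list[str] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        d = row._asdict()
        pid = d["IlmnID"].strip()
        try:
            strand = _STRAND_ALIASES.get(d["Strand"].strip())
            if strand is None:
                raise FormatError(f"bad strand {d['Strand']!r}")
            mapinfo = int(d["MAPINFO"])
            seq_b = d["AlleleB_ProbeSeq"].strip() if has_b else ""
            probe = ProbeRecord(
                probe_id=pid,
                infinium_type=d["Infinium_Design_Type"].strip(),
                chrom=d["CHR"].strip(),
                target_pos=mapinfo - 1,
                design_strand=strand,
                sequence_u=d["AlleleA_ProbeSeq"].strip().upper(),
                sequence_m=seq_b.upper() or None,
            )
        except (FormatError, ValueError) as exc:
            problems.append(f"row {row_no}: {exc}")
            continue
        if pid in probes:
            raise IntegrityError(f"duplicate probe id {pid!r} at row {row_no}")
        probes[pid] = probe
    if problems:
        raise FormatError(
            "rejected {} manifest row(s): {}".format(len(problems), "; ".join(problems))
        )
    return Manifest(platform_name=platform_name, probes=probes)


def write_manifest(manifest: Manifest, path) -> None:
    rows = []
    for p in manifest.probes.values():
        rows.append(
            {
                "IlmnID": p.probe_id,
                "Infinium_Design_Type": p.infinium_type,
                "CHR": p.chrom,
                "MAPINFO": p.target_pos + 1,
                "Strand": p.design_strand,
                "AlleleA_ProbeSeq": p.sequence_u,
                "AlleleB_ProbeSeq": p.sequence_m or "",
            }
        )
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def footprints_to_bed(manifest: Manifest) -> pd.DataFrame:
    """Probe footprints as a BED-shaped frame (0-based half-open)."""
    rows = [
        {
            "chrom": p.chrom,
            "start": p.footprint[0],
            "end": p.footprint[1],
            "name": p.probe_id,
            "score": 0,
            "strand": p.design_strand,
        }
        for p in manifest.probes.values()
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    ).sort_values(["chrom", "start"], kind="mergesort", ignore_index=True)


def odds_ratio(
    table: tuple[int, int, int, int], z: float = 1.959963984540054
) -> tuple[float, float, float]:
    """Odds ratio and Wald CI for a 2x2 table ``(a, b, c, d)``.

    The table is read as rows (exposed, unexposed) x columns (event,
    no-event): ``OR = (a*d)/(b*c)``. When any cell is zero the
    Haldane-Anscombe 0.5 correction is applied to every cell.
    """
    a, b, c, d = (float(x) for x in table)
    if min(a, b, c, d) < 0:
        raise IntegrityError("2x2 table cells must be non-negative")
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return math.exp(log_or), math.exp(log_or - z * se), math.exp(log_or + z * se)


def compare_platforms(
    a: Manifest,
    b: Manifest,
    property_map: Mapping[str, bool] | None = None,
    probe_class: str | None = "cg",
) -> PlatformComparison:
    """Set comparison of two manifests with an optional enrichment test.

    When ``property_map`` (probe id -> boolean property, over platform
    ``a``'s probes) is supplied, the odds ratio for the property among
    probes of ``a`` excluded from ``b`` versus retained on ``b`` is
    computed from the 2x2 table with a Wald 95 % CI on the log scale.
    """
    if not a.probes or not b.probes:
        raise IntegrityError("cannot compare an empty manifest")
    ids_a = a.ids(probe_class)
    ids_b = b.ids(probe_class)
    shared = ids_a & ids_b
    unique_a = ids_a - ids_b
    unique_b = ids_b - ids_a
    comp = PlatformComparison(
        platform_a=a.platform_name,
        platform_b=b.platform_name,
        shared_ids=shared,
        unique_to_a=unique_a,
        unique_to_b=unique_b,
    )
    if property_map is not None:
        excl_prop = sum(1 for pid in unique_a if property_map.get(pid, False))
        ret_prop = sum(1 for pid in shared if property_map.get(pid, False))
        table = (
            excl_prop,
            len(unique_a) - excl_prop,
            ret_prop,
            len(shared) - ret_prop,
        )
        comp.table = table
        comp.odds_ratio, comp.ci_low, comp.ci_high = odds_ratio(table)
    return comp
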