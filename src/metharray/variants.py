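"""Classification of genetic variants overlapping array probes.

Variants are filtered on the maximum minor allele frequency (folded over
all alternate alleles) and each overlapping (probe, variant) pair is
assigned exactly one category with precedence
``TARGET_CPG > SBE > PROBE_BODY``. The target zone spans both bases of the
CpG dinucleotide; the SBE category applies to Type I probes only (for
Type II probes the extension base is the target cytosine itself).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import FormatError, IntegrityError
from .manifest import Manifest, ProbeRecord

__all__ = [
    "VariantRecord",
    "ProbeVariantOverlap",
    "TARGET_CPG",
    "SBE",
    "PROBE_BODY",
    "fold_maf",
    "read_variants",
    "classify_overlaps",
    "summarize_overlaps",
]

TARGET_CPG = "TARGET_CPG"
SBE = "SBE"
PROBE_BODY = "PROBE_BODY"


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int  # 0-based
    ref: str
    alts: tuple[str, ...]
    allele_frequencies: tuple[float, ...]
    variant_class: str  # SNP | INDEL
    maf: float

    @property
    def span(self) -> tuple[int, int]:
        """Plus-strand footprint of the variant, ``[pos, pos + len(ref))``."""
        return (self.pos, self.pos + len(self.ref))


@dataclass(frozen=True)
class ProbeVariantOverlap:
    probe_id: str
    variant: VariantRecord
    category: str
    offset_from_3prime: int


def fold_maf(allele_frequencies: Iterable[float]) -> float:
    """Maximum over alternate alleles of ``min(AF, 1 - AF)``."""
    folded = [min(float(af), 1.0 - float(af)) for af in allele_frequencies]
    if not folded:
        raise ValueError("no allele frequencies to fold")
    return max(folded)


def _variant_class(ref: str, alts: Sequence[str]) -> str:
    if len(ref) == 1 and all(len(a) == 1 for a in alts):
        return "SNP"
    return "INDEL"


def read_variants(vcf_path, maf_threshold: float = 0.05) -> list[VariantRecord]:
    """Read a VCF, keeping records with folded MAF strictly above threshold.

    AF is taken from the INFO field, falling back to AC/AN; records lacking
    both raise :class:`FormatError` naming the offending record.
    """
    import pysam

    out: list[VariantRecord] = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            alts = tuple(rec.alts or ())
            if not alts:
                continue
            info = rec.info
            if "AF" in info:
                afs = info["AF"]
                # round away float32 noise introduced by the VCF parser
                afs = tuple(
                    round(float(x), 6)
                    for x in (afs if isinstance(afs, tuple) else (afs,))
                )
            elif "AC" in info and "AN" in info:
                an = float(info["AN"])
                acs = info["AC"]
                acs = acs if isinstance(acs, tuple) else (acs,)
                if an <= 0:
                    raise FormatError(
                        f"variant {rec.chrom}:{rec.pos} has AN={an}"
                    )
                afs = tuple(float(ac) / an for ac in acs)
            else:
                raise FormatError(
                    f"variant {rec.chrom}:{rec.pos} lacks AF and AC/AN fields"
                )
            if len(afs) != len(alts):
                raise FormatError(
                    f"variant {rec.chrom}:{rec.pos}: {len(afs)} AF values for "
                    f"{len(alts)} alternate alleles"
                )
            maf = fold_maf(afs)
            if maf <= maf_threshold:
                continue
            out.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.start,
                    ref=rec.ref,
                    alts=alts,
                    allele_frequencies=afs,
                    variant_class=_variant_class(rec.ref, alts),
                    maf=maf,
                )
            )
    return out


def _zones(probe: ProbeRecord):
    """(target, sbe, body, extent) plus-strand intervals for one probe."""
    p = probe.target_pos
    target = (p, p + 2)
    sbe = (probe.sbe_pos, probe.sbe_pos + 1) if probe.infinium_type == "I" else None
    body = probe.body_intervals
    pieces = [target, *body] + ([sbe] if sbe else [])
    extent = (min(s for s, _ in pieces), max(e for _, e in pieces))
    return target, sbe, body, extent


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and a[1] > b[0]


def classify_overlaps(
    manifest: Manifest,
    variants: Iterable[VariantRecord],
    include_noncpg: bool = False,
) -> list[ProbeVariantOverlap]:
    """Emit every overlapping (probe, variant) pair once, with its category.

    INDELs are classified by any overlapping base, taking the highest-
    precedence zone they touch. Output is sorted by (probe id, chrom, pos)
    and thus invariant to input record order.
    """
    by_chrom: dict[str, list[ProbeRecord]] = defaultdict(list)
    for probe in manifest.probes.values():
        if not include_noncpg and probe.probe_class != "cg":
            continue
        by_chrom[probe.chrom].append(probe)
    index: dict[str, tuple[np.ndarray, list[ProbeRecord]]] = {}
    max_extent = 0
    for chrom, probes in by_chrom.items():
        probes.sort(key=lambda p: _zones(p)[3][0])
        starts = np.array([_zones(p)[3][0] for p in probes], dtype=np.int64)
        index[chrom] = (starts, probes)
        if probes:
            max_extent = max(
                max_extent, max(_zones(p)[3][1] - _zones(p)[3][0] for p in probes)
            )
    out: list[ProbeVariantOverlap] = []
    for var in variants:
        entry = index.get(var.chrom)
        if entry is None:
            continue
        starts, probes = entry
        vs, ve = var.span
        lo = int(np.searchsorted(starts, vs - max_extent, side="left"))
        hi = int(np.searchsorted(starts, ve, side="left"))
        for probe in probes[lo:hi]:
            target, sbe, body, extent = _zones(probe)
            if not _overlaps((vs, ve), extent):
                continue
            if _overlaps((vs, ve), target):
                category = TARGET_CPG
            elif sbe is not None and _overlaps((vs, ve), sbe):
                category = SBE
            elif any(_overlaps((vs, ve), iv) for iv in body):
                category = PROBE_BODY
            else:
                continue
            anchor = (
                probe.target_pos
                if probe.design_strand == "+"
                else probe.target_pos + 1
            )
            ov_start = max(vs, extent[0])
            out.append(
                ProbeVariantOverlap(
                    probe_id=probe.probe_id,
                    variant=var,
                    category=category,
                    offset_from_3prime=abs(ov_start - anchor),
                )
            )
    out.sort(key=lambda o: (o.probe_id, o.variant.chrom, o.variant.pos))
    return out


def summarize_overlaps(overlaps: Iterable[ProbeVariantOverlap]) -> dict[str, int]:
    """Distinct probes per category (a probe counts once per category)."""
    probes_by_cat: dict[str, set[str]] = {TARGET_CPG: set(), SBE: set(), PROBE_BODY: set()}
    for ov in overlaps:
        probes_by_cat[ov.category].add(ov.probe_id)
    return {cat: len(pids) for cat, pids in probes_by_cat.items()}


def overlaps_to_frame(overlaps: Iterable[ProbeVariantOverlap]):
    """Tabular export mirroring the annotated-probe list shape."""
    import pandas as pd

    rows = [
        {
            "probe_id": ov.probe_id,
            "category": ov.category,
            "chrom": ov.variant.chrom,
            "pos": ov.variant.pos,
            "ref": ov.variant.ref,
            "alt": ",".join(ov.variant.alts),
            "maf": ov.variant.maf,
            "variant_class": ov.variant.variant_class,
            "offset_from_3prime": ov.offset_from_3prime,
        }
        for ov in overlaps
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "probe_id",
            "category",
            "chrom",
            "pos",
            "ref",
            "alt",
            "maf",
            "variant_class",
            "offset_from_3prime",
        ],
    )
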