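"""Genomic context assignment and regulatory coverage accounting.

Derived tracks follow fixed definitions: promoters are +/-2 kb around every
transcript TSS; gene bodies are transcripts +/-2 kb minus promoters;
intergenic is the complement, so the three gene contexts partition each
chromosome. CpG island shores are the 2 kb island flanks minus any island
overlap. Region coverage counts probes by their target CpG position
(point-in-interval), stratified as >=1 / >=2 / >=3 overlaps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _intervals as iv
from .errors import IntegrityError
from .manifest import Manifest

__all__ = [
    "AnnotationBundle",
    "CoverageSummary",
    "build_annotation",
    "assign_probe_categories",
    "coverage_stratified",
    "split_specific_common",
]

PROMOTER_FLANK = 2000
BODY_FLANK = 2000
SHORE_FLANK = 2000

ChromIntervals = dict[str, list[tuple[int, int]]]


@dataclass
class AnnotationBundle:
    chrom_lengths: dict[str, int]
    promoters: ChromIntervals
    gene_bodies: ChromIntervals
    intergenic: ChromIntervals
    islands: ChromIntervals
    shores: ChromIntervals
    dhs_proximal: pd.DataFrame
    dhs_distal: pd.DataFrame
    enhancers: pd.DataFrame
    dhs_presence: pd.DataFrame | None = None


@dataclass
class CoverageSummary:
    """Stratified coverage of one region catalog by a set of positions."""

    catalog: str
    n_regions: int
    n_ge1: int
    n_ge2: int
    n_ge3: int
    per_region_counts: pd.Series = field(repr=False, default=None)

    @property
    def fraction_ge1(self) -> float:
        return self.n_ge1 / self.n_regions if self.n_regions else 0.0


def _frame_to_intervals(df: pd.DataFrame) -> ChromIntervals:
    out: ChromIntervals = {}
    for chrom, grp in df.groupby("chrom", sort=True):
        out[chrom] = [(int(s), int(e)) for s, e in zip(grp["start"], grp["end"])]
    return out


def _clip_track(track: ChromIntervals, lengths: Mapping[str, int], name: str) -> ChromIntervals:
    out: ChromIntervals = {}
    for chrom, ivs in track.items():
        length = lengths[chrom]
        clipped = iv.clip(ivs, length)
        if any(s < 0 or e > length for s, e in ivs):
            warnings.warn(
                f"{name}: regions on {chrom} extend beyond [0, {length}); clipped",
                stacklevel=3,
            )
        out[chrom] = clipped
    return out


def build_annotation(
    genes: pd.DataFrame,
    islands: pd.DataFrame,
    dhs_proximal: pd.DataFrame,
    dhs_distal: pd.DataFrame,
    enhancers: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    dhs_presence: pd.DataFrame | None = None,
) -> AnnotationBundle:
    """Assemble derived tracks from gene models and BED-shaped catalogs.

    ``genes`` needs columns chrom/start/end/strand (one row per transcript);
    catalogs need chrom/start/end and, for the DHS/enhancer frames, a
    ``region_id`` column (one is synthesised when absent).
    """
    lengths = {c: int(l) for c, l in dict(chrom_lengths).items()}
    promoters: ChromIntervals = {c: [] for c in lengths}
    bodies_raw: ChromIntervals = {c: [] for c in lengths}
    for row in genes.itertuples(index=False):
        tss = int(row.start) if row.strand == "+" else int(row.end) - 1
        promoters.setdefault(row.chrom, []).append(
            (tss - PROMOTER_FLANK, tss + PROMOTER_FLANK)
        )
        bodies_raw.setdefault(row.chrom, []).append(
            (int(row.start) - BODY_FLANK, int(row.end) + BODY_FLANK)
        )
    promoters = _clip_track(promoters, lengths, "promoters")
    bodies_raw = _clip_track(bodies_raw, lengths, "gene bodies")
    gene_bodies: ChromIntervals = {}
    intergenic: ChromIntervals = {}
    for chrom, length in lengths.items():
        prom = iv.merge(promoters.get(chrom, []))
        body = iv.subtract(bodies_raw.get(chrom, []), prom)
        promoters[chrom] = prom
        gene_bodies[chrom] = body
        intergenic[chrom] = iv.complement(prom + body, length)
    island_track = _clip_track(_frame_to_intervals(islands), lengths, "islands")
    shores: ChromIntervals = {}
    for chrom, length in lengths.items():
        isl = iv.merge(island_track.get(chrom, []))
        island_track[chrom] = isl
        flanks = [(s - SHORE_FLANK, e + SHORE_FLANK) for s, e in isl]
        shores[chrom] = iv.subtract(iv.clip(flanks, length), isl)

    def _with_ids(df: pd.DataFrame, prefix: str) -> pd.DataFrame:
        df = df.copy()
        if "region_id" not in df.columns:
            df["region_id"] = [f"{prefix}{i}" for i in range(len(df))]
        return df.reset_index(drop=True)

    return AnnotationBundle(
        chrom_lengths=lengths,
        promoters=promoters,
        gene_bodies=gene_bodies,
        intergenic=intergenic,
        islands=island_track,
        shores=shores,
        dhs_proximal=_with_ids(dhs_proximal, "dhsP"),
        dhs_distal=_with_ids(dhs_distal, "dhsD"),
        enhancers=_with_ids(enhancers, "enh"),
        dhs_presence=dhs_presence,
    )


def assign_probe_categories(
    manifest: Manifest,
    bundle: AnnotationBundle,
    include_noncpg: bool = False,
) -> pd.DataFrame:
    """Per-probe gene, CpG and regulatory context.

    Gene context precedence is promoter > gene body > intergenic; CpG
    context is island > shore > open sea. Regulatory memberships (DHS
    proximal/distal, enhancer) are independent booleans. Probes on unknown
    chromosomes are reported as ``unassigned`` with a warning.
    """
    records = []
    reg_catalogs = {
        "dhs_proximal": bundle.dhs_proximal,
        "dhs_distal": bundle.dhs_distal,
        "enhancer": bundle.enhancers,
    }
    reg_tracks = {
        name: _frame_to_intervals(df) for name, df in reg_catalogs.items()
    }
    unknown = set()
    for pid in sorted(manifest.probes):
        probe = manifest.probes[pid]
        if not include_noncpg and probe.probe_class != "cg":
            continue
        chrom, pos = probe.chrom, probe.target_pos
        if chrom not in bundle.chrom_lengths:
            unknown.add(chrom)
            records.append(
                {
                    "probe_id": pid,
                    "gene_context": "unassigned",
                    "cpg_context": "unassigned",
                    **{name: False for name in reg_catalogs},
                }
            )
            continue
        point = np.array([pos])
        if iv.points_in(bundle.promoters.get(chrom, []), point)[0]:
            gene_context = "promoter"
        elif iv.points_in(bundle.gene_bodies.get(chrom, []), point)[0]:
            gene_context = "gene_body"
        else:
            gene_context = "intergenic"
        if iv.points_in(bundle.islands.get(chrom, []), point)[0]:
            cpg_context = "island"
        elif iv.points_in(bundle.shores.get(chrom, []), point)[0]:
            cpg_context = "shore"
        else:
            cpg_context = "open_sea"
        row = {"probe_id": pid, "gene_context": gene_context, "cpg_context": cpg_context}
        for name, track in reg_tracks.items():
            row[name] = bool(iv.points_in(track.get(chrom, []), point)[0])
        records.append(row)
    if unknown:
        warnings.warn(
            f"probes on chromosomes absent from the annotation bundle: {sorted(unknown)}"
        )
    return pd.DataFrame.from_records(records).set_index("probe_id")


def _positions_by_chrom(positions) -> dict[str, np.ndarray]:
    if isinstance(positions, pd.DataFrame):
        col = "pos" if "pos" in positions.columns else "start"
        return {
            chrom: grp[col].to_numpy(dtype=np.int64)
            for chrom, grp in positions.groupby("chrom")
        }
    return {c: np.asarray(v, dtype=np.int64) for c, v in dict(positions).items()}


def coverage_stratified(
    regions: pd.DataFrame, positions, catalog: str = ""
) -> CoverageSummary:
    """Count positions per region and stratify regions at >=1/>=2/>=3.

    ``positions`` is a frame with chrom/pos (or chrom/start) columns or a
    chrom -> array mapping; overlap is a point-in-interval test.
    """
    by_chrom = _positions_by_chrom(positions)
    counts = np.zeros(len(regions), dtype=np.int64)
    for chrom, grp in regions.groupby("chrom"):
        pos = by_chrom.get(chrom)
        if pos is None or len(pos) == 0:
            continue
        ivs = list(zip(grp["start"].astype(int), grp["end"].astype(int)))
        counts[grp.index.to_numpy()] = iv.count_points_per_interval(ivs, pos)
    ids = (
        regions["region_id"]
        if "region_id" in regions.columns
        else pd.RangeIndex(len(regions))
    )
    series = pd.Series(counts, index=ids, name="n_overlaps")
    return CoverageSummary(
        catalog=catalog,
        n_regions=len(regions),
        n_ge1=int((counts >= 1).sum()),
        n_ge2=int((counts >= 2).sum()),
        n_ge3=int((counts >= 3).sum()),
        per_region_counts=series,
    )


def split_specific_common(
    dhs_presence: pd.DataFrame,
) -> tuple[pd.Index, pd.Index]:
    """Split a boolean region x cell-type presence matrix at the median.

    Occurrence is the row sum; regions strictly below the median occurrence
    are ``specific``, the rest (ties included) are ``common``. The two sets
    partition the catalog.
    """
    if dhs_presence.size == 0:
        raise IntegrityError("empty DHS presence matrix")
    occurrence = dhs_presence.astype(bool).sum(axis=1)
    median = float(np.median(occurrence.to_numpy()))
    specific = occurrence.index[occurrence < median]
    common = occurrence.index[occurrence >= median]
    return specific, common
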