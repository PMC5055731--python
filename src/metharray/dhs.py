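"""Region-level methylation at distal regulatory elements and platform concordance.

WGBS region methylation is the pooled ratio of methylated to total CpG
observations over the region; array region methylation is the unweighted
mean beta of passing probes. Regions are classified low (beta <= 0.3),
mid, or high (beta > 0.6), compared across platforms, and large
disagreements are typed as probe positioning versus technical artifact
using the WGBS readout at the probe's own target CpG.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import _intervals as iv
from .errors import IntegrityError
from .manifest import Manifest, odds_ratio

__all__ = [
    "PROBE_POSITIONING",
    "TECHNICAL_ARTIFACT",
    "UNCLASSIFIED",
    "methylation_status",
    "select_regions",
    "region_methylation_wgbs",
    "region_methylation_array",
    "methylation_vs_dhs",
    "DhsAssociation",
    "ConcordanceResult",
    "cross_platform_concordance",
    "classify_disagreements",
]

LOW_THRESHOLD = 0.3
HIGH_THRESHOLD = 0.6

PROBE_POSITIONING = "PROBE_POSITIONING"
TECHNICAL_ARTIFACT = "TECHNICAL_ARTIFACT"
UNCLASSIFIED = "UNCLASSIFIED"


def methylation_status(beta: float) -> str:
    if beta <= LOW_THRESHOLD:
        return "low"
    if beta > HIGH_THRESHOLD:
        return "high"
    return "mid"


@dataclass
class DhsAssociation:
    log_odds_ratio: float
    ci_low: float
    ci_high: float
    table: tuple[int, int, int, int]
    haldane_corrected: bool


@dataclass
class ConcordanceResult:
    n_common_regions: int
    spearman_rho: float
    agreement_fractions: dict[float, float]
    disagreements: pd.DataFrame


def select_regions(
    regions: pd.DataFrame, cpg_positions: pd.DataFrame, min_cpgs: int = 3
) -> pd.DataFrame:
    """Keep regions overlapping at least ``min_cpgs`` genomic CpG sites.

    Adds an ``n_cpgs`` column; overlap is a point test on the CpG C
    position.
    """
    regions = regions.reset_index(drop=True)
    counts = np.zeros(len(regions), dtype=np.int64)
    pos_by_chrom = {
        chrom: grp["start"].to_numpy(dtype=np.int64)
        for chrom, grp in cpg_positions.groupby("chrom")
    }
    for chrom, grp in regions.groupby("chrom"):
        pos = pos_by_chrom.get(chrom)
        if pos is None:
            continue
        ivs = list(zip(grp["start"].astype(int), grp["end"].astype(int)))
        counts[grp.index.to_numpy()] = iv.count_points_per_interval(ivs, pos)
    out = regions.copy()
    out["n_cpgs"] = counts
    return out[out["n_cpgs"] >= min_cpgs].reset_index(drop=True)


def _region_frame(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(
        rows,
        columns=[
            "region_id",
            "platform",
            "mean_beta",
            "n_used",
            "total_coverage",
            "status",
            "informative",
        ],
    )
    return df.set_index("region_id")


def region_methylation_wgbs(
    counts: pd.DataFrame,
    regions: pd.DataFrame,
    min_region_cov: int = 50,
) -> pd.DataFrame:
    """Pooled-ratio region methylation from per-CpG count tables.

    ``counts`` columns: chrom, start, end, methylated, total. The region
    mean is sum(methylated)/sum(total) over CpGs in the region — the
    coverage-weighted mean of per-CpG ratios. A region is informative when
    the pooled total is at least ``min_region_cov``; regions with zero
    observations never divide by zero.
    """
    rows = []
    counts_by_chrom = {c: g for c, g in counts.groupby("chrom")}
    for reg in regions.itertuples(index=False):
        grp = counts_by_chrom.get(reg.chrom)
        if grp is None:
            meth_sum = total_sum = 0
            n_used = 0
        else:
            inside = (grp["start"] >= reg.start) & (grp["start"] < reg.end)
            meth_sum = int(grp.loc[inside, "methylated"].sum())
            total_sum = int(grp.loc[inside, "total"].sum())
            n_used = int((grp.loc[inside, "total"] > 0).sum())
        mean_beta = meth_sum / total_sum if total_sum > 0 else np.nan
        rows.append(
            {
                "region_id": reg.region_id,
                "platform": "WGBS",
                "mean_beta": mean_beta,
                "n_used": n_used,
                "total_coverage": total_sum,
                "status": methylation_status(mean_beta) if total_sum else "na",
                "informative": total_sum >= min_region_cov,
            }
        )
    return _region_frame(rows)


def region_methylation_array(
    beta: pd.Series,
    manifest: Manifest,
    regions: pd.DataFrame,
    detection_p: pd.Series | None = None,
    detection_thresh: float = 0.01,
) -> pd.DataFrame:
    """Unweighted mean beta of passing probes per region (one sample).

    A probe passes when its detection p-value is below the threshold (all
    probes pass when no detection p is supplied); a region is informative
    with at least one passing probe inside it (target CpG position test).
    """
    passing = beta.dropna()
    if detection_p is not None:
        passing = passing[detection_p.reindex(passing.index) < detection_thresh]
    probe_pos: dict[str, list[tuple[int, str]]] = {}
    for pid in passing.index:
        probe = manifest.probes.get(pid)
        if probe is None:
            continue
        probe_pos.setdefault(probe.chrom, []).append((probe.target_pos, pid))
    for chrom in probe_pos:
        probe_pos[chrom].sort()
    rows = []
    for reg in regions.itertuples(index=False):
        entries = probe_pos.get(reg.chrom, [])
        positions = np.array([p for p, _ in entries], dtype=np.int64)
        lo = int(np.searchsorted(positions, reg.start, side="left"))
        hi = int(np.searchsorted(positions, reg.end, side="left"))
        pids = [pid for _, pid in entries[lo:hi]]
        vals = passing.loc[pids]
        mean_beta = float(vals.mean()) if len(pids) else np.nan
        rows.append(
            {
                "region_id": reg.region_id,
                "platform": "array",
                "mean_beta": mean_beta,
                "n_used": len(pids),
                "total_coverage": len(pids),
                "status": methylation_status(mean_beta) if len(pids) else "na",
                "informative": len(pids) >= 1,
            }
        )
    return _region_frame(rows)


def methylation_vs_dhs(
    region_meth: pd.DataFrame, presence: pd.Series
) -> DhsAssociation:
    """Log odds ratio of low methylation versus DHS presence.

    Built from informative regions only: rows are (DHS present, absent),
    columns are (low, not low). A zero margin triggers the Haldane
    correction, which is flagged in the result.
    """
    info = region_meth[region_meth["informative"]]
    pres = presence.reindex(info.index).fillna(False).astype(bool)
    low = info["status"] == "low"
    a = int((pres & low).sum())
    b = int((pres & ~low).sum())
    c = int((~pres & low).sum())
    d = int((~pres & ~low).sum())
    or_, lo, hi = odds_ratio((a, b, c, d))
    return DhsAssociation(
        log_odds_ratio=float(np.log(or_)),
        ci_low=float(np.log(lo)),
        ci_high=float(np.log(hi)),
        table=(a, b, c, d),
        haldane_corrected=min(a, b, c, d) == 0,
    )


def cross_platform_concordance(
    wgbs_regions: pd.DataFrame,
    array_regions: pd.DataFrame,
    agreement_bands: tuple[float, ...] = (0.20, 0.10, 0.05),
) -> ConcordanceResult:
    """Compare region methylation between WGBS and array readouts.

    Works on regions informative on both platforms; reports Spearman rho,
    nested agreement fractions at the given absolute-difference bands, and
    the list of large disagreements (low on one platform, high on the
    other).
    """
    common = wgbs_regions.index[wgbs_regions["informative"]].intersection(
        array_regions.index[array_regions["informative"]]
    )
    if len(common) < 3:
        raise IntegrityError(
            f"only {len(common)} regions informative on both platforms (need >= 3)"
        )
    w = wgbs_regions.loc[common, "mean_beta"].astype(float)
    a = array_regions.loc[common, "mean_beta"].astype(float)
    diff = (w - a).abs()
    rho = float(stats.spearmanr(w, a).statistic)
    fractions = {
        band: float((diff < band).mean()) for band in sorted(agreement_bands, reverse=True)
    }
    w_status = wgbs_regions.loc[common, "status"]
    a_status = array_regions.loc[common, "status"]
    flagged = ((w_status == "low") & (a_status == "high")) | (
        (w_status == "high") & (a_status == "low")
    )
    disagreements = pd.DataFrame(
        {
            "beta_wgbs": w[flagged],
            "beta_array": a[flagged],
            "status_wgbs": w_status[flagged],
            "status_array": a_status[flagged],
        }
    )
    return ConcordanceResult(
        n_common_regions=int(len(common)),
        spearman_rho=rho,
        agreement_fractions=fractions,
        disagreements=disagreements,
    )


def classify_disagreements(
    disagreements: pd.DataFrame,
    counts: pd.DataFrame,
    manifest: Manifest,
    regions: pd.DataFrame,
    tau: float = 0.2,
    min_single_cov: int = 10,
) -> pd.Series:
    """Type each disagreement region.

    ``PROBE_POSITIONING``: the array value agrees (within ``tau``) with the
    WGBS beta at the probe's own target CpG while differing from the WGBS
    region mean by at least ``tau`` — the probe reads its CpG faithfully
    but the CpG does not represent the region. Otherwise
    ``TECHNICAL_ARTIFACT``. Regions whose probe CpGs lack
    ``min_single_cov`` WGBS coverage stay ``UNCLASSIFIED``.
    """
    cpg_lookup = {
        (row.chrom, int(row.start)): (int(row.methylated), int(row.total))
        for row in counts.itertuples(index=False)
    }
    region_rows = {r.region_id: r for r in regions.itertuples(index=False)}
    probes_by_chrom: dict[str, list] = {}
    for probe in manifest.probes.values():
        probes_by_chrom.setdefault(probe.chrom, []).append(probe)
    out = {}
    for region_id, row in disagreements.iterrows():
        reg = region_rows.get(region_id)
        if reg is None:
            out[region_id] = UNCLASSIFIED
            continue
        meth = total = 0
        for probe in probes_by_chrom.get(reg.chrom, []):
            if reg.start <= probe.target_pos < reg.end:
                entry = cpg_lookup.get((probe.chrom, probe.target_pos))
                if entry and entry[1] >= min_single_cov:
                    meth += entry[0]
                    total += entry[1]
        if total == 0:
            out[region_id] = UNCLASSIFIED
            continue
        own_beta = meth / total
        array_beta = float(row["beta_array"])
        region_beta = float(row["beta_wgbs"])
        if abs(array_beta - own_beta) < tau and abs(array_beta - region_beta) >= tau:
            out[region_id] = PROBE_POSITIONING
        else:
            out[region_id] = TECHNICAL_ARTIFACT
    return pd.Series(out, name="disagreement_type", dtype=object)
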