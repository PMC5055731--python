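"""Synthetic inputs with known ground truth for every pipeline stage.

A small multi-chromosome genome is generated with CpG-dense islands,
CpG-sparse regulatory regions and planted near-identical duplications; an
array manifest, a variant call set, two-group intensity matrices and WGBS
count tables are then derived from it. Every planted feature (off-target
duplication, variant-in-probe, differential probe, discordant region) is
recorded in a :class:`GroundTruth` object so downstream modules can be
tested by parameter recovery.

Each generator draws from its own RNG stream, derived from the master seed
by a stable label, so adding a generator never perturbs the others and a
fixed seed yields byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .crossreact import build_converted_genomes, revcomp
from .errors import ConfigurationError
from .manifest import Manifest, ProbeRecord, compute_footprint, write_manifest
from .variants import VariantRecord, _variant_class, fold_maf

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticDataset",
    "simulate_genome",
    "simulate_all",
    "simulate_wgbs_counts",
    "draw_intensities",
    "write_dataset",
    "write_fasta",
    "write_vcf",
]

_COMPL = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

PROBE_LEN = 50
_DUP_CPG_OFFSET = 0  # duplicated windows carry their CpG at the window start
_FEATURE_PAD = 2100  # clearance on each side of a placed feature within its block


def _rng(seed: int, label: str) -> np.random.Generator:
    digest = hashlib.sha256(label.encode()).digest()
    sub = int.from_bytes(digest[:8], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), sub]))


@dataclass
class SimulationConfig:
    """Knobs for the synthetic dataset. Defaults run the suite in seconds."""

    seed: int = 1
    genome_length_bp: int = 400_000
    n_chromosomes: int = 2
    n_islands: int = 4
    island_cpg_rate: float = 0.25
    background_cpg_rate: float = 0.02
    n_duplicated_segments: int = 2
    duplication_identity: float = 47 / 50
    n_probes_type1: int = 40
    n_probes_type2: int = 160
    n_variants: int = 60
    maf_distribution: tuple[float, float] = (0.08, 0.45)
    n_samples_per_group: int = 3
    delta_beta_true: tuple[float, ...] = (0.3, -0.3, 0.3, 0.25, -0.25, 0.2, -0.2, 0.3)
    wgbs_mean_coverage: int = 30
    n_negative_controls: int = 200
    # layout details
    island_length: int = 400
    n_genes: int = 6
    n_dhs_distal: int = 12
    n_dhs_proximal: int = 4
    n_enhancers: int = 6
    dhs_length: int = 300
    dhs_cpg_rate: float = 0.08
    n_cell_types: int = 8
    n_fault_positioning: int = 1
    n_fault_artifact: int = 1
    # intensity model
    intensity_mean: float = 12_000.0
    intensity_sd: float = 1_500.0
    background_mean: float = 100.0
    background_sd: float = 30.0

    def __post_init__(self) -> None:
        for name in ("island_cpg_rate", "background_cpg_rate", "dhs_cpg_rate",
                     "duplication_identity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        matches = self.duplication_identity * PROBE_LEN
        if abs(matches - round(matches)) > 1e-9:
            raise ConfigurationError(
                f"duplication_identity*{PROBE_LEN} must be an integer, got {matches}"
            )
        if self.genome_length_bp < 10_000:
            raise ConfigurationError("genome_length_bp must be >= 10,000")
        if self.n_dhs_proximal > self.n_genes:
            raise ConfigurationError("n_dhs_proximal cannot exceed n_genes")
        lo, hi = self.maf_distribution
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_distribution bounds must satisfy 0 < lo <= hi <= 0.5")


@dataclass
class Layout:
    chrom_lengths: dict[str, int]
    islands: list[tuple[str, int, int]]
    dup_pairs: list[dict]  # {chrom_src, src, chrom_copy, copy, n_matches}
    dhs_distal: list[tuple[str, int, int]]
    dhs_proximal: list[tuple[str, int, int]]
    genes: list[tuple[str, int, int, str]]
    enhancers: list[tuple[str, int, int]]


@dataclass
class GroundTruth:
    planted_crossreactive_probe_ids: list[str]
    planted_variant_overlaps: dict[str, str]
    planted_variant_pairs: list[tuple[str, str, int, str]]
    true_beta: pd.DataFrame
    true_dmp_ids: list[str]
    dhs_regions: pd.DataFrame
    dhs_fault_types: dict[str, str]
    cpg_true_m: pd.Series
    duplication_pairs: list[dict]


@dataclass
class IntensityData:
    meth: pd.DataFrame
    unmeth: pd.DataFrame
    control_meth: pd.DataFrame
    control_unmeth: pd.DataFrame
    groups: pd.Series


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genome: dict[str, str]
    cpg_positions: pd.DataFrame
    layout: Layout
    manifest: Manifest
    variants: list[VariantRecord]
    intensities: IntensityData
    wgbs: pd.DataFrame
    annotation: dict[str, pd.DataFrame]
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# genome


def _plan_layout(config: SimulationConfig, rng: np.random.Generator) -> Layout:
    n_chrom = config.n_chromosomes
    chrom_len = config.genome_length_bp // n_chrom
    chroms = [f"chr{i + 1}" for i in range(n_chrom)]
    features: list[tuple[str, int]] = []
    features += [("island", config.island_length)] * config.n_islands
    for _ in range(config.n_duplicated_segments):
        features.append(("dup_src", PROBE_LEN))
        features.append(("dup_copy", PROBE_LEN))
    features += [("dhs_distal", config.dhs_length)] * config.n_dhs_distal
    features += [("gene", 4000)] * config.n_genes
    features += [("enhancer", 300)] * config.n_enhancers

    per_chrom: dict[str, list[tuple[str, int]]] = {c: [] for c in chroms}
    for i, feat in enumerate(features):
        per_chrom[chroms[i % n_chrom]].append(feat)

    placed: dict[str, list[tuple[str, int, int]]] = {name: [] for name in (
        "island", "dup_src", "dup_copy", "dhs_distal", "gene", "enhancer")}
    margin = 200
    for chrom in chroms:
        feats = per_chrom[chrom]
        if not feats:
            continue
        block_len = (chrom_len - 2 * margin) // len(feats)
        order = list(rng.permutation(len(feats)))
        for block_idx, feat_idx in enumerate(order):
            kind, flen = feats[feat_idx]
            slack = block_len - flen - 2 * _FEATURE_PAD
            if slack < 1:
                raise ConfigurationError(
                    f"layout infeasible on {chrom}: block {block_len} bp cannot "
                    f"hold a {flen} bp feature with {_FEATURE_PAD} bp clearance"
                )
            start = margin + block_idx * block_len + _FEATURE_PAD + int(rng.integers(slack))
            placed[kind].append((chrom, start, start + flen))

    dup_pairs = []
    n_matches = int(round(config.duplication_identity * PROBE_LEN))
    for (cs, ss, _), (cc, cs2, _) in zip(placed["dup_src"], placed["dup_copy"]):
        dup_pairs.append(
            {"chrom_src": cs, "src": ss, "chrom_copy": cc, "copy": cs2,
             "n_matches": n_matches}
        )
    genes = []
    strands = ["+", "-"]
    for i, (chrom, s, e) in enumerate(placed["gene"]):
        genes.append((chrom, s, e, strands[i % 2]))
    # proximal DHS inside promoter windows: just downstream of each TSS
    dhs_proximal = []
    for chrom, s, e, strand in genes[: config.n_dhs_proximal]:
        tss = s if strand == "+" else e - 1
        start = tss + 200 if strand == "+" else tss - 200 - config.dhs_length
        dhs_proximal.append((chrom, start, start + config.dhs_length))
    return Layout(
        chrom_lengths={c: chrom_len for c in chroms},
        islands=sorted(placed["island"]),
        dup_pairs=dup_pairs,
        dhs_distal=sorted(placed["dhs_distal"]),
        dhs_proximal=sorted(dhs_proximal),
        genes=sorted(genes),
        enhancers=sorted(placed["enhancer"]),
    )


def _generate_chromosome(
    length: int,
    rate: np.ndarray,
    rng: np.random.Generator,
) -> list[str]:
    """Random sequence with position-dependent CpG planting.

    Non-planted letters avoid forming accidental CG dinucleotides so CpG
    density is controlled by ``rate`` alone.
    """
    chars: list[str] = []
    bases = "ACGT"
    no_g = "ACT"
    i = 0
    draws = rng.random(length)
    while i < length - 1:
        if draws[i] < rate[i]:
            chars.append("C")
            chars.append("G")
            i += 2
            continue
        pool = no_g if (chars and chars[-1] == "C") else bases
        chars.append(pool[int(rng.integers(len(pool)))])
        i += 1
    while len(chars) < length:
        pool = no_g if (chars and chars[-1] == "C") else bases
        chars.append(pool[int(rng.integers(len(pool)))])
    return chars


def _craft_dup_window(rng: np.random.Generator) -> list[str]:
    """A 50-mer with one CpG at the window start and no other CG."""
    chars = ["C", "G"]
    bases = "ACGT"
    no_g = "ACT"
    while len(chars) < PROBE_LEN - 1:
        pool = no_g if chars[-1] == "C" else bases
        chars.append(pool[int(rng.integers(len(pool)))])
    chars.append("T" if chars[-1] != "C" else "A")
    return chars


def _mutate_copy(window: list[str], n_mismatches: int, rng: np.random.Generator) -> list[str]:
    """Swap A<->G at positions that are conversion-neutral mismatches."""
    out = list(window)
    eligible = [
        i
        for i in range(3, PROBE_LEN - 1)
        if out[i] in "AG" and out[i - 1] != "C"
    ]
    if len(eligible) < n_mismatches:
        raise ConfigurationError("not enough mutable positions in duplicated window")
    picks = rng.choice(len(eligible), size=n_mismatches, replace=False)
    for k in sorted(int(p) for p in picks):
        i = eligible[k]
        out[i] = "G" if out[i] == "A" else "A"
    return out


def _scan_cpgs(genome: Mapping[str, str]) -> pd.DataFrame:
    rows = []
    for chrom in sorted(genome):
        seq = genome[chrom]
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        starts = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
        for s in starts:
            rows.append((chrom, int(s), int(s) + 2))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def simulate_genome(
    config: SimulationConfig,
) -> tuple[dict[str, str], pd.DataFrame, Layout]:
    """Generate the genome, its CpG position table and the feature layout."""
    layout = _plan_layout(config, _rng(config.seed, "layout"))
    genome: dict[str, str] = {}
    for chrom, length in layout.chrom_lengths.items():
        rate = np.full(length, config.background_cpg_rate)
        for c, s, e in layout.islands:
            if c == chrom:
                rate[s:e] = config.island_cpg_rate
        for c, s, e in layout.dhs_distal + layout.dhs_proximal:
            if c == chrom:
                rate[s:e] = config.dhs_cpg_rate
        chars = _generate_chromosome(length, rate, _rng(config.seed, f"genome:{chrom}"))
        genome[chrom] = "".join(chars)
    # plant duplications: overwrite source, copy with controlled mismatches
    dup_rng = _rng(config.seed, "duplications")
    for pair in layout.dup_pairs:
        window = _craft_dup_window(dup_rng)
        copy = _mutate_copy(window, PROBE_LEN - pair["n_matches"], dup_rng)
        for chrom_key, start_key, content in (
            ("chrom_src", "src", window),
            ("chrom_copy", "copy", copy),
        ):
            chrom = pair[chrom_key]
            s = pair[start_key]
            seq = genome[chrom]
            genome[chrom] = seq[:s] + "".join(content) + seq[s + PROBE_LEN :]
    cpgs = _scan_cpgs(genome)
    return genome, cpgs, layout


# ---------------------------------------------------------------------------
# manifest


def _probe_sequences(conv, chrom: str, footprint: tuple[int, int], strand: str,
                     infinium_type: str) -> tuple[str, str | None]:
    """Read probe sequences off the converted genomes for one footprint.

    The stored probe sequence is the reverse complement of the converted
    target window, so retained-CpG cytosines surface as purines and the
    degenerate Type II base is ``R``.
    """
    s, e = footprint
    if strand == "+":
        un = conv[("plus", "unmethylated")].sequences[chrom][s:e]
        me = conv[("plus", "cpg_methylated")].sequences[chrom][s:e]
    else:
        length = conv[("plus", "unmethylated")].source_lengths[chrom]
        un = conv[("minus", "unmethylated")].sequences[chrom][length - e : length - s]
        me = conv[("minus", "cpg_methylated")].sequences[chrom][length - e : length - s]
    if infinium_type == "I":
        return revcomp(un), revcomp(me)
    chars = [
        "R" if (cm == "C" and cu == "T") else _COMPL[cm]
        for cu, cm in zip(un, me)
    ]
    return "".join(reversed(chars)), None


def simulate_manifest(
    genome: Mapping[str, str],
    cpg_positions: pd.DataFrame,
    config: SimulationConfig,
    layout: Layout,
) -> tuple[Manifest, dict[str, dict]]:
    """Place probes on CpGs and read their sequences off converted genomes.

    Returns the manifest plus per-probe metadata: a ``tag`` of ``dup``,
    ``dhs:<region index>`` or ``regular``. Probes tagged ``dup`` sit on a
    planted duplication source and are cross-reactive by construction.
    """
    rng = _rng(config.seed, "manifest")
    conv = build_converted_genomes(genome)
    cpg_by_chrom = {
        chrom: grp["start"].to_numpy(dtype=np.int64)
        for chrom, grp in cpg_positions.groupby("chrom")
    }
    exclusion: dict[str, list[tuple[int, int]]] = {}
    for pair in layout.dup_pairs:
        for chrom, start in ((pair["chrom_src"], pair["src"]),
                             (pair["chrom_copy"], pair["copy"])):
            exclusion.setdefault(chrom, []).append((start - 60, start + PROBE_LEN + 60))

    def excluded(chrom: str, pos: int) -> bool:
        return any(s <= pos < e for s, e in exclusion.get(chrom, []))

    selected: list[dict] = []  # chrom, pos, type, strand, tag
    used: set[tuple[str, int]] = set()
    n_type1 = n_type2 = 0

    for i, pair in enumerate(layout.dup_pairs):
        chrom, pos = pair["chrom_src"], pair["src"] + _DUP_CPG_OFFSET
        itype = "II" if i % 2 == 0 else "I"
        selected.append({"chrom": chrom, "pos": pos, "type": itype,
                         "strand": "+", "tag": "dup"})
        used.add((chrom, pos))
        n_type1 += itype == "I"
        n_type2 += itype == "II"

    for ridx, (chrom, s, e) in enumerate(layout.dhs_distal):
        pos_arr = cpg_by_chrom.get(chrom, np.empty(0, dtype=np.int64))
        inside = pos_arr[(pos_arr >= s) & (pos_arr < e)]
        inside = [int(p) for p in inside if not excluded(chrom, int(p))
                  and (chrom, int(p)) not in used]
        if not inside:
            continue
        center = (s + e) // 2
        pos = min(inside, key=lambda p: abs(p - center))
        selected.append({"chrom": chrom, "pos": pos, "type": "II",
                         "strand": "+", "tag": f"dhs:{ridx}"})
        used.add((chrom, pos))
        n_type2 += 1

    # distal DHS regions keep exactly their one designated probe so that
    # planted region-level faults are not diluted by random placements
    dhs_zones: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in layout.dhs_distal:
        dhs_zones.setdefault(chrom, []).append((s, e))

    def in_dhs(chrom: str, pos: int) -> bool:
        return any(s <= pos < e for s, e in dhs_zones.get(chrom, []))

    candidates = []
    for chrom, pos_arr in sorted(cpg_by_chrom.items()):
        length = layout.chrom_lengths[chrom]
        for p in pos_arr:
            p = int(p)
            if (p < 60 or p + 60 > length or excluded(chrom, p)
                    or in_dhs(chrom, p) or (chrom, p) in used):
                continue
            candidates.append((chrom, p))
    need1 = config.n_probes_type1 - n_type1
    need2 = config.n_probes_type2 - n_type2
    if need1 < 0 or need2 < 0:
        raise ConfigurationError("probe counts too small for planted features")
    if need1 + need2 > len(candidates):
        raise ConfigurationError(
            f"only {len(candidates)} CpGs available for {need1 + need2} probes"
        )
    picks = rng.choice(len(candidates), size=need1 + need2, replace=False)
    types = ["I"] * need1 + ["II"] * need2
    for k, itype in zip(picks, types):
        chrom, pos = candidates[int(k)]
        strand = "+" if rng.random() < 0.5 else "-"
        selected.append({"chrom": chrom, "pos": pos, "type": itype,
                         "strand": strand, "tag": "regular"})

    selected.sort(key=lambda d: (d["chrom"], d["pos"]))
    probes: dict[str, ProbeRecord] = {}
    meta: dict[str, dict] = {}
    for i, d in enumerate(selected):
        pid = f"cg{i + 1:07d}"
        footprint, _, _ = compute_footprint(d["type"], d["pos"], d["strand"])
        seq_u, seq_m = _probe_sequences(conv, d["chrom"], footprint, d["strand"], d["type"])
        probes[pid] = ProbeRecord(
            probe_id=pid,
            infinium_type=d["type"],
            chrom=d["chrom"],
            target_pos=d["pos"],
            design_strand=d["strand"],
            sequence_u=seq_u,
            sequence_m=seq_m,
        )
        meta[pid] = d
    return Manifest(platform_name="synthetic", probes=probes), meta


# ---------------------------------------------------------------------------
# annotation, methylation truth


def _simulate_dhs_states(config: SimulationConfig, layout: Layout):
    rng = _rng(config.seed, "dhs-states")
    cell_types = ["cellA", "cellB"] + [f"cell{c}" for c in range(3, config.n_cell_types + 1)]
    rows = []
    presence = {}
    for i, (chrom, s, e) in enumerate(layout.dhs_distal):
        region_id = f"reD{i}"
        state_a = bool(rng.random() < 0.5)
        occupancy = float(rng.uniform(0.05, 0.95))
        pres = [bool(rng.random() < occupancy) for _ in cell_types]
        pres[0] = state_a
        rows.append({"region_id": region_id, "chrom": chrom, "start": s, "end": e,
                     "present_cellA": state_a})
        presence[region_id] = pres
    regions = pd.DataFrame(rows, columns=["region_id", "chrom", "start", "end",
                                          "present_cellA"])
    presence_df = pd.DataFrame.from_dict(presence, orient="index", columns=cell_types)
    presence_df.index.name = "region_id"
    return regions, presence_df


def _truth_for_position(chrom: str, pos: int, layout: Layout,
                        dhs_state: Mapping[tuple[str, int, int], bool]) -> float:
    for (c, s, e), present in dhs_state.items():
        if c == chrom and s <= pos < e:
            return 0.1 if present else 0.9
    for c, s, e in layout.islands:
        if c == chrom and s <= pos < e:
            return 0.1
    return 0.85


# ---------------------------------------------------------------------------
# intensities, wgbs, variants


def draw_intensities(
    rng: np.random.Generator,
    beta_truth: np.ndarray,
    intensity_mean: float = 12_000.0,
    intensity_sd: float = 1_500.0,
    background_mean: float = 100.0,
    background_sd: float = 30.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (methylated, unmethylated) signal for a truth matrix.

    Total intensity is Gaussian per cell; the methylated share is binomial
    at the true beta, and both channels pick up non-specific background so
    beta estimates shrink slightly towards the +100-offset formula's fixed
    point, as on the real platform.
    """
    beta_truth = np.asarray(beta_truth, dtype=float)
    total = np.clip(
        rng.normal(intensity_mean, intensity_sd, size=beta_truth.shape), 2_000, None
    ).astype(np.int64)
    x = rng.binomial(total, np.clip(beta_truth, 0.0, 1.0))
    bg_m = np.abs(rng.normal(background_mean, background_sd, size=beta_truth.shape))
    bg_u = np.abs(rng.normal(background_mean, background_sd, size=beta_truth.shape))
    return x + bg_m, (total - x) + bg_u


def simulate_intensities(
    config: SimulationConfig,
    manifest: Manifest,
    true_beta: pd.DataFrame,
) -> IntensityData:
    """Two-group intensity matrices plus negative controls."""
    rng = _rng(config.seed, "intensities")
    n = config.n_samples_per_group
    samples = [f"A{i + 1}" for i in range(n)] + [f"B{i + 1}" for i in range(n)]
    groups = pd.Series(["A"] * n + ["B"] * n, index=samples)
    probe_ids = list(manifest.probes)
    truth = np.column_stack(
        [true_beta.loc[probe_ids, groups[s]].to_numpy() for s in samples]
    )
    meth, unmeth = draw_intensities(
        rng, truth, config.intensity_mean, config.intensity_sd,
        config.background_mean, config.background_sd,
    )
    ctrl_shape = (config.n_negative_controls, len(samples))
    ctrl_m = np.abs(rng.normal(config.background_mean, config.background_sd, ctrl_shape))
    ctrl_u = np.abs(rng.normal(config.background_mean, config.background_sd, ctrl_shape))
    ctrl_index = [f"neg{i + 1:04d}" for i in range(config.n_negative_controls)]
    return IntensityData(
        meth=pd.DataFrame(meth, index=probe_ids, columns=samples),
        unmeth=pd.DataFrame(unmeth, index=probe_ids, columns=samples),
        control_meth=pd.DataFrame(ctrl_m, index=ctrl_index, columns=samples),
        control_unmeth=pd.DataFrame(ctrl_u, index=ctrl_index, columns=samples),
        groups=groups,
    )


def simulate_wgbs_counts(
    cpg_positions: pd.DataFrame,
    true_m: pd.Series,
    config: SimulationConfig,
    label: str = "wgbs",
) -> pd.DataFrame:
    """Per-CpG count table: coverage ~ Poisson, methylated ~ Binomial.

    ``true_m`` is indexed by (chrom, start) and must cover every CpG.
    """
    rng = _rng(config.seed, label)
    key = list(zip(cpg_positions["chrom"], cpg_positions["start"]))
    truth = true_m.loc[key].to_numpy(dtype=float)
    coverage = rng.poisson(config.wgbs_mean_coverage, size=len(truth))
    methylated = rng.binomial(coverage, np.clip(truth, 0.0, 1.0))
    out = cpg_positions.copy().reset_index(drop=True)
    out["methylated"] = methylated
    out["total"] = coverage
    return out


def _isolated_probes(manifest: Manifest) -> list[str]:
    """Probes whose footprint (plus SBE) is clear of all other probes."""
    extents = []
    for pid, probe in manifest.probes.items():
        s, e = probe.footprint
        lo = min(s, probe.sbe_pos)
        hi = max(e, probe.sbe_pos + 1)
        extents.append((probe.chrom, lo, hi, pid))
    extents.sort()
    isolated = []
    for i, (chrom, lo, hi, pid) in enumerate(extents):
        left_clear = i == 0 or extents[i - 1][0] != chrom or extents[i - 1][2] <= lo
        right_clear = (
            i == len(extents) - 1
            or extents[i + 1][0] != chrom
            or extents[i + 1][1] >= hi
        )
        if left_clear and right_clear:
            isolated.append(pid)
    return isolated


def _simulate_variants(
    config: SimulationConfig,
    genome: Mapping[str, str],
    manifest: Manifest,
    meta: dict[str, dict],
) -> tuple[list[dict], dict[str, str], list[tuple[str, str, int, str]]]:
    """Plant high-MAF variants in probe zones, plus low-MAF decoys.

    Every variant with folded MAF above the default 0.05 threshold is a
    planted one, so the classifier's output on the filtered set equals the
    planted ground truth exactly.
    """
    rng = _rng(config.seed, "variants")
    lo, hi = config.maf_distribution
    lo = max(lo, 0.06)
    isolated = [pid for pid in _isolated_probes(manifest) if meta[pid]["tag"] == "regular"]
    # SBE planting needs Type I probes; serve each category from its own queue
    type1_queue = [pid for pid in isolated if manifest.probes[pid].infinium_type == "I"]
    other_queue = [pid for pid in isolated if pid not in set(type1_queue)]
    categories = ["TARGET_CPG", "SBE", "PROBE_BODY"]
    planted: list[dict] = []
    planted_pairs: list[tuple[str, str, int, str]] = []
    overlaps: dict[str, str] = {}
    used_pos: set[tuple[str, int]] = set()
    n_planted_target = min(len(isolated), max(6, config.n_variants // 4))
    cat_idx = 0
    while len(planted) < n_planted_target:
        category = categories[cat_idx % 3]
        cat_idx += 1
        if category == "SBE":
            if not type1_queue:
                category = "PROBE_BODY"
                if not other_queue:
                    break
                pid = other_queue.pop(0)
            else:
                pid = type1_queue.pop(0)
        else:
            if not other_queue:
                if not type1_queue:
                    break
                pid = type1_queue.pop(0)
            else:
                pid = other_queue.pop(0)
        probe = manifest.probes[pid]
        p = probe.target_pos
        if category == "TARGET_CPG":
            pos = p if len(planted) % 2 == 0 else p + 1
        elif category == "SBE":
            pos = probe.sbe_pos
        else:
            bs, be = probe.body_intervals[0]
            pos = (bs + be) // 2
            if abs(pos - p) < 3:
                pos = bs + 5
        chrom = probe.chrom
        if (chrom, pos) in used_pos:
            continue
        seq = genome[chrom]
        make_indel = category != "SBE" and len(planted) % 5 == 4
        if make_indel and category == "PROBE_BODY":
            ref = seq[pos : pos + 2]
            alts = (ref[0],)
        else:
            ref = seq[pos]
            alt_pool = [b for b in "ACGT" if b != ref]
            if len(planted) % 7 == 6:
                alts = tuple(rng.choice(alt_pool, size=2, replace=False))
            else:
                alts = (alt_pool[int(rng.integers(len(alt_pool)))],)
        afs = tuple(float(rng.uniform(lo, min(hi, 0.45))) for _ in alts)
        planted.append({"chrom": chrom, "pos": pos, "ref": ref, "alts": alts, "afs": afs})
        planted_pairs.append((pid, chrom, pos, category))
        overlaps[pid] = category
        used_pos.add((chrom, pos))
    # low-MAF decoys anywhere on the genome
    n_decoys = max(0, config.n_variants - len(planted))
    chroms = sorted(genome)
    attempts = 0
    decoys: list[dict] = []
    while len(decoys) < n_decoys and attempts < 50 * n_decoys + 100:
        attempts += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(1, len(genome[chrom]) - 2))
        if (chrom, pos) in used_pos:
            continue
        ref = genome[chrom][pos]
        alt_pool = [b for b in "ACGT" if b != ref]
        if len(decoys) % 9 == 8:  # occasional near-fixed multi-allelic record
            alts = tuple(rng.choice(alt_pool, size=2, replace=False))
            afs = (float(rng.uniform(0.95, 0.99)), float(rng.uniform(0.001, 0.01)))
        else:
            alts = (alt_pool[int(rng.integers(len(alt_pool)))],)
            afs = (float(rng.uniform(0.001, 0.045)),)
        decoys.append({"chrom": chrom, "pos": pos, "ref": ref, "alts": alts, "afs": afs})
        used_pos.add((chrom, pos))
    records = sorted(planted + decoys, key=lambda d: (d["chrom"], d["pos"]))
    return records, overlaps, planted_pairs


def _variant_records(raw: Sequence[dict], maf_threshold: float = 0.05) -> list[VariantRecord]:
    out = []
    for d in raw:
        maf = fold_maf(d["afs"])
        if maf <= maf_threshold:
            continue
        out.append(
            VariantRecord(
                chrom=d["chrom"],
                pos=d["pos"],
                ref=d["ref"],
                alts=tuple(d["alts"]),
                allele_frequencies=tuple(d["afs"]),
                variant_class=_variant_class(d["ref"], d["alts"]),
                maf=maf,
            )
        )
    return out


# ---------------------------------------------------------------------------
# orchestration


def simulate_all(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Run every generator and assemble the dataset with its ground truth."""
    config = config or SimulationConfig()
    genome, cpgs, layout = simulate_genome(config)
    manifest, meta = simulate_manifest(genome, cpgs, config, layout)
    dhs_regions, presence = _simulate_dhs_states(config, layout)
    dhs_state = {
        (r.chrom, r.start, r.end): bool(r.present_cellA)
        for r in dhs_regions.itertuples(index=False)
    }

    # per-CpG truth for the reference cell line, with planted faults
    cpg_key = list(zip(cpgs["chrom"], cpgs["start"]))
    base_truth = pd.Series(
        [_truth_for_position(c, p, layout, dhs_state) for c, p in cpg_key],
        index=pd.MultiIndex.from_tuples(cpg_key),
    )
    region_rows = {r.region_id: r for r in dhs_regions.itertuples(index=False)}
    probe_by_region: dict[str, list[str]] = {}
    for pid, d in meta.items():
        if d["tag"].startswith("dhs:"):
            region_id = f"reD{d['tag'].split(':')[1]}"
            probe_by_region.setdefault(region_id, []).append(pid)
    fault_candidates = []
    for region_id, pids in sorted(probe_by_region.items()):
        r = region_rows[region_id]
        if not r.present_cellA:
            continue
        n_cpgs = int(
            ((cpgs["chrom"] == r.chrom) & (cpgs["start"] >= r.start)
             & (cpgs["start"] < r.end)).sum()
        )
        if n_cpgs >= 6:
            fault_candidates.append((region_id, pids[0], n_cpgs))
    fault_candidates.sort(key=lambda t: -t[2])
    fault_types: dict[str, str] = {}
    artifact_probes: set[str] = set()
    for region_id, pid, _ in fault_candidates:
        if sum(v == "PROBE_POSITIONING" for v in fault_types.values()) < config.n_fault_positioning:
            fault_types[region_id] = "PROBE_POSITIONING"
            probe = manifest.probes[pid]
            base_truth.loc[(probe.chrom, probe.target_pos)] = 0.9
        elif sum(v == "TECHNICAL_ARTIFACT" for v in fault_types.values()) < config.n_fault_artifact:
            fault_types[region_id] = "TECHNICAL_ARTIFACT"
            artifact_probes.add(pid)
        else:
            break

    # per-probe truth: group A mirrors the reference cell line (except
    # artifact probes, whose array signal contradicts the genome truth)
    probe_ids = list(manifest.probes)
    beta_a = []
    for pid in probe_ids:
        probe = manifest.probes[pid]
        if pid in artifact_probes:
            beta_a.append(0.9)
        else:
            beta_a.append(float(base_truth.loc[(probe.chrom, probe.target_pos)]))
    true_beta = pd.DataFrame({"A": beta_a}, index=probe_ids)
    dmp_rng = _rng(config.seed, "dmp-selection")
    eligible = [pid for pid in probe_ids
                if meta[pid]["tag"] == "regular" and pid not in artifact_probes]
    if len(config.delta_beta_true) > len(eligible):
        raise ConfigurationError("more DMP effects requested than eligible probes")
    dmp_picks = sorted(
        int(i) for i in dmp_rng.choice(len(eligible), size=len(config.delta_beta_true),
                                       replace=False)
    )
    beta_b = true_beta["A"].copy()
    true_dmp_ids = []
    for k, delta in zip(dmp_picks, config.delta_beta_true):
        pid = eligible[k]
        base = float(beta_b.loc[pid])
        shifted = base + delta
        if not 0.02 <= shifted <= 0.98:
            shifted = base - delta
        beta_b.loc[pid] = float(np.clip(shifted, 0.02, 0.98))
        if abs(beta_b.loc[pid] - base) > 1e-9 and delta != 0:
            true_dmp_ids.append(pid)
    true_beta["B"] = beta_b

    raw_variants, overlaps, planted_pairs = _simulate_variants(
        config, genome, manifest, meta
    )
    intensities = simulate_intensities(config, manifest, true_beta)
    wgbs = simulate_wgbs_counts(cpgs, base_truth, config, label="wgbs:cellA")

    annotation = {
        "genes": pd.DataFrame(
            layout.genes, columns=["chrom", "start", "end", "strand"]
        ),
        "islands": pd.DataFrame(layout.islands, columns=["chrom", "start", "end"]),
        "dhs_distal": dhs_regions[["region_id", "chrom", "start", "end"]].copy(),
        "dhs_proximal": pd.DataFrame(
            [
                {"region_id": f"reP{i}", "chrom": c, "start": s, "end": e}
                for i, (c, s, e) in enumerate(layout.dhs_proximal)
            ],
            columns=["region_id", "chrom", "start", "end"],
        ),
        "enhancers": pd.DataFrame(
            [
                {"region_id": f"enh{i}", "chrom": c, "start": s, "end": e}
                for i, (c, s, e) in enumerate(layout.enhancers)
            ],
            columns=["region_id", "chrom", "start", "end"],
        ),
        "dhs_presence": presence,
        "variants_raw": pd.DataFrame(raw_variants),
    }
    ground_truth = GroundTruth(
        planted_crossreactive_probe_ids=sorted(
            pid for pid, d in meta.items() if d["tag"] == "dup"
        ),
        planted_variant_overlaps=overlaps,
        planted_variant_pairs=planted_pairs,
        true_beta=true_beta,
        true_dmp_ids=sorted(true_dmp_ids),
        dhs_regions=dhs_regions,
        dhs_fault_types=fault_types,
        cpg_true_m=base_truth,
        duplication_pairs=layout.dup_pairs,
    )
    return SyntheticDataset(
        config=config,
        genome=genome,
        cpg_positions=cpgs,
        layout=layout,
        manifest=manifest,
        variants=_variant_records(raw_variants),
        intensities=intensities,
        wgbs=wgbs,
        annotation=annotation,
        ground_truth=ground_truth,
    )


# ---------------------------------------------------------------------------
# writers


def write_fasta(genome: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_vcf(raw_variants: Sequence[dict], path, chrom_lengths: Mapping[str, int]) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
        for chrom in sorted(chrom_lengths):
            fh.write(f"##contig=<ID={chrom},length={chrom_lengths[chrom]}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for d in sorted(raw_variants, key=lambda d: (d["chrom"], d["pos"])):
            af = ",".join(f"{a:.6g}" for a in d["afs"])
            fh.write(
                f"{d['chrom']}\t{d['pos'] + 1}\t.\t{d['ref']}\t"
                f"{','.join(d['alts'])}\t.\t.\tAF={af}\n"
            )


def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, Path]:
    """Emit the whole dataset as plain-text files; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _save(name, fn):
        p = outdir / name
        fn(p)
        paths[name] = p

    _save("genome.fa", lambda p: write_fasta(ds.genome, p))
    _save("cpg_positions.bed", lambda p: ds.cpg_positions.to_csv(
        p, sep="\t", header=False, index=False))
    _save("manifest.csv", lambda p: write_manifest(ds.manifest, p))
    _save("variants.vcf", lambda p: write_vcf(
        ds.annotation["variants_raw"].to_dict("records"), p, ds.layout.chrom_lengths))
    _save("intensities_meth.csv", lambda p: ds.intensities.meth.to_csv(p))
    _save("intensities_unmeth.csv", lambda p: ds.intensities.unmeth.to_csv(p))
    _save("controls_meth.csv", lambda p: ds.intensities.control_meth.to_csv(p))
    _save("controls_unmeth.csv", lambda p: ds.intensities.control_unmeth.to_csv(p))
    _save("wgbs_counts.tsv", lambda p: ds.wgbs.to_csv(p, sep="\t", index=False))
    for name in ("islands", "dhs_distal", "dhs_proximal", "enhancers"):
        df = ds.annotation[name]
        cols = ["chrom", "start", "end"] + (
            ["region_id"] if "region_id" in df.columns else []
        )
        _save(f"{name}.bed", lambda p, df=df, cols=cols: df[cols].to_csv(
            p, sep="\t", header=False, index=False))
    _save("genes.tsv", lambda p: ds.annotation["genes"].to_csv(p, sep="\t", index=False))
    _save("dhs_presence.csv", lambda p: ds.annotation["dhs_presence"].astype(int).to_csv(p))
    gt = ds.ground_truth
    truth_payload = {
        "planted_crossreactive_probe_ids": gt.planted_crossreactive_probe_ids,
        "planted_variant_overlaps": gt.planted_variant_overlaps,
        "planted_variant_pairs": gt.planted_variant_pairs,
        "true_dmp_ids": gt.true_dmp_ids,
        "dhs_fault_types": gt.dhs_fault_types,
        "duplication_pairs": gt.duplication_pairs,
        "true_beta": gt.true_beta.reset_index().to_dict("records"),
        "config": asdict(ds.config),
    }
    _save("ground_truth.json", lambda p: p.write_text(
        json.dumps(truth_payload, indent=2, default=str)))
    return paths
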