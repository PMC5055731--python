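"""In-silico bisulfite-converted genomes and off-target probe homology screen.

The screen builds four converted genomes (plus/minus strand, fully
unmethylated or CpG-methylated), then aligns every 50-base probe sequence
against all four in both orientations, counting matched bases per window.
A probe is called cross-reactive when a window away from its annotated
footprint matches at or above the homology threshold (default 47/50).

Alignment is ungapped: exact-match seeds of length ``k`` (default 10, five
non-overlapping seeds per 50-mer) nominate candidate windows which are then
scored by full base-wise comparison. With five seeds, any window with at
most four mismatches leaves at least one seed untouched, so detection is
complete for match counts >= 46 — comfortably below the 47 calling
threshold. Degenerate probe bases follow purine/pyrimidine semantics:
``R`` matches ``A`` or ``G``; its complement ``Y`` matches ``C`` or ``T``.
``N`` in the genome never matches anything.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import FormatError, IntegrityError
from .manifest import Manifest, ProbeRecord

__all__ = [
    "GENOME_IDS",
    "ConvertedGenome",
    "AlignmentHit",
    "CrossReactivityCall",
    "revcomp",
    "build_converted_genomes",
    "ProbeScanner",
    "scan_probe",
    "call_crossreactive",
    "validate_against_reference",
]

GenomeId = tuple[str, str]

#: The four in-silico genomes: strand x methylation state.
GENOME_IDS: tuple[GenomeId, ...] = (
    ("plus", "unmethylated"),
    ("plus", "cpg_methylated"),
    ("minus", "unmethylated"),
    ("minus", "cpg_methylated"),
)

_COMP = str.maketrans("ACGTNRY", "TGCANYR")
_VALID_GENOME = frozenset(b"ACGTN")
_A, _C, _G, _T = (ord(c) for c in "ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement over the extended alphabet (R <-> Y)."""
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class ConvertedGenome:
    """One of the four converted genomes.

    ``sequences`` are stored in the orientation of the converted strand:
    plus genomes read left-to-right in plus coordinates, minus genomes are
    the converted reverse complement (index ``j`` corresponds to plus
    position ``length - 1 - j``).
    """

    strand: str
    methylation: str
    sequences: Mapping[str, str]
    source_lengths: Mapping[str, int]

    @property
    def genome_id(self) -> GenomeId:
        return (self.strand, self.methylation)

    def plus_window(self, chrom: str, start: int, width: int = 50) -> tuple[int, int]:
        """Map a window start in stored orientation to a plus-strand interval."""
        if self.strand == "plus":
            return (start, start + width)
        length = self.source_lengths[chrom]
        return (length - start - width, length - start)


@dataclass(frozen=True)
class AlignmentHit:
    """A scored 50-base window in one converted genome.

    ``start`` is the 0-based plus-strand start of the window;
    ``orientation`` says whether the probe matched the stored genome string
    directly (``forward``) or via its reverse complement (``reverse``).
    """

    probe_id: str
    genome_id: GenomeId
    chrom: str
    start: int
    orientation: str
    match_count: int
    is_target: bool


@dataclass
class CrossReactivityCall:
    probe_id: str
    n_offtarget_hits_at_threshold: int
    best_offtarget: AlignmentHit
    tie: bool
    hits_at_threshold: list[AlignmentHit] = field(default_factory=list)


def _convert_plus(seq: str, keep_cpg: bool) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    bad = ~np.isin(arr, np.frombuffer(b"ACGTN", dtype=np.uint8))
    if bad.any():
        pos = int(np.flatnonzero(bad)[0])
        raise FormatError(
            f"non-ACGTN character {chr(arr[pos])!r} at position {pos}"
        )
    c_mask = arr == _C
    if keep_cpg:
        followed_by_g = np.zeros(arr.shape, dtype=bool)
        followed_by_g[:-1] = arr[1:] == _G
        c_mask &= ~followed_by_g
    arr[c_mask] = _T
    return arr.tobytes().decode("ascii")


def _load_genome(genome) -> dict[str, str]:
    if isinstance(genome, (str, Path)):
        from pyfaidx import Fasta

        with Fasta(str(genome)) as fa:
            return {name: str(fa[name][:]).upper() for name in fa.keys()}
    return {chrom: seq.upper() for chrom, seq in dict(genome).items()}


def build_converted_genomes(genome) -> dict[GenomeId, ConvertedGenome]:
    """Build the four converted genomes from a FASTA path or chrom->seq mapping.

    The minus-strand genomes are the bisulfite-converted reverse complement
    of each chromosome, stored in minus orientation; coordinate mapping back
    to the plus strand is handled by :meth:`ConvertedGenome.plus_window`.
    """
    seqs = _load_genome(genome)
    lengths = {c: len(s) for c, s in seqs.items()}
    out: dict[GenomeId, ConvertedGenome] = {}
    for strand in ("plus", "minus"):
        oriented = (
            seqs
            if strand == "plus"
            else {c: revcomp(s) for c, s in seqs.items()}
        )
        for meth in ("unmethylated", "cpg_methylated"):
            converted = {
                c: _convert_plus(s, keep_cpg=(meth == "cpg_methylated"))
                for c, s in oriented.items()
            }
            out[(strand, meth)] = ConvertedGenome(
                strand=strand,
                methylation=meth,
                sequences=converted,
                source_lengths=lengths,
            )
    return out


def _expand_degenerate(kmer: str) -> list[str]:
    pools = []
    for ch in kmer:
        if ch == "R":
            pools.append("AG")
        elif ch == "Y":
            pools.append("CT")
        else:
            pools.append(ch)
    return ["".join(p) for p in itertools.product(*pools)]


def _probe_masks(seq: str):
    """Byte codes plus R/Y wildcard masks for vectorised window scoring."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    is_r = arr == ord("R")
    is_y = arr == ord("Y")
    arr[is_r | is_y] = 0  # never equal to a genome byte
    return arr, is_r, is_y


def _window_match_count(garr: np.ndarray, start: int, codes, is_r, is_y) -> int:
    w = garr[start : start + codes.size]
    m = w == codes
    if is_r.any():
        m |= is_r & ((w == _A) | (w == _G))
    if is_y.any():
        m |= is_y & ((w == _C) | (w == _T))
    return int(np.count_nonzero(m))


def _all_match_counts(garr: np.ndarray, seq: str) -> np.ndarray:
    """Match count of ``seq`` against every window (fallback, O(50·L))."""
    n = garr.size - len(seq) + 1
    if n <= 0:
        return np.zeros(0, dtype=np.uint16)
    counts = np.zeros(n, dtype=np.uint16)
    for i, ch in enumerate(seq):
        seg = garr[i : i + n]
        if ch == "R":
            m = (seg == _A) | (seg == _G)
        elif ch == "Y":
            m = (seg == _C) | (seg == _T)
        else:
            m = seg == ord(ch)
        counts += m
    return counts


class ProbeScanner:
    """Seed-and-extend scanner over the four converted genomes.

    Parameters
    ----------
    genomes
        Output of :func:`build_converted_genomes`.
    k
        Seed length. Seeds are placed at ``k``-spaced offsets across the
        50-mer; the default (10) yields five seeds and guarantees complete
        detection of every window matching at >= 46 of 50 bases.
    report_floor
        Minimum match count for a window to be reported. Completeness is
        only guaranteed down to ``51 - number_of_seeds``; windows below
        that are reported on a best-effort basis.
    """

    PROBE_LEN = 50

    def __init__(
        self,
        genomes: Mapping[GenomeId, ConvertedGenome],
        k: int = 10,
        report_floor: int = 40,
        max_seed_expansion: int = 128,
    ):
        self.genomes = dict(genomes)
        self.k = int(k)
        self.report_floor = int(report_floor)
        self.max_seed_expansion = int(max_seed_expansion)
        self.seed_offsets = list(range(0, self.PROBE_LEN - self.k + 1, self.k))
        self._arrays: dict[tuple[GenomeId, str], np.ndarray] = {}
        self._indexes: dict[tuple[GenomeId, str], dict[str, list[int]]] = {}

    @property
    def guaranteed_floor(self) -> int:
        """Smallest match count at which seed detection is provably complete."""
        return self.PROBE_LEN - len(self.seed_offsets) + 1

    def _array(self, gid: GenomeId, chrom: str) -> np.ndarray:
        key = (gid, chrom)
        if key not in self._arrays:
            seq = self.genomes[gid].sequences[chrom]
            self._arrays[key] = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        return self._arrays[key]

    def _index(self, gid: GenomeId, chrom: str) -> dict[str, list[int]]:
        key = (gid, chrom)
        if key not in self._indexes:
            seq = self.genomes[gid].sequences[chrom]
            idx: dict[str, list[int]] = {}
            k = self.k
            for i in range(len(seq) - k + 1):
                idx.setdefault(seq[i : i + k], []).append(i)
            self._indexes[key] = idx
        return self._indexes[key]

    def _candidates(self, gid: GenomeId, chrom: str, query: str) -> tuple[set[int], bool]:
        """Candidate window starts from seed lookups.

        Returns (candidates, exhaustive) where ``exhaustive`` signals that a
        full scan replaced the seed search (degenerate seed blow-up).
        """
        idx = self._index(gid, chrom)
        garr = self._array(gid, chrom)
        limit = garr.size - self.PROBE_LEN
        cands: set[int] = set()
        for off in self.seed_offsets:
            kmer = query[off : off + self.k]
            variants = _expand_degenerate(kmer)
            if len(variants) > self.max_seed_expansion:
                counts = _all_match_counts(garr, query)
                starts = np.flatnonzero(counts >= self.report_floor)
                return set(int(s) for s in starts), True
            for v in variants:
                for pos in idx.get(v, ()):
                    start = pos - off
                    if 0 <= start <= limit:
                        cands.add(start)
        return cands, False

    def scan_sequence(
        self,
        seq: str,
        probe_id: str = "",
        chrom: str | None = None,
        footprint: tuple[int, int] | None = None,
    ) -> list[AlignmentHit]:
        """Return all windows matching ``seq`` at >= ``report_floor`` bases.

        Windows are deduplicated on (genome, chrom, plus-strand start),
        keeping the best orientation.
        """
        if len(seq) != self.PROBE_LEN:
            raise IntegrityError(
                f"probe sequence length {len(seq)} != {self.PROBE_LEN}"
            )
        best: dict[tuple[GenomeId, str, int], tuple[int, str]] = {}
        queries = (("forward", seq), ("reverse", revcomp(seq)))
        for gid, genome in self.genomes.items():
            for g_chrom in genome.sequences:
                garr = self._array(gid, g_chrom)
                for orientation, query in queries:
                    codes, is_r, is_y = _probe_masks(query)
                    cands, _ = self._candidates(gid, g_chrom, query)
                    for start in cands:
                        mc = _window_match_count(garr, start, codes, is_r, is_y)
                        if mc < self.report_floor:
                            continue
                        ps, _pe = genome.plus_window(g_chrom, start)
                        key = (gid, g_chrom, ps)
                        if key not in best or mc > best[key][0]:
                            best[key] = (mc, orientation)
        hits = []
        for (gid, g_chrom, ps), (mc, orientation) in best.items():
            on_target = bool(
                footprint is not None
                and chrom == g_chrom
                and ps < footprint[1]
                and ps + self.PROBE_LEN > footprint[0]
            )
            hits.append(
                AlignmentHit(
                    probe_id=probe_id,
                    genome_id=gid,
                    chrom=g_chrom,
                    start=ps,
                    orientation=orientation,
                    match_count=mc,
                    is_target=on_target,
                )
            )
        hits.sort(key=lambda h: (-h.match_count, h.genome_id, h.chrom, h.start))
        return hits


def scan_probe(probe: ProbeRecord, scanner: ProbeScanner) -> list[AlignmentHit]:
    """Scan both allele sequences of a probe; merge hits per window."""
    seqs = [probe.sequence_u]
    if probe.sequence_m is not None:
        seqs.append(probe.sequence_m)
    best: dict[tuple[GenomeId, str, int], AlignmentHit] = {}
    for seq in seqs:
        for hit in scanner.scan_sequence(
            seq,
            probe_id=probe.probe_id,
            chrom=probe.chrom,
            footprint=probe.footprint,
        ):
            key = (hit.genome_id, hit.chrom, hit.start)
            if key not in best or hit.match_count > best[key].match_count:
                best[key] = hit
    hits = list(best.values())
    hits.sort(key=lambda h: (-h.match_count, h.genome_id, h.chrom, h.start))
    return hits


def call_crossreactive(
    manifest: Manifest,
    scanner: ProbeScanner | None = None,
    genomes: Mapping[GenomeId, ConvertedGenome] | None = None,
    threshold: int = 47,
    include_noncpg: bool = False,
) -> list[CrossReactivityCall]:
    """Flag probes with >= ``threshold`` matched bases at an off-target window.

    A hit overlapping the probe's annotated footprint by at least one base
    counts as the target; everything else is off-target. ``tie`` is set when
    the best off-target match count is reached in more than one of the four
    converted genomes. Output is sorted by probe id and is therefore
    invariant to probe and chromosome input order.
    """
    if scanner is None:
        if genomes is None:
            raise IntegrityError("either a scanner or converted genomes required")
        scanner = ProbeScanner(genomes)
    calls: list[CrossReactivityCall] = []
    for probe_id in sorted(manifest.probes):
        probe = manifest.probes[probe_id]
        if not include_noncpg and probe.probe_class != "cg":
            continue
        hits = scan_probe(probe, scanner)
        offtarget = [
            h for h in hits if not h.is_target and h.match_count >= threshold
        ]
        if not offtarget:
            continue
        best = offtarget[0]
        genomes_at_best = {
            h.genome_id for h in offtarget if h.match_count == best.match_count
        }
        calls.append(
            CrossReactivityCall(
                probe_id=probe_id,
                n_offtarget_hits_at_threshold=len(offtarget),
                best_offtarget=best,
                tie=len(genomes_at_best) > 1,
                hits_at_threshold=offtarget,
            )
        )
    return calls


def validate_against_reference(
    calls: Iterable[CrossReactivityCall],
    reference: Sequence[tuple[str, str, int]],
    tolerance: int = 0,
) -> dict[str, float]:
    """Score (probe, off-target locus) calls against a reference list.

    Matching is on ``(probe_id, chrom, start)`` with ``start`` allowed to
    deviate by up to ``tolerance`` bases. Returns precision, recall and the
    TP/FP/FN counts.
    """
    ref = list(reference)
    if not ref:
        raise IntegrityError("reference list is empty")
    # the same locus can be hit in several converted genomes; it is one call
    call_pairs = sorted(
        {
            (c.probe_id, h.chrom, h.start)
            for c in calls
            for h in c.hits_at_threshold
        }
    )
    ref_by_key: dict[tuple[str, str], list[int]] = {}
    for pid, chrom, start in ref:
        ref_by_key.setdefault((pid, chrom), []).append(int(start))
    matched = {k: [False] * len(v) for k, v in ref_by_key.items()}
    tp = fp = 0
    for pid, chrom, start in call_pairs:
        starts = ref_by_key.get((pid, chrom))
        hit = False
        if starts is not None:
            for i, rs in enumerate(starts):
                if not matched[(pid, chrom)][i] and abs(rs - start) <= tolerance:
                    matched[(pid, chrom)][i] = True
                    hit = True
                    break
        if hit:
            tp += 1
        else:
            fp += 1
    fn = sum(flags.count(False) for flags in matched.values())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return {
        "precision": precision,
        "recall": recall,
        "tp": tp,
        "fp": fp,
        "fn": fn,
    }
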