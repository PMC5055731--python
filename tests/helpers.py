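"""Independent oracles used by the test suite.

These deliberately re-derive results from first principles (exhaustive
window comparison, per-base membership) without touching the package's
seed-and-extend or interval machinery.
"""

from __future__ import annotations

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N", "R": "Y", "Y": "R"}


def rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def oracle_window_counts(genome_seq: str, probe_seq: str) -> np.ndarray:
    """Match count of the probe against every window of the genome string.

    R matches A/G, Y matches C/T, N in the genome matches nothing.
    """
    g = np.frombuffer(genome_seq.encode("ascii"), dtype=np.uint8)
    n = g.size - len(probe_seq) + 1
    counts = np.zeros(max(n, 0), dtype=np.int16)
    for i, ch in enumerate(probe_seq):
        seg = g[i : i + n]
        if ch == "R":
            m = (seg == ord("A")) | (seg == ord("G"))
        elif ch == "Y":
            m = (seg == ord("C")) | (seg == ord("T"))
        else:
            m = seg == ord(ch)
        counts += m.astype(np.int16)
    return counts


def oracle_hits(probe, converted, floor: int = 47) -> dict:
    """All-window hits for a probe, keyed (genome_id, chrom, plus_start).

    Scans both allele sequences in both orientations against all four
    converted genomes, keeping the best match count per window.
    """
    seqs = [probe.sequence_u]
    if probe.sequence_m is not None:
        seqs.append(probe.sequence_m)
    best: dict[tuple, int] = {}
    for gid, genome in converted.items():
        for chrom, gseq in genome.sequences.items():
            length = genome.source_lengths[chrom]
            for seq in seqs:
                for query in (seq, rc(seq)):
                    counts = oracle_window_counts(gseq, query)
                    for start in np.flatnonzero(counts >= floor):
                        start = int(start)
                        if gid[0] == "plus":
                            ps = start
                        else:
                            ps = length - start - len(seq)
                        key = (gid, chrom, ps)
                        mc = int(counts[start])
                        if best.get(key, -1) < mc:
                            best[key] = mc
    return best


def oracle_footprints(probe, converted) -> set[tuple[str, int, int]]:
    """Plus-strand windows where the probe hybridises perfectly (50/50)."""
    return {
        (chrom, ps, ps + 50)
        for (gid, chrom, ps), mc in oracle_hits(probe, converted, floor=50).items()
    }
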