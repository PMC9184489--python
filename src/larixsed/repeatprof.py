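"""Satellite-repeat profiling: wraparound mapping and base-frequency constancy.

The Larix satellite EulaSat1 has a ~173 bp motif arranged in long tandem
arrays; reads deriving from an array start at an arbitrary phase of the
motif and routinely span copy junctions.  Reads are therefore aligned
against the motif concatenated enough times to contain any read, and the
alignment start modulo the period gives the phase.  Per-sample profiles
count the read base at every motif position; cross-sample constancy is
summarised as the mean total-variation distance between per-position base
frequency vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd

from ._util import cigar_pairs, revcomp

BASE_TO_COL = {"A": 0, "C": 1, "G": 2, "T": 3}
BASE_COLS = ["A", "C", "G", "T"]


@dataclass
class RepeatMotif:
    id: str
    consensus: str

    def __post_init__(self) -> None:
        if not self.consensus or set(self.consensus) - set("ACGT"):
            raise ValueError("motif consensus must be non-empty over ACGT")

    @property
    def period(self) -> int:
        return len(self.consensus)


@dataclass
class PhasedAlignment:
    """Alignment of one read in motif-phase coordinates."""

    read_id: str
    phase: int  # start position in [0, period)
    strand: str
    edit_distance: int
    cigar: str
    aligned_query: str
    target_start: int  # start on the concatenated motif


@dataclass
class RepeatProfile:
    """Position × base counts for one sample."""

    sample: str
    period: int
    counts: np.ndarray  # (period, 4) int

    @property
    def coverage(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def freqs(self) -> np.ndarray:
        cov = self.coverage
        with np.errstate(invalid="ignore"):
            return np.where(cov[:, None] > 0, self.counts / np.maximum(cov[:, None], 1), np.nan)

    def to_frame(self) -> pd.DataFrame:
        f = self.freqs
        rows = []
        for p in range(self.period):
            rows.append(
                (p + 1, *self.counts[p].tolist(), int(self.coverage[p]), *f[p].tolist())
            )
        return pd.DataFrame(
            rows,
            columns=["pos_1based"]
            + BASE_COLS
            + ["coverage"]
            + [f"freq_{b}" for b in BASE_COLS],
        )


def map_to_motif(
    read_id: str,
    sequence: str,
    motif: RepeatMotif,
    min_len: int = 30,
    max_div: float = 0.2,
) -> PhasedAlignment | None:
    """Wraparound (phased) alignment of a read on a tandem motif.

    The read is aligned semi-globally against the motif concatenated
    ceil(len/P)+1 times, both strands; the better strand wins and the
    alignment start modulo P is the phase.  Reads shorter than ``min_len``
    or with best edit-distance fraction above ``max_div`` return no hit.
    """
    P = motif.period
    if len(sequence) < min_len:
        return None
    target = motif.consensus * (math.ceil(len(sequence) / P) + 1)
    max_k = int(max_div * len(sequence))
    best = None
    for strand, query in (("+", sequence), ("-", revcomp(sequence))):
        res = edlib.align(query, target, mode="HW", task="path", k=max_k)
        if res["editDistance"] < 0:
            continue
        if best is None or res["editDistance"] < best[0]:
            s, _e = res["locations"][0]
            best = (res["editDistance"], strand, query, s, res["cigar"])
    if best is None:
        return None
    dist, strand, query, start, cigar = best
    return PhasedAlignment(
        read_id=read_id,
        phase=start % P,
        strand=strand,
        edit_distance=dist,
        cigar=cigar,
        aligned_query=query,
        target_start=start,
    )


def build_profile(
    alignments: Iterable[PhasedAlignment], motif: RepeatMotif, sample: str = "sample"
) -> RepeatProfile:
    """Tally every aligned base at its motif position (strand-resolved)."""
    P = motif.period
    counts = np.zeros((P, 4), dtype=np.int64)
    for aln in alignments:
        if aln is None:
            continue
        for qi, ti, op in cigar_pairs(aln.cigar, 0, aln.target_start):
            if qi is None or ti is None:
                continue
            col = BASE_TO_COL.get(aln.aligned_query[qi])
            if col is not None:
                counts[ti % P, col] += 1
    return RepeatProfile(sample=sample, period=P, counts=counts)


def compare_profiles(profiles: Sequence[RepeatProfile]) -> dict:
    """Cross-sample constancy report.

    Pairwise distance between two samples is the mean, over positions
    covered in both, of the total-variation distance (half the L1 norm)
    between their base-frequency vectors.  Also reports, per position
    covered in all samples, the maximum spread (max-min frequency over
    samples, maximised over bases).
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to compare")
    periods = {p.period for p in profiles}
    if len(periods) != 1:
        raise ValueError("profiles have differing periods")
    P = periods.pop()
    pair_rows = []
    for i in range(len(profiles)):
        for j in range(i + 1, len(profiles)):
            a, b = profiles[i], profiles[j]
            both = (a.coverage > 0) & (b.coverage > 0)
            if not both.any():
                pair_rows.append((a.sample, b.sample, np.nan, 0))
                continue
            tv = 0.5 * np.abs(a.freqs[both] - b.freqs[both]).sum(axis=1)
            pair_rows.append((a.sample, b.sample, float(tv.mean()), int(both.sum())))
    pairs = pd.DataFrame(
        pair_rows, columns=["sample_1", "sample_2", "mean_tv_distance", "n_positions"]
    )
    all_cov = np.all([p.coverage > 0 for p in profiles], axis=0)
    spread = np.full(P, np.nan)
    if all_cov.any():
        stack = np.stack([p.freqs for p in profiles])  # (S, P, 4)
        spread[all_cov] = (
            stack[:, all_cov].max(axis=0) - stack[:, all_cov].min(axis=0)
        ).max(axis=1)
    dists = pairs["mean_tv_distance"].dropna()
    return {
        "pairs": pairs,
        "mean_distance": float(dists.mean()) if len(dists) else np.nan,
        "max_distance": float(dists.max()) if len(dists) else np.nan,
        "per_position_max_spread": spread,
    }
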