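"""Small shared helpers: sequence ops, seeded RNG streams, cigar walking."""

from __future__ import annotations

import zlib

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Fixed adapter constant used by the simulator for read-through padding and
#: by the merger for exact-match trimming.  Illumina P7 prefix.
ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmer(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def child_rng(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-stage random stream.

    Stages of a simulation draw from independent generators derived from one
    master seed plus a fixed label, so a stage can be regenerated without
    replaying the stages before it.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(label.encode())])
    )


def parse_cigar(cigar: str):
    """Yield (count, op) pairs from an extended cigar string (=, X, I, D, M)."""
    n = 0
    for ch in cigar:
        if ch.isdigit():
            n = n * 10 + ord(ch) - 48
        else:
            yield n, ch
            n = 0


def cigar_pairs(cigar: str, q_start: int = 0, t_start: int = 0):
    """Yield (query_pos, target_pos, op) for every aligned column.

    For 'I' (query-only) target_pos is None; for 'D' (target-only) query_pos
    is None.  Follows edlib conventions: query is the read, target the
    reference.
    """
    qi, ti = q_start, t_start
    for n, op in parse_cigar(cigar):
        if op in "=XM":
            for _ in range(n):
                yield qi, ti, op
                qi += 1
                ti += 1
        elif op == "I":
            for _ in range(n):
                yield qi, None, op
                qi += 1
        elif op == "D":
            for _ in range(n):
                yield None, ti, op
                ti += 1
        else:  # pragma: no cover - edlib emits no other ops
            raise ValueError(f"unsupported cigar op {op!r}")
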