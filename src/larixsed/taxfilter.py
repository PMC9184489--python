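"""K-mer LCA read classification with a confidence threshold.

A deliberately small classifier in the KRAKEN mould: every canonical k-mer
of a reference set is assigned to the lowest common ancestor of the genomes
containing it in a user-supplied rooted taxonomy.  A read is classified to
the node whose root-to-node path collects the most k-mer support, and the
call is kept only when that support, as a fraction of *all* k-mers queried
(hits and misses alike), reaches the confidence threshold.  The study
setting is conservative: threshold 0.8, keeping only reads classified to
the target genus or below.

This is not a KRAKEN2 clone — no minimizers, no spaced seeds, and a
simpler confidence denominator; the semantics that matter downstream are
the LCA assignment and the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import canonical_kmer

UNCLASSIFIED = "unclassified"


class TaxonomyError(ValueError):
    pass


@dataclass
class Taxonomy:
    """Small rooted taxonomy as a child→parent map (root maps to itself)."""

    parent: dict[str, str]

    def __post_init__(self) -> None:
        roots = {n for n, p in self.parent.items() if p == n}
        if len(roots) != 1:
            raise TaxonomyError(f"taxonomy must have exactly one root, found {roots}")
        self.root = roots.pop()
        self._depth: dict[str, int] = {}
        for n in self.parent:
            self.path(n)  # validates connectivity, caches depth

    def path(self, node: str) -> list[str]:
        """Root-to-node path."""
        out = [node]
        seen = {node}
        while self.parent[out[-1]] != out[-1]:
            nxt = self.parent[out[-1]]
            if nxt in seen or nxt not in self.parent:
                raise TaxonomyError(f"broken parent chain at {node!r}")
            out.append(nxt)
            seen.add(nxt)
        out.reverse()
        self._depth[node] = len(out) - 1
        return out

    def depth(self, node: str) -> int:
        return self._depth[node]

    def lca(self, a: str, b: str) -> str:
        pa, pb = self.path(a), self.path(b)
        last = self.root
        for x, y in zip(pa, pb):
            if x != y:
                break
            last = x
        return last

    def is_descendant(self, node: str, ancestor: str) -> bool:
        return ancestor in self.path(node)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Taxonomy":
        parent = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            child, par = line.split("\t")
            parent[child] = par
        return cls(parent)


@dataclass
class KmerIndex:
    """Canonical k-mer → taxonomy node (LCA over source genomes)."""

    k: int
    entries: dict[str, str]
    taxonomy: Taxonomy

    def save(self, path: str | Path) -> None:
        """Sorted-text persistence: header line, then `kmer\\tnode` rows."""
        with open(path, "w") as fh:
            fh.write(f"#k={self.k}\n")
            for kmer in sorted(self.entries):
                fh.write(f"{kmer}\t{self.entries[kmer]}\n")

    @classmethod
    def load(cls, path: str | Path, taxonomy: Taxonomy) -> "KmerIndex":
        lines = Path(path).read_text().splitlines()
        k = int(lines[0].split("=", 1)[1])
        entries = dict(line.split("\t") for line in lines[1:] if line)
        return cls(k=k, entries=entries, taxonomy=taxonomy)


@dataclass
class TaxCall:
    """Classification of one read."""

    read_id: str
    label: str
    confidence: float
    n_support: int
    n_queried: int


def build_index(
    genomes: Iterable[tuple[str, str]],
    leaf_map: Mapping[str, str],
    taxonomy: Taxonomy,
    k: int = 25,
) -> KmerIndex:
    """Index labelled genomes: shared k-mers fall to the LCA of their sources.

    ``genomes`` yields (genome_id, sequence); ``leaf_map`` attaches each
    genome to a taxonomy leaf.  K-mers containing non-ACGT characters are
    skipped.  ``k`` must be odd (so a k-mer is never its own reverse
    complement) and within [15, 31].
    """
    if k % 2 == 0 or not 15 <= k <= 31:
        raise ValueError("k must be odd and in [15, 31]")
    entries: dict[str, str] = {}
    for gid, seq in genomes:
        if gid not in leaf_map:
            raise TaxonomyError(f"genome {gid!r} has no taxonomy leaf")
        node = leaf_map[gid]
        if node not in taxonomy.parent:
            raise TaxonomyError(f"leaf {node!r} not in taxonomy")
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if any(c not in "ACGT" for c in kmer):
                continue
            kmer = canonical_kmer(kmer)
            cur = entries.get(kmer)
            if cur is None:
                entries[kmer] = node
            elif cur != node:
                entries[kmer] = taxonomy.lca(cur, node)
    return KmerIndex(k=k, entries=entries, taxonomy=taxonomy)


def classify_read(
    read_id: str, sequence: str, index: KmerIndex, threshold: float = 0.8
) -> TaxCall:
    """Classify one sequence (a merged pair or single read).

    Support for a candidate node is the total k-mer count on its
    root-to-node path; the candidate maximising support wins, ties broken
    toward the root (the conservative, genus-over-leaf choice).  Confidence
    is support over all queried k-mers, and a call below the threshold is
    reported unclassified.
    """
    tax = index.taxonomy
    seq = sequence.upper()
    n_queried = max(0, len(seq) - index.k + 1)
    if n_queried == 0:
        return TaxCall(read_id, UNCLASSIFIED, 0.0, 0, 0)
    hits: dict[str, int] = {}
    for i in range(n_queried):
        kmer = seq[i : i + index.k]
        if any(c not in "ACGT" for c in kmer):
            continue
        node = index.entries.get(canonical_kmer(kmer))
        if node is not None:
            hits[node] = hits.get(node, 0) + 1
    if not hits:
        return TaxCall(read_id, UNCLASSIFIED, 0.0, 0, n_queried)
    support = {
        node: sum(hits.get(p, 0) for p in tax.path(node)) for node in hits
    }
    best = max(support.values())
    tied = [n for n, s in support.items() if s == best]
    label = tied[0]
    for other in tied[1:]:
        label = tax.lca(label, other)
    n_support = sum(hits.get(p, 0) for p in tax.path(label))
    confidence = n_support / n_queried
    if confidence < threshold:
        return TaxCall(read_id, UNCLASSIFIED, confidence, n_support, n_queried)
    return TaxCall(read_id, label, confidence, n_support, n_queried)


def filter_readset(
    reads: Sequence[tuple[str, str]],
    index: KmerIndex,
    threshold: float,
    target_node: str,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Keep reads classified to ``target_node`` or a descendant.

    Returns (kept reads, full TaxCall table).
    """
    tax = index.taxonomy
    kept = []
    calls = []
    for rid, seq in reads:
        call = classify_read(rid, seq, index, threshold)
        calls.append((call.read_id, call.label, call.confidence, call.n_support, call.n_queried))
        if call.label != UNCLASSIFIED and tax.is_descendant(call.label, target_node):
            kept.append((rid, seq))
    table = pd.DataFrame(
        calls, columns=["read_id", "label", "confidence", "n_support", "n_queried"]
    )
    return kept, table
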