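"""Reference panel handling and diagnostic-site discovery.

A *reference panel* is a set of labelled congeneric organelle genomes (here:
Larix chloroplasts assigned to the species groups ``gmelinii`` — including
L. cajanderi — and ``sibirica``).  One genome is declared the *anchor* and
defines the coordinate system.  All other genomes are aligned to the anchor
and columns at which the two species groups are fixed for different bases
are reported as *diagnostic sites*: a short sedimentary-aDNA read covering
such a site can be assigned to a species.

The anchoring strategy assumes collinear genomes (true for congeneric
chloroplasts): unique shared k-mers are chained by longest increasing
subsequence and the stretches between chained anchors are closed with
global edit-distance alignment.  Rearrangement-aware alignment is out of
scope by contract.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
from Bio import SeqIO

from ._util import parse_cigar

TRANSITIONS = ({"C", "T"}, {"A", "G"})


class PanelConfigError(ValueError):
    """A reference lacks a group label or the panel is otherwise mis-specified."""


class PanelInputError(ValueError):
    """Unusable input data (empty FASTA, degenerate sequence)."""


class AlignmentFailure(RuntimeError):
    """A genome could not be anchored to the coordinate-defining reference."""


@dataclass
class ReferenceGenome:
    """One labelled genome of the panel."""

    id: str
    group: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise PanelInputError(f"genome {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReferencePanel:
    """A set of reference genomes with unique ids and a declared label set."""

    genomes: list[ReferenceGenome]

    def __post_init__(self) -> None:
        ids = [g.id for g in self.genomes]
        if len(set(ids)) != len(ids):
            raise PanelConfigError("duplicate genome ids in panel")

    def __len__(self) -> int:
        return len(self.genomes)

    def __getitem__(self, genome_id: str) -> ReferenceGenome:
        for g in self.genomes:
            if g.id == genome_id:
                return g
        raise KeyError(genome_id)

    @property
    def groups(self) -> set[str]:
        return {g.group for g in self.genomes}

    def members(self, group: str) -> list[ReferenceGenome]:
        return [g for g in self.genomes if g.group == group]


@dataclass
class PanelAlignment:
    """Column-wise multi-alignment of a panel against its anchor genome.

    ``anchor_map[c]`` is the 0-based anchor position of column ``c`` or -1
    for columns that are insertions relative to the anchor.
    """

    anchor_id: str
    ids: list[str]
    rows: list[str]
    anchor_map: list[int]
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError("ragged alignment rows")
        anchor_row = self.rows[self.ids.index(self.anchor_id)]
        if "-" in {anchor_row[c] for c, p in enumerate(self.anchor_map) if p >= 0}:
            raise ValueError("anchor row gapped at an anchor-mapped column")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def anchor_sequence(self) -> str:
        """Anchor row with gaps removed; must equal the input anchor."""
        row = self.rows[self.ids.index(self.anchor_id)]
        return row.replace("-", "")

    def column(self, c: int) -> str:
        return "".join(row[c] for row in self.rows)


@dataclass
class DiagnosticSiteTable:
    """Fixed single-nucleotide differences between two species groups.

    Coordinates are 0-based anchor positions internally; emitted tables are
    1-based.  ``allele_a`` is fixed in ``group_a``, ``allele_b`` in
    ``group_b``; transition sites ({C,T} or {A,G}) are flagged because
    post-mortem deamination can mimic them.
    """

    group_a: str
    group_b: str
    sites: pd.DataFrame  # columns: anchor_pos, allele_a, allele_b, is_transition

    COLUMNS = ["anchor_pos", "allele_a", "allele_b", "is_transition"]

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)[self.COLUMNS]
        pos = self.sites["anchor_pos"]
        if not pos.is_monotonic_increasing or pos.duplicated().any():
            raise ValueError("diagnostic sites must be strictly increasing")

    def __len__(self) -> int:
        return len(self.sites)

    def positions(self) -> list[int]:
        return self.sites["anchor_pos"].tolist()

    def to_tsv(self, path: str | Path) -> None:
        out = self.sites.copy()
        out["anchor_pos_1based"] = out.pop("anchor_pos") + 1
        out = out.rename(
            columns={"allele_a": f"allele_{self.group_a}", "allele_b": f"allele_{self.group_b}"}
        )
        cols = ["anchor_pos_1based", f"allele_{self.group_a}", f"allele_{self.group_b}", "is_transition"]
        out[cols].to_csv(path, sep="\t", index=False, lineterminator="\n")

    @classmethod
    def from_records(cls, group_a: str, group_b: str, records: Iterable[tuple]) -> "DiagnosticSiteTable":
        df = pd.DataFrame(records, columns=["anchor_pos", "allele_a", "allele_b"])
        df["is_transition"] = [
            is_transition(a, b) for a, b in zip(df["allele_a"], df["allele_b"])
        ]
        return cls(group_a, group_b, df)


def is_transition(a: str, b: str) -> bool:
    return {a, b} in TRANSITIONS


# ---------------------------------------------------------------------------
# panel construction


def read_label_map(path: str | Path) -> dict[str, str]:
    """Read a two-column (id, group) TSV into a label map."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise PanelConfigError(f"label map line not two columns: {line!r}")
        out[fields[0]] = fields[1]
    return out


def build_panel(
    fasta_paths: Sequence[str | Path],
    label_map: Mapping[str, str],
    circular: bool = True,
    max_ambiguous_frac: float = 0.05,
) -> ReferencePanel:
    """Load labelled reference genomes from multi-FASTA files.

    Sequences are uppercased and U is normalised to T.  Records whose id is
    missing from ``label_map`` raise :class:`PanelConfigError`; records with
    more than ``max_ambiguous_frac`` non-ACGT characters are rejected with
    :class:`PanelInputError`.
    """
    genomes: list[ReferenceGenome] = []
    for path in fasta_paths:
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise PanelInputError(f"no FASTA records in {path}")
        for rec in records:
            if rec.id not in label_map:
                raise PanelConfigError(f"no group label for FASTA record {rec.id!r}")
            seq = str(rec.seq).upper().replace("U", "T")
            if not seq:
                raise PanelInputError(f"record {rec.id!r} is empty")
            n_bad = sum(seq.count(c) for c in set(seq) - set("ACGT"))
            if n_bad / len(seq) > max_ambiguous_frac:
                raise PanelInputError(
                    f"record {rec.id!r}: {n_bad}/{len(seq)} non-ACGT characters"
                )
            genomes.append(ReferenceGenome(rec.id, label_map[rec.id], seq, circular))
    return ReferencePanel(genomes)


# ---------------------------------------------------------------------------
# anchoring


_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i


def _unique_kmers(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit-packed k-mers occurring exactly once (ACGT only).

    Returns (values, positions), sorted by value.  Requires k <= 31 so a
    k-mer packs into a uint64.
    """
    if k > 31:
        raise ValueError("anchoring k must be <= 31")
    arr = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(arr, k)
    valid = np.lib.stride_tricks.sliding_window_view(arr < 4, k).all(axis=1)
    pows = 4 ** np.arange(k - 1, -1, -1, dtype=np.uint64)
    vals = (win.astype(np.uint64) * pows).sum(axis=1, dtype=np.uint64)
    idx = np.flatnonzero(valid)
    order = np.argsort(vals[idx], kind="stable")
    sv = vals[idx][order]
    keep = np.ones(len(sv), dtype=bool)
    dup = sv[1:] == sv[:-1]
    keep[1:][dup] = False
    keep[:-1][dup] = False
    return sv[keep], idx[order][keep]


def _shared_matches(
    a_uniq: tuple[np.ndarray, np.ndarray], o_uniq: tuple[np.ndarray, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """(anchor_pos, other_pos) arrays for k-mers unique in both, sorted by
    anchor position."""
    av, ap = a_uniq
    ov, op = o_uniq
    _, ia, io = np.intersect1d(av, ov, assume_unique=True, return_indices=True)
    order = np.argsort(ap[ia], kind="stable")
    return ap[ia][order], op[io][order]


def _chain_matches(apos: np.ndarray, gpos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Longest collinear chain over (anchor, other) match positions.

    Fast path: a fully increasing match list (the collinear common case)
    chains as-is; otherwise the longest strictly-increasing subsequence of
    the other-genome positions is taken.
    """
    if len(apos) == 0:
        return apos, gpos
    if np.all(np.diff(gpos) > 0):
        return apos, gpos
    chain = _lis_chain(list(zip(apos.tolist(), gpos.tolist())))
    arr = np.asarray(chain, dtype=np.int64)
    return arr[:, 0], arr[:, 1]


def _lis_chain(matches: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest chain strictly increasing in both coordinates.

    ``matches`` must be sorted by the first coordinate (all first coordinates
    distinct, as unique-k-mer matches are).  Patience sorting on the second
    coordinate, O(n log n).
    """
    if not matches:
        return []
    tails: list[int] = []  # tails[l] = min possible end gpos of a chain of length l+1
    tail_idx: list[int] = []
    prev = [-1] * len(matches)
    for i, (_, g) in enumerate(matches):
        j = bisect.bisect_left(tails, g)
        if j == len(tails):
            tails.append(g)
            tail_idx.append(i)
        else:
            tails[j] = g
            tail_idx[j] = i
        prev[i] = tail_idx[j - 1] if j > 0 else -1
    chain = []
    i = tail_idx[-1]
    while i >= 0:
        chain.append(matches[i])
        i = prev[i]
    return chain[::-1]


def _compress_chain(apos: np.ndarray, gpos: np.ndarray) -> list[tuple[int, int]]:
    """Keep only run boundaries of constant-diagonal stretches."""
    if len(apos) <= 2:
        return list(zip(apos.tolist(), gpos.tolist()))
    diag = gpos - apos
    keep = np.zeros(len(apos), dtype=bool)
    keep[0] = keep[-1] = True
    keep[1:-1] = diag[1:-1] != diag[:-2]
    return list(zip(apos[keep].tolist(), gpos[keep].tolist()))


def _pairwise_align(
    anchor: str, other: str, k: int, min_anchors: int, name: str,
    a_uniq=None, o_uniq=None,
):
    """Align ``other`` to ``anchor`` by unique k-mer chaining + gap closure.

    Returns (aligned_anchor, aligned_other) strings of equal length.
    ``a_uniq``/``o_uniq`` let the caller reuse unique k-mer tables.
    """
    if a_uniq is None:
        a_uniq = _unique_kmers(anchor, k)
    if o_uniq is None:
        o_uniq = _unique_kmers(other, k)
    apos, gpos = _chain_matches(*_shared_matches(a_uniq, o_uniq))
    if len(apos) < min_anchors:
        raise AlignmentFailure(
            f"genome {name!r}: only {len(apos)} chained anchors (need {min_anchors})"
        )
    chain = _compress_chain(apos, gpos)
    out_a: list[str] = []
    out_o: list[str] = []

    def close(a_seg: str, o_seg: str) -> None:
        if not a_seg and not o_seg:
            return
        if not o_seg:
            out_a.append(a_seg)
            out_o.append("-" * len(a_seg))
            return
        if not a_seg:
            out_a.append("-" * len(o_seg))
            out_o.append(o_seg)
            return
        if a_seg == o_seg:
            out_a.append(a_seg)
            out_o.append(o_seg)
            return
        res = edlib.align(o_seg, a_seg, mode="NW", task="path")
        if len(a_seg) == len(o_seg):
            # prefer the substitution-only form when it ties the optimum:
            # adjacent substitutions otherwise surface as spurious indels
            hamming = sum(a != b for a, b in zip(a_seg, o_seg))
            if hamming == res["editDistance"]:
                out_a.append(a_seg)
                out_o.append(o_seg)
                return
        ai = oi = 0
        for n, op in parse_cigar(res["cigar"]):
            if op in "=XM":
                out_a.append(a_seg[ai : ai + n])
                out_o.append(o_seg[oi : oi + n])
                ai += n
                oi += n
            elif op == "D":  # in target (anchor) only
                out_a.append(a_seg[ai : ai + n])
                out_o.append("-" * n)
                ai += n
            else:  # 'I': in query (other) only
                out_a.append("-" * n)
                out_o.append(o_seg[oi : oi + n])
                oi += n

    pa = po = 0
    for am, om in chain:
        close(anchor[pa:am], other[po:om])
        pa, po = am, om
    close(anchor[pa:], other[po:])
    return "".join(out_a), "".join(out_o)


def _best_rotation(anchor: str, other: str, k: int, a_uniq=None, o_uniq=None) -> int:
    """Rotation offset aligning a circular genome to the anchor's origin.

    The modal difference (other_pos - anchor_pos) mod len(other) over unique
    shared k-mers; 0 when no shared k-mers exist (caller will then fail with
    an anchoring error).
    """
    if a_uniq is None:
        a_uniq = _unique_kmers(anchor, k)
    if o_uniq is None:
        o_uniq = _unique_kmers(other, k)
    apos, gpos = _shared_matches(a_uniq, o_uniq)
    if len(apos) == 0:
        return 0
    diffs = (gpos - apos) % len(other)
    vals, counts = np.unique(diffs, return_counts=True)
    return int(vals[np.argmax(counts)])


def align_to_anchor(
    panel: ReferencePanel,
    anchor_id: str,
    k: int = 21,
    min_anchors: int = 10,
) -> PanelAlignment:
    """Column-wise alignment of every panel genome against the anchor.

    Circular genomes are first rotated to the anchor's origin (modal unique
    k-mer offset), then anchored by chained unique shared k-mers with the
    inter-anchor stretches closed by global edit-distance alignment.
    Pairwise alignments are merged on anchor coordinates; insertions of
    different genomes at the same anchor gap are left-aligned and padded,
    not aligned to each other (they can never yield diagnostic sites).
    """
    anchor = panel[anchor_id]
    others = [g for g in panel.genomes if g.id != anchor_id]

    # per-genome: base aligned to each anchor position ('-' = deletion),
    # plus insertion strings keyed by the anchor position they follow
    # (-1 = before the first anchor base).
    per_base: dict[str, str] = {}
    per_ins: dict[str, dict[int, str]] = {}
    L = len(anchor.sequence)
    a_uniq = _unique_kmers(anchor.sequence, k)
    def _chain_len(o_uniq) -> int:
        apos, gpos = _chain_matches(*_shared_matches(a_uniq, o_uniq))
        return len(apos)

    for g in others:
        seq = g.sequence
        o_uniq = _unique_kmers(seq, k)
        if g.circular:
            r = _best_rotation(anchor.sequence, seq, k, a_uniq, o_uniq)
            if r:
                # rotate only if it genuinely lengthens the collinear chain:
                # small modal offsets are indel shifts, not origin differences
                rot = seq[r:] + seq[:r]
                rot_uniq = _unique_kmers(rot, k)
                if _chain_len(rot_uniq) > _chain_len(o_uniq):
                    seq, o_uniq = rot, rot_uniq
        arow, orow = _pairwise_align(
            anchor.sequence, seq, k, min_anchors, g.id, a_uniq, o_uniq
        )
        if len(arow) == L and "-" not in arow:
            # substitution-only alignment: columns are anchor positions as-is
            per_base[g.id] = orow
            per_ins[g.id] = {}
            continue
        bases: list[str] = [""] * L
        ins: dict[int, str] = {}
        apos = -1
        pending: list[str] = []
        for ac, oc in zip(arow, orow):
            if ac == "-":
                pending.append(oc)
            else:
                if pending:
                    ins[apos] = "".join(pending)
                    pending = []
                apos += 1
                bases[apos] = oc
        if pending:
            ins[apos] = "".join(pending)
        per_base[g.id] = "".join(bases)
        per_ins[g.id] = ins

    ids = [anchor_id] + [g.id for g in others]
    if not any(per_ins[g.id] for g in others):
        rows = [anchor.sequence] + [per_base[g.id] for g in others]
        anchor_map = list(range(L))
    else:
        cols_per_row: dict[str, list[str]] = {i: [] for i in ids}
        anchor_map = []

        def emit_insertions(apos: int) -> None:
            width = max((len(per_ins[g.id].get(apos, "")) for g in others), default=0)
            if width == 0:
                return
            cols_per_row[anchor_id].append("-" * width)
            for g in others:
                s = per_ins[g.id].get(apos, "")
                cols_per_row[g.id].append(s + "-" * (width - len(s)))
            anchor_map.extend([-1] * width)

        emit_insertions(-1)
        for p in range(L):
            cols_per_row[anchor_id].append(anchor.sequence[p])
            for g in others:
                cols_per_row[g.id].append(per_base[g.id][p])
            anchor_map.append(p)
            emit_insertions(p)

        rows = ["".join(cols_per_row[i]) for i in ids]
    aln = PanelAlignment(
        anchor_id=anchor_id,
        ids=ids,
        rows=rows,
        anchor_map=anchor_map,
        groups={g.id: g.group for g in panel.genomes},
    )
    assert aln.anchor_sequence() == anchor.sequence
    return aln


# ---------------------------------------------------------------------------
# diagnostic sites


def call_diagnostic_sites(
    aln: PanelAlignment, group_a: str, group_b: str
) -> DiagnosticSiteTable:
    """Anchor-mapped columns fixed for different bases between two groups.

    A column yields a site iff it maps to an anchor position, no row carries
    a gap or N, every group-A row shares one base, every group-B row shares
    another, and the two bases differ.  Indel and ambiguous columns are
    never diagnostic: the caller targets point differences usable on reads
    as short as 30 bp.
    """
    idx_a = [i for i, gid in enumerate(aln.ids) if aln.groups.get(gid) == group_a]
    idx_b = [i for i, gid in enumerate(aln.ids) if aln.groups.get(gid) == group_b]
    if not idx_a or not idx_b:
        raise PanelConfigError(f"empty group among {group_a!r}, {group_b!r}")
    mat = np.stack([np.frombuffer(r.encode(), dtype=np.uint8) for r in aln.rows])
    amap = np.asarray(aln.anchor_map)
    clean = ~((mat == ord("-")) | (mat == ord("N"))).any(axis=0)
    fixed_a = (mat[idx_a] == mat[idx_a[0]]).all(axis=0)
    fixed_b = (mat[idx_b] == mat[idx_b[0]]).all(axis=0)
    differs = mat[idx_a[0]] != mat[idx_b[0]]
    sel = np.flatnonzero((amap >= 0) & clean & fixed_a & fixed_b & differs)
    records = [
        (int(amap[c]), chr(mat[idx_a[0], c]), chr(mat[idx_b[0], c])) for c in sel
    ]
    records.sort()
    return DiagnosticSiteTable.from_records(group_a, group_b, records)


def write_alignment_fasta(aln: PanelAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid, row in zip(aln.ids, aln.rows):
            fh.write(f">{gid}\n{row}\n")
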