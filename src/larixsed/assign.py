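"""Read mapping against the anchor genome and per-site species assignment.

Genus-filtered fragments are aligned semi-globally (free end-gaps on the
reference) against the anchor chloroplast genome, deduplicated, and read
bases observed at the diagnostic sites.  Each read with at least one
informative observation is assigned to a species by majority vote over its
covered sites; per-site counts and per-sample species totals form the
assignment matrix (percentage of reads per species at every diagnostic
position, plus per-sample totals).

Deamination can mimic the derived allele at transition-diagnostic sites
(C→T / G→A), so an optional damage filter masks transition-site
observations within a few bases of a fragment terminus.  It is off by
default; the bias-reduction property is demonstrated in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
import pandas as pd

from ._util import ADAPTER, cigar_pairs, parse_cigar, revcomp
from .refpanel import DiagnosticSiteTable, ReferenceGenome


@dataclass
class AssignOptions:
    """Knobs of the assignment stage.

    ``min_len`` follows the study's 30 bp minimum usable molecule length;
    ``max_div`` admits terminal damage plus residual divergence on short
    reads; ``mask_m`` is the terminal mask width applied to
    transition-site observations when ``mask_on``.
    """

    min_len: int = 30
    max_div: float = 0.1
    mask_m: int = 5
    mask_on: bool = False
    per_read_rule: str = "majority"


@dataclass
class ReadAlignment:
    """Semi-global alignment of one fragment on the anchor."""

    read_id: str
    ref_id: str
    start: int  # 0-based half-open on the anchor
    end: int
    strand: str
    cigar: str
    n_mismatches: int
    aligned_len: int
    aligned_query: str  # reference-oriented fragment sequence
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("empty alignment span")


@dataclass
class MergeResult:
    merged: list[tuple[str, str]] = field(default_factory=list)
    unmerged: list[tuple[str, str, str]] = field(default_factory=list)
    discarded: list[str] = field(default_factory=list)  # empty-insert read ids


@dataclass
class SiteObservation:
    read_id: str
    anchor_pos: int
    observed_base: str
    call: str  # group_a label, group_b label, or "other"
    is_transition_site: bool
    dist_to_end: int


# ---------------------------------------------------------------------------
# pair merging


def _trim_adapter(seq: str, adapter: str) -> str:
    """Trim adapter read-through by exact match.

    Cuts at the first occurrence of the 10 bp adapter prefix; failing that,
    removes the longest read suffix that exactly equals an adapter prefix
    (read-through shorter than the probe).  A chance suffix match on a
    long insert only shortens the overlap the merger sees; the mate still
    covers the trimmed bases.
    """
    probe = adapter[:10]
    i = seq.find(probe)
    if i >= 0:
        return seq[:i]
    for l in range(min(len(adapter), len(seq) - 1), 0, -1):
        if seq.endswith(adapter[:l]):
            return seq[: len(seq) - l]
    return seq


def merge_pairs(
    pairs: Iterable[tuple[str, str, str]],
    min_overlap: int = 11,
    max_mismatch_frac: float = 0.1,
    adapter: str = ADAPTER,
) -> MergeResult:
    """Overlap-merge read pairs into fragments.

    For each (read_id, mate1, mate2): adapter read-through is trimmed by
    exact adapter match, then the longest suffix of mate 1 matching a
    prefix of the reverse-complemented mate 2 with at most
    ``max_mismatch_frac`` mismatches and length >= ``min_overlap`` is
    collapsed (mate-1 base kept at conflicts; qualities are not modelled).
    Pairs with no admissible overlap stay unmerged; zero-length inserts
    (adapter-only mates) are discarded.
    """
    res = MergeResult()
    for rid, m1, m2 in pairs:
        t1 = _trim_adapter(m1, adapter)
        r2 = revcomp(_trim_adapter(m2, adapter))
        if not t1 or not r2:
            res.discarded.append(rid)
            continue
        merged = None
        for o in range(min(len(t1), len(r2)), min_overlap - 1, -1):
            tail = t1[-o:]
            head = r2[:o]
            mism = sum(a != b for a, b in zip(tail, head))
            if mism <= max_mismatch_frac * o:
                merged = t1 + r2[o:]
                break
        if merged is None:
            res.unmerged.append((rid, m1, m2))
        else:
            res.merged.append((rid, merged))
    return res


# ---------------------------------------------------------------------------
# mapping


def _span_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def _refine_alignment(
    query: str, ref: str, start: int, end: int
) -> tuple[str, int, int, int]:
    """Re-anchor an imperfect free-end-gap hit with global alignment.

    Free end-gaps make a substitution at the very first or last read base
    tie in cost with shifting the reference span by one (the substituted
    base becomes an insertion, or pairs a matching neighbour while the
    true reference base is deleted).  Either form hides exactly the
    terminal substitutions the deamination profile measures.  Global
    alignment over candidate windows with the span ends jittered by ±1
    strictly prefers the mismatch form (an indel pair costs 2); ties go to
    the window with fewest indel columns.  ``end`` half-open; returns
    (cigar, start, end, edit_distance).
    """
    best = None
    for ds in (0, -1, 1):
        for de in (0, 1, -1):
            s, e = start + ds, end + de
            if s < 0 or e > len(ref) or e <= s:
                continue
            res = edlib.align(query, ref[s:e], mode="NW", task="path")
            n_indel = sum(n for n, op in parse_cigar(res["cigar"]) if op in "ID")
            key = (res["editDistance"], n_indel, abs(ds) + abs(de))
            if best is None or key < best[0]:
                best = (key, res["cigar"], s, e)
    key, cigar, s, e = best
    return cigar, s, e, key[0]


def map_reads(
    fragments: Iterable[tuple[str, str]],
    anchor: ReferenceGenome,
    opts: AssignOptions | None = None,
) -> tuple[list[ReadAlignment], dict]:
    """Semi-global mapping of fragments on the anchor genome.

    Both strands are tried and the lower edit distance kept; alignments
    above ``max_div`` edit-distance fraction are dropped, fragments shorter
    than ``min_len`` are dropped and counted, and fragments with optimal
    hits at more than one locus are flagged ambiguous (excluded from site
    calling: chloroplast repeats would otherwise inject false calls).
    Returns (alignments, stage counts).
    """
    opts = opts or AssignOptions()
    ref = anchor.sequence
    out: list[ReadAlignment] = []
    counts = {"input": 0, "too_short": 0, "unmapped": 0, "mapped": 0, "ambiguous": 0}
    for rid, seq in fragments:
        counts["input"] += 1
        if len(seq) < opts.min_len:
            counts["too_short"] += 1
            continue
        max_k = int(opts.max_div * len(seq))
        best = None
        for strand, query in (("+", seq), ("-", revcomp(seq))):
            res = edlib.align(query, ref, mode="HW", task="locations", k=max_k)
            if res["editDistance"] < 0:
                continue
            if best is None or res["editDistance"] < best[0]:
                best = (res["editDistance"], strand, query, res["locations"])
            elif res["editDistance"] == best[0]:
                best = (best[0], best[1], best[2], best[3] + res["locations"])
        if best is None:
            counts["unmapped"] += 1
            continue
        dist, strand, query, locations = best
        spans = []
        for s, e in locations:
            span = (s, e)
            if not any(_span_overlap(span, sp) for sp in spans):
                spans.append(span)
        ambiguous = len(spans) > 1
        path = edlib.align(query, ref, mode="HW", task="path", k=max_k)
        (s, e) = path["locations"][0]
        if path["editDistance"] == 0:
            cigar, e = path["cigar"], e + 1
        else:
            cigar, s, e, _ = _refine_alignment(query, ref, s, e + 1)
        n_mm = sum(n for n, op in parse_cigar(cigar) if op == "X")
        aln = ReadAlignment(
            read_id=rid,
            ref_id=anchor.id,
            start=s,
            end=e,
            strand=strand,
            cigar=cigar,
            n_mismatches=n_mm,
            aligned_len=len(query),
            aligned_query=query,
            ambiguous=ambiguous,
        )
        counts["ambiguous" if ambiguous else "mapped"] += 1
        out.append(aln)
    return out, counts


def deduplicate(alignments: Sequence[ReadAlignment]) -> tuple[list[ReadAlignment], int]:
    """Collapse alignments identical in (span, strand, sequence).

    Keeps the first representative of each key; idempotent.  Returns
    (kept, number removed).
    """
    seen = set()
    kept = []
    for aln in alignments:
        key = (aln.ref_id, aln.start, aln.end, aln.strand, aln.aligned_query)
        if key in seen:
            continue
        seen.add(key)
        kept.append(aln)
    return kept, len(alignments) - len(kept)


# ---------------------------------------------------------------------------
# site observation and aggregation


def observe_sites(
    alignment: ReadAlignment,
    sites: DiagnosticSiteTable,
    opts: AssignOptions | None = None,
) -> list[SiteObservation]:
    """Read bases at diagnostic sites covered by one alignment.

    Sites under a deletion in the read emit nothing.  ``dist_to_end`` is
    the distance of the observed base to the nearer fragment terminus.
    Ambiguous alignments are excluded upstream.
    """
    if alignment.ambiguous:
        return []
    df = sites.sites
    in_span = df[(df["anchor_pos"] >= alignment.start) & (df["anchor_pos"] < alignment.end)]
    if in_span.empty:
        return []
    wanted = dict(zip(in_span["anchor_pos"], zip(in_span["allele_a"], in_span["allele_b"], in_span["is_transition"])))
    out = []
    qlen = len(alignment.aligned_query)
    for qi, ti, op in cigar_pairs(alignment.cigar, 0, alignment.start):
        if ti is None or ti not in wanted:
            continue
        if qi is None:  # deletion over the site
            continue
        allele_a, allele_b, is_tr = wanted[ti]
        base = alignment.aligned_query[qi]
        if base == allele_a:
            call = sites.group_a
        elif base == allele_b:
            call = sites.group_b
        else:
            call = "other"
        out.append(
            SiteObservation(
                read_id=alignment.read_id,
                anchor_pos=ti,
                observed_base=base,
                call=call,
                is_transition_site=bool(is_tr),
                dist_to_end=min(qi, qlen - 1 - qi),
            )
        )
    return out


def damage_filter(
    observations: Sequence[SiteObservation], opts: AssignOptions
) -> tuple[list[SiteObservation], int]:
    """Mask transition-site observations near fragment termini.

    When ``opts.mask_on``, observations at transition-diagnostic sites
    closer than ``mask_m`` bp to either fragment end are dropped (they are
    confoundable with deamination).  Returns (kept, number masked).
    """
    if not opts.mask_on or opts.mask_m <= 0:
        return list(observations), 0
    kept = [
        o
        for o in observations
        if not (o.is_transition_site and o.dist_to_end < opts.mask_m)
    ]
    return kept, len(observations) - len(kept)


@dataclass
class SpeciesAssignmentMatrix:
    """Per-site counts and per-sample species totals (the reporting object).

    ``per_site``: sample, anchor_pos, n_a, n_b, n_other, coverage, pct_a,
    pct_b.  ``totals``: sample, reads_a, reads_b, reads_unassigned, where a
    read's species is the majority of its informative site calls.
    """

    group_a: str
    group_b: str
    per_site: pd.DataFrame
    totals: pd.DataFrame

    def to_tsv(self, site_path, totals_path) -> None:
        site = self.per_site.copy()
        site["anchor_pos_1based"] = site.pop("anchor_pos") + 1
        cols = ["sample", "anchor_pos_1based", "n_a", "n_b", "n_other", "coverage", "pct_a", "pct_b"]
        site[cols].to_csv(site_path, sep="\t", index=False, lineterminator="\n", float_format="%.2f")
        self.totals.to_csv(totals_path, sep="\t", index=False, lineterminator="\n")


def _round_half_up(x: float, ndigits: int = 2) -> float:
    import decimal

    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def aggregate(
    observations: Sequence[SiteObservation],
    sites: DiagnosticSiteTable,
    sample: str = "sample",
    per_read_rule: str = "majority",
) -> SpeciesAssignmentMatrix:
    """Tally observations into the per-site/per-sample assignment matrix.

    Per-read species is the majority over that read's informative calls
    ("other" ignored); ties and zero informative calls leave the read
    unassigned.  Per-site percentages are over A+B+other coverage, rounded
    half-up to 2 decimals.
    """
    if per_read_rule != "majority":
        raise ValueError(f"unknown per-read rule {per_read_rule!r}")
    ga, gb = sites.group_a, sites.group_b
    site_rows: dict[int, list[int]] = {}
    per_read: dict[str, list[int]] = {}
    for o in observations:
        row = site_rows.setdefault(o.anchor_pos, [0, 0, 0])
        votes = per_read.setdefault(o.read_id, [0, 0])
        if o.call == ga:
            row[0] += 1
            votes[0] += 1
        elif o.call == gb:
            row[1] += 1
            votes[1] += 1
        else:
            row[2] += 1
    recs = []
    for pos in sorted(site_rows):
        n_a, n_b, n_other = site_rows[pos]
        cov = n_a + n_b + n_other
        recs.append(
            (
                sample,
                pos,
                n_a,
                n_b,
                n_other,
                cov,
                _round_half_up(100.0 * n_a / cov),
                _round_half_up(100.0 * n_b / cov),
            )
        )
    per_site = pd.DataFrame(
        recs,
        columns=["sample", "anchor_pos", "n_a", "n_b", "n_other", "coverage", "pct_a", "pct_b"],
    )
    reads_a = reads_b = unassigned = 0
    for va, vb in per_read.values():
        if va > vb:
            reads_a += 1
        elif vb > va:
            reads_b += 1
        else:
            unassigned += 1
    totals = pd.DataFrame(
        [(sample, reads_a, reads_b, unassigned)],
        columns=["sample", "reads_a", "reads_b", "reads_unassigned"],
    )
    return SpeciesAssignmentMatrix(ga, gb, per_site, totals)


def screen_controls(
    sample_matrix: SpeciesAssignmentMatrix,
    control_matrix: SpeciesAssignmentMatrix,
    mode: str = "report",
) -> tuple[SpeciesAssignmentMatrix, pd.DataFrame]:
    """Compare a sample matrix against its negative-control matrix.

    ``mode="report"`` leaves the sample untouched; ``mode="subtract"``
    reduces each per-site count by the control's count at the same
    position.  Both return a per-site delta summary (positions where the
    control has any coverage).  The study's finding — excluding control
    sequences does not change the patterns — is checkable by comparing the
    two modes.
    """
    if mode not in ("report", "subtract"):
        raise ValueError(f"unknown mode {mode!r}")
    ctrl = control_matrix.per_site.set_index("anchor_pos")
    samp = sample_matrix.per_site.copy()
    deltas = []
    count_cols = ["n_a", "n_b", "n_other"]
    for i, row in samp.iterrows():
        pos = row["anchor_pos"]
        if pos not in ctrl.index:
            continue
        c = ctrl.loc[pos]
        removed = {col: int(min(row[col], c[col])) for col in count_cols}
        deltas.append((pos, removed["n_a"], removed["n_b"], removed["n_other"]))
        if mode == "subtract":
            for col in count_cols:
                samp.at[i, col] = int(row[col]) - removed[col]
    delta = pd.DataFrame(deltas, columns=["anchor_pos", "removed_a", "removed_b", "removed_other"])
    if mode == "subtract":
        samp["coverage"] = samp["n_a"] + samp["n_b"] + samp["n_other"]
        samp = samp[samp["coverage"] > 0].reset_index(drop=True)
        samp["pct_a"] = [
            _round_half_up(100.0 * a / c) for a, c in zip(samp["n_a"], samp["coverage"])
        ]
        samp["pct_b"] = [
            _round_half_up(100.0 * b / c) for b, c in zip(samp["n_b"], samp["coverage"])
        ]
        out = SpeciesAssignmentMatrix(
            sample_matrix.group_a, sample_matrix.group_b, samp, sample_matrix.totals
        )
    else:
        out = sample_matrix
    return out, delta


# ---------------------------------------------------------------------------
# SAM emission


def write_sam(
    alignments: Sequence[ReadAlignment], anchor: ReferenceGenome, path
) -> None:
    """Minimal SAM output (0x10 flag on minus-strand alignments)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{anchor.id}\tLN:{len(anchor.sequence)}\n")
        for a in alignments:
            flag = 16 if a.strand == "-" else 0
            cigar = "".join(
                f"{n}{'M' if op in '=X' else op}" for n, op in parse_cigar(a.cigar)
            )
            fh.write(
                f"{a.read_id}\t{flag}\t{a.ref_id}\t{a.start + 1}\t255\t{cigar}\t*\t0\t0\t"
                f"{a.aligned_query}\t*\tNM:i:{a.n_mismatches}\n"
            )
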