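"""Truth-labelled synthetic data with the structure the pipeline assumes.

The generator emulates target-enriched sedimentary ancient DNA: short
fragments (lognormal length, truncated to 20–500 bp, 30 bp being the
downstream usable minimum), terminal C→T / G→A deamination decaying
exponentially into the fragment, uniform sequencing error, 2×250 bp
paired-end reads with adapter read-through on short inserts, PCR
duplicates, species mixtures over a reference panel, tandem arrays of a
~173 bp satellite motif, and divergent non-target background.  Every
emitted read id resolves to a truth record.

All randomness flows from one master seed through labelled child streams
(:func:`larixsed._util.child_rng`), so each stage is reproducible on its
own and a fixed seed yields byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import ADAPTER, child_rng, revcomp
from .damage import DamageParams
from .refpanel import DiagnosticSiteTable, ReferenceGenome, ReferencePanel

BASES = np.array(list("ACGT"))


@dataclass
class FragLenDist:
    """Lognormal fragment-length distribution truncated to [lo, hi] bp."""

    mean_log: float = np.log(75.0)
    sd_log: float = 0.35
    lo: int = 20
    hi: int = 500

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        out = np.empty(n, dtype=np.int64)
        filled = 0
        while filled < n:
            draw = np.rint(rng.lognormal(self.mean_log, self.sd_log, size=n)).astype(np.int64)
            keep = draw[(draw >= self.lo) & (draw <= self.hi)][: n - filled]
            out[filled : filled + len(keep)] = keep
            filled += len(keep)
        return out


@dataclass
class Fragment:
    """One simulated molecule with its truth provenance."""

    read_id: str
    sequence: str
    source_id: str
    group: str
    start: int  # 0-based on the source genome
    strand: str
    n_damage_5p: int = 0
    n_damage_3p: int = 0
    is_duplicate: bool = False


@dataclass
class SimulationConfig:
    """Study conditions for one simulated sample."""

    seed: int = 0
    n_fragments: int = 2000
    mixture: dict = field(default_factory=lambda: {"gmelinii": 0.7, "sibirica": 0.3})
    frag_len: FragLenDist = field(default_factory=FragLenDist)
    damage: DamageParams = field(default_factory=lambda: DamageParams(d0=0.3, lam=0.3, e=0.01))
    seq_error: float = 0.001
    read_len: int = 250
    duplicate_rate: float = 0.0
    background_frac: float = 0.0
    repeat_spec: tuple = (173, 200, 0.05)  # (motif length, copies, divergence)

    def __post_init__(self) -> None:
        if isinstance(self.damage, dict):
            self.damage = DamageParams(**self.damage)
        if isinstance(self.frag_len, dict):
            self.frag_len = FragLenDist(**self.frag_len)
        if isinstance(self.repeat_spec, list):
            self.repeat_spec = tuple(self.repeat_spec)
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture proportions sum to {total}, not 1")
        for r in (self.seq_error, self.duplicate_rate, self.background_frac):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate {r} outside [0, 1]")

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# reference panels with implanted truth


def generate_panel(
    n_per_group: Mapping[str, int],
    genome_len: int,
    n_sites: int,
    within_group_snps: int = 0,
    seed: int = 0,
    circular: bool = True,
) -> tuple[ReferencePanel, DiagnosticSiteTable]:
    """Random panel with exactly ``n_sites`` implanted fixed differences.

    Two (or more) species groups share a random base genome; at ``n_sites``
    distinct positions the groups receive fixed different alleles, and
    ``within_group_snps`` additional positions carry polymorphisms private
    to a strict subset of one group (never creating or destroying a fixed
    difference).  Returns the panel and the truth table of implanted sites
    for the first two group labels in ``n_per_group`` order.
    """
    if n_sites > genome_len // 10:
        raise ValueError("n_sites must be at most genome_len/10")
    groups = list(n_per_group)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if within_group_snps > 0 and all(n_per_group[g] < 2 for g in groups):
        raise ValueError("within-group SNPs need a group with at least 2 members")
    rng = child_rng(seed, "panel")
    base = rng.choice(BASES, size=genome_len)
    positions = rng.choice(genome_len, size=n_sites + within_group_snps, replace=False)
    site_pos = np.sort(positions[:n_sites])
    poly_pos = positions[n_sites:]

    seqs = {g: [base.copy() for _ in range(n_per_group[g])] for g in groups}
    ga, gb = groups[0], groups[1]
    records = []
    for p in site_pos:
        a, b = rng.choice(4, size=2, replace=False)
        for arr in seqs[ga]:
            arr[p] = BASES[a]
        for arr in seqs[gb]:
            arr[p] = BASES[b]
        # further groups, if any, side with group A
        for g in groups[2:]:
            for arr in seqs[g]:
                arr[p] = BASES[a]
        records.append((int(p), str(BASES[a]), str(BASES[b])))

    eligible = [g for g in groups if n_per_group[g] >= 2]
    for p in poly_pos:
        g = eligible[rng.integers(len(eligible))]
        n = n_per_group[g]
        n_mut = int(rng.integers(1, n))  # strict subset
        members = rng.choice(n, size=n_mut, replace=False)
        cur = seqs[g][0][p]
        alt = rng.choice([b for b in BASES if b != cur])
        for m in members:
            seqs[g][m][p] = alt

    genomes = [
        ReferenceGenome(f"{g}_{i}", g, "".join(seqs[g][i]), circular)
        for g in groups
        for i in range(n_per_group[g])
    ]
    truth = DiagnosticSiteTable.from_records(ga, gb, records)
    return ReferencePanel(genomes), truth


# ---------------------------------------------------------------------------
# fragments, damage, reads


def sample_fragments(
    genome: ReferenceGenome,
    n: int,
    frag_len: FragLenDist | None = None,
    seed: int = 0,
    id_prefix: str = "frag",
) -> list[Fragment]:
    """Uniform fragments from one genome; minus-strand fragments are
    reverse-complemented so the sequence is the molecule as sequenced."""
    frag_len = frag_len or FragLenDist()
    rng = child_rng(seed, f"fragments:{id_prefix}:{genome.id}")
    L = len(genome.sequence)
    lens = np.minimum(frag_len.sample(n, rng), L)
    starts = rng.integers(0, np.maximum(L - lens + 1, 1))
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    out = []
    for i in range(n):
        s, ln = int(starts[i]), int(lens[i])
        seq = genome.sequence[s : s + ln]
        if strands[i] == "-":
            seq = revcomp(seq)
        out.append(
            Fragment(
                read_id=f"{id_prefix}:{genome.id}:{i}",
                sequence=seq,
                source_id=genome.id,
                group=genome.group,
                start=s,
                strand=str(strands[i]),
            )
        )
    return out


def apply_damage(
    fragments: Sequence[Fragment],
    damage: DamageParams,
    seq_error: float = 0.0,
    seed: int = 0,
) -> list[Fragment]:
    """Deaminate fragment termini and add uniform sequencing error.

    Each C at 0-based distance ``i`` from the 5' end becomes T with
    probability ``e + d0*exp(-lam*i)``; symmetrically G→A from the 3' end.
    Positions not deaminated get a uniform substitution at ``seq_error``.
    Truth damage counts are recorded per fragment.
    """
    rng = child_rng(seed, "damage")
    maxlen = max((len(f.sequence) for f in fragments), default=0)
    p_curve = damage.rate(np.arange(maxlen)) if maxlen else np.empty(0)
    out = []
    for frag in fragments:
        seq = list(frag.sequence)
        L = len(seq)
        u = rng.random(L)
        u_err = rng.random(L)
        n5 = n3 = 0
        for i in range(L):
            b = seq[i]
            if b == "C" and u[i] < p_curve[i]:
                seq[i] = "T"
                n5 += 1
            elif b == "G" and u[i] < p_curve[L - 1 - i]:
                seq[i] = "A"
                n3 += 1
            elif seq_error > 0 and u_err[i] < seq_error:
                seq[i] = str(rng.choice([c for c in "ACGT" if c != b]))
        out.append(
            Fragment(
                read_id=frag.read_id,
                sequence="".join(seq),
                source_id=frag.source_id,
                group=frag.group,
                start=frag.start,
                strand=frag.strand,
                n_damage_5p=n5,
                n_damage_3p=n3,
                is_duplicate=frag.is_duplicate,
            )
        )
    return out


def add_duplicates(
    fragments: Sequence[Fragment], duplicate_rate: float, seed: int = 0
) -> list[Fragment]:
    """Re-emit a fraction of fragments as PCR duplicates (identical
    molecules under new read ids)."""
    if duplicate_rate <= 0 or not fragments:
        return list(fragments)
    rng = child_rng(seed, "duplicates")
    n_dup = int(round(duplicate_rate * len(fragments)))
    picks = rng.integers(0, len(fragments), size=n_dup)
    out = list(fragments)
    for j, i in enumerate(picks):
        src = fragments[int(i)]
        out.append(
            Fragment(
                read_id=f"{src.read_id}:dup{j}",
                sequence=src.sequence,
                source_id=src.source_id,
                group=src.group,
                start=src.start,
                strand=src.strand,
                n_damage_5p=src.n_damage_5p,
                n_damage_3p=src.n_damage_3p,
                is_duplicate=True,
            )
        )
    return out


def to_paired_reads(
    fragments: Sequence[Fragment], read_len: int, adapter: str = ADAPTER
) -> list[tuple[str, str, str]]:
    """Paired-end reads: (read_id, mate1, mate2).

    Mate 1 is the first ``read_len`` bases of the fragment, mate 2 the
    first ``read_len`` bases of its reverse complement; short inserts read
    through into the fixed adapter constant (repeated if necessary).
    """
    out = []
    for frag in fragments:
        pad = (adapter * (read_len // len(adapter) + 2))
        m1 = (frag.sequence + pad)[:read_len]
        m2 = (revcomp(frag.sequence) + pad)[:read_len]
        out.append((frag.read_id, m1, m2))
    return out


def generate_background(
    source: ReferenceGenome | str,
    n: int,
    frag_len: FragLenDist | None = None,
    seed: int = 0,
    genome_len: int = 50_000,
) -> list[Fragment]:
    """Non-target fragments, from a given genome or a random one."""
    if source == "random":
        rng = child_rng(seed, "background-genome")
        seq = "".join(rng.choice(BASES, size=genome_len))
        source = ReferenceGenome("background_random", "background", seq, circular=False)
    frags = sample_fragments(source, n, frag_len, seed, id_prefix="bg")
    for f in frags:
        f.group = "background"
    return frags


# ---------------------------------------------------------------------------
# repeat arrays


def generate_repeat_array(
    motif_len: int = 173,
    copies: int = 200,
    divergence: float = 0.0,
    seed: int = 0,
    consensus: str | None = None,
) -> tuple[str, str]:
    """Satellite consensus and a tandem array of diverged copies.

    Each copy of the consensus (random unless supplied) is mutated by
    independent substitutions at rate ``divergence``.  Returns
    (consensus, array sequence); the array has length ``motif_len * copies``.
    """
    rng = child_rng(seed, "repeat")
    if consensus is None:
        consensus = "".join(rng.choice(BASES, size=motif_len))
    elif len(consensus) != motif_len:
        raise ValueError("consensus length must equal motif_len")
    parts = []
    for _ in range(copies):
        copy = list(consensus)
        if divergence > 0:
            hits = np.flatnonzero(rng.random(motif_len) < divergence)
            for i in hits:
                copy[i] = str(rng.choice([b for b in BASES if b != copy[i]]))
        parts.append("".join(copy))
    return consensus, "".join(parts)


# ---------------------------------------------------------------------------
# whole-sample assembly


def simulate_sample(
    panel: ReferencePanel, config: SimulationConfig
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """End-to-end simulated sample: paired reads plus a truth table.

    Fragment counts per species group follow the configured mixture
    (largest-remainder rounding); a ``background_frac`` slice comes from a
    random non-target genome; damage, sequencing error, PCR duplicates and
    pairing are applied in fixed stage order under labelled child seeds.
    """
    cfg = config
    n_bg = int(round(cfg.background_frac * cfg.n_fragments))
    n_target = cfg.n_fragments - n_bg
    quotas = {g: cfg.mixture[g] * n_target for g in cfg.mixture}
    counts = {g: int(np.floor(q)) for g, q in quotas.items()}
    rest = n_target - sum(counts.values())
    for g in sorted(quotas, key=lambda g: quotas[g] - counts[g], reverse=True)[:rest]:
        counts[g] += 1

    rng = child_rng(cfg.seed, "sources")
    fragments: list[Fragment] = []
    for g, n in counts.items():
        members = panel.members(g)
        if not members:
            raise ValueError(f"mixture group {g!r} absent from panel")
        per = [n // len(members)] * len(members)
        for i in range(n - sum(per)):
            per[i] += 1
        for genome, m in zip(members, per):
            fragments.extend(
                sample_fragments(genome, m, cfg.frag_len, cfg.seed, id_prefix=f"s{cfg.seed}")
            )
    if n_bg:
        fragments.extend(generate_background("random", n_bg, cfg.frag_len, cfg.seed))
    order = rng.permutation(len(fragments))
    fragments = [fragments[i] for i in order]

    fragments = apply_damage(fragments, cfg.damage, cfg.seq_error, cfg.seed)
    fragments = add_duplicates(fragments, cfg.duplicate_rate, cfg.seed)
    reads = to_paired_reads(fragments, cfg.read_len)
    truth = pd.DataFrame(
        [
            (
                f.read_id,
                f.group,
                f.start + 1,
                len(f.sequence),
                f.strand,
                f.n_damage_5p,
                f.n_damage_3p,
                f.is_duplicate,
            )
            for f in fragments
        ],
        columns=[
            "read_id",
            "group",
            "frag_start_1based",
            "frag_len",
            "strand",
            "n_damage_5p",
            "n_damage_3p",
            "is_duplicate",
        ],
    )
    return reads, truth


def write_fastq_pair(
    reads: Sequence[tuple[str, str, str]], prefix: str | Path
) -> tuple[Path, Path]:
    """Write mate FASTQ files ``<prefix>_R1.fastq`` / ``<prefix>_R2.fastq``."""
    prefix = Path(prefix)
    p1 = prefix.with_name(prefix.name + "_R1.fastq")
    p2 = prefix.with_name(prefix.name + "_R2.fastq")
    with open(p1, "w") as f1, open(p2, "w") as f2:
        for rid, m1, m2 in reads:
            f1.write(f"@{rid}/1\n{m1}\n+\n{'I' * len(m1)}\n")
            f2.write(f"@{rid}/2\n{m2}\n+\n{'I' * len(m2)}\n")
    return p1, p2
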