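import numpy as np
import pandas as pd
import pytest
from Bio import Align

from larixsed import simulate
from larixsed._util import ADAPTER, parse_cigar, revcomp
from larixsed.assign import (
    AssignOptions,
    SiteObservation,
    aggregate,
    damage_filter,
    deduplicate,
    map_reads,
    merge_pairs,
    observe_sites,
    screen_controls,
    write_sam,
)
from larixsed.damage import DamageParams
from larixsed.refpanel import DiagnosticSiteTable
from larixsed.simulate import FragLenDist, sample_fragments, to_paired_reads


def _sites(group_a="gmelinii", group_b="sibirica", records=()):
    return DiagnosticSiteTable.from_records(group_a, group_b, list(records))


def _dp_oracle(read, window):
    """Independent edit-distance oracle: Biopython global aligner with free
    end gaps on the reference window (match 0, everything else -1)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 0
    aligner.mismatch_score = -1
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    # free reference overhangs (gaps in the query row at either end)
    aligner.open_left_deletion_score = 0
    aligner.extend_left_deletion_score = 0
    aligner.open_right_deletion_score = 0
    aligner.extend_right_deletion_score = 0
    best = max(
        aligner.score(window, read), aligner.score(window, revcomp(read))
    )
    return -best


class TestMergePairs:
    def test_non_overlapping_pair_stays_unmerged(self, anchor_genome):
        frag = sample_fragments(
            anchor_genome, 1, FragLenDist(np.log(490), 0.001), seed=1
        )[0]
        pairs = to_paired_reads([frag], read_len=100)
        res = merge_pairs(pairs)
        assert len(res.unmerged) == 1 and not res.merged

    def test_zero_insert_discarded(self):
        pad = (ADAPTER * 4)[:100]
        res = merge_pairs([("empty", pad, pad)])
        assert res.discarded == ["empty"]

    def test_exactly_double_read_len_merges_without_adapter(self, anchor_genome):
        frag = sample_fragments(
            anchor_genome, 1, FragLenDist(np.log(200), 1e-6), seed=2
        )[0]
        assert len(frag.sequence) == 200
        res = merge_pairs(to_paired_reads([frag], read_len=100), min_overlap=0)
        # zero overlap is only mergeable when explicitly allowed
        assert res.merged == [(frag.read_id, frag.sequence)]

    def test_count_conservation(self, anchor_genome):
        frags = sample_fragments(anchor_genome, 300, seed=3)
        res = merge_pairs(to_paired_reads(frags, read_len=100))
        assert len(res.merged) + len(res.unmerged) + len(res.discarded) == 300


class TestMapReads:
    def test_exact_fragment_maps_exactly(self, anchor_genome):
        seq = anchor_genome.sequence[1000:1070]
        alns, counts = map_reads([("r", seq)], anchor_genome)
        a = alns[0]
        assert (a.start, a.end, a.strand, a.n_mismatches) == (1000, 1070, "+", 0)
        assert counts["mapped"] == 1

    def test_reverse_complement_same_span(self, anchor_genome):
        seq = revcomp(anchor_genome.sequence[1000:1070])
        a = map_reads([("r", seq)], anchor_genome)[0][0]
        assert (a.start, a.end, a.strand) == (1000, 1070, "-")

    def test_two_substitutions_counted(self, anchor_genome):
        seq = list(anchor_genome.sequence[2000:2070])
        seq[10] = "A" if seq[10] != "A" else "C"
        seq[50] = "G" if seq[50] != "G" else "T"
        a = map_reads([("r", "".join(seq))], anchor_genome)[0][0]
        assert (a.start, a.end, a.n_mismatches) == (2000, 2070, 2)

    def test_edit_distance_matches_dp_oracle(self, anchor_genome):
        rng = np.random.default_rng(4)
        window = anchor_genome.sequence[3000:3500]
        for trial in range(15):
            s = rng.integers(0, 420)
            ln = rng.integers(40, 80)
            read = list(window[s : s + ln])
            for _ in range(rng.integers(0, 4)):
                op = rng.integers(3)
                p = rng.integers(1, len(read) - 1)
                if op == 0:
                    read[p] = "ACGT"[rng.integers(4)]
                elif op == 1 and len(read) > 35:
                    del read[p]
                else:
                    read.insert(p, "ACGT"[rng.integers(4)])
            read = "".join(read)
            if rng.random() < 0.5:
                read = revcomp(read)
            alns, _ = map_reads([("r", read)], anchor_genome)
            got = sum(n for n, op in parse_cigar(alns[0].cigar) if op in "XID")
            assert got == _dp_oracle(read, anchor_genome.sequence)

    def test_too_short_and_too_divergent_dropped(self, anchor_genome):
        rng = np.random.default_rng(5)
        random_read = "".join(rng.choice(list("ACGT"), 60))
        alns, counts = map_reads(
            [("short", "ACGTACGT"), ("junk", random_read)], anchor_genome
        )
        assert not alns
        assert counts["too_short"] == 1 and counts["unmapped"] == 1

    def test_repeated_locus_flagged_ambiguous(self):
        from larixsed.refpanel import ReferenceGenome

        rng = np.random.default_rng(6)
        unit = "".join(rng.choice(list("ACGT"), 400))
        spacer = "".join(rng.choice(list("ACGT"), 200))
        genome = ReferenceGenome("rep", "g", unit + spacer + unit, circular=False)
        alns, counts = map_reads([("r", unit[100:160])], genome)
        assert counts["ambiguous"] == 1
        assert alns[0].ambiguous


class TestDeduplicate:
    def test_duplicates_collapsed_and_idempotent(self, anchor_genome):
        frags = sample_fragments(anchor_genome, 400, seed=7)
        dup = simulate.add_duplicates(frags, 0.25, seed=8)
        alns, _ = map_reads([(f.read_id, f.sequence) for f in dup], anchor_genome)
        kept, removed = deduplicate(alns)
        # duplicates of mapped originals collapse (a duplicated fragment that
        # is itself dropped for length removes both copies from the input)
        assert removed >= 95
        assert len(kept) <= 400
        again, removed2 = deduplicate(kept)
        assert removed2 == 0 and len(again) == len(kept)

    def test_same_span_different_sequence_both_kept(self, anchor_genome):
        seq = anchor_genome.sequence[500:560]
        seq2 = ("A" if seq[30] != "A" else "C").join([seq[:30], seq[31:]])
        alns, _ = map_reads([("r1", seq), ("r2", seq2)], anchor_genome)
        kept, removed = deduplicate(alns)
        assert len(kept) == 2 and removed == 0


class TestObserveSites:
    def test_read_covering_no_sites_empty(self, anchor_genome):
        sites = _sites(records=[(5000, "A", "C")])
        a = map_reads([("r", anchor_genome.sequence[100:160])], anchor_genome)[0][0]
        assert observe_sites(a, sites) == []

    def test_species_a_read_two_sites(self, anchor_genome):
        ref = anchor_genome.sequence
        sites = _sites(records=[(1010, ref[1010], _other(ref[1010])), (1050, ref[1050], _other(ref[1050]))])
        a = map_reads([("r", ref[1000:1070])], anchor_genome)[0][0]
        obs = observe_sites(a, sites)
        assert [o.anchor_pos for o in obs] == [1010, 1050]
        assert all(o.call == "gmelinii" for o in obs)
        assert obs[0].dist_to_end == 10 and obs[1].dist_to_end == 19

    def test_strand_invariance(self, anchor_genome):
        ref = anchor_genome.sequence
        sites = _sites(records=[(1010, ref[1010], _other(ref[1010]))])
        fwd = map_reads([("r", ref[1000:1070])], anchor_genome)[0][0]
        rev = map_reads([("r", revcomp(ref[1000:1070]))], anchor_genome)[0][0]
        o1, o2 = observe_sites(fwd, sites)[0], observe_sites(rev, sites)[0]
        assert (o1.anchor_pos, o1.observed_base, o1.call) == (
            o2.anchor_pos,
            o2.observed_base,
            o2.call,
        )

    def test_deletion_spanning_site_emits_nothing(self, anchor_genome):
        ref = anchor_genome.sequence
        sites = _sites(records=[(1030, ref[1030], _other(ref[1030]))])
        read = ref[1000:1028] + ref[1033:1070]  # 5 bp deletion over the site
        a = map_reads([("r", read)], anchor_genome)[0][0]
        assert observe_sites(a, sites) == []


def _other(base):
    return "ACGT"[("ACGT".index(base) + 1) % 4]


class TestDamageFilterAndAggregate:
    def _obs(self, read_id, pos, call, transition, dist):
        return SiteObservation(read_id, pos, "N", call, transition, dist)

    def test_mask_zero_is_identity(self):
        obs = [self._obs("r", 10, "gmelinii", True, 1)]
        kept, masked = damage_filter(obs, AssignOptions(mask_on=True, mask_m=0))
        assert kept == obs and masked == 0

    def test_terminal_transition_observation_dropped(self):
        obs = [
            self._obs("r1", 10, "sibirica", True, 2),
            self._obs("r2", 10, "sibirica", True, 7),
            self._obs("r3", 20, "gmelinii", False, 2),
        ]
        kept, masked = damage_filter(obs, AssignOptions(mask_on=True, mask_m=5))
        assert masked == 1
        assert [o.read_id for o in kept] == ["r2", "r3"]

    def test_masking_reduces_damage_miscalls(self, no_damage):
        """On all-A reads with heavy damage over C/T diagnostic sites, the
        fraction of B miscalls drops when terminal masking is on."""
        from larixsed.refpanel import ReferenceGenome

        rng = np.random.default_rng(9)
        base = list(rng.choice(list("ACGT"), 12000))
        site_pos = list(range(100, 11900, 120))
        for p in site_pos:
            base[p] = "C"  # allele A = C, allele B = T: deamination-confoundable
        genome_a = ReferenceGenome("A0", "A", "".join(base), circular=False)
        sites = _sites("A", "B", [(p, "C", "T") for p in site_pos])
        frags = sample_fragments(genome_a, 2500, seed=10)
        damaged = simulate.apply_damage(
            frags, DamageParams(d0=0.4, lam=0.2, e=0.005), seq_error=0.0, seed=11
        )
        alns, _ = map_reads([(f.read_id, f.sequence) for f in damaged], genome_a)
        obs = [o for a in alns for o in observe_sites(a, sites)]

        def miscall_frac(observations):
            calls = [o.call for o in observations if o.call in ("A", "B")]
            return calls.count("B") / len(calls)

        unmasked = miscall_frac(obs)
        masked_obs, n_masked = damage_filter(obs, AssignOptions(mask_on=True, mask_m=5))
        assert n_masked > 0
        assert miscall_frac(masked_obs) < unmasked

    def test_single_read_single_site(self):
        sites = _sites(records=[(10, "A", "C")])
        m = aggregate([self._obs("r", 10, "gmelinii", False, 5)], sites)
        row = m.per_site.iloc[0]
        assert (row["n_a"], row["n_b"], row["coverage"]) == (1, 0, 1)
        assert row["pct_a"] == 100.0
        assert m.totals.iloc[0]["reads_a"] == 1

    def test_split_read_unassigned(self):
        sites = _sites(records=[(10, "A", "C"), (20, "A", "C")])
        obs = [
            self._obs("r", 10, "gmelinii", False, 5),
            self._obs("r", 20, "sibirica", False, 5),
        ]
        m = aggregate(obs, sites)
        t = m.totals.iloc[0]
        assert (t["reads_a"], t["reads_b"], t["reads_unassigned"]) == (0, 0, 1)

    def test_percentages_sum_to_100(self):
        sites = _sites(records=[(10, "A", "C")])
        obs = [
            self._obs(f"r{i}", 10, ["gmelinii", "sibirica", "other"][i % 3], False, 5)
            for i in range(7)
        ]
        m = aggregate(obs, sites)
        row = m.per_site.iloc[0]
        pct_other = 100.0 * row["n_other"] / row["coverage"]
        assert row["pct_a"] + row["pct_b"] + pct_other == pytest.approx(100.0, abs=0.02)

    def test_mixture_proportion_recovered(self, toy_panel):
        panel, truth = toy_panel
        cfg = simulate.SimulationConfig(
            seed=20,
            n_fragments=3000,
            mixture={"gmelinii": 0.7, "sibirica": 0.3},
            damage=DamageParams(0.0, 0.3, 0.0),
            seq_error=0.0,
        )
        reads, _ = simulate.simulate_sample(panel, cfg)
        merged = merge_pairs(reads).merged
        alns, _ = map_reads(merged, panel["gmelinii_0"])
        kept, _ = deduplicate(alns)
        obs = [o for a in kept for o in observe_sites(a, truth)]
        m = aggregate(obs, truth)
        t = m.totals.iloc[0]
        p = t["reads_a"] / (t["reads_a"] + t["reads_b"])
        assert abs(p - 0.7) < 0.03


class TestScreenControls:
    def _matrix(self, counts):
        sites = _sites(records=[(p, "A", "C") for p in sorted(counts)])
        obs = []
        for p, (na, nb) in counts.items():
            obs += [self._obs(f"a{p}{i}", p, "gmelinii", False, 5) for i in range(na)]
            obs += [self._obs(f"b{p}{i}", p, "sibirica", False, 5) for i in range(nb)]
        return aggregate(obs, sites)

    _obs = TestDamageFilterAndAggregate._obs

    def test_empty_control_no_change(self):
        sample = self._matrix({10: (3, 1)})
        empty = self._matrix({})
        out, delta = screen_controls(sample, empty, mode="subtract")
        assert out.per_site.equals(sample.per_site)
        assert len(delta) == 0

    def test_control_equal_to_sample_zeroes_matrix(self):
        sample = self._matrix({10: (3, 1), 20: (0, 2)})
        out, delta = screen_controls(sample, self._matrix({10: (3, 1), 20: (0, 2)}), mode="subtract")
        assert len(out.per_site) == 0
        assert delta["removed_a"].sum() == 3 and delta["removed_b"].sum() == 3

    def test_single_control_read_decrements_one_count(self):
        sample = self._matrix({10: (3, 1), 20: (2, 0)})
        out, delta = screen_controls(sample, self._matrix({10: (1, 0)}), mode="subtract")
        assert out.per_site.set_index("anchor_pos").loc[10, "n_a"] == 2
        assert out.per_site.set_index("anchor_pos").loc[20, "n_a"] == 2
        assert len(delta) == 1

    def test_report_mode_leaves_sample_untouched(self):
        sample = self._matrix({10: (3, 1)})
        out, delta = screen_controls(sample, self._matrix({10: (1, 1)}), mode="report")
        assert out is sample
        assert list(delta.iloc[0][["removed_a", "removed_b"]]) == [1, 1]


class TestSamOutput:
    def test_sam_roundtrips_through_pysam(self, anchor_genome, tmp_path):
        import pysam

        seq = anchor_genome.sequence[1000:1070]
        alns, _ = map_reads([("fwd", seq), ("rev", revcomp(seq))], anchor_genome)
        path = tmp_path / "out.sam"
        write_sam(alns, anchor_genome, path)
        with pysam.AlignmentFile(str(path), "r") as fh:
            records = list(fh)
        assert [r.reference_start for r in records] == [1000, 1000]
        assert [r.is_reverse for r in records] == [False, True]
        assert records[0].query_sequence == seq
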