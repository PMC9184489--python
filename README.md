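# larixsed

Species-level typing of *Larix* (larch) sedimentary ancient DNA from
target-enriched chloroplast reads.

## The problem

Siberian boreal forests are dominated by two larches with very different
ecologies: *Larix sibirica* in the west and *L. gmelinii* (including
*L. cajanderi*) in the centre and east. Pollen and short metabarcodes cannot
separate them, but their chloroplast genomes differ at a fixed set of
single-nucleotide positions. Hybridization-capture sequencing of lake-sediment
ancient DNA (sedaDNA) recovers short (≥30 bp), degraded chloroplast fragments
that cover these diagnostic sites, so each informative read can be assigned to
a species — turning a sediment core into a time series of species presence.

`larixsed` implements that computational chain as a tested, reusable library:

- **`refpanel`** — load labelled reference chloroplast genomes, align them to
  an anchor genome (unique 21-mer chaining + global gap closure, circular
  rotation handled), and call *diagnostic sites*: positions where every
  genome of group A carries one base and every genome of group B another.
- **`taxfilter`** — a small k-mer LCA classifier with KRAKEN-style confidence
  semantics: a read is kept only when the fraction of its k-mers supporting
  the assigned clade reaches the threshold (study setting: 0.8, genus level).
- **`assign`** — paired-end merging, semi-global mapping against the anchor,
  deduplication, per-site base observation, optional masking of
  deamination-confoundable (transition-site, near-terminus) observations, and
  aggregation into per-site percentages plus per-sample species totals by
  per-read majority vote.
- **`damage`** — terminal C→T / G→A misincorporation profiles, a weighted
  least-squares fit of `f(i) = e + d0·exp(−λ·i)`, and an authentication
  verdict with a read-bootstrap interval on `d0`.
- **`repeatprof`** — wraparound (phased) mapping of reads onto a tandem
  satellite motif (the 173 bp EulaSat1 class), per-position nucleotide
  frequency profiles, and a cross-sample constancy statistic (mean
  total-variation distance).
- **`simulate`** — a truth-labelled generator of all of the above: reference
  panels with implanted diagnostic sites, species mixtures, lognormal
  fragment lengths, exponential terminal deamination, sequencing error, PCR
  duplicates, adapter read-through, background reads and satellite arrays.
- **`pipeline` / `larixsed` CLI** — orchestration with a JSON config, a
  manifest of per-stage counts and checksums, and full determinism under a
  fixed seed.

## Worked example

```python
from larixsed import assign, refpanel, simulate
from larixsed.damage import DamageParams

# a 20 kb two-species panel with 60 implanted diagnostic sites
panel, sites = simulate.generate_panel(
    {"gmelinii": 3, "sibirica": 3}, 20_000, 60, within_group_snps=10, seed=11
)

# a 70:30 species mixture of damaged, short paired-end reads
cfg = simulate.SimulationConfig(
    seed=11, n_fragments=2000,
    mixture={"gmelinii": 0.7, "sibirica": 0.3},
    damage=DamageParams(d0=0.2, lam=0.3, e=0.01),
)
reads, truth = simulate.simulate_sample(panel, cfg)

fragments = assign.merge_pairs(reads).merged
alignments, _ = assign.map_reads(fragments, panel["gmelinii_0"])
kept, _ = assign.deduplicate(alignments)
obs = [o for a in kept for o in assign.observe_sites(a, sites)]
totals = assign.aggregate(obs, sites).totals
print(totals.to_string(index=False))
```

prints

```
sample  reads_a  reads_b  reads_unassigned
sample      310      143                 2
```

310 of the 453 majority-voted reads carry gmelinii alleles at the sites they
cover (68.4 %, versus the simulated 70 % — within binomial noise at this
depth); 2 reads had tied votes and stay unassigned. Only reads covering at
least one diagnostic site vote: with 60 sites in 20 kb and ~75 bp fragments,
roughly a fifth of the 2000 fragments are informative.

The same workflow runs end-to-end from a config file:

```bash
larixsed run-all --config run.json   # writes site matrix, totals, SAM,
                                     # damage profile + verdict, manifest
larixsed report --run-dir run/
```

## The published reference panel

`larixsed.accessions` describes the 20 complete chloroplast genomes
(GenBank MK468630.1–MK468648.1 grouped as gmelinii/cajanderi, anchor
MK468637.1, and NC_036811.1 as sibirica). The sequences are not shipped;
download them once (~2.5 MB) with

```python
from larixsed import accessions
accessions.fetch_panel("data/genbank")          # needs network, one time
print(accessions.diagnostic_site_count("data/genbank"))
```

and the diagnostic-site test in the suite will pick the directory up.

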