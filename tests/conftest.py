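import numpy as np
import pytest

from larixsed import refpanel, simulate
from larixsed.damage import DamageParams


@pytest.fixture(scope="session")
def toy_panel():
    """Five 4 kb genomes in two groups with 12 implanted diagnostic sites."""
    panel, truth = simulate.generate_panel(
        {"gmelinii": 3, "sibirica": 2}, 4000, 12, within_group_snps=4, seed=11
    )
    return panel, truth


@pytest.fixture(scope="session")
def toy_alignment(toy_panel):
    panel, _ = toy_panel
    return refpanel.align_to_anchor(panel, "gmelinii_0", k=15)


@pytest.fixture(scope="session")
def anchor_genome():
    """One 12 kb linear genome for read-level tests."""
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), size=12000))
    return refpanel.ReferenceGenome("anchor", "gmelinii", seq, circular=False)


@pytest.fixture
def no_damage():
    return DamageParams(d0=0.0, lam=0.3, e=0.0)


def brute_force_sites(aln, group_a, group_b):
    """Independent per-column scan used as the diagnostic-site oracle."""
    rows_a = [r for i, r in zip(aln.ids, aln.rows) if aln.groups.get(i) == group_a]
    rows_b = [r for i, r in zip(aln.ids, aln.rows) if aln.groups.get(i) == group_b]
    out = []
    for c, apos in enumerate(aln.anchor_map):
        if apos < 0:
            continue
        column = [r[c] for r in aln.rows]
        if any(ch in "-N" for ch in column):
            continue
        seen_a = {r[c] for r in rows_a}
        seen_b = {r[c] for r in rows_b}
        if len(seen_a) == 1 and len(seen_b) == 1 and seen_a != seen_b:
            out.append((apos, seen_a.pop(), seen_b.pop()))
    return sorted(out)
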