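"""The published chloroplast reference panel: accessions and group labels.

Twenty complete Larix chloroplast genomes define the species groups:
L. gmelinii and L. cajanderi genomes (treated as one species, following the
single-species classification of the eastern larches) versus L. sibirica.
MK468637.1 is the anchor that defines the coordinate system.

The sequences themselves are not shipped (about 2.4 MB); download them once
with :func:`fetch_panel` or place per-accession FASTA files in a directory
and point :func:`load_panel` at it.
"""

from __future__ import annotations

from pathlib import Path

from . import refpanel

ANCHOR_ACCESSION = "MK468637.1"

GMELINII_GROUP = [f"MK4686{n}.1" for n in range(30, 49)]  # MK468630.1..MK468648.1
SIBIRICA_GROUP = ["NC_036811.1"]

LABEL_MAP = {acc: "gmelinii" for acc in GMELINII_GROUP}
LABEL_MAP.update({acc: "sibirica" for acc in SIBIRICA_GROUP})

ALL_ACCESSIONS = GMELINII_GROUP + SIBIRICA_GROUP


def fetch_panel(dest: str | Path, email: str = "larixsed@example.org") -> Path:
    """Download the 20-genome panel from NCBI into ``dest`` (one-time,
    ~2.5 MB).  Requires network access."""
    from Bio import Entrez, SeqIO

    dest = Path(dest)
    dest.mkdir(parents=True, exist_ok=True)
    Entrez.email = email
    for acc in ALL_ACCESSIONS:
        out = dest / f"{acc}.fasta"
        if out.exists():
            continue
        with Entrez.efetch(
            db="nuccore", id=acc, rettype="fasta", retmode="text"
        ) as handle:
            record = next(SeqIO.parse(handle, "fasta"))
        record.id = acc
        record.description = ""
        SeqIO.write(record, str(out), "fasta")
    return dest


def load_panel(directory: str | Path) -> refpanel.ReferencePanel:
    """Build the labelled panel from a directory of downloaded FASTA files.

    Record ids are normalised to bare accessions (NCBI FASTA headers often
    carry descriptions).
    """
    directory = Path(directory)
    paths = sorted(directory.glob("*.fasta")) + sorted(directory.glob("*.fa"))
    if not paths:
        raise FileNotFoundError(f"no FASTA files in {directory}")
    label_map = dict(LABEL_MAP)
    # accept headers like 'MK468637.1 Larix gmelinii chloroplast...' too
    panel = refpanel.build_panel(paths, label_map)
    missing = set(ALL_ACCESSIONS) - {g.id for g in panel.genomes}
    if missing:
        raise refpanel.PanelInputError(f"panel incomplete, missing {sorted(missing)}")
    return panel


def diagnostic_site_count(directory: str | Path) -> int:
    """End-to-end panel statistic: diagnostic sites between the species
    groups on the published 20-genome panel."""
    panel = load_panel(directory)
    aln = refpanel.align_to_anchor(panel, ANCHOR_ACCESSION)
    sites = refpanel.call_diagnostic_sites(aln, "gmelinii", "sibirica")
    return len(sites)
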