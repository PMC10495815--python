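"""Plain-text readers/writers for pipeline artifacts.

Everything is TSV/CSV/JSON so any stage can be inspected or replaced: the
community as FASTA (genome placeholders) plus a gene table, counts and
profiles as TSV matrices, the peptide report as TSV with ';'-separated match
lists, the ion table as CSV, and YAML configs.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml
from Bio.Seq import Seq
from Bio.SeqIO import write as seqio_write
from Bio.SeqRecord import SeqRecord

from .community import CommunitySpec
from .profiles import LayerCounts, ReadAssignments


def write_community(community: CommunitySpec, outdir: str | Path) -> None:
    """Write genome-placeholder FASTA, gene table, pathway table, peptides."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = [
        SeqRecord(
            Seq("N" * 60),
            id=sp.species_id,
            description=f"phylum={sp.phylum} genome_length_bp={sp.genome_length_bp} placeholder",
        )
        for sp in community.species
    ]
    seqio_write(records, str(outdir / "genomes.fasta"), "fasta")

    genes = community.genes.reset_index()
    # GFF3-like coordinates: genes laid end-to-end on each placeholder genome
    starts, ends = [], []
    pos: dict[str, int] = {}
    for row in genes.itertuples(index=False):
        s = pos.get(row.species_id, 1)
        starts.append(s)
        ends.append(s + row.length_bp - 1)
        pos[row.species_id] = s + row.length_bp
    genes = genes.assign(start=starts, end=ends, strand="+")
    cols = ["species_id", "gene_id", "start", "end", "strand", "is_rrna", "ko_id", "cog_id"]
    genes[cols].to_csv(outdir / "genes.tsv", sep="\t", index=False)

    rows = [(pid, ko) for pid, kos in sorted(community.pathways.items()) for ko in sorted(kos)]
    pd.DataFrame(rows, columns=["pathway_id", "ko_id"]).to_csv(
        outdir / "pathways.tsv", sep="\t", index=False
    )
    community.peptides.to_csv(outdir / "peptides.tsv", sep="\t", index=False)


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "feature") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_layer_counts(counts: LayerCounts, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix(counts.values, outdir / f"{counts.layer}_counts.tsv")
    counts.feature_map.to_csv(outdir / f"{counts.layer}_features.tsv", sep="\t")


def write_assignments(assignments: ReadAssignments, path: str | Path) -> None:
    assignments.table.to_csv(path, sep="\t", index=False)


def read_assignments(path: str | Path, layer: str) -> ReadAssignments:
    return ReadAssignments(layer, pd.read_csv(path, sep="\t"))


def write_peptide_report(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, sep="\t", index=False, na_rep="")


def read_peptide_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_ion_table(ions: pd.DataFrame, path: str | Path) -> None:
    ions.to_csv(path, index=False)


def read_ion_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
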