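"""Readers and writers for the plain-text formats the pipeline consumes.

Marker counts, ANI tables, filtration and AFE tables are TSV; trees are
Newick; genomes and proteomes are (optionally gzipped) FASTA; ORFs come
from GFF3 or from a protein FASTA with amino-acid to nucleotide length
conversion (nt = 3 * aa + 3, counting the stop codon).
"""

from __future__ import annotations

import gzip
from pathlib import Path

import dendropy
import pandas as pd
from Bio import SeqIO

from .aai import Proteome
from .ecology import AFE_COLUMNS, FiltrationObservation

__all__ = [
    "read_marker_counts", "write_marker_counts",
    "read_tree",
    "read_fastani", "write_ani_matrix",
    "read_genome_fasta", "read_proteome_fasta",
    "read_orf_gff3", "orf_table_from_protein_fasta",
    "read_name_catalog",
    "read_filtration_table", "read_afe_table",
    "write_clusters",
]

FASTANI_COLUMNS = ["query", "reference", "ani", "n_mapped", "n_total"]
ORF_COLUMNS = ["genome_id", "contig", "start", "end", "strand", "length_nt"]


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_marker_counts(path) -> pd.DataFrame:
    """Genomes x markers integer copy-count matrix from TSV
    (first column genome_id, remaining columns marker accessions)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError("marker counts must be non-negative")
    return df.astype(int)


def write_marker_counts(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="genome_id")


def read_tree(path) -> dendropy.Tree:
    """Newick tree with branch lengths."""
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)


def read_fastani(path) -> pd.DataFrame:
    """FastANI 5-column output: query, reference, ANI, mapped, total fragments.

    Genome paths are reduced to file stems so they match assembly ids.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=FASTANI_COLUMNS)
    for col in ("query", "reference"):
        df[col] = df[col].map(lambda p: Path(str(p)).name.removesuffix(".gz")
                              .rsplit(".", 1)[0])
    return df


def write_ani_matrix(ani: pd.DataFrame, path) -> None:
    ani.to_csv(path, sep="\t", index_label="genome_id")


def read_genome_fasta(path) -> list:
    """Contig sequences (uppercase strings) of one assembly."""
    with _open_text(path) as fh:
        return [str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")]


def read_proteome_fasta(path, genome_id: str | None = None) -> Proteome:
    """Protein FASTA -> Proteome; genome_id defaults to the file stem."""
    path = Path(path)
    if genome_id is None:
        genome_id = path.name.removesuffix(".gz").rsplit(".", 1)[0]
    with _open_text(path) as fh:
        seqs = [(rec.id, str(rec.seq).upper().removesuffix("*"))
                for rec in SeqIO.parse(fh, "fasta")]
    return Proteome(genome_id=genome_id, sequences=seqs)


def read_orf_gff3(path, genome_id: str = "", feature_type: str = "CDS") -> pd.DataFrame:
    """ORF table from GFF3 (1-based inclusive coordinates).

    Returns columns genome_id, contig, start, end, strand, length_nt with
    length_nt = end - start + 1.
    """
    rows = []
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8 or fields[2] != feature_type:
                continue
            start, end = int(fields[3]), int(fields[4])
            if end < start:
                raise ValueError(f"invalid coordinates {start}..{end}")
            rows.append((genome_id, fields[0], start, end, fields[6],
                         end - start + 1))
    return pd.DataFrame(rows, columns=ORF_COLUMNS)


def orf_table_from_protein_fasta(path, genome_id: str = "") -> pd.DataFrame:
    """ORF lengths from a protein FASTA: nt = 3 * aa + 3 (incl. stop codon)."""
    rows = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            aa = len(str(rec.seq).removesuffix("*"))
            rows.append((genome_id, rec.id, 1, 3 * aa + 3, "+", 3 * aa + 3))
    return pd.DataFrame(rows, columns=ORF_COLUMNS)


def read_name_catalog(path, source: str | None = None):
    """Name catalog from plain text (one name per line) or 2-column TSV
    (name, source); gzip allowed.  Returns (names, sources) lists."""
    names, sources = [], []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            names.append(parts[0].strip())
            sources.append(parts[1].strip() if len(parts) > 1 and source is None
                           else (source or "catalog"))
    return names, sources


def read_filtration_table(path) -> list:
    """Filtration observations from TSV with columns
    taxon_id, pore_um, retained (0/1) and optional rel_abundance."""
    df = pd.read_csv(path, sep="\t")
    obs = []
    for taxon, grp in df.groupby("taxon_id", sort=True):
        grp = grp.sort_values("pore_um", ascending=False)
        obs.append(FiltrationObservation(
            taxon_id=str(taxon),
            pore_sizes=tuple(grp["pore_um"]),
            retained=tuple(grp["retained"].astype(bool)),
            rel_abundance=tuple(grp["rel_abundance"])
            if "rel_abundance" in grp.columns else None))
    return obs


def read_afe_table(path) -> pd.DataFrame:
    """AFE replicate table: taxon_id, sample_id, replicate, isotope, afe, guild."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in AFE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"AFE table missing columns: {missing}")
    return df


def write_clusters(clusters, path) -> None:
    """Species clusters as TSV: genome_id, cluster_id, is_representative."""
    rows = [(g, c.cluster_id, int(g == c.representative))
            for c in clusters for g in c.members]
    pd.DataFrame(rows, columns=["genome_id", "cluster_id", "is_representative"]) \
        .to_csv(path, sep="\t", index=False)
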