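"""Readers and writers for the tabular dialects used across the workflow.

All tables are plain text (tab-delimited unless stated otherwise), with a
mandatory header row.  Missing values are encoded as ``NA`` on disk and as
``NaN`` in memory; a missing abundance is never silently converted to zero.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

__all__ = [
    "read_psm_table",
    "write_psm_table",
    "read_fasta",
    "write_fasta",
    "read_homology_table",
    "write_homology_table",
    "read_design_table",
    "write_design_table",
    "read_quant_matrix",
    "write_quant_matrix",
    "reporter_columns",
]

_UNIPROT_HEADER = re.compile(r"^(?:sp|tr)\|(?P<acc>[^|]+)\|")


def reporter_columns(columns: Iterable[str]) -> list[str]:
    """Return the ``reporter_<channel>`` columns of a PSM table, in file order."""
    return [c for c in columns if c.startswith("reporter_")]


def read_psm_table(path: str | Path) -> pd.DataFrame:
    """Read a PSM-level quantification table.

    Required columns: ``peptide``, ``proteins`` (semicolon-delimited
    accessions), ``ms1_intensity`` and one ``reporter_<channel>`` column per
    TMT channel.  An optional ``run`` column records the source run.
    """
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "proteins": str})
    required = {"peptide", "proteins", "ms1_intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"PSM table missing required columns: {sorted(missing)}")
    if not reporter_columns(df.columns):
        raise ValueError("PSM table has no reporter_<channel> columns")
    return df


def write_psm_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def parse_fasta_accession(header: str) -> str:
    """Extract the accession from a FASTA header token.

    The first whitespace-delimited token is used; UniProt ``db|ACC|NAME``
    headers are recognized and ``ACC`` extracted.  Isoform suffixes
    (``P12345-2``) are preserved.
    """
    token = header.split()[0]
    m = _UNIPROT_HEADER.match(token)
    return m.group("acc") if m else token


def parse_fasta_gene(description: str) -> str | None:
    """Pull the gene symbol from a UniProt-style ``GN=`` field, if present."""
    m = re.search(r"\bGN=(\S+)", description)
    return m.group(1) if m else None


def read_fasta(path: str | Path) -> tuple[dict[str, str], dict[str, str]]:
    """Read a protein FASTA.

    Returns ``(accession -> sequence, accession -> gene)``; the gene map only
    contains entries whose header carried a ``GN=`` field.
    """
    seqs: dict[str, str] = {}
    genes: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = parse_fasta_accession(rec.description)
        seqs[acc] = str(rec.seq).upper()
        gene = parse_fasta_gene(rec.description)
        if gene is not None:
            genes[acc] = gene
    return seqs, genes


def write_fasta(seqs: Mapping[str, str], path: str | Path,
                genes: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for acc, seq in seqs.items():
            gn = f" GN={genes[acc]}" if genes and acc in genes else ""
            fh.write(f">{acc}{gn}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def read_homology_table(path: str | Path) -> pd.DataFrame:
    """Read an Ensembl BioMart-style paralog homology export.

    Expected columns: ``gene_id``, ``paralog_gene_id``, ``perc_id``
    (query→target percent identity), ``perc_id_r1`` (target→query),
    ``paralog_type``, ``ancestor``.  Extra columns are ignored.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "paralog_gene_id", "perc_id", "perc_id_r1"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"homology table missing columns: {sorted(missing)}")
    for col in ("perc_id", "perc_id_r1"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("paralog_type", "ancestor"):
        if col not in df.columns:
            df[col] = ""
    return df


def write_homology_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_design_table(path: str | Path) -> pd.DataFrame:
    """Read the sample design table (CSV): ``sample, channel, <factors...>``."""
    df = pd.read_csv(path, dtype=str)
    required = {"sample", "channel"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"duplicate sample names in design table: {dup}")
    return df


def write_design_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_quant_matrix(path: str | Path) -> pd.DataFrame:
    """Read a protein quantification matrix (rows = accessions)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return df.astype(float)


def write_quant_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    out = matrix.copy()
    out.index.name = "accession"
    out.to_csv(path, sep="\t", na_rep="NA")
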