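"""Light IO helpers: FASTA (via Biopython), BED6 and bedGraph (via pandas).

Coordinates are 0-based half-open throughout (BED convention). Lowercase
FASTA bases are preserved on read — soft-masking is meaningful downstream.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (multi-)FASTA into {name: sequence}, case preserved."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED (3-6 columns) into a DataFrame with canonical column names."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED6_COLUMNS[: df.shape[1]]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in BED6_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a bedGraph track (track/comment lines skipped)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, value = line.split("\t")
            rows.append((chrom, int(start), int(end), float(value)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def write_bedgraph(df: pd.DataFrame, path: str | Path, name: str = "signal") -> None:
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{name}"\n')
        for row in df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.value:.6g}\n")
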