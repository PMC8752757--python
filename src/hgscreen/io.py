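"""Readers and writers for the pipeline's plain-text interchange formats.

All tables are TSV with documented headers; sequences are FASTA (wrapped at
60 columns on write), peak intervals are BED (0-based half-open), and PFMs
are JASPAR text.  Every reader validates its header contract and names the
offending column or line on error; every writer round-trips through its
reader.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .atac import PeakSet, read_jaspar, write_jaspar  # noqa: F401  (re-export)
from .deg import DEG_COLUMNS, ExpressionDataset
from .survival import SURVIVAL_COLUMNS
from .cna import CNA_COLUMNS

__all__ = [
    "read_expression", "write_expression",
    "read_survival", "write_survival",
    "read_cna", "write_cna",
    "read_gene_set", "write_gene_set",
    "read_deg", "write_deg",
    "read_fasta", "write_fasta",
    "read_bed", "write_bed",
    "read_counts", "write_counts",
    "read_labels", "write_labels",
    "read_jaspar", "write_jaspar",
    "run_provenance", "write_provenance",
]


def _require(df: pd.DataFrame, columns: Sequence[str], what: str) -> pd.DataFrame:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing required column(s) {missing}")
    return df


def read_expression(matrix_path, groups_path, dataset_id: Optional[str] = None
                    ) -> ExpressionDataset:
    """Expression TSV (first column 'gene', header = sample ids) plus a
    two-column sample/group sidecar with groups in {control, case}."""
    df = pd.read_csv(matrix_path, sep="\t")
    if df.columns[0] != "gene":
        raise ValueError("expression matrix: first column must be 'gene'")
    if pd.Index(df.columns[1:]).duplicated().any():
        raise ValueError("expression matrix: duplicate sample ids")
    values = df.set_index("gene")
    groups = pd.read_csv(groups_path, sep="\t")
    _require(groups, ["sample_id", "group"], "group file")
    if groups["sample_id"].duplicated().any():
        raise ValueError("group file: duplicate sample ids")
    group = groups.set_index("sample_id")["group"]
    return ExpressionDataset(dataset_id or Path(matrix_path).stem, values, group)


def write_expression(ds: ExpressionDataset, matrix_path, groups_path) -> None:
    ds.values.rename_axis("gene").to_csv(matrix_path, sep="\t")
    ds.group.rename("group").rename_axis("sample_id").to_csv(groups_path, sep="\t")


def read_survival(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require(df, SURVIVAL_COLUMNS, "survival table")
    if df["sample_id"].duplicated().any():
        raise ValueError("survival table: duplicate sample ids")
    return df


def write_survival(cohort: pd.DataFrame, path) -> None:
    cohort[SURVIVAL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_cna(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return _require(df, CNA_COLUMNS, "CNA table")


def write_cna(cohort: pd.DataFrame, path) -> None:
    cohort[CNA_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gene_set(path) -> List[str]:
    """One symbol per line; blank lines and '#' comments ignored, case
    preserved."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_gene_set(genes: Iterable[str], path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_deg(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return _require(df, DEG_COLUMNS, "DEG table")


def write_deg(table: pd.DataFrame, path) -> None:
    table[DEG_COLUMNS].to_csv(path, sep="\t", index=False)


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")  # wraps at 60 columns


def read_bed(path) -> pd.DataFrame:
    """BED3+1: chrom, start, end, name (peak_id).  0-based half-open."""
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"BED line {lineno}: fewer than 3 fields")
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        if end <= start:
            raise ValueError(f"BED line {lineno}: end <= start")
        name = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
        rows.append((name, chrom, start, end))
    return pd.DataFrame(rows, columns=["peak_id", "chrom", "start", "end"])


def write_bed(intervals: pd.DataFrame, path) -> None:
    _require(intervals, ["peak_id", "chrom", "start", "end"], "peak intervals")
    intervals[["chrom", "start", "end", "peak_id"]].to_csv(
        path, sep="\t", header=False, index=False)


def read_counts(path) -> pd.DataFrame:
    """peaks × samples count matrix, first column 'peak_id'."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "peak_id":
        raise ValueError("count matrix: first column must be 'peak_id'")
    return df.set_index("peak_id")


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.rename_axis("peak_id").to_csv(path, sep="\t")


def read_labels(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    _require(df, ["sample_id", "condition"], "label file")
    return df.set_index("sample_id")["condition"]


def write_labels(labels: pd.Series, path) -> None:
    labels.rename("condition").rename_axis("sample_id").to_csv(path, sep="\t")


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_provenance(params: Mapping, inputs: Sequence) -> Dict:
    """Provenance block embedded next to every analysis output: parameters,
    package version, timestamp, and SHA-256 of each input file."""
    from . import __version__
    return {
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "params": dict(params),
        "inputs": {str(p): _sha256(p) for p in inputs},
    }


def write_provenance(out_path, params: Mapping, inputs: Sequence) -> None:
    sidecar = Path(str(out_path) + ".run.json")
    sidecar.write_text(json.dumps(run_provenance(params, inputs), indent=2) + "\n")
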