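"""Plain-text readers and writers for every pipeline artifact.

All tables are TSV; promoter sequences are FASTA with the TSS offset in the
record description (``tss_index=<int>``).  Readers validate the column
contract and hand back the in-memory containers the analysis modules use.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .expression import ExpressionMatrix
from .motifs import Motif
from .peaks import ArrayDesign

DESIGN_COLUMNS = ["chrom", "start", "end", "probe_id", "seq_id", "gene_symbol"]
ANNOTATION_COLUMNS = ["gene", "chrom", "cds_start", "cds_end", "tss", "strand"]


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_symbol": str})
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_design(design: ArrayDesign, path) -> None:
    design.probes[DESIGN_COLUMNS].to_csv(path, sep="\t", index=False)


def read_design(path) -> ArrayDesign:
    df = _read_tsv(path, DESIGN_COLUMNS)
    df["gene_symbol"] = df["gene_symbol"].fillna("")
    return ArrayDesign(df)


def write_signal(signal: pd.DataFrame, path) -> None:
    signal.to_csv(path, sep="\t", index=True)


def read_signal(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe_id")


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    return _read_tsv(path, ANNOTATION_COLUMNS)


def write_expression(matrix: ExpressionMatrix, values_path, groups_path, map_path) -> None:
    matrix.values.to_csv(values_path, sep="\t", index=True)
    matrix.groups.rename_axis("sample").to_frame("group").to_csv(
        groups_path, sep="\t"
    )
    matrix.probe_map.rename_axis("probe_set").to_frame("gene").to_csv(
        map_path, sep="\t"
    )


def read_expression(values_path, groups_path, map_path) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col="probe_set")
    groups = pd.read_csv(groups_path, sep="\t", index_col="sample")["group"]
    probe_map = pd.read_csv(
        map_path, sep="\t", index_col="probe_set", dtype={"gene": str}
    )["gene"].fillna("")
    return ExpressionMatrix(values, groups, probe_map)


def write_promoters(promoters: dict[str, tuple[str, int]], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=seq_id, description=f"tss_index={tss_index}")
        for seq_id, (seq, tss_index) in sorted(promoters.items())
    ]
    SeqIO.write(records, str(path), "fasta")


def read_promoters(path) -> dict[str, tuple[str, int]]:
    promoters = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = dict(
            kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv
        )
        if "tss_index" not in fields:
            raise ValueError(f"{path}: record {rec.id} lacks tss_index=<int>")
        promoters[rec.id] = (str(rec.seq).upper(), int(fields["tss_index"]))
    return promoters


def write_motif_table(motifs, path) -> None:
    pd.DataFrame(
        [(m.name, m.consensus) for m in motifs], columns=["name", "consensus"]
    ).to_csv(path, sep="\t", index=False)


def read_motif_table(path) -> list[Motif]:
    df = _read_tsv(path, ["name", "consensus"])
    return [Motif(r.name, r.consensus) for r in df.itertuples(index=False)]


def write_truth(truth, directory) -> None:
    directory = Path(directory)
    truth.bound.to_csv(directory / "truth_bound.tsv", sep="\t", index=False)
    truth.de.to_csv(directory / "truth_de.tsv", sep="\t", index=False)
    truth.planted.to_csv(directory / "truth_planted.tsv", sep="\t", index=False)


def read_gene_sets(path) -> dict[str, set[str]]:
    """Category sets from a two-column TSV (category, gene) or GMT lines."""
    path = Path(path)
    first = path.read_text().splitlines()
    if not first:
        return {}
    header = first[0].split("\t")
    if header[:2] == ["category", "gene"]:
        df = pd.read_csv(path, sep="\t")
        return {
            str(cat): set(grp["gene"].astype(str))
            for cat, grp in df.groupby("category")
        }
    sets: dict[str, set[str]] = {}
    for line in first:
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            continue
        sets[parts[0]] = {g for g in parts[2:] if g}
    return sets
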