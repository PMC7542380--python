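"""Readers and writers for every external representation the pipeline touches.

All internal coordinates are 0-based half-open; GFF3's 1-based inclusive
convention is converted exactly at this boundary and nowhere else.  A gene
that wraps the circular origin is encoded with ``end_bp <= start_bp`` and
resolved downstream by :mod:`panpos.geometry`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ChromosomeDef",
    "GeneRecord",
    "GffParseError",
    "read_gff",
    "write_gff",
    "read_ori_table",
    "write_ori_table",
    "read_pangenome_matrix",
    "read_counts",
    "read_sample_sheet",
    "genes_to_frame",
    "frame_to_genes",
    "write_circos_tracks",
    "write_report_tables",
    "CATEGORY_COLORS",
]

#: Default Circos color per pangene category (config-driven, fixed defaults).
CATEGORY_COLORS: Mapping[str, str] = {
    "core": "vdblue",
    "softcore": "blue",
    "shell": "orange",
    "cloud": "vdred",
    "unassigned": "grey",
}


class GffParseError(ValueError):
    """A malformed GFF3 line; carries the offending 1-based line number."""


@dataclass(frozen=True)
class ChromosomeDef:
    """A circular chromosome with its replication origin (and optional terminus).

    Positions are 0-based.  ``ter_bp`` is only needed for unequal replichores;
    the default geometry places *ter* at the antipode of *ori*.
    """

    chrom_id: str
    length_bp: int
    ori_bp: int = 0
    ter_bp: int | None = None

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"{self.chrom_id}: length_bp must be positive")
        if not 0 <= self.ori_bp < self.length_bp:
            raise ValueError(
                f"{self.chrom_id}: ori_bp {self.ori_bp} outside [0, {self.length_bp})"
            )
        if self.ter_bp is not None:
            if not 0 <= self.ter_bp < self.length_bp:
                raise ValueError(
                    f"{self.chrom_id}: ter_bp {self.ter_bp} outside [0, {self.length_bp})"
                )
            if self.ter_bp == self.ori_bp:
                raise ValueError(f"{self.chrom_id}: ter_bp equals ori_bp")


@dataclass(frozen=True)
class GeneRecord:
    """One CDS on a circular chromosome, 0-based half-open.

    ``end_bp <= start_bp`` encodes a gene wrapping the sequence origin.
    """

    gene_id: str
    genome_id: str
    chrom_id: str
    start_bp: int
    end_bp: int
    strand: str = "+"
    cluster_id: str | None = None

    def __post_init__(self) -> None:
        if self.start_bp < 0 or self.end_bp < 0:
            raise ValueError(f"{self.gene_id}: negative coordinate")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _parse_attributes(col: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in col.strip().split(";"):
        if not item:
            continue
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff(
    path: str | Path, genome_id: str
) -> tuple[list[GeneRecord], list[ChromosomeDef]]:
    """Read CDS features from a GFF3 file.

    Chromosome lengths come from ``##sequence-region`` pragmas.  Returned
    :class:`ChromosomeDef` objects carry ``ori_bp=0``; merge real *ori*
    positions from :func:`read_ori_table` before geometry.

    GFF3 coordinates (1-based inclusive) are converted to 0-based half-open.
    Non-CDS features are ignored.  A ``cluster`` attribute, if present, is
    kept as the gene's cluster id.
    """
    path = Path(path)
    lengths: dict[str, int] = {}
    genes: list[GeneRecord] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) != 4:
                    raise GffParseError(f"{path}:{lineno}: bad sequence-region pragma")
                lengths[parts[1]] = int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GffParseError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype != "CDS":
                continue
            if seqid not in lengths:
                raise GffParseError(f"{path}:{lineno}: CDS on unknown chromosome {seqid!r}")
            try:
                start_1 = int(start)
                end_1 = int(end)
            except ValueError as exc:
                raise GffParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if strand not in ("+", "-"):
                raise GffParseError(f"{path}:{lineno}: bad strand {strand!r}")
            a = _parse_attributes(attrs)
            gid = a.get("ID", f"{genome_id}_cds{len(genes) + 1}")
            genes.append(
                GeneRecord(
                    gene_id=gid,
                    genome_id=genome_id,
                    chrom_id=seqid,
                    start_bp=start_1 - 1,
                    end_bp=end_1,
                    strand=strand,
                    cluster_id=a.get("cluster"),
                )
            )
    chroms = [ChromosomeDef(cid, ln) for cid, ln in lengths.items()]
    return genes, chroms


def write_gff(
    genes: Sequence[GeneRecord],
    chroms: Sequence[ChromosomeDef],
    path: str | Path,
) -> None:
    """Write CDS features as GFF3 (inverse of :func:`read_gff` on its output)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for c in sorted(chroms, key=lambda c: c.chrom_id):
            fh.write(f"##sequence-region {c.chrom_id} 1 {c.length_bp}\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.cluster_id is not None:
                attrs += f";cluster={g.cluster_id}"
            fh.write(
                "\t".join(
                    [
                        g.chrom_id,
                        "panpos",
                        "CDS",
                        str(g.start_bp + 1),
                        str(g.end_bp),
                        ".",
                        g.strand,
                        "0",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# ori table
# ---------------------------------------------------------------------------

def read_ori_table(path: str | Path) -> list[ChromosomeDef]:
    """Read a CSV of chromosome definitions: chrom_id,length_bp,ori_bp[,ter_bp]."""
    path = Path(path)
    out: list[ChromosomeDef] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"chrom_id", "length_bp", "ori_bp"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"{path}: need columns {sorted(required)}")
        for row in reader:
            ter_raw = (row.get("ter_bp") or "").strip()
            out.append(
                ChromosomeDef(
                    chrom_id=row["chrom_id"].strip(),
                    length_bp=int(row["length_bp"]),
                    ori_bp=int(row["ori_bp"]),
                    ter_bp=int(ter_raw) if ter_raw else None,
                )
            )
    return out


def write_ori_table(chroms: Sequence[ChromosomeDef], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["chrom_id", "length_bp", "ori_bp", "ter_bp"])
        for c in sorted(chroms, key=lambda c: c.chrom_id):
            w.writerow([c.chrom_id, c.length_bp, c.ori_bp, "" if c.ter_bp is None else c.ter_bp])


# ---------------------------------------------------------------------------
# pangenome matrix
# ---------------------------------------------------------------------------

def read_pangenome_matrix(
    path: str | Path,
    genome_ids: Sequence[str] | None = None,
    transpose: bool | None = None,
):
    """Read a tab-delimited cluster-membership matrix into a PangenomeMatrix.

    Clustering tools emit both orientations (genomes as rows or as columns).
    Orientation is auto-detected by matching labels against ``genome_ids``
    when supplied, else the header row is assumed to hold the genome ids;
    an explicit ``transpose`` overrides detection (``True`` means the file
    has genomes as rows).  Cells are non-negative integer member counts
    (paralogs > 1).
    """
    from .classify import PangenomeMatrix  # local import: avoid cycle

    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(header) != len(set(header)):
        raise ValueError(f"{path}: duplicated column identifier")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicated row identifier")
    try:
        values = df.to_numpy()
        if not (values == values.astype(int)).all():
            raise ValueError
        df = df.astype(int)
    except (TypeError, ValueError):
        raise ValueError(f"{path}: matrix cells must be non-negative integers") from None
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative cell value")

    if transpose is None:
        if genome_ids is not None:
            gset = set(genome_ids)
            rows_match = len(gset & set(df.index)) > len(gset & set(df.columns))
            transpose = rows_match
        else:
            transpose = False  # convention: header row holds the genome ids
    if transpose:  # genomes are rows -> flip to clusters x genomes
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return PangenomeMatrix(df)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def read_counts(path: str | Path) -> pd.Series:
    """Read a two-column ``gene_id<TAB>count`` table into a Series."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "read_count"],
                     dtype={"gene_id": str}, comment="#")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"{path}: duplicated gene id {dup!r}")
    counts = pd.to_numeric(df["read_count"], errors="raise")
    if (counts < 0).any() or not (counts == counts.astype(int)).all():
        raise ValueError(f"{path}: read counts must be non-negative integers")
    return pd.Series(counts.astype(int).to_numpy(), index=df["gene_id"], name="read_count")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet TSV with columns sample, condition, counts_path."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "condition", "counts_path"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    return df


# ---------------------------------------------------------------------------
# gene table <-> records
# ---------------------------------------------------------------------------

_GENE_COLS = ["gene_id", "genome_id", "chrom_id", "start_bp", "end_bp", "strand", "cluster_id"]


def genes_to_frame(genes: Iterable[GeneRecord]) -> pd.DataFrame:
    """Tabulate GeneRecords into the canonical gene DataFrame."""
    rows = [
        (g.gene_id, g.genome_id, g.chrom_id, g.start_bp, g.end_bp, g.strand, g.cluster_id)
        for g in genes
    ]
    return pd.DataFrame(rows, columns=_GENE_COLS)


def frame_to_genes(df: pd.DataFrame) -> list[GeneRecord]:
    return [
        GeneRecord(
            gene_id=str(r.gene_id),
            genome_id=str(r.genome_id),
            chrom_id=str(r.chrom_id),
            start_bp=int(r.start_bp),
            end_bp=int(r.end_bp),
            strand=str(r.strand),
            cluster_id=None if pd.isna(r.cluster_id) else str(r.cluster_id),
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Circos output
# ---------------------------------------------------------------------------

def write_circos_tracks(
    loci: pd.DataFrame,
    chroms: Sequence[ChromosomeDef],
    out_dir: str | Path,
    expression: pd.Series | None = None,
    colors: Mapping[str, str] = CATEGORY_COLORS,
) -> list[Path]:
    """Emit a Circos karyotype file plus one interval track per category.

    Coordinates are recentred so position 0 is *ori* on every chromosome
    (plots centred at the origin); a gene upstream of *ori* by ``d`` starts
    at ``L - d``.  An ``expression.track.txt`` with a fourth value column is
    written when ``expression`` (indexed by gene_id) is supplied.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if "category" not in loci.columns or loci["category"].isna().any():
        missing = [] if "category" not in loci.columns else \
            loci.loc[loci["category"].isna(), "gene_id"].tolist()
        raise ValueError(f"every gene needs a category; missing for {missing[:5]}")

    by_id = {c.chrom_id: c for c in chroms}
    written: list[Path] = []

    karyo = out_dir / "karyotype.txt"
    with karyo.open("w") as fh:
        for c in sorted(chroms, key=lambda c: c.chrom_id):
            fh.write(f"chr - {c.chrom_id} {c.chrom_id} 0 {c.length_bp} grey\n")
    written.append(karyo)

    def shifted(row) -> tuple[int, int]:
        c = by_id[row.chrom_id]
        gene_len = (row.end_bp - row.start_bp) % c.length_bp or (
            row.end_bp - row.start_bp if row.end_bp > row.start_bp else c.length_bp
        )
        start = (row.start_bp - c.ori_bp) % c.length_bp
        return start, start + gene_len

    for cat in sorted(loci["category"].unique()):
        sub = loci[loci["category"] == cat].sort_values(
            ["chrom_id", "start_bp", "gene_id"], kind="mergesort"
        )
        p = out_dir / f"{cat}.track.txt"
        with p.open("w") as fh:
            for row in sub.itertuples(index=False):
                s, e = shifted(row)
                fh.write(f"{row.chrom_id} {s} {e} color={colors.get(cat, 'black')}\n")
        written.append(p)

    if expression is not None:
        p = out_dir / "expression.track.txt"
        sub = loci.sort_values(["chrom_id", "start_bp", "gene_id"], kind="mergesort")
        with p.open("w") as fh:
            for row in sub.itertuples(index=False):
                if row.gene_id not in expression.index:
                    continue
                s, e = shifted(row)
                fh.write(f"{row.chrom_id} {s} {e} {expression[row.gene_id]:.6g}\n")
        written.append(p)
    return written


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

def write_report_tables(
    tables: Mapping[str, pd.DataFrame], out_dir: str | Path
) -> list[Path]:
    """Write each table as a deterministic TSV (fixed column order, %.6g floats)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        p = out_dir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.6g")
        written.append(p)
    return written
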