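"""Readers and writers for the external formats the pipeline touches.

Formats
-------
* Bismark-style cytosine report ("CX report"): 7-column TSV with 1-based
  positions — chrom, pos, strand, methylated count, unmethylated count,
  context, trinucleotide.
* GFF3 gene annotation (via :mod:`gffutils`).
* BED intervals (0-based half-open) with an optional label column, used for
  transposable elements and chromosome compartments.
* Gene x sample FPKM matrix as TSV with ``tissue_stage_rep`` sample tokens.
* GO annotation map as TSV (gene_id, go_id, go_description).

Internally every coordinate is 0-based half-open; conversion from the
1-based cytosine-report and GFF3 conventions happens here and only here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd

from .models import (
    CONTEXTS,
    CYTOSINE_COLUMNS,
    TE_CLASSES,
    Compartment,
    GeneModel,
    TEModel,
)

__all__ = [
    "read_cx_report",
    "write_cx_report",
    "read_gff3_genes",
    "write_gff3_genes",
    "read_te_bed",
    "read_compartment_bed",
    "write_intervals_bed",
    "ExpressionMatrix",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_go_map",
    "write_go_map",
]

_STRANDS = {"+", "-"}

_SAMPLE_TOKEN = re.compile(r"^(?P<tissue>[A-Za-z]+)_(?P<stage>[A-Za-z0-9]+)_(?P<rep>\d+)$")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# cytosine report


def read_cx_report(path: str | Path) -> pd.DataFrame:
    """Read a per-cytosine methylation report into the canonical table.

    Returns a DataFrame with columns ``chrom, pos, strand, meth, unmeth,
    context, tricontext`` in file order; ``pos`` is converted to 0-based.
    Malformed rows raise :class:`FormatError` naming the 1-based line number.
    """
    rows: list[tuple] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise FormatError(
                    f"{path}: line {lineno}: expected 7 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, pos_s, strand, meth_s, unmeth_s, context, tri = fields
            try:
                pos = int(pos_s)
                meth = int(meth_s)
                unmeth = int(unmeth_s)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            if pos < 1:
                raise FormatError(f"{path}: line {lineno}: position {pos} < 1")
            if strand not in _STRANDS:
                raise FormatError(f"{path}: line {lineno}: bad strand {strand!r}")
            if meth < 0 or unmeth < 0:
                raise FormatError(f"{path}: line {lineno}: negative call count")
            if context not in CONTEXTS:
                raise FormatError(
                    f"{path}: line {lineno}: unknown context token {context!r}"
                )
            rows.append((chrom, pos - 1, strand, meth, unmeth, context, tri))
    df = pd.DataFrame(rows, columns=list(CYTOSINE_COLUMNS))
    if df.empty:
        df = df.astype(
            {"pos": np.int64, "meth": np.int64, "unmeth": np.int64}, errors="ignore"
        )
    return df


def write_cx_report(records: pd.DataFrame, path: str | Path) -> None:
    """Write the canonical cytosine table back to the 1-based 7-column TSV."""
    out = records.loc[:, list(CYTOSINE_COLUMNS)].copy()
    out["pos"] = out["pos"].astype(np.int64) + 1
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# GFF3 genes


def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Read gene features from a GFF3 file.

    The TSS is the 5' boundary in transcription orientation (GFF3 ``start``
    for + strand genes, ``end`` for - strand).  Missing strand or duplicated
    gene IDs raise :class:`FormatError`.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        if gene_id in seen or feat.id != gene_id:
            # create_unique renames the second copy (ID_1); detect either way
            base = gene_id.rsplit("_", 1)[0]
            dup = gene_id if gene_id in seen else base
            raise FormatError(f"{path}: duplicate gene ID {dup!r}")
        seen.add(gene_id)
        if feat.strand not in _STRANDS:
            raise FormatError(f"{path}: gene {gene_id!r} has no strand")
        # GFF3 is 1-based closed: [start, end] -> half-open [start-1, end)
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=feat.seqid,
                strand=feat.strand,
                start=feat.start - 1,
                end=feat.end,
            )
        )
    return genes


def write_gff3_genes(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tmethylseed\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# BED intervals


def _read_bed_rows(path: str | Path, min_cols: int) -> list[list[str]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < min_cols:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= {min_cols} columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            if start < 0 or start >= end:
                raise FormatError(
                    f"{path}: line {lineno}: invalid interval [{start}, {end})"
                )
            rows.append([str(lineno)] + fields)
    return rows


def read_te_bed(path: str | Path) -> list[TEModel]:
    """Read transposable elements from BED with the class in column 4.

    An optional column 6 carries the strand (BED6 layout with a placeholder
    score in column 5); otherwise + is assumed.
    """
    tes = []
    for row in _read_bed_rows(path, min_cols=4):
        lineno, fields = row[0], row[1:]
        te_class = fields[3]
        if te_class not in TE_CLASSES:
            raise FormatError(
                f"{path}: line {lineno}: unknown TE class {te_class!r}"
            )
        strand = fields[5] if len(fields) >= 6 and fields[5] in _STRANDS else "+"
        tes.append(
            TEModel(
                te_id=f"TE{len(tes) + 1:05d}",
                chrom=fields[0],
                start=int(fields[1]),
                end=int(fields[2]),
                te_class=te_class,
                strand=strand,
            )
        )
    return tes


def read_compartment_bed(path: str | Path) -> list[Compartment]:
    """Read compartment intervals from BED with the label in column 4."""
    comps = []
    for row in _read_bed_rows(path, min_cols=4):
        fields = row[1:]
        comps.append(
            Compartment(
                chrom=fields[0],
                start=int(fields[1]),
                end=int(fields[2]),
                label=fields[3],
            )
        )
    # non-overlap invariant within each chromosome
    by_chrom: dict[str, list[Compartment]] = {}
    for c in comps:
        by_chrom.setdefault(c.chrom, []).append(c)
    for chrom, items in by_chrom.items():
        items = sorted(items, key=lambda c: c.start)
        for a, b in zip(items, items[1:]):
            if b.start < a.end:
                raise FormatError(
                    f"{path}: overlapping compartments on {chrom} at {b.start}"
                )
    return comps


def write_intervals_bed(intervals, path: str | Path) -> None:
    """Write TEModel or Compartment collections as labelled BED."""
    with open(path, "w") as fh:
        for iv in intervals:
            label = getattr(iv, "te_class", None) or getattr(iv, "label")
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label}\n")


# ---------------------------------------------------------------------------
# expression matrix


@dataclass
class ExpressionMatrix:
    """Gene x sample FPKM matrix with parsed sample metadata.

    Columns of ``values`` are sample tokens ``tissue_stage_rep`` (for example
    ``cotyledon_S2_1`` or ``leaf_leaf_1``); ``samples`` maps each token to its
    (tissue, stage, rep) triple.  All FPKM values are >= 0.
    """

    values: pd.DataFrame
    samples: dict[str, tuple[str, str, int]]

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise FormatError("negative FPKM value in expression matrix")
        reps_per_stage = {}
        for _, (tissue, stage, _rep) in self.samples.items():
            if tissue == "cotyledon":
                reps_per_stage[stage] = reps_per_stage.get(stage, 0) + 1
        if len(set(reps_per_stage.values())) > 1:
            raise FormatError(
                "cotyledon stages have unequal replicate counts: "
                f"{reps_per_stage}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def stages(self) -> list[str]:
        """Cotyledon stages in column order."""
        out = []
        for _, (tissue, stage, _) in self.samples.items():
            if tissue == "cotyledon" and stage not in out:
                out.append(stage)
        return out

    def stage_columns(self, stage: str) -> list[str]:
        return [
            tok
            for tok, (tissue, st, _) in self.samples.items()
            if tissue == "cotyledon" and st == stage
        ]

    @property
    def leaf_columns(self) -> list[str]:
        return [tok for tok, (tissue, _, _) in self.samples.items() if tissue == "leaf"]

    def stage_means(self) -> pd.DataFrame:
        """Mean FPKM per cotyledon stage (genes x stages)."""
        return pd.DataFrame(
            {st: self.values[self.stage_columns(st)].mean(axis=1) for st in self.stages}
        )


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Read a gene x sample FPKM TSV.

    The header row names samples as ``tissue_stage_rep`` tokens; the first
    column holds gene IDs.  Ragged rows, negative values or an unparseable
    header raise :class:`FormatError`.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise FormatError(f"{path}: missing header row")
        columns = header.split("\t")
        if len(columns) < 2:
            raise FormatError(f"{path}: header must name at least one sample")
        samples = {}
        for tok in columns[1:]:
            m = _SAMPLE_TOKEN.match(tok)
            if not m:
                raise FormatError(
                    f"{path}: sample token {tok!r} is not tissue_stage_rep"
                )
            samples[tok] = (m["tissue"], m["stage"], int(m["rep"]))
        n_fields = len(columns)
        index, data = [], []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != n_fields:
                raise FormatError(
                    f"{path}: line {lineno}: expected {n_fields} fields, "
                    f"got {len(fields)}"
                )
            index.append(fields[0])
            try:
                data.append([float(v) for v in fields[1:]])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    values = pd.DataFrame(data, index=pd.Index(index, name="gene_id"), columns=columns[1:])
    return ExpressionMatrix(values=values, samples=samples)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# GO annotation map


def read_go_map(path: str | Path) -> pd.DataFrame:
    """Read a gene-to-GO map TSV with columns gene_id, go_id, go_description."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=0,
        dtype=str,
    )
    expected = ["gene_id", "go_id", "go_description"]
    if list(df.columns[:3]) != expected:
        raise FormatError(f"{path}: header must be {expected}")
    return df[expected]


def write_go_map(go_map: pd.DataFrame, path: str | Path) -> None:
    go_map.to_csv(path, sep="\t", index=False)
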