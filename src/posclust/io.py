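"""Readers, writers and validated in-memory containers for the pipeline's formats.

Three containers flow through the pipeline:

``GenomeTable``
    The gene-order coordinate system: every gene sits on one scaffold at an
    ordinal position (its 0-based rank in the coordinate-sorted gene list of
    that scaffold).  Ordinals, not base pairs, are the distance unit of the
    cluster scan.
``ExpressionMatrix``
    A genes x samples matrix of strictly positive hybridization intensities
    with a sample design (condition, replicate).
``GeneList``
    An ordered, duplicate-free list of gene ids with an optional regulation
    direction.

Formats: TSV (tab-separated, header row, ``#`` comments, UTF-8), GFF3 (gene
features only), BED6 and one-id-per-line gene lists.  Internally ordinals are
0-based and bp coordinates 1-based inclusive; BED is read and written with the
standard 0-based half-open convention.
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeTable",
    "ExpressionMatrix",
    "GeneList",
    "ValidationError",
    "read_genome_table",
    "read_expression",
    "write_expression",
    "read_gene_list",
    "write_gene_list",
    "write_clusters_bed",
]

GENOME_COLUMNS = ["gene_id", "scaffold", "ordinal", "start_bp", "end_bp", "strand", "categories"]


class ValidationError(ValueError):
    """An input file or container violates a format invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenomeTable:
    """Ordered gene loci per scaffold, with optional bp coordinates and labels.

    ``df`` holds one row per gene with columns ``gene_id``, ``scaffold``,
    ``ordinal`` (0-based, contiguous within scaffold), optional ``start_bp`` /
    ``end_bp`` (1-based inclusive), ``strand`` and ``categories`` (semicolon-
    separated labels, empty string for none).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in GENOME_COLUMNS:
            if col not in df.columns:
                if col in ("start_bp", "end_bp"):
                    df[col] = pd.NA
                elif col == "strand":
                    df[col] = "."
                elif col == "categories":
                    df[col] = ""
                else:
                    raise ValidationError(f"genome table is missing required column {col!r}")
        df["categories"] = df["categories"].fillna("").astype(str)
        df["strand"] = df["strand"].fillna(".").astype(str)
        df = df.sort_values(["scaffold", "ordinal"], kind="mergesort").reset_index(drop=True)
        self.df = df[GENOME_COLUMNS + [c for c in df.columns if c not in GENOME_COLUMNS]]
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        df = self.df
        dup = df["gene_id"][df["gene_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate gene ids: {sorted(set(dup))[:5]}")
        for scaffold, sub in df.groupby("scaffold", sort=False):
            ords = np.sort(sub["ordinal"].to_numpy())
            if not np.array_equal(ords, np.arange(len(sub))):
                raise ValidationError(
                    f"ordinals on scaffold {scaffold!r} are not contiguous 0..{len(sub) - 1}"
                )
            if sub["start_bp"].notna().all() and len(sub) > 1:
                s = sub.sort_values("ordinal")
                starts = s["start_bp"].to_numpy(float)
                ends = s["end_bp"].to_numpy(float)
                if (ends < starts).any():
                    bad = s.loc[ends < starts, "gene_id"].iloc[0]
                    raise ValidationError(f"gene {bad!r}: end_bp < start_bp")
                if (np.diff(starts) < 0).any():
                    i = int(np.where(np.diff(starts) < 0)[0][0])
                    bad = s["gene_id"].iloc[i + 1]
                    raise ValidationError(
                        f"gene {bad!r} on {scaffold!r}: ordinal order conflicts with start_bp order"
                    )

    # -- accessors ----------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.df)

    @property
    def scaffolds(self) -> list[str]:
        return list(dict.fromkeys(self.df["scaffold"]))

    def scaffold_sizes(self) -> dict[str, int]:
        return self.df.groupby("scaffold", sort=False).size().to_dict()

    def hit_ordinals(self, hit_ids: Iterable[str]) -> dict[str, np.ndarray]:
        """Sorted hit ordinals per scaffold; raises if any id is absent."""
        hit_ids = list(hit_ids)
        idx = self.df.set_index("gene_id")
        missing = [g for g in hit_ids if g not in idx.index]
        if missing:
            raise ValidationError(f"{len(missing)} hit ids absent from genome: {missing[:10]}")
        sub = idx.loc[hit_ids]
        return {
            scaf: np.sort(grp["ordinal"].to_numpy(int))
            for scaf, grp in sub.groupby("scaffold", sort=False)
        }

    def category_mask(self, label: str) -> pd.Series:
        """Boolean per-gene mask for a category label (exact, case-sensitive)."""
        pat = re.compile(rf"(?:^|;){re.escape(label)}(?:;|$)")
        return self.df["categories"].map(lambda s: bool(pat.search(s)))

    def genes_in_span(self, scaffold: str, start_ordinal: int, end_ordinal: int) -> pd.DataFrame:
        sub = self.df[self.df["scaffold"] == scaffold]
        return sub[(sub["ordinal"] >= start_ordinal) & (sub["ordinal"] <= end_ordinal)]

    # -- IO ------------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        self.df[GENOME_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="")

    def to_gff3(self, path: str | Path) -> None:
        if self.df["start_bp"].isna().any():
            raise ValidationError("cannot write GFF3 without bp coordinates")
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for row in self.df.itertuples(index=False):
                attrs = f"ID={row.gene_id}"
                if row.categories:
                    attrs += f";categories={row.categories.replace(';', ',')}"
                fh.write(
                    f"{row.scaffold}\tposclust\tgene\t{int(row.start_bp)}\t{int(row.end_bp)}"
                    f"\t.\t{row.strand}\t.\t{attrs}\n"
                )


@dataclass
class ExpressionMatrix:
    """Positive intensity matrix (genes x samples) with a replicate design.

    ``values``: DataFrame indexed by gene_id with one column per sample.
    ``design``: DataFrame indexed by sample_id with columns ``condition``
    (``control`` / ``treatment``) and ``replicate`` (1-based int).
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = [s for s in self.values.columns if s not in self.design.index]
        if missing:
            raise ValidationError(f"samples absent from design: {missing}")
        extra = [s for s in self.design.index if s not in self.values.columns]
        if extra:
            raise ValidationError(f"design samples absent from matrix: {extra}")
        vals = self.values.to_numpy(float)
        if not np.all(vals > 0):
            bad = self.values.index[np.where(vals <= 0)[0][0]]
            raise ValidationError(f"non-positive intensity at gene {bad!r}; intensities must be > 0")
        conds = set(self.design["condition"])
        if not conds <= {"control", "treatment"}:
            raise ValidationError(f"conditions must be control/treatment, got {sorted(conds)}")
        for cond in conds:
            if (self.design["condition"] == cond).sum() < 1:
                raise ValidationError(f"condition {cond!r} has no samples")

    def samples_of(self, condition: str) -> list[str]:
        return list(self.design.index[self.design["condition"] == condition])

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def to_tsv(self, path_matrix: str | Path, path_design: str | Path) -> None:
        self.values.rename_axis("gene_id").to_csv(path_matrix, sep="\t")
        self.design.rename_axis("sample_id").to_csv(path_design, sep="\t")


@dataclass
class GeneList:
    """Ordered duplicate-free gene ids with a label and optional direction."""

    ids: tuple[str, ...]
    label: str = ""
    direction: str | None = None  # "up" | "down" | None

    def __post_init__(self) -> None:
        ids = tuple(self.ids)
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dups = [g for g in ids if g in seen or seen.add(g)]  # type: ignore[func-returns-value]
            raise ValidationError(f"duplicate ids in gene list {self.label!r}: {dups[:5]}")
        if self.direction not in (None, "up", "down"):
            raise ValidationError(f"direction must be up/down/None, got {self.direction!r}")
        self.ids = ids

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(self.ids)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            if self.label:
                fh.write(f"# {self.label}\n")
            for g in self.ids:
                fh.write(g + "\n")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str, "scaffold": str})


def read_genome_table(path: str | Path, format: str = "tsv") -> GenomeTable:
    """Load a genome gene-order table from TSV, GFF3 or BED.

    For GFF3 and BED the ordinal index is derived by sorting gene features
    within each scaffold by (start, end, gene_id); BED's 0-based half-open
    intervals are converted to 1-based inclusive ``start_bp``/``end_bp``.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"genome table not found: {path}")
    if format == "tsv":
        df = _read_tsv(path)
        need = {"gene_id", "scaffold", "ordinal"}
        if not need <= set(df.columns):
            raise ValidationError(f"genome TSV must have columns {sorted(need)}")
        return GenomeTable(df)
    if format == "gff3":
        return _read_gff3(path)
    if format == "bed":
        return _read_bed(path)
    raise ValidationError(f"unknown genome format {format!r}")


def _read_gff3(path: Path) -> GenomeTable:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        cats = feat.attributes.get("categories", [""])[0].replace(",", ";")
        rows.append((gene_id, feat.seqid, feat.start, feat.end, feat.strand or ".", cats))
    if not rows:
        raise ValidationError(f"no gene features in {path}")
    df = pd.DataFrame(rows, columns=["gene_id", "scaffold", "start_bp", "end_bp", "strand", "categories"])
    return _ordinals_from_coords(df)


def _read_bed(path: Path) -> GenomeTable:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["scaffold", "chromStart", "chromEnd", "gene_id", "score", "strand"],
        usecols=range(6),
    )
    # BED is 0-based half-open; internal bp is 1-based inclusive
    df["start_bp"] = df["chromStart"].astype(int) + 1
    df["end_bp"] = df["chromEnd"].astype(int)
    df["categories"] = ""
    df["gene_id"] = df["gene_id"].astype(str)
    return _ordinals_from_coords(df[["gene_id", "scaffold", "start_bp", "end_bp", "strand", "categories"]])


def _ordinals_from_coords(df: pd.DataFrame) -> GenomeTable:
    df = df.sort_values(["scaffold", "start_bp", "end_bp", "gene_id"], kind="mergesort").reset_index(drop=True)
    df["ordinal"] = df.groupby("scaffold", sort=False).cumcount()
    return GenomeTable(df)


def read_expression(path_matrix: str | Path, path_design: str | Path) -> ExpressionMatrix:
    """Load an intensity matrix and its sample design TSV."""
    values = pd.read_csv(path_matrix, sep="\t", comment="#", index_col=0)
    values.index = values.index.astype(str)
    design = pd.read_csv(path_design, sep="\t", comment="#", index_col=0)
    design.index = design.index.astype(str)
    if "condition" not in design.columns or "replicate" not in design.columns:
        raise ValidationError("design TSV needs columns sample_id, condition, replicate")
    return ExpressionMatrix(values, design)


def write_expression(em: ExpressionMatrix, path_matrix: str | Path, path_design: str | Path) -> None:
    em.to_tsv(path_matrix, path_design)


def read_gene_list(path: str | Path, label: str | None = None, direction: str | None = None) -> GeneList:
    """One gene id per line; ``#`` lines are comments."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"gene list not found: {path}")
    ids = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.append(line)
    return GeneList(tuple(ids), label=label or path.stem, direction=direction)


def write_gene_list(gl: GeneList, path: str | Path) -> None:
    gl.to_file(path)


# ---------------------------------------------------------------------------
# cluster output
# ---------------------------------------------------------------------------

def write_clusters_bed(scan, genome: GenomeTable, path: str | Path) -> None:
    """Write called clusters as BED6 (bp space) or a TSV fallback (ordinal space).

    BED6 fields: chrom=scaffold, chromStart=min start_bp - 1 (0-based),
    chromEnd=max end_bp, name=cluster id, score=round(100 * enrichment)
    capped at 1000, strand ".".  Without bp coordinates the same clusters are
    written as a TSV in ordinal space.
    """
    have_bp = genome.df["start_bp"].notna().all()
    with open(path, "w") as fh:
        if not scan.clusters:
            fh.write("# no clusters called\n")
            return
        if have_bp:
            for i, c in enumerate(scan.clusters, 1):
                span = genome.genes_in_span(c.scaffold, c.start_ordinal, c.end_ordinal)
                start = int(span["start_bp"].min()) - 1
                end = int(span["end_bp"].max())
                score = min(1000, round(100 * c.enrichment))
                fh.write(f"{c.scaffold}\t{start}\t{end}\tcluster_{i}\t{score}\t.\n")
        else:
            fh.write("# ordinal-space cluster table (no bp coordinates available)\n")
            fh.write("scaffold\tstart_ordinal\tend_ordinal\tn_hits\tenrichment\n")
            for c in scan.clusters:
                fh.write(
                    f"{c.scaffold}\t{c.start_ordinal}\t{c.end_ordinal}\t{c.n_hits}\t{c.enrichment:.4g}\n"
                )
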