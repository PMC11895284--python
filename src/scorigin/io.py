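"""Readers and writers for the package's input and output tables.

Expression input follows the Cell Ranger v3 directory layout: a MatrixMarket
``matrix.mtx`` storing genes x cells (transposed to cells x genes on read),
``barcodes.tsv`` and a three-column ``features.tsv`` (id, symbol, type).
Plain and gzip-compressed files are both accepted.

Allele counts arrive as a long-format TSV (one row per cell/variant with
nonzero coverage) and are pivoted into sparse cells x variants matrices.
Variant positions are 1-based, following VCF convention; all matrix indices
are 0-based internally.

Results are emitted as TSV rather than a language-specific serialization so
they can be consumed from any environment.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from ._errors import FormatError

COMPARTMENTS = ("blood", "tissue", "unassigned")

#: sentinel origin values beyond integer origin indices
ORIGIN_SPECIAL = ("doublet", "ambiguous", "unassigned")

ANNOTATION_COLUMNS = ["barcode", "cell_type", "compartment", "origin", "doublet_flag"]


@dataclass
class ExpressionMatrix:
    """Sparse cells x genes count (or normalized) matrix with identifiers.

    Parameters
    ----------
    counts
        Sparse matrix, rows are cells, columns genes. Raw data is
        nonnegative integers; normalized data is nonnegative reals.
    barcodes
        Unique cell barcodes, one per row.
    genes
        ``(gene_id, gene_symbol)`` pairs, one per column.
    """

    counts: sp.csr_matrix
    barcodes: list[str]
    genes: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.barcodes = list(self.barcodes)
        self.genes = [tuple(g) for g in self.genes]
        n, m = self.counts.shape
        if n != len(self.barcodes):
            raise FormatError(
                f"matrix has {n} rows but {len(self.barcodes)} barcodes"
            )
        if m != len(self.genes):
            raise FormatError(f"matrix has {m} columns but {len(self.genes)} genes")
        if len(set(self.barcodes)) != len(self.barcodes):
            dupes = pd.Series(self.barcodes)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise FormatError(f"duplicate barcodes: {dupes[:5]}")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("expression matrix contains negative entries")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def gene_ids(self) -> list[str]:
        return [g[0] for g in self.genes]

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        """Column subset in the given gene order."""
        index = {g: j for j, g in enumerate(self.gene_ids)}
        cols = [index[g] for g in gene_ids]
        return ExpressionMatrix(
            self.counts[:, cols], self.barcodes, [self.genes[j] for j in cols]
        )

    def subset_cells(self, barcodes: list[str]) -> "ExpressionMatrix":
        """Row subset in the given barcode order."""
        index = {b: i for i, b in enumerate(self.barcodes)}
        rows = [index[b] for b in barcodes]
        return ExpressionMatrix(self.counts[rows], list(barcodes), self.genes)


@dataclass
class AlleleCountMatrix:
    """Paired sparse ref/alt read-count matrices over cells x variants."""

    ref_counts: sp.csr_matrix
    alt_counts: sp.csr_matrix
    variants: pd.DataFrame  # columns: chrom, pos, ref, alt, maf
    barcodes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ref_counts = sp.csr_matrix(self.ref_counts)
        self.alt_counts = sp.csr_matrix(self.alt_counts)
        self.barcodes = list(self.barcodes)
        if self.ref_counts.shape != self.alt_counts.shape:
            raise FormatError("ref and alt count layers differ in shape")
        n, v = self.ref_counts.shape
        if n != len(self.barcodes):
            raise FormatError(f"{n} rows but {len(self.barcodes)} barcodes")
        if v != len(self.variants):
            raise FormatError(f"{v} columns but {len(self.variants)} variants")
        for layer in (self.ref_counts, self.alt_counts):
            if layer.nnz and layer.data.min() < 0:
                raise FormatError("negative read counts")
        maf = np.asarray(self.variants["maf"], dtype=float)
        if ((maf < 0) | (maf > 0.5)).any():
            raise FormatError("population MAF outside [0, 0.5]")

    @property
    def n_cells(self) -> int:
        return self.ref_counts.shape[0]

    @property
    def n_variants(self) -> int:
        return self.ref_counts.shape[1]

    @property
    def depth(self) -> sp.csr_matrix:
        """Total read depth per cell/variant."""
        return self.ref_counts + self.alt_counts

    def subset_variants(self, mask: np.ndarray) -> "AlleleCountMatrix":
        idx = np.flatnonzero(np.asarray(mask, dtype=bool))
        return AlleleCountMatrix(
            self.ref_counts[:, idx],
            self.alt_counts[:, idx],
            self.variants.iloc[idx].reset_index(drop=True),
            self.barcodes,
        )


def _find_10x_file(directory: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = directory / name
        if p.exists():
            return p
    raise FormatError(f"missing required file {stem}[.gz] in {directory}")


def _read_tsv_column(path: Path, column: int = 0) -> list[list[str]]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n").split("\t") for line in fh if line.strip()]


def read_10x_mtx(directory: str | Path) -> ExpressionMatrix:
    """Read a Cell Ranger v3 matrix directory into a cells x genes matrix.

    The MatrixMarket file stores genes as rows and cells as columns; this
    reader transposes so that cells are rows.
    """
    directory = Path(directory)
    mtx_path = _find_10x_file(directory, "matrix.mtx")
    barcodes_path = _find_10x_file(directory, "barcodes.tsv")
    features_path = _find_10x_file(directory, "features.tsv")

    try:
        mat = scipy.io.mmread(str(mtx_path))
    except Exception as exc:  # noqa: BLE001 - surface as format error
        raise FormatError(f"cannot parse MatrixMarket file {mtx_path}: {exc}") from exc
    mat = sp.csr_matrix(mat).T  # genes x cells on disk -> cells x genes

    barcodes = [row[0] for row in _read_tsv_column(barcodes_path)]
    feature_rows = _read_tsv_column(features_path)
    genes = [(row[0], row[1] if len(row) > 1 else row[0]) for row in feature_rows]

    if mat.shape[0] != len(barcodes):
        raise FormatError(
            f"matrix declares {mat.shape[0]} cells but barcodes.tsv has "
            f"{len(barcodes)} entries"
        )
    if mat.shape[1] != len(genes):
        raise FormatError(
            f"matrix declares {mat.shape[1]} genes but features.tsv has "
            f"{len(genes)} entries"
        )
    return ExpressionMatrix(mat, barcodes, genes)


def write_10x_mtx(m: ExpressionMatrix, directory: str | Path) -> None:
    """Write the Cell Ranger v3 plain-text dialect (genes x cells on disk)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(directory / "matrix.mtx"), sp.coo_matrix(m.counts.T))
    (directory / "barcodes.tsv").write_text("".join(b + "\n" for b in m.barcodes))
    (directory / "features.tsv").write_text(
        "".join(f"{gid}\t{sym}\tGene Expression\n" for gid, sym in m.genes)
    )


def new_annotations(barcodes: list[str], cell_types: list[str]) -> pd.DataFrame:
    """Build a fresh annotation table with compartment/origin unassigned."""
    return pd.DataFrame(
        {
            "barcode": list(barcodes),
            "cell_type": list(cell_types),
            "compartment": "unassigned",
            "origin": "unassigned",
            "doublet_flag": False,
        }
    )


def _validate_annotations(df: pd.DataFrame) -> pd.DataFrame:
    if df["barcode"].duplicated().any():
        dupes = sorted(df.loc[df["barcode"].duplicated(), "barcode"].unique())
        raise FormatError(f"duplicate barcodes in annotations: {dupes[:5]}")
    bad = set(df["compartment"]) - set(COMPARTMENTS)
    if bad:
        raise FormatError(f"unknown compartment values: {sorted(bad)}")
    return df


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a per-cell annotation TSV.

    Mandatory columns: ``barcode``, ``cell_type``. Optional: ``compartment``,
    ``origin``, ``doublet_flag``; anything else is ignored. Origin values are
    kept as strings ("0", "1", ..., "doublet", "ambiguous", "unassigned").
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("barcode", "cell_type"):
        if col not in df.columns:
            raise FormatError(f"annotation file {path} lacks mandatory column {col!r}")
    out = pd.DataFrame({"barcode": df["barcode"], "cell_type": df["cell_type"]})
    out["compartment"] = df.get("compartment", pd.Series("unassigned", index=df.index))
    out["origin"] = df.get("origin", pd.Series("unassigned", index=df.index))
    out["compartment"] = out["compartment"].fillna("unassigned")
    out["origin"] = out["origin"].fillna("unassigned")
    if "doublet_flag" in df.columns:
        out["doublet_flag"] = df["doublet_flag"].str.lower().isin(("true", "1"))
    else:
        out["doublet_flag"] = out["origin"] == "doublet"
    return _validate_annotations(out.reset_index(drop=True))


def write_results(annotations: pd.DataFrame, path: str | Path) -> None:
    """Write the annotation table as TSV; round-trips via read_annotations."""
    df = annotations.copy()
    for col in ("compartment", "origin"):
        if col not in df.columns:
            df[col] = "unassigned"
    if "doublet_flag" not in df.columns:
        df["doublet_flag"] = False
    df["doublet_flag"] = df["doublet_flag"].astype(bool) | (
        df["origin"].astype(str) == "doublet"
    )
    df = df[ANNOTATION_COLUMNS]
    df.to_csv(path, sep="\t", index=False)


def read_allele_counts(path: str | Path) -> AlleleCountMatrix:
    """Read a long-format allele-count TSV into sparse matrices.

    Expected columns: barcode, chrom, pos, ref, alt, ref_count, alt_count,
    maf. Duplicate (barcode, variant) rows have their counts summed.
    Variants are ordered by (chrom, pos); barcodes keep first-seen order.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"barcode": str, "chrom": str, "ref": str, "alt": str},
    )
    required = ["barcode", "chrom", "pos", "ref", "alt", "ref_count", "alt_count", "maf"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"allele-count file lacks columns {missing}")
    if (df[["ref_count", "alt_count"]].to_numpy() < 0).any():
        raise FormatError("negative read counts in allele-count file")
    if ((df["maf"] < 0) | (df["maf"] > 0.5)).any():
        raise FormatError("population MAF outside [0, 0.5]")

    variants = (
        df[["chrom", "pos", "ref", "alt", "maf"]]
        .drop_duplicates(subset=["chrom", "pos", "ref", "alt"])
        .sort_values(["chrom", "pos"], kind="stable")
        .reset_index(drop=True)
    )
    var_key = list(zip(variants["chrom"], variants["pos"], variants["ref"], variants["alt"]))
    var_index = {k: j for j, k in enumerate(var_key)}

    barcodes = list(dict.fromkeys(df["barcode"]))
    bc_index = {b: i for i, b in enumerate(barcodes)}

    rows = df["barcode"].map(bc_index).to_numpy()
    cols = [
        var_index[k] for k in zip(df["chrom"], df["pos"], df["ref"], df["alt"])
    ]
    shape = (len(barcodes), len(variants))
    ref_m = sp.coo_matrix((df["ref_count"], (rows, cols)), shape=shape).tocsr()
    alt_m = sp.coo_matrix((df["alt_count"], (rows, cols)), shape=shape).tocsr()
    return AlleleCountMatrix(ref_m, alt_m, variants, barcodes)


def write_allele_counts(a: AlleleCountMatrix, path: str | Path) -> None:
    """Write the long-format TSV dialect read by :func:`read_allele_counts`.

    Emits one row per cell/variant with nonzero total coverage.
    """
    depth = sp.coo_matrix(a.depth)
    order = np.lexsort((depth.col, depth.row))
    rows, cols = depth.row[order], depth.col[order]
    ref = np.asarray(a.ref_counts[rows, cols]).ravel().astype(int)
    alt = np.asarray(a.alt_counts[rows, cols]).ravel().astype(int)
    var = a.variants.iloc[cols]
    out = pd.DataFrame(
        {
            "barcode": [a.barcodes[i] for i in rows],
            "chrom": var["chrom"].to_numpy(),
            "pos": var["pos"].to_numpy(),
            "ref": var["ref"].to_numpy(),
            "alt": var["alt"].to_numpy(),
            "ref_count": ref,
            "alt_count": alt,
            "maf": var["maf"].to_numpy(),
        }
    )
    out.to_csv(path, sep="\t", index=False)
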