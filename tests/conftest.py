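import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from scorigin import AlleleCountMatrix, ExpressionMatrix


@pytest.fixture
def toy_10x_dir(tmp_path):
    """Cell Ranger v3 plain-text directory: 3 genes x 2 cells.

    Entries (gene1, cell1)=5 and (gene3, cell2)=2 in the on-disk
    genes x cells orientation.
    """
    d = tmp_path / "toy10x"
    d.mkdir()
    (d / "matrix.mtx").write_text(
        "%%MatrixMarket matrix coordinate integer general\n"
        "3 2 2\n"
        "1 1 5\n"
        "3 2 2\n"
    )
    (d / "barcodes.tsv").write_text("AAAC-1\nAAAG-1\n")
    (d / "features.tsv").write_text(
        "ENSG1\tGENE1\tGene Expression\n"
        "ENSG2\tGENE2\tGene Expression\n"
        "ENSG3\tGENE3\tGene Expression\n"
    )
    return d


@pytest.fixture
def small_expression():
    """4 cells x 3 genes dense-ish count matrix."""
    counts = sp.csr_matrix(
        np.array([[10, 0, 0], [1, 1, 0], [3, 3, 0], [0, 2, 8]])
    )
    return ExpressionMatrix(
        counts,
        ["c1", "c2", "c3", "c4"],
        [("g1", "G1"), ("g2", "G2"), ("g3", "G3")],
    )


def make_allele_counts(ref, alt, maf=None, barcodes=None):
    """Build an AlleleCountMatrix from dense arrays."""
    ref = np.asarray(ref)
    alt = np.asarray(alt)
    n, v = ref.shape
    if maf is None:
        maf = np.full(v, 0.05)
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, v + 1),
            "ref": "A",
            "alt": "G",
            "maf": maf,
        }
    )
    if barcodes is None:
        barcodes = [f"c{i}" for i in range(n)]
    return AlleleCountMatrix(sp.csr_matrix(ref), sp.csr_matrix(alt), variants, barcodes)


@pytest.fixture
def toy_allele_counts():
    ref = [[2, 0], [0, 1], [1, 1]]
    alt = [[0, 3], [2, 0], [1, 0]]
    return make_allele_counts(ref, alt)
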