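"""Normalization, feature selection and the shared latent space.

Query and reference cells must live in one coordinate system before
distances to the reference mean anything. Both matrices therefore pass
through the identical transform: library-size normalization, a common
feature list, per-gene z-scaling fitted on the concatenation, and a joint
PCA (optionally followed by UMAP on the PCA coordinates).

PCA output is made bit-reproducible by fixing each component's sign so that
its largest-magnitude loading is positive. UMAP is deterministic under a
fixed ``seed``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA

from ._errors import ConfigError, DataError
from .io import ExpressionMatrix

TARGET_SUM = 10_000.0

#: UMAP hyperparameters used whenever method="umap"
UMAP_PARAMS = {"n_neighbors": 30, "min_dist": 0.3}


@dataclass
class Embedding:
    """Cells x d latent coordinates.

    ``coords`` rows align with ``cell_index`` barcodes. ``method`` records
    whether the space is PCA or UMAP; distances are only comparable between
    embeddings produced by the same joint call.
    """

    coords: np.ndarray
    cell_index: list[str]
    method: str

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2:
            raise DataError("embedding coordinates must be 2-D")
        if not np.isfinite(self.coords).all():
            raise DataError("embedding contains non-finite values")
        if self.coords.shape[0] != len(self.cell_index):
            raise DataError("embedding rows do not match cell index")

    @property
    def d(self) -> int:
        return self.coords.shape[1]


def normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each cell to 10,000 total counts, then log1p.

    Raises
    ------
    DataError
        If any cell has zero total counts (the offending barcodes are
        listed; filter them upstream).
    """
    totals = np.asarray(m.counts.sum(axis=1)).ravel()
    zero = totals == 0
    if zero.any():
        bad = [m.barcodes[i] for i in np.flatnonzero(zero)[:10]]
        raise DataError(f"cells with zero total counts: {bad}")
    scaled = sp.diags(TARGET_SUM / totals) @ m.counts.astype(float)
    scaled.data = np.log1p(scaled.data)
    return ExpressionMatrix(scaled, m.barcodes, m.genes)


def _dispersion(x: sp.csr_matrix) -> np.ndarray:
    """Per-gene variance/mean ratio (0 where the gene is silent)."""
    x = sp.csr_matrix(x)
    mean = np.asarray(x.mean(axis=0)).ravel()
    sq = np.asarray(x.multiply(x).mean(axis=0)).ravel()
    var = np.maximum(sq - mean**2, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    return disp


def select_features(
    query: ExpressionMatrix, ref: ExpressionMatrix, n_hvg: int = 2000
) -> list[str]:
    """Pick highly variable genes shared by query and reference.

    Both inputs are expected normalized. Genes in the intersection are
    ranked by dispersion (variance/mean) on the concatenated matrix; the top
    ``n_hvg`` gene ids are returned, or the whole intersection when it is
    smaller. Ties break toward query gene order for determinism.
    """
    shared = [g for g in query.gene_ids if g in set(ref.gene_ids)]
    if not shared:
        raise DataError("query and reference share no genes")
    q = query.subset_genes(shared)
    r = ref.subset_genes(shared)
    disp = _dispersion(sp.vstack([q.counts, r.counts]))
    if len(shared) <= n_hvg:
        return shared
    order = np.argsort(-disp, kind="stable")[:n_hvg]
    return [shared[j] for j in sorted(order)]


def _zscale(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0  # constant features carry no signal; leave centered
    return (x - mu) / sd


def _pca_fixed_sign(x: np.ndarray, d: int) -> np.ndarray:
    pca = PCA(n_components=d, svd_solver="full")
    coords = pca.fit_transform(x)
    # orient each component so its largest-|loading| entry is positive
    for j in range(d):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, j] *= -1
    return coords


def joint_embed(
    query: ExpressionMatrix,
    ref: ExpressionMatrix,
    d: int = 10,
    method: str = "umap",
    seed: int = 0,
) -> tuple[Embedding, Embedding]:
    """Embed query and reference cells jointly into a d-dimensional space.

    Cells are concatenated, features z-scaled on the concatenation, and a
    d-component PCA computed. With ``method="umap"`` the PCA coordinates are
    further embedded into d-dimensional UMAP (n_neighbors=30, min_dist=0.3,
    fixed seed). The rows are then split back into the two embeddings.
    """
    if method not in ("pca", "umap"):
        raise ConfigError(f"unknown embedding method {method!r}")
    if query.gene_ids != ref.gene_ids:
        raise DataError("query and reference must share an identical feature list")
    n_q, n_r = query.n_cells, ref.n_cells
    n_features = query.n_genes
    if d > n_features:
        raise ConfigError(f"latent dimension {d} exceeds feature count {n_features}")
    if n_q + n_r < d + 1:
        raise DataError(f"need at least {d + 1} cells for a {d}-dimensional embedding")

    x = np.vstack([np.asarray(query.counts.todense()), np.asarray(ref.counts.todense())])
    coords = _pca_fixed_sign(_zscale(x), d)

    if method == "umap":
        import umap  # deferred: numba-jitted import is slow

        n_neighbors = min(UMAP_PARAMS["n_neighbors"], n_q + n_r - 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # umap warns about forced determinism
            reducer = umap.UMAP(
                n_components=d,
                n_neighbors=n_neighbors,
                min_dist=UMAP_PARAMS["min_dist"],
                random_state=seed,
            )
            coords = np.asarray(reducer.fit_transform(coords), dtype=float)

    return (
        Embedding(coords[:n_q], query.barcodes, method),
        Embedding(coords[n_q:], ref.barcodes, method),
    )
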