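"""Blood vs. tissue-resident classification of immune cells.

Dissociated solid-tissue samples carry immune cells from the blood in their
vessels alongside genuinely tissue-resident cells of the same types. The
two populations are transcriptionally close, so instead of marker genes the
classifier uses geometry: for each immune cell type, query cells and a
whole-blood reference are embedded jointly, each query cell is summarized
by its vector of Euclidean distances to every reference cell (its distance
profile), and k-means (k=2) on those profiles splits the cells into two
clusters. The cluster closer to the whole-blood reference — smaller average
of per-cell mean reference distances — is called blood; the other is the
expected tissue-resident population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from ._errors import ConfigError, DataError
from .io import ExpressionMatrix
from .preprocess import Embedding, joint_embed, normalize, select_features

#: immune cell types processed by default
DEFAULT_IMMUNE_TYPES = (
    "monocytes",
    "macrophages",
    "T-cells",
    "regulatory T-cells",
    "plasma cells",
    "NK cells",
    "B-cells",
)


@dataclass
class DistanceProfile:
    """Pairwise Euclidean distances: query cells (rows) x reference cells."""

    dist: np.ndarray
    query_index: list[str]
    ref_index: list[str]

    def __post_init__(self) -> None:
        self.dist = np.asarray(self.dist, dtype=float)
        if self.dist.shape != (len(self.query_index), len(self.ref_index)):
            raise DataError("distance matrix shape does not match indices")
        if (self.dist < 0).any():
            raise DataError("negative distances")


@dataclass
class BloodTissueConfig:
    """Tunable knobs of the blood/tissue step.

    ``profile_summary`` selects the k-means feature vector: "full" clusters
    the complete distance-profile rows (default, preserves geometry);
    "mean" clusters the scalar per-cell mean reference distance.
    """

    immune_types: tuple[str, ...] = DEFAULT_IMMUNE_TYPES
    min_cells: int = 20
    n_hvg: int = 2000
    latent_dim: int = 10
    embed_method: str = "umap"
    k: int = 2
    seed: int = 0
    profile_summary: str = "full"
    extra: dict = field(default_factory=dict)


def distance_profiles(q: Embedding, r: Embedding) -> DistanceProfile:
    """Euclidean distance from every query cell to every reference cell."""
    if q.d != r.d:
        raise DataError(f"embedding dimensions differ: {q.d} vs {r.d}")
    if q.method != r.method:
        raise DataError("query and reference embeddings use different methods")
    return DistanceProfile(
        cdist(q.coords, r.coords, metric="euclidean"), q.cell_index, r.cell_index
    )


def _deterministic_init(features: np.ndarray, row_means: np.ndarray, k: int) -> np.ndarray:
    """Initial centers at quantiles of mean reference distance.

    Geometry-based initialization keeps the clustering invariant to the
    order and naming of cells, which seeded k-means++ is not.
    """
    order = np.argsort(row_means, kind="stable")
    picks = [order[int(round(t * (len(order) - 1)))] for t in np.linspace(0, 1, k)]
    return features[picks]


def cluster_profiles(p: DistanceProfile, k: int = 2, seed: int = 0,
                     profile_summary: str = "full") -> np.ndarray:
    """k-means over distance profiles; returns labels in {0..k-1}.

    Each query cell's feature vector is its full row of distances to the
    reference (or the scalar row mean with ``profile_summary="mean"``).
    With fewer query cells than k, all cells fall in cluster 0 and a
    warning is emitted.
    """
    if profile_summary == "full":
        features = p.dist
    elif profile_summary == "mean":
        features = p.dist.mean(axis=1, keepdims=True)
    else:
        raise ConfigError(f"unknown profile_summary {profile_summary!r}")

    n = features.shape[0]
    if n < k:
        warnings.warn(
            f"only {n} query cells for k={k}; assigning all to cluster 0",
            stacklevel=2,
        )
        return np.zeros(n, dtype=int)
    if len(np.unique(features, axis=0)) < k:
        # degenerate: fewer distinct profiles than clusters
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        return km.fit_predict(features)
    init = _deterministic_init(features, p.dist.mean(axis=1), k)
    km = KMeans(n_clusters=k, init=init, n_init=1, random_state=seed)
    return km.fit_predict(features)


def label_compartments(p: DistanceProfile, labels: np.ndarray,
                       cell_type: str = "") -> pd.DataFrame:
    """Name the cluster nearer the whole-blood reference "blood".

    Per cell, ``mean_ref_distance`` is the row mean of the distance matrix.
    The cluster whose cells have the smaller average mean_ref_distance is
    blood; the other is tissue. A tie breaks toward cluster 0 = blood with
    a warning, as does a degenerate single-cluster input.
    """
    labels = np.asarray(labels, dtype=int)
    row_means = p.dist.mean(axis=1)
    present = np.unique(labels)
    if len(present) == 1:
        warnings.warn("single cluster present; labeling all cells blood", stacklevel=2)
        mapping = {present[0]: "blood"}
    else:
        means = {c: row_means[labels == c].mean() for c in present}
        lo, hi = sorted(present, key=lambda c: (means[c], c))
        if means[lo] == means[hi]:
            warnings.warn(
                "cluster mean distances tied; labeling cluster 0 blood", stacklevel=2
            )
            lo, hi = sorted(present)
        mapping = {lo: "blood", hi: "tissue"}
    return pd.DataFrame(
        {
            "barcode": p.query_index,
            "cell_type": cell_type,
            "compartment": [mapping[c] for c in labels],
            "cluster_id": labels,
            "mean_ref_distance": row_means,
        }
    )


def _type_seed(seed: int, cell_type: str) -> int:
    """Fan the top-level seed out per cell type, stably across runs."""
    h = 0
    for ch in cell_type:
        h = (h * 131 + ord(ch)) % 1_000_003
    return int((seed * 1_000_003 + h) % (2**31 - 1))


def classify(
    query: ExpressionMatrix,
    query_ann: pd.DataFrame,
    ref: ExpressionMatrix,
    config: BloodTissueConfig | None = None,
    ref_ann: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Run the per-cell-type blood/tissue loop.

    For every configured immune cell type with at least ``min_cells`` query
    cells, the pipeline normalize -> select_features -> joint_embed ->
    distance_profiles -> cluster_profiles -> label_compartments runs on
    that type's cells against the matching reference cells (cells of the
    same annotated type when ``ref_ann`` is given and the type is present,
    otherwise the whole reference). Cells of unlisted or under-populated
    types keep compartment "unassigned".

    Returns the annotation table with ``compartment`` filled in, plus
    ``cluster_id`` and ``mean_ref_distance`` columns for classified cells.
    """
    config = config or BloodTissueConfig()
    ann = query_ann.copy().reset_index(drop=True)
    if "compartment" not in ann.columns:
        ann["compartment"] = "unassigned"
    ann["cluster_id"] = pd.array([pd.NA] * len(ann), dtype="Int64")
    ann["mean_ref_distance"] = np.nan

    listed = [t for t in config.immune_types if (ann["cell_type"] == t).any()]
    if not listed:
        raise DataError(
            "no configured immune cell type present in the query annotations"
        )

    query_norm = normalize(query)
    ref_norm = normalize(ref)

    for cell_type in listed:
        mask = (ann["cell_type"] == cell_type).to_numpy()
        if mask.sum() < config.min_cells:
            warnings.warn(
                f"{cell_type}: {int(mask.sum())} cells < min_cells="
                f"{config.min_cells}; left unassigned",
                stacklevel=2,
            )
            continue
        if ref_ann is not None:
            ref_mask = (ref_ann["cell_type"] == cell_type).to_numpy()
            if ref_mask.any():
                ref_sub = ref_norm.subset_cells(
                    [b for b, m in zip(ref_norm.barcodes, ref_mask) if m]
                )
            else:
                warnings.warn(
                    f"{cell_type}: no matching reference cells; "
                    "using the whole reference",
                    stacklevel=2,
                )
                ref_sub = ref_norm
        else:
            ref_sub = ref_norm
        q_sub = query_norm.subset_cells(
            [b for b, m in zip(query_norm.barcodes, mask) if m]
        )

        features = select_features(q_sub, ref_sub, n_hvg=config.n_hvg)
        seed = _type_seed(config.seed, cell_type)
        q_emb, r_emb = joint_embed(
            q_sub.subset_genes(features),
            ref_sub.subset_genes(features),
            d=config.latent_dim,
            method=config.embed_method,
            seed=seed,
        )
        profile = distance_profiles(q_emb, r_emb)
        labels = cluster_profiles(
            profile, k=config.k, seed=seed, profile_summary=config.profile_summary
        )
        calls = label_compartments(profile, labels, cell_type=cell_type)

        calls = calls.set_index("barcode")
        idx = ann.index[mask]
        barcodes = ann.loc[idx, "barcode"]
        ann.loc[idx, "compartment"] = calls.loc[barcodes, "compartment"].to_numpy()
        ann.loc[idx, "cluster_id"] = calls.loc[barcodes, "cluster_id"].to_numpy()
        ann.loc[idx, "mean_ref_distance"] = calls.loc[
            barcodes, "mean_ref_distance"
        ].to_numpy()

    return ann
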