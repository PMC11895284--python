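"""Genotype-based demultiplexing of barcoded cells.

Cells pooled from multiple individuals (e.g., maternal and fetal cells in
placenta) can be separated using the alternate-allele content of their
reads at polymorphic sites, without external genotypes. The model is a
finite mixture over N origins: each origin k carries a diploid dosage
d_kv in {0, 0.5, 1} per variant v, and reads are Bernoulli draws with
alt probability p_v = d_v(1-eps) + (1-d_v)eps, eps being the sequencing
error rate. Dosages, mixing weights and per-cell origin responsibilities
are estimated by EM. Mosaic doublets — one barcode containing a ~50/50
genetic mixture of two individuals — are scored afterwards against
pairwise-averaged dosage profiles.

Rare variants carry most of the identity signal, so variants with
population minor allele frequency above a threshold (default 10%) are
excluded first.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from ._errors import ConfigError, DataError
from .io import AlleleCountMatrix

DOSAGE_LEVELS = np.array([0.0, 0.5, 1.0])


@dataclass
class GenotypeModel:
    """Fitted genotype mixture.

    dosages: (N origins x V variants) alternate-allele dosages in
    {0, 0.5, 1}. mix_weights: origin proportions (simplex). error_rate:
    per-read error probability, fixed during fitting. doublet_rate: prior
    probability that a barcode is a mosaic doublet.
    """

    dosages: np.ndarray
    mix_weights: np.ndarray
    error_rate: float = 0.01
    doublet_rate: float = 0.05
    converged: bool = True
    n_iter: int = 0
    loglik_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.mix_weights = np.asarray(self.mix_weights, dtype=float)
        if not np.isin(self.dosages, DOSAGE_LEVELS).all():
            raise DataError("dosages must lie in {0, 0.5, 1}")
        if abs(self.mix_weights.sum() - 1.0) > 1e-8 or (self.mix_weights < 0).any():
            raise DataError("mix_weights must be a simplex")
        if not 0.0 < self.error_rate < 0.5:
            raise ConfigError("error_rate must lie in (0, 0.5)")

    @property
    def n_origins(self) -> int:
        return self.dosages.shape[0]


def filter_snps(a: AlleleCountMatrix, max_maf: float = 10.0) -> AlleleCountMatrix:
    """Keep variants informative of individual identity.

    Retains variants with population MAF <= ``max_maf`` percent (boundary
    inclusive: MAF exactly at the threshold is kept) and nonzero total read
    coverage across cells.
    """
    maf = a.variants["maf"].to_numpy(dtype=float)
    coverage = np.asarray(a.depth.sum(axis=0)).ravel()
    keep = (maf <= max_maf / 100.0) & (coverage > 0)
    if not keep.any():
        raise DataError(
            f"no variants survive MAF <= {max_maf}% with nonzero coverage; "
            "raise --max-maf or check the input"
        )
    return a.subset_variants(keep)


def _alt_prob(dosage: np.ndarray, eps: float) -> np.ndarray:
    """Per-read alternate-allele probability under a dosage profile."""
    return dosage * (1.0 - eps) + (1.0 - dosage) * eps


def cell_loglik(
    ref: np.ndarray, alt: np.ndarray, dosage: np.ndarray, eps: float
) -> float:
    """Log-likelihood of one cell's read counts under a dosage profile.

    sum_v [ alt_v log p_v + ref_v log(1-p_v) ] with
    p_v = d_v (1-eps) + (1-d_v) eps. Zero-coverage variants contribute 0.
    """
    if not 0.0 < eps < 0.5:
        raise ConfigError("error rate must lie in (0, 0.5)")
    ref = np.asarray(ref, dtype=float)
    alt = np.asarray(alt, dtype=float)
    p = _alt_prob(np.asarray(dosage, dtype=float), eps)
    return float(alt @ np.log(p) + ref @ np.log1p(-p))


def _loglik_matrix(a: AlleleCountMatrix, dosages: np.ndarray, eps: float) -> np.ndarray:
    """Cells x profiles log-likelihood table (sparse-friendly)."""
    p = _alt_prob(dosages, eps)  # (profiles x V)
    return np.asarray(
        a.alt_counts @ np.log(p).T + a.ref_counts @ np.log1p(-p).T
    )


def _mstep_dosages(
    resp: np.ndarray, a: AlleleCountMatrix, eps: float
) -> np.ndarray:
    """Per origin and variant, the dosage level maximizing expected loglik."""
    alt_w = np.asarray(resp.T @ a.alt_counts)  # (N x V)
    ref_w = np.asarray(resp.T @ a.ref_counts)
    p = _alt_prob(DOSAGE_LEVELS, eps)  # (3,)
    # scores: (3 x N x V)
    scores = (
        np.log(p)[:, None, None] * alt_w[None] + np.log1p(-p)[:, None, None] * ref_w[None]
    )
    return DOSAGE_LEVELS[np.argmax(scores, axis=0)]


def _init_responsibilities(
    a: AlleleCountMatrix, n_origins: int, seed: int
) -> np.ndarray:
    """One-hot init from k-means on per-cell alt-fraction vectors.

    Zero-coverage entries are imputed at the variant's population MAF.
    """
    depth = np.asarray(a.depth.todense(), dtype=float)
    alt = np.asarray(a.alt_counts.todense(), dtype=float)
    maf = a.variants["maf"].to_numpy(dtype=float)
    frac = np.where(depth > 0, alt / np.maximum(depth, 1.0), maf[None, :])
    km = KMeans(n_clusters=n_origins, n_init=10, random_state=seed)
    labels = km.fit_predict(frac)
    resp = np.zeros((a.n_cells, n_origins))
    resp[np.arange(a.n_cells), labels] = 1.0
    return resp


def fit_mixture(
    a: AlleleCountMatrix,
    n_origins: int = 2,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-6,
    error_rate: float = 0.01,
    doublet_rate: float = 0.05,
) -> tuple[GenotypeModel, np.ndarray]:
    """Fit the N-origin genotype mixture by EM.

    E-step: responsibilities proportional to mix_weight_k x exp(cell
    log-likelihood under origin k). M-step: per origin/variant, pick the
    dosage in {0, 0.5, 1} maximizing the responsibility-weighted
    log-likelihood, then update mixing weights. The observed-data
    log-likelihood is verified non-decreasing at every iteration.

    Returns the model and the (cells x N) responsibility matrix.
    """
    if n_origins < 1:
        raise ConfigError("n_origins must be >= 1")
    if not 0.0 < error_rate < 0.5:
        raise ConfigError("error_rate must lie in (0, 0.5)")
    if a.n_cells < 1 or a.n_variants < 1:
        raise DataError("empty allele-count matrix")

    if n_origins == 1:
        resp = np.ones((a.n_cells, 1))
        dosages = _mstep_dosages(resp, a, error_rate)
        ll = float(_loglik_matrix(a, dosages, error_rate).sum())
        model = GenotypeModel(
            dosages, np.array([1.0]), error_rate, doublet_rate,
            converged=True, n_iter=1, loglik_trace=[ll],
        )
        return model, resp

    resp = _init_responsibilities(a, n_origins, seed)
    weights = resp.mean(axis=0)
    weights = np.maximum(weights, 1e-12)
    weights /= weights.sum()
    dosages = _mstep_dosages(resp, a, error_rate)

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step
        log_joint = _loglik_matrix(a, dosages, error_rate) + np.log(weights)[None, :]
        ll = float(logsumexp(log_joint, axis=1).sum())
        if trace and ll < trace[-1] - 1e-9:
            raise AssertionError(
                f"EM log-likelihood decreased: {trace[-1]} -> {ll}"
            )
        resp = np.exp(log_joint - logsumexp(log_joint, axis=1, keepdims=True))
        if trace and abs(ll - trace[-1]) < tol:
            trace.append(ll)
            converged = True
            break
        trace.append(ll)
        # M-step
        dosages = _mstep_dosages(resp, a, error_rate)
        weights = resp.mean(axis=0)
        weights = np.maximum(weights, 1e-12)
        weights /= weights.sum()

    if not converged:
        warnings.warn(f"EM did not converge in {max_iter} iterations", stacklevel=2)

    model = GenotypeModel(
        dosages, weights, error_rate, doublet_rate,
        converged=converged, n_iter=it, loglik_trace=trace,
    )
    return model, resp


def call_doublets(
    a: AlleleCountMatrix, m: GenotypeModel, threshold: float = 0.8
) -> pd.DataFrame:
    """Posterior origin / mosaic-doublet call per barcode.

    Categories are the N singlet origins plus every unordered origin pair,
    the latter carrying the averaged dosage profile (d_j + d_k)/2 — the
    50/50 mosaic-doublet model. The doublet prior is split evenly over
    pairs and the singlet prior (1 - doublet_rate) over origins by mixing
    weight. Cells whose best posterior falls below ``threshold`` are called
    ambiguous; a cell with no reads at all keeps the prior and is therefore
    ambiguous at the default threshold.

    Returns a table with one row per cell: call, log_likelihood,
    posterior_origin_<k> columns and posterior_doublet.
    """
    n = m.n_origins
    if n < 2:
        raise ConfigError("doublet calling requires at least 2 origins")
    pairs = list(itertools.combinations(range(n), 2))
    profiles = np.vstack(
        [m.dosages] + [(m.dosages[j] + m.dosages[k]) / 2.0 for j, k in pairs]
    )
    priors = np.concatenate(
        [
            (1.0 - m.doublet_rate) * m.mix_weights,
            np.full(len(pairs), m.doublet_rate / len(pairs)),
        ]
    )
    log_joint = _loglik_matrix(a, profiles, m.error_rate) + np.log(priors)[None, :]
    log_norm = logsumexp(log_joint, axis=1, keepdims=True)
    post = np.exp(log_joint - log_norm)

    singlet_post = post[:, :n]
    doublet_post = post[:, n:].sum(axis=1)
    best = np.argmax(post, axis=1)
    best_post = post[np.arange(len(post)), best]

    calls = []
    for i in range(a.n_cells):
        if best_post[i] < threshold:
            calls.append("ambiguous")
        elif best[i] < n:
            calls.append(str(int(best[i])))
        else:
            calls.append("doublet")

    out = pd.DataFrame({"barcode": a.barcodes, "call": calls})
    for k in range(n):
        out[f"posterior_origin_{k}"] = singlet_post[:, k]
    out["posterior_doublet"] = doublet_post
    out["log_likelihood"] = log_norm.ravel()
    return out


def label_origins(
    results: pd.DataFrame,
    ann: pd.DataFrame,
    anchor_type: str,
    anchor_label: str,
    other_label: str | None = None,
) -> pd.DataFrame:
    """Translate origin indices into biological labels via an anchor type.

    A cell type of known origin (e.g., trophoblasts, which are fetal)
    anchors the labels: the origin index holding the majority of that
    type's singlet cells receives ``anchor_label``; the other origin gets
    ``other_label``. Doublet and ambiguous calls are left untouched.
    Requires exactly 2 origins; an exact 50/50 split of anchor cells is an
    error demanding manual assignment.
    """
    origin_calls = [c for c in results["call"].unique() if c.isdigit()]
    if len(origin_calls) > 2 or any(int(c) > 1 for c in origin_calls):
        raise ConfigError("origin labeling supports exactly 2 origins")
    if other_label is None:
        other_label = f"non-{anchor_label}"

    merged = results.merge(ann[["barcode", "cell_type"]], on="barcode", how="left")
    anchors = merged[merged["cell_type"] == anchor_type]
    if anchors.empty:
        raise DataError(f"anchor cell type {anchor_type!r} absent from annotations")
    anchor_singlets = anchors[anchors["call"].isin(("0", "1"))]
    if anchor_singlets.empty:
        raise DataError(f"no {anchor_type!r} cell received a singlet origin call")
    n1 = int((anchor_singlets["call"] == "1").sum())
    n0 = len(anchor_singlets) - n1
    if n0 == n1:
        raise DataError(
            f"anchor cells split exactly {n0}/{n1} between origins; "
            "assign labels manually"
        )
    anchor_origin = "1" if n1 > n0 else "0"
    mapping = {
        anchor_origin: anchor_label,
        ("0" if anchor_origin == "1" else "1"): other_label,
    }
    out = results.copy()
    out["origin_label"] = out["call"].map(lambda c: mapping.get(c, c))
    return out
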