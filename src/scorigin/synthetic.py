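"""Synthetic data with known ground truth.

Two generators make the whole pipeline testable offline:

* :func:`simulate_expression` builds an artificial tissue/blood immune-cell
  mixture plus a matching whole-blood reference. Each cell type carries a
  mean log-expression program and a low-dimensional latent state: cells
  vary along ``n_programs`` orthogonal gene-space directions with per-axis
  SD ``within_sd``, and tissue-resident cells are displaced from their
  blood counterparts by a shift of norm ``latent_shift`` along a random
  latent direction fixed per type — so the planted blood/tissue separation
  is ``latent_shift / within_sd`` in latent units, the geometry the
  embedding step is meant to recover. Counts are multinomial draws over
  the softmax of the resulting log-expression, which adds realistic count
  noise without modeling dropout or ambient RNA.

* :func:`simulate_allele_counts` builds a pooled-individuals allele-count
  matrix. Population MAFs come from a Beta distribution truncated to
  (0, 0.5]; per-origin dosages follow Hardy-Weinberg at each MAF; read
  depth is Poisson per cell/variant and alt reads binomial with the same
  error model the demultiplexer assumes. Doublets are 50/50 mixtures of
  two origins' dosage profiles.

Both generators are fully deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._errors import ConfigError
from .io import AlleleCountMatrix, ExpressionMatrix, new_annotations


@dataclass
class MixtureSpec:
    """Conditions for the expression-mixture generator.

    latent_shift is the blood-to-tissue displacement norm in latent units;
    within_sd the per-axis SD of each cell's latent state around the type
    program. program_scale sets how strongly one latent unit moves
    log-expression (larger values mean expression programs dominate count
    noise). The defaults give four immune types with 250 cells per type
    per compartment and a shift of five within-population SDs — a clearly
    but not trivially separated mixture.
    """

    n_cell_types: int = 4
    cells_per_type_per_compartment: int = 250
    n_genes: int = 500
    latent_shift: float = 5.0
    within_sd: float = 1.0
    library_size: int = 2000
    n_programs: int = 10
    program_scale: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_shift < 0:
            raise ConfigError("latent_shift must be >= 0")
        for name in ("n_cell_types", "cells_per_type_per_compartment",
                     "n_genes", "library_size", "n_programs"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.within_sd <= 0:
            raise ConfigError("within_sd must be positive")


@dataclass
class DemuxSpec:
    """Conditions for the allele-count generator.

    coverage is the Poisson mean read depth per cell and variant.
    maf_beta_params shapes the population-MAF spectrum; the default is
    skewed toward rare variants, matching the pool left after upstream
    frequency filtering.
    """

    n_origins: int = 2
    n_cells: int = 200
    n_snps: int = 500
    coverage: float = 2.0
    doublet_rate: float = 0.05
    maf_beta_params: tuple[float, float] = (1.5, 20.0)
    error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.doublet_rate < 1.0:
            raise ConfigError("doublet_rate must lie in [0, 1)")
        if self.coverage < 0:
            raise ConfigError("coverage must be >= 0")
        if self.n_origins < 1 or self.n_cells < 1 or self.n_snps < 1:
            raise ConfigError("n_origins, n_cells, n_snps must be positive")


class ExpressionSim(NamedTuple):
    query: ExpressionMatrix
    reference: ExpressionMatrix
    truth: pd.DataFrame  # barcode, cell_type, compartment
    ref_annotation: pd.DataFrame  # barcode, cell_type


class AlleleCountSim(NamedTuple):
    counts: AlleleCountMatrix
    truth: pd.DataFrame  # barcode, origin, doublet, pair
    dosages: np.ndarray  # (n_origins x n_snps) true dosages


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _sample_counts(
    rng: np.random.Generator,
    program: np.ndarray,
    loadings: np.ndarray,
    latent_mean: np.ndarray,
    n_cells: int,
    within_sd: float,
    library_size: int,
) -> np.ndarray:
    """Draw cells from a latent-program expression model.

    Each cell's latent state is Gaussian around ``latent_mean`` with
    per-axis SD ``within_sd``; log-expression is the type program plus the
    latent state mapped through the loading matrix; counts are multinomial.
    """
    z = latent_mean[None, :] + rng.normal(0.0, within_sd, (n_cells, len(latent_mean)))
    logits = program[None, :] + z @ loadings
    probs = _softmax(logits)
    return np.vstack([rng.multinomial(library_size, p) for p in probs])


def simulate_expression(spec: MixtureSpec) -> ExpressionSim:
    """Generate (query, reference, truth, reference annotation).

    The query holds blood and tissue cells of every type; the reference
    holds an equal number of additional, independently drawn blood cells
    per type. Truth records the planted compartment per query barcode.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [(f"G{j:05d}", f"GENE{j}") for j in range(spec.n_genes)]
    baseline = rng.normal(0.0, 1.0, spec.n_genes)
    if spec.n_programs > spec.n_genes:
        raise ConfigError("n_programs cannot exceed n_genes")

    q_blocks, r_blocks = [], []
    q_types, q_comps, r_types = [], [], []
    n = spec.cells_per_type_per_compartment
    for t in range(spec.n_cell_types):
        program = baseline + rng.normal(0.0, 1.0, spec.n_genes)
        # orthonormal latent-to-gene loadings, scaled; type-specific
        basis, _ = np.linalg.qr(rng.normal(0.0, 1.0, (spec.n_genes, spec.n_programs)))
        loadings = basis.T * spec.program_scale
        direction = rng.normal(0.0, 1.0, spec.n_programs)
        direction /= np.linalg.norm(direction)
        blood_mean = np.zeros(spec.n_programs)
        tissue_mean = spec.latent_shift * direction

        q_blocks.append(
            _sample_counts(rng, program, loadings, blood_mean, n,
                           spec.within_sd, spec.library_size)
        )
        q_blocks.append(
            _sample_counts(rng, program, loadings, tissue_mean, n,
                           spec.within_sd, spec.library_size)
        )
        r_blocks.append(
            _sample_counts(rng, program, loadings, blood_mean, n,
                           spec.within_sd, spec.library_size)
        )
        q_types += [f"type{t}"] * (2 * n)
        q_comps += ["blood"] * n + ["tissue"] * n
        r_types += [f"type{t}"] * n

    q_counts = sp.csr_matrix(np.vstack(q_blocks))
    r_counts = sp.csr_matrix(np.vstack(r_blocks))
    q_barcodes = [f"Q{i:06d}" for i in range(q_counts.shape[0])]
    r_barcodes = [f"R{i:06d}" for i in range(r_counts.shape[0])]

    truth = new_annotations(q_barcodes, q_types)
    truth["compartment"] = q_comps
    ref_ann = new_annotations(r_barcodes, r_types)
    return ExpressionSim(
        ExpressionMatrix(q_counts, q_barcodes, genes),
        ExpressionMatrix(r_counts, r_barcodes, genes),
        truth,
        ref_ann,
    )


def _hardy_weinberg_dosages(
    rng: np.random.Generator, maf: np.ndarray, n_origins: int
) -> np.ndarray:
    """Draw {0, 0.5, 1} dosages from Hardy-Weinberg proportions per MAF."""
    q = maf[None, :]
    probs = np.stack(
        [(1 - q) ** 2, 2 * q * (1 - q), q**2], axis=-1
    )  # (1 x V x 3), broadcast over origins
    probs = np.broadcast_to(probs, (n_origins, len(maf), 3))
    u = rng.random((n_origins, len(maf)))
    cum = probs.cumsum(axis=-1)
    idx = (u[..., None] > cum).sum(axis=-1)
    return np.array([0.0, 0.5, 1.0])[idx]


def simulate_allele_counts(spec: DemuxSpec) -> AlleleCountSim:
    """Generate an allele-count matrix with planted origins and doublets."""
    rng = np.random.default_rng(spec.seed)
    v, n = spec.n_snps, spec.n_cells

    a, b = spec.maf_beta_params
    maf = rng.beta(a, b, v)
    # truncate to (0, 0.5]: fold the upper tail, nudge exact zeros
    maf = np.where(maf > 0.5, 1.0 - maf, maf)
    maf = np.clip(maf, 1e-4, 0.5)

    dosages = _hardy_weinberg_dosages(rng, maf, spec.n_origins)

    origins = rng.integers(0, spec.n_origins, n)
    is_doublet = (
        rng.random(n) < spec.doublet_rate if spec.n_origins >= 2 else np.zeros(n, bool)
    )
    partners = np.full(n, -1)
    for i in np.flatnonzero(is_doublet):
        choices = [k for k in range(spec.n_origins) if k != origins[i]]
        partners[i] = rng.choice(choices)

    cell_dosage = dosages[origins]
    mask = is_doublet
    if mask.any():
        cell_dosage = cell_dosage.copy()
        cell_dosage[mask] = (dosages[origins[mask]] + dosages[partners[mask]]) / 2.0

    depth = rng.poisson(spec.coverage, (n, v))
    eps = spec.error_rate
    p = cell_dosage * (1 - eps) + (1 - cell_dosage) * eps
    alt = rng.binomial(depth, p)
    ref = depth - alt

    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, v + 1) * 10,
            "ref": "A",
            "alt": "G",
            "maf": maf,
        }
    )
    barcodes = [f"C{i:05d}" for i in range(n)]
    counts = AlleleCountMatrix(
        sp.csr_matrix(ref), sp.csr_matrix(alt), variants, barcodes
    )
    truth = pd.DataFrame(
        {
            "barcode": barcodes,
            "origin": [
                "doublet" if d else str(int(o)) for o, d in zip(origins, is_doublet)
            ],
            "doublet": is_doublet,
            "origin_a": origins,
            "origin_b": np.where(is_doublet, partners, origins),
        }
    )
    return AlleleCountSim(counts, truth, dosages)
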