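"""Permutation-based empirical p-values for SPER scores.

The null reassigns gene expression values to shuffled spot positions while
the compositions and the geometry stay fixed. Because the SPER score is
linear in the expression matrix, ``S = B @ E`` for a precomputed
``k x n`` operator ``B`` (the weight-combined, composition-pushed shell
averages), each permutation costs a single matrix product.

Two permutation modes:

* ``coherent`` (default): all genes share each permutation's spot shuffle.
  This preserves gene-gene covariance in the null and costs one ``k x n x m``
  product per permutation.
* ``per_gene``: every gene draws its own shuffles, giving independent
  null streams per gene (useful for calibration studies), at higher cost.

The empirical p-value uses the add-one correction
``p = (1 + #{null >= observed}) / (1 + n_perm)`` so p is never 0 (a raw
proportion can return 0, which breaks Benjamini-Hochberg); ties count as
``>=`` up to a small relative tolerance, so a constant gene gets p = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core import (
    SPERConfig,
    build_bins,
    composition_shell_operators,
    poisson_weights,
    sper_score,
    _row_normalized_composition,
)
from .datatypes import (
    CompositionMatrix,
    ExpressionMatrix,
    SpotGeometry,
    check_spot_alignment,
)
from .io import normalize_expression

_TIE_TOL = 1e-9


@dataclass
class PermutationResult:
    """Observed scores with empirical p-values and BH q-values (all k x m)."""

    cell_type_ids: "object"
    gene_ids: "object"
    observed: np.ndarray
    p_values: np.ndarray
    q_values: np.ndarray
    n_permutations: int
    seed: int
    null_mean: np.ndarray
    null_sd: np.ndarray

    def p_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.p_values, index=self.cell_type_ids, columns=self.gene_ids)

    def q_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.q_values, index=self.cell_type_ids, columns=self.gene_ids)


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone in rank)."""
    flat = np.asarray(p, dtype=float).ravel()
    _, q, _, _ = multipletests(flat, method="fdr_bh")
    return q.reshape(np.shape(p))


def permute_scores(
    E: ExpressionMatrix,
    C: CompositionMatrix,
    geometry: SpotGeometry,
    config: SPERConfig | None = None,
    n_perm: int = 999,
    seed: int = 0,
    mode: str = "coherent",
) -> PermutationResult:
    """Empirical permutation p-values for every (cell type, gene) pair.

    Prevalence adjustment multiplies observed and null scores by the same
    factor, so p-values are computed on (and identical for) the raw scores.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if mode not in ("coherent", "per_gene"):
        raise ValueError(f"unknown permutation mode {mode!r}")
    config = config or SPERConfig()
    check_spot_alignment(E, C, geometry)
    if not E.normalized:
        E = normalize_expression(E)
    bins = build_bins(geometry, config.bin_width_um, config.max_distance_um)
    weights = poisson_weights(config.weight_lambda, bins.n_shells)
    Ct = _row_normalized_composition(C, config.c_normalization)
    shell_ops = composition_shell_operators(Ct, bins)
    B = sper_score(shell_ops, weights)  # k x n combined operator
    X = E.values  # n x m
    observed = B @ X
    k, m = observed.shape
    n = X.shape[0]
    tol = _TIE_TOL * np.maximum(1.0, np.abs(observed))
    rng = np.random.default_rng(seed)
    exceed = np.zeros((k, m), dtype=np.int64)
    null_sum = np.zeros((k, m))
    null_sq = np.zeros((k, m))
    if mode == "coherent":
        for _ in range(n_perm):
            perm = rng.permutation(n)
            null = B[:, perm] @ X
            exceed += null >= observed - tol
            null_sum += null
            null_sq += null * null
    else:
        # independent shuffles per gene, vectorized over permutations
        for g in range(m):
            keys = rng.random((n, n_perm))
            order = np.argsort(keys, axis=0)
            shuffled = X[order, g]  # n x n_perm
            null = B @ shuffled  # k x n_perm
            obs_g = observed[:, g][:, None]
            exceed[:, g] = (null >= obs_g - tol[:, g][:, None]).sum(axis=1)
            null_sum[:, g] = null.sum(axis=1)
            null_sq[:, g] = (null * null).sum(axis=1)
    p = (1.0 + exceed) / (1.0 + n_perm)
    q = bh_qvalues(p)
    null_mean = null_sum / n_perm
    null_var = np.maximum(null_sq / n_perm - null_mean**2, 0.0)
    return PermutationResult(
        cell_type_ids=C.cell_type_ids,
        gene_ids=E.gene_ids,
        observed=observed,
        p_values=p,
        q_values=q,
        n_permutations=n_perm,
        seed=seed,
        null_mean=null_mean,
        null_sd=np.sqrt(null_var),
    )
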