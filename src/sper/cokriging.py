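"""Geostatistical denoising of compositional cell-type maps.

Pipeline: additive log-ratio (alr) transform of the simplex-valued
compositions, empirical direct/cross variograms, a linear model of
coregionalization (LMC) with a nugget and three Gaussian structures, local
ordinary co-kriging with the nugget filtered as measurement error, and the
inverse-alr back-transform onto the simplex.

Conventions
-----------
* alr (not clr) with a configurable reference component, so the LMC fit and
  the kriging systems work in a full-rank coordinate system; the reference
  defaults to the most abundant cell type.
* Gaussian structure ``g(h; a) = 1 - exp(-3 h^2 / a^2)``: the semivariance
  reaches 95% of its sill at the stated effective range, which is where the
  factor 3 in the exponent comes from.
* Coefficient matrices are projected to the nearest PSD matrix by eigenvalue
  clipping after an unconstrained weighted least-squares fit (weights = pair
  counts), a simple deterministic choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .datatypes import CompositionMatrix, SpotGeometry

logger = logging.getLogger(__name__)

_CHUNK = 512
_RIDGE = 1e-8


@dataclass
class CokrigingConfig:
    """Parameters of the denoising pipeline (distances in micrometers)."""

    alr_reference: str | None = None
    pseudocount: float = 1e-4
    n_lag_bins: int = 15
    lag_width_um: float = 120.0
    ranges_um: tuple = (600.0, 1300.0, 3000.0)
    nugget: bool = True
    neighborhood: int = 50


def alr_transform(
    C: CompositionMatrix,
    reference_type: str | None = None,
    pseudocount: float = 1e-4,
):
    """Additive log-ratio transform of compositions.

    Returns ``(Z, component_ids, reference_type)`` where ``Z`` is the
    ``n_spots x (k-1)`` matrix ``ln((c_t + eps) / (c_ref + eps))`` over the
    non-reference components in their original order. With ``pseudocount=0``
    the inverse map restores strictly positive compositions exactly.
    """
    types = list(C.cell_type_ids)
    if reference_type is None:
        reference_type = types[int(np.argmax(C.values.mean(axis=1)))]
        logger.info("alr reference defaults to most abundant type %r", reference_type)
    if reference_type not in types:
        raise ValueError(f"reference type {reference_type!r} absent from compositions")
    ref_idx = types.index(reference_type)
    others = [i for i in range(len(types)) if i != ref_idx]
    eps = float(pseudocount)
    ref = C.values[ref_idx] + eps
    Z = np.log((C.values[others] + eps) / ref).T
    component_ids = [types[i] for i in others]
    return Z, component_ids, reference_type


def inverse_alr(Z: np.ndarray, component_ids, reference_type, cell_type_order=None) -> CompositionMatrix:
    """Map alr coordinates back onto the simplex (types x spots)."""
    Z = np.asarray(Z, dtype=float)
    expz = np.exp(Z - Z.max(axis=1, keepdims=True))  # overflow-safe softmax form
    ref_col = np.exp(-Z.max(axis=1, keepdims=True))
    denom = ref_col[:, 0] + expz.sum(axis=1)
    comp = {reference_type: ref_col[:, 0] / denom}
    for j, t in enumerate(component_ids):
        comp[t] = expz[:, j] / denom
    order = list(cell_type_order) if cell_type_order is not None else list(component_ids) + [reference_type]
    values = np.vstack([comp[t] for t in order])
    values /= values.sum(axis=0, keepdims=True)
    spot_ids = [f"s{i}" for i in range(Z.shape[0])]
    return CompositionMatrix(order, spot_ids, values)


@dataclass
class VariogramSet:
    """Empirical direct/cross semivariances per lag bin.

    ``gamma`` has shape ``(n_lags, p, p)``: diagonal entries are direct
    variograms, off-diagonal entries cross variograms. Lags without pairs are
    reported with count 0 and excluded from fitting.
    """

    lag_centers: np.ndarray
    lag_width: float
    gamma: np.ndarray
    pair_counts: np.ndarray
    component_ids: list = field(default_factory=list)


def empirical_variogram(
    Z: np.ndarray,
    geometry: SpotGeometry,
    n_bins: int = 15,
    bin_width: float = 120.0,
) -> VariogramSet:
    """Classical (Matheron) estimator for every component pair.

    ``gamma_ab(h) = mean over pairs in the lag bin of
    (z_a(s) - z_a(s')) (z_b(s) - z_b(s')) / 2``; lag bin ``l`` covers
    ``[l*w, (l+1)*w)`` with the zero-distance bin excluding coincident pairs.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    coords = geometry.coordinates
    n, p = Z.shape
    if coords.shape[0] != n:
        raise ValueError("geometry / field size mismatch")
    if n < 2:
        raise ValueError("need at least 2 spots")
    if not np.isfinite(Z).all():
        raise ValueError("field must be finite")
    gamma_sum = np.zeros((n_bins, p, p))
    counts = np.zeros(n_bins, dtype=np.int64)
    for start in range(0, n, _CHUNK):
        block = coords[start : start + _CHUNK]
        d = cdist(block, coords)
        rows_g = np.arange(start, start + block.shape[0])
        upper = np.arange(n)[None, :] > rows_g[:, None]  # each pair once
        lag = np.floor(d / bin_width).astype(np.int64)
        for ell in range(n_bins):
            mask = upper & (lag == ell) & (d > 0)
            if not mask.any():
                continue
            bi, bj = np.nonzero(mask)
            diff = Z[rows_g[bi]] - Z[bj]
            gamma_sum[ell] += 0.5 * diff.T @ diff
            counts[ell] += len(bi)
    gamma = np.zeros_like(gamma_sum)
    nz = counts > 0
    gamma[nz] = gamma_sum[nz] / counts[nz, None, None]
    centers = (np.arange(n_bins) + 0.5) * bin_width
    return VariogramSet(centers, float(bin_width), gamma, counts)


def gaussian_structure(h, effective_range: float) -> np.ndarray:
    """Gaussian variogram basis reaching 95% of its sill at the stated range."""
    h = np.asarray(h, dtype=float)
    return 1.0 - np.exp(-3.0 * h**2 / effective_range**2)


def _project_psd(mat: np.ndarray) -> np.ndarray:
    sym = 0.5 * (mat + mat.T)
    vals, vecs = np.linalg.eigh(sym)
    return (vecs * np.maximum(vals, 0.0)) @ vecs.T


@dataclass
class LMCModel:
    """Linear model of coregionalization: nugget + Gaussian structures.

    ``gamma(h) = B0 * 1{h > 0} + sum_s Bs * g(h; a_s)``. The signal
    covariance used by the kriging systems is ``sum_s Bs * exp(-3 h^2 /
    a_s^2)``; the nugget is treated as measurement error and filtered.
    """

    nugget_matrix: np.ndarray
    structure_matrices: list
    effective_ranges: tuple

    def __post_init__(self):
        ranges = tuple(float(a) for a in self.effective_ranges)
        if not all(a < b for a, b in zip(ranges[:-1], ranges[1:], strict=False)):
            raise ValueError("effective ranges must be strictly increasing")
        self.effective_ranges = ranges
        for mat in [self.nugget_matrix, *self.structure_matrices]:
            vals = np.linalg.eigvalsh(0.5 * (mat + mat.T))
            if vals.min() < -1e-10:
                raise ValueError("LMC coefficient matrices must be PSD")

    @property
    def n_components(self) -> int:
        return self.nugget_matrix.shape[0]

    def gamma_model(self, h) -> np.ndarray:
        """Model semivariance, shape ``h.shape + (p, p)``."""
        h = np.asarray(h, dtype=float)
        out = np.where(h > 0, 1.0, 0.0)[..., None, None] * self.nugget_matrix
        for B, a in zip(self.structure_matrices, self.effective_ranges, strict=True):
            out = out + gaussian_structure(h, a)[..., None, None] * B
        return out

    def signal_covariance(self, h) -> np.ndarray:
        """Nugget-free covariance, shape ``h.shape + (p, p)``."""
        h = np.asarray(h, dtype=float)
        out = np.zeros(h.shape + (self.n_components, self.n_components))
        for B, a in zip(self.structure_matrices, self.effective_ranges, strict=True):
            out = out + np.exp(-3.0 * h**2 / a**2)[..., None, None] * B
        return out


def fit_lmc(
    variograms: VariogramSet,
    ranges=(600.0, 1300.0, 3000.0),
    with_nugget: bool = True,
) -> LMCModel:
    """Weighted least-squares LMC fit on {nugget, Gaussian(a1..a3)} bases.

    Weights are per-lag pair counts; each fitted coefficient matrix is
    symmetrized and projected to the nearest PSD matrix by eigenvalue
    clipping. Raises on a rank-deficient basis design (collinear bases at the
    populated lags).
    """
    used = variograms.pair_counts > 0
    h = variograms.lag_centers[used]
    if len(h) < 4:
        raise ValueError("need at least 4 populated lags to fit the LMC")
    bases = [gaussian_structure(h, a) for a in ranges]
    if with_nugget:
        bases = [np.ones_like(h)] + bases
    G = np.column_stack(bases)
    w = variograms.pair_counts[used].astype(float)
    Gw = G * w[:, None]
    gram = G.T @ Gw
    if np.linalg.cond(gram) > 1e12:
        raise ValueError(
            "collinear variogram bases at the populated lags; "
            "try different effective ranges or wider lag coverage"
        )
    p = variograms.gamma.shape[1]
    y = variograms.gamma[used].reshape(len(h), p * p)
    beta = np.linalg.solve(gram, Gw.T @ y)  # (n_bases, p*p)
    mats = [_project_psd(beta[s].reshape(p, p)) for s in range(beta.shape[0])]
    if with_nugget:
        nugget, structures = mats[0], mats[1:]
    else:
        nugget, structures = np.zeros((p, p)), mats
    return LMCModel(nugget, structures, tuple(float(a) for a in ranges))


def cokrige_smooth(
    Z: np.ndarray,
    geometry: SpotGeometry,
    model: LMCModel,
    neighborhood: int = 50,
) -> np.ndarray:
    """Ordinary co-kriging estimate of the noise-free field at each spot.

    For every spot the ``neighborhood`` nearest data points (including the
    spot itself) enter an ordinary co-kriging system with per-component
    unbiasedness constraints; the nugget enters the data-data covariance but
    not the data-prediction covariances, so observation noise is filtered.
    With a zero nugget the prediction interpolates the data exactly.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    n, p = Z.shape
    if p != model.n_components:
        raise ValueError("field / model component count mismatch")
    coords = geometry.coordinates
    N = min(int(neighborhood), n)
    tree = cKDTree(coords)
    dist, nbr = tree.query(coords, k=N)
    if N == 1:
        dist, nbr = dist[:, None], nbr[:, None]
    out = np.empty_like(Z)
    Q = np.tile(np.eye(p), (N, 1))  # (N*p, p) unbiasedness design
    eyep = np.eye(p)
    for j in range(n):
        idx = nbr[j]
        H = cdist(coords[idx], coords[idx])
        K = model.signal_covariance(H).transpose(0, 2, 1, 3).reshape(N * p, N * p)
        K = K + np.kron(np.eye(N), model.nugget_matrix)
        c0 = model.signal_covariance(dist[j]).reshape(N * p, p)
        A = np.zeros((N * p + p, N * p + p))
        A[: N * p, : N * p] = K
        A[: N * p, N * p :] = Q
        A[N * p :, : N * p] = Q.T
        rhs = np.vstack([c0, eyep])
        try:
            sol = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError:
            logger.info("singular co-kriging system at spot %d; ridge %.0e added", j, _RIDGE)
            A[: N * p, : N * p] += _RIDGE * np.eye(N * p)
            sol = np.linalg.solve(A, rhs)
        w = sol[: N * p]  # (N*p, p)
        out[j] = Z[idx].reshape(N * p) @ w
    return out


def denoise_compositions(
    C: CompositionMatrix,
    geometry: SpotGeometry,
    config: CokrigingConfig | None = None,
) -> CompositionMatrix:
    """alr -> variograms -> LMC -> co-krige -> inverse alr -> simplex.

    Returns a composition matrix of the same shape and type order whose spot
    columns are exactly renormalized onto the simplex.
    """
    config = config or CokrigingConfig()
    Z, component_ids, ref = alr_transform(C, config.alr_reference, config.pseudocount)
    vario = empirical_variogram(Z, geometry, config.n_lag_bins, config.lag_width_um)
    model = fit_lmc(vario, config.ranges_um, config.nugget)
    Z_smooth = cokrige_smooth(Z, geometry, model, config.neighborhood)
    smoothed = inverse_alr(Z_smooth, component_ids, ref, cell_type_order=list(C.cell_type_ids))
    return CompositionMatrix(C.cell_type_ids, C.spot_ids, smoothed.values)
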