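"""Competitor metrics, AUROC benchmarking, candidate selection, enrichment.

The benchmark pits the prevalence-adjusted SPER score against per-spot
Pearson / Spearman correlation and (optionally) the Earth Mover's Distance
on simulated tissues with known paracrine genes. Positives are the designed
paracrine genes; negatives are the spatially unstructured noise genes
(markers of any cell type belong to neither class). AUROC uses midranks for
ties and is orientation-aware (EMD: lower = stronger association).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.spatial.distance import cdist
from scipy.stats import hypergeom, rankdata
from sklearn.metrics import roc_auc_score

from .core import SPERConfig, run_sper
from .datatypes import (
    CompositionMatrix,
    ExpressionMatrix,
    GeneSet,
    LigandReceptorTable,
    SpotGeometry,
    check_spot_alignment,
)
from .io import normalize_expression
from .simulation import SimulationConfig, SimulationTruth, make_scenario

logger = logging.getLogger(__name__)

#: Sentinel reported when an EMD side has zero mass (distance undefined).
EMD_UNDEFINED = np.inf
_EMD_MAX_SPOTS = 2500


@dataclass
class MetricScores:
    """A k x m score matrix for one metric, with its orientation."""

    metric: str
    cell_type_ids: "object"
    gene_ids: "object"
    values: np.ndarray
    higher_is_stronger: bool = True

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_type_ids, columns=self.gene_ids)


def _columnwise_correlation(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson correlation of every column of Y (k) with every column of X (m).

    Constant columns on either side get correlation 0 by convention.
    """
    const_x = np.ptp(X, axis=0) == 0
    const_y = np.ptp(Y, axis=0) == 0
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    xs = np.sqrt((Xc**2).sum(axis=0))
    ys = np.sqrt((Yc**2).sum(axis=0))
    num = Yc.T @ Xc
    denom = np.outer(ys, xs)
    ok = (denom > 0) & ~const_x[np.newaxis, :] & ~const_y[:, np.newaxis]
    out = np.zeros_like(num)
    out[ok] = num[ok] / denom[ok]
    return out


def correlation_scores(E: ExpressionMatrix, C: CompositionMatrix, method: str = "pearson") -> MetricScores:
    """Per (cell type, gene) Pearson or Spearman correlation across spots."""
    check_spot_alignment(E, C)
    X = E.values
    Y = C.values.T
    if method == "spearman":
        X = rankdata(X, axis=0)
        Y = rankdata(Y, axis=0)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    vals = _columnwise_correlation(X, Y)
    return MetricScores(method, C.cell_type_ids, E.gene_ids, vals, higher_is_stronger=True)


def emd_pair(weights_a: np.ndarray, weights_b: np.ndarray, ground_distance: np.ndarray) -> float:
    """Exact Earth Mover's Distance between two mass distributions.

    Solves the transportation linear program (HiGHS); both sides are
    renormalized to unit mass. A zero-mass side is undefined and returns
    :data:`EMD_UNDEFINED`.
    """
    a = np.asarray(weights_a, dtype=float)
    b = np.asarray(weights_b, dtype=float)
    if a.sum() <= 0 or b.sum() <= 0:
        return EMD_UNDEFINED
    a = a / a.sum()
    b = b / b.sum()
    na, nb = len(a), len(b)
    cost = np.asarray(ground_distance, dtype=float).reshape(na * nb)
    # equality constraints: row sums = a, column sums = b
    import scipy.sparse as sp

    row_idx = np.repeat(np.arange(na), nb)
    col_idx = np.tile(np.arange(nb), na) + na
    var = np.arange(na * nb)
    A_eq = sp.coo_matrix(
        (np.ones(2 * na * nb), (np.concatenate([row_idx, col_idx]), np.concatenate([var, var]))),
        shape=(na + nb, na * nb),
    ).tocsr()
    res = linprog(cost, A_eq=A_eq, b_eq=np.concatenate([a, b]), bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"EMD transportation LP failed: {res.message}")
    return float(res.fun)


def emd_scores(
    E: ExpressionMatrix,
    C: CompositionMatrix,
    geometry: SpotGeometry,
    cell_types=None,
) -> MetricScores:
    """EMD between each gene's expression mass and each type's composition mass.

    Physical spot distances are the ground distances; lower = stronger
    association. Exact LP only, hence guarded to small instances.
    """
    check_spot_alignment(E, C, geometry)
    n = E.n_spots
    if n > _EMD_MAX_SPOTS:
        raise ValueError(
            f"exact EMD is guarded to <= {_EMD_MAX_SPOTS} spots (got {n}); "
            "reduce or aggregate the data first"
        )
    D = cdist(geometry.coordinates, geometry.coordinates)
    types = list(C.cell_type_ids) if cell_types is None else [str(t) for t in cell_types]
    vals = np.empty((len(types), E.n_genes))
    type_pos = {t: i for i, t in enumerate(C.cell_type_ids)}
    for ti, t in enumerate(types):
        comp = C.values[type_pos[t]]
        for g in range(E.n_genes):
            vals[ti, g] = emd_pair(comp, E.values[:, g], D)
    return MetricScores("emd", types, E.gene_ids, vals, higher_is_stronger=False)


def auroc(truth_labels: np.ndarray, scores: np.ndarray, higher_is_stronger: bool = True) -> float:
    """Rank-based AUROC with midrank tie handling.

    Equals the Mann-Whitney U statistic divided by ``n_pos * n_neg``; EMD-like
    metrics are negated via ``higher_is_stronger=False``. Undefined scores
    (inf sentinels) are mapped to the weakest finite rank.
    """
    y = np.asarray(truth_labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.min() == y.max():
        raise ValueError("AUROC needs at least one positive and one negative")
    if not higher_is_stronger:
        s = -s
    finite = np.isfinite(s)
    if not finite.all():
        floor = s[finite].min() if finite.any() else 0.0
        s = np.where(finite, s, floor - 1.0)
    return float(roc_auc_score(y, s))


@dataclass
class BenchmarkReport:
    """Per-scenario, per-metric AUROC over simulation replicates."""

    table: pd.DataFrame  # columns: scenario, metric, replicate, seed, auroc
    seeds: list

    def summary(self) -> pd.DataFrame:
        return (
            self.table.groupby(["scenario", "metric"])["auroc"]
            .agg(["mean", "min", "max", "count"])
            .reset_index()
        )


def benchmark_gene_classes(truth: SimulationTruth):
    """(positives, negatives) gene lists for the discrimination task."""
    positives = [p["gene"] for p in truth.paracrine_genes]
    negatives = list(truth.noise_genes)
    return positives, negatives


def score_dataset(truth: SimulationTruth, metrics, sper_config: SPERConfig | None = None) -> dict:
    """Score every requested metric on one simulated dataset.

    SPER uses the prevalence-adjusted score; correlations are computed on
    the normalized expression against the raw simulated compositions.
    """
    out = {}
    E_norm = normalize_expression(truth.expression)
    for metric in metrics:
        if metric == "sper":
            res = run_sper(
                E_norm, truth.compositions, truth.geometry,
                sper_config or SPERConfig(), prevalence=truth.prevalence,
            )
            out["sper"] = MetricScores(
                "sper", res.cell_type_ids, res.gene_ids, res.adjusted_scores, True
            )
        elif metric in ("pearson", "spearman"):
            out[metric] = correlation_scores(E_norm, truth.compositions, metric)
        elif metric == "emd":
            out["emd"] = _emd_scores_coarse(E_norm, truth)
        else:
            raise ValueError(f"unknown metric {metric!r}")
    return out


def _emd_scores_coarse(E_norm: ExpressionMatrix, truth: SimulationTruth, block: int = 8) -> MetricScores:
    """EMD on a block-aggregated grid (the exact LP is too costly at full size)."""
    side = truth.config.grid_side
    n_blocks = side // block
    idx = (
        np.repeat(np.arange(side) // block, side).reshape(side, side) * n_blocks
        + np.tile(np.arange(side) // block, side).reshape(side, side)
    ).reshape(-1)
    n_coarse = n_blocks * n_blocks
    agg = np.zeros((n_coarse, E_norm.n_genes))
    comp_agg = np.zeros((truth.compositions.n_types, n_coarse))
    np.add.at(agg, idx, E_norm.values)
    np.add.at(comp_agg.T, idx, truth.compositions.values.T)
    centers = np.column_stack(
        [
            (np.tile(np.arange(n_blocks), n_blocks) + 0.5) * block,
            (np.repeat(np.arange(n_blocks), n_blocks) + 0.5) * block,
        ]
    ) * truth.config.tile_spacing_um
    D = cdist(centers, centers)
    comp_sums = comp_agg.sum(axis=0, keepdims=True)
    comp_frac = comp_agg / np.where(comp_sums > 0, comp_sums, 1.0)
    target_row = truth.cell_type_ids.index(truth.target_type)
    vals = np.full((len(truth.cell_type_ids), E_norm.n_genes), np.nan)
    for g in range(E_norm.n_genes):
        vals[target_row, g] = emd_pair(comp_frac[target_row], agg[:, g], D)
    return MetricScores("emd", truth.cell_type_ids, E_norm.gene_ids, vals, higher_is_stronger=False)


def run_benchmark(
    scenarios=("simple", "single_source", "multi_source"),
    metrics=("sper", "pearson", "spearman"),
    n_replicates: int = 10,
    base_seed: int = 0,
    config: SimulationConfig | None = None,
    sper_config: SPERConfig | None = None,
) -> BenchmarkReport:
    """Simulate, score and evaluate every scenario x metric x replicate.

    Replicate ``r`` uses seed ``base_seed + r`` so a single integer
    reproduces the whole report.
    """
    rows = []
    seeds = [int(base_seed) + r for r in range(n_replicates)]
    base = config.to_dict() if config is not None else {}
    base.pop("scenario", None)
    base.pop("seed", None)
    for scenario in scenarios:
        for r, seed in enumerate(seeds):
            truth = make_scenario(SimulationConfig(scenario=scenario, seed=seed, **base))
            positives, negatives = benchmark_gene_classes(truth)
            scored = score_dataset(truth, metrics, sper_config)
            target_row = truth.cell_type_ids.index(truth.target_type)
            gene_pos = {g: i for i, g in enumerate(truth.expression.gene_ids)}
            genes = positives + negatives
            y = np.array([1] * len(positives) + [0] * len(negatives))
            for metric, ms in scored.items():
                s = ms.values[target_row, [gene_pos[g] for g in genes]]
                rows.append(
                    {
                        "scenario": scenario,
                        "metric": metric,
                        "replicate": r,
                        "seed": seed,
                        "auroc": auroc(y, s, ms.higher_is_stronger),
                    }
                )
    return BenchmarkReport(pd.DataFrame(rows), seeds)


def select_candidates(
    scores: pd.DataFrame,
    prevalence: pd.DataFrame,
    percentile: float = 95.0,
    prevalence_max: float = 0.20,
    per_type: bool = False,
) -> pd.DataFrame:
    """(cell type, gene) pairs above the score percentile with low prevalence.

    The percentile is computed over the full score matrix by default (single
    threshold across types); ``per_type`` switches to per-row thresholds.
    ``prevalence_max=1.0`` disables the prevalence filter.
    """
    S = scores.to_numpy(dtype=float)
    P = prevalence.reindex(index=scores.index, columns=scores.columns).to_numpy(dtype=float)
    P = np.where(np.isnan(P), 1.0, P)
    if per_type:
        thr = np.percentile(S, percentile, axis=1, keepdims=True)
    else:
        thr = np.percentile(S, percentile)
    mask = (S > thr) & (P < prevalence_max)
    ti, gi = np.nonzero(mask)
    return pd.DataFrame(
        {
            "cell_type": scores.index[ti],
            "gene": scores.columns[gi],
            "score": S[ti, gi],
            "prevalence": P[ti, gi],
        }
    ).reset_index(drop=True)


@dataclass
class EnrichmentResult:
    """Upper-tail hypergeometric test of candidate / annotation overlap."""

    population_size: int
    set_successes: int
    sample_size: int
    sample_successes: int
    p_value: float


def hypergeom_enrichment(candidates, gene_set: GeneSet, population) -> EnrichmentResult:
    """Is the candidate gene list enriched for the annotation set?

    ``population`` is the full gene universe (the candidates must be a
    subset); the p-value is ``P[X >= observed overlap]`` for a hypergeometric
    draw of ``len(candidates)`` genes.
    """
    population = [str(g) for g in dict.fromkeys(population)]
    if not population:
        raise ValueError("empty population")
    pop = set(population)
    cand = [str(g) for g in dict.fromkeys(candidates)]
    if not set(cand) <= pop:
        raise ValueError("candidates must be drawn from the population")
    successes_pop = sum(g in gene_set for g in population)
    overlap = sum(g in gene_set for g in cand)
    M, n, N = len(population), successes_pop, len(cand)
    p = float(hypergeom.sf(overlap - 1, M, n, N)) if N else 1.0
    return EnrichmentResult(M, n, N, overlap, min(p, 1.0))


def pair_ligand_receptor(
    candidates: pd.DataFrame,
    lr_table: LigandReceptorTable,
    prevalence: pd.DataFrame,
    receptor_prevalence_min: float = 0.5,
) -> pd.DataFrame:
    """Pair candidate ligands with receptors expressed in the target type.

    Keeps (ligand, receptor, cell type) triples where the candidate gene is
    an annotated ligand and the cognate receptor's expression prevalence in
    that cell type exceeds the threshold. Candidates absent from the table
    simply produce no pairs (they stay candidates elsewhere).
    """
    rows = []
    for _, rec in candidates.iterrows():
        gene, cell_type = str(rec["gene"]), str(rec["cell_type"])
        for receptor in lr_table.receptors_for(gene):
            if receptor not in prevalence.columns or cell_type not in prevalence.index:
                continue
            prev = float(prevalence.loc[cell_type, receptor])
            if prev > receptor_prevalence_min:
                rows.append(
                    {
                        "ligand": gene,
                        "receptor": receptor,
                        "cell_type": cell_type,
                        "receptor_prevalence": prev,
                    }
                )
    return pd.DataFrame(rows, columns=["ligand", "receptor", "cell_type", "receptor_prevalence"])
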