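"""Synthetic spot-based spatial transcriptomics with known paracrine structure.

A square tissue grid of multicellular tiles is labeled with cell types, per
three scenarios:

* ``simple`` — a deterministic, analytically transparent layout: small
  square target blocks with the paracrine expression region shifted a couple
  of tiles, leaving a slight overlap.
* ``single_source`` — cell-type patches from a symmetric Potts Markov
  random field sampled by checkerboard Gibbs sweeps near criticality; the
  target patches are then boundary-smoothed (greater spatial
  autocorrelation than the controls) and the source type is seeded from the
  dilated borders of the target patches, so source tiles interleave around
  the target — spatially associated with, yet distinct from, it.
* ``multi_source`` — same mechanism with the border tiles split between two
  distinct source types.

Expression follows the hierarchical generative model: each cell type's
marker genes draw a Poisson rate ``Unif(15, 30)`` in their own type's tiles
and a noise rate ``Unif(0, 3)`` elsewhere; designed paracrine genes are
markers of the source type(s) only, with a near-zero off-source rate so
their expression prevalence in the target type stays low; pure-noise genes
draw ``Unif(0, 3)`` everywhere. Per-tile cell-type counts are Poisson with
rate ``alpha * sum_{g in markers(i)} lambda_{g,tile} * y_{g,tile}`` and the
compositions are their within-tile fractions.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CompositionMatrix, ExpressionMatrix, PrevalenceMatrix, SpotGeometry

logger = logging.getLogger(__name__)

SCENARIOS = ("simple", "single_source", "multi_source")


@dataclass
class SimulationConfig:
    """Study conditions of the simulated tissues.

    ``alpha`` scales the Poisson rate of per-tile cell counts (default 0.01
    gives ~25 cells of the resident type per tile, a plausible spot load);
    ``mrf_interaction`` is the Potts coupling of the label field (0 = iid
    labels; the default 1.45 sits just below the ordering transition of the
    13-state field so tissue-like patches of a few to a few dozen tiles
    form); ``target_autocorr_boost`` (> 1) sets how strongly the target's
    patch boundaries are smoothed relative to the controls;
    ``source_border_radius`` is the dilation radius (tiles) of the border
    zone around target patches from which source tiles are seeded, and
    ``source_fill_prob`` the per-tile seeding probability.
    """

    grid_side: int = 80
    scenario: str = "single_source"
    n_control_types: int = 2
    markers_per_type: int = 5
    n_paracrine_genes: int = 5
    n_noise_genes: int = 40
    marker_rate_range: tuple = (15.0, 30.0)
    noise_rate_range: tuple = (0.0, 3.0)
    paracrine_off_rate_range: tuple = (0.0, 0.1)
    alpha: float = 0.01
    mrf_interaction: float = 1.45
    target_autocorr_boost: float = 1.5
    source_border_radius: int = 2
    source_fill_prob: float = 0.75
    gibbs_sweeps: int = 200
    tile_spacing_um: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        if self.grid_side < 4:
            raise ValueError("grid_side must be >= 4")
        for name in ("marker_rate_range", "noise_rate_range", "paracrine_off_rate_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} must be nonnegative and ordered")

    @property
    def n_sources(self) -> int:
        return 2 if self.scenario == "multi_source" else 1

    @property
    def cell_types(self) -> list:
        sources = ["source"] if self.n_sources == 1 else ["source_1", "source_2"]
        controls = [f"control_{i + 1}" for i in range(self.n_control_types)]
        return ["target", *sources, *controls]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SimulationTruth:
    """A generated dataset bundled with its ground truth."""

    config: SimulationConfig
    labels: np.ndarray  # (side, side) int indices into cell_type_ids
    cell_type_ids: list
    marker_map: dict  # gene -> cell type
    paracrine_genes: list  # dicts: gene, source_types, target_type
    expression: ExpressionMatrix  # counts
    compositions: CompositionMatrix
    geometry: SpotGeometry
    prevalence: PrevalenceMatrix
    noise_genes: list = field(default_factory=list)

    @property
    def target_type(self) -> str:
        return "target"

    def truth_dict(self) -> dict:
        return {
            "scenario": self.config.scenario,
            "seed": self.config.seed,
            "cell_types": self.cell_type_ids,
            "labels": self.labels.tolist(),
            "marker_map": self.marker_map,
            "paracrine_genes": self.paracrine_genes,
            "noise_genes": self.noise_genes,
        }


def _neighbor_onehot_counts(labels: np.ndarray, k: int) -> np.ndarray:
    """(side, side, k) count of 4-neighbors carrying each label (no wrap)."""
    side = labels.shape[0]
    onehot = np.zeros((side, side, k))
    onehot[np.arange(side)[:, None], np.arange(side)[None, :], labels] = 1.0
    counts = np.zeros_like(onehot)
    counts[1:, :] += onehot[:-1, :]
    counts[:-1, :] += onehot[1:, :]
    counts[:, 1:] += onehot[:, :-1]
    counts[:, :-1] += onehot[:, 1:]
    return counts


def _sample_potts(side: int, n_states: int, coupling: float, sweeps: int, rng) -> np.ndarray:
    """Symmetric Potts field via checkerboard Gibbs sweeps from an iid start."""
    labels = rng.integers(0, n_states, size=(side, side))
    rr, cc = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    colors = [(rr + cc) % 2 == 0, (rr + cc) % 2 == 1]
    for _ in range(sweeps):
        for mask in colors:
            field_counts = _neighbor_onehot_counts(labels, n_states)
            logits = coupling * field_counts
            gumbel = -np.log(-np.log(rng.random(logits.shape)))
            proposal = np.argmax(logits + gumbel, axis=-1)
            labels = np.where(mask, proposal, labels)
    return labels


def _smooth_target_boundary(labels: np.ndarray, n_states: int, rounds: int, rng) -> np.ndarray:
    """Neighborhood-majority smoothing applied only where the target state is
    involved, so target patches get smoother boundaries (greater spatial
    autocorrelation) than the control patches."""
    for _ in range(rounds):
        counts = _neighbor_onehot_counts(labels, n_states)
        mode = np.argmax(counts + 1e-6 * rng.random(counts.shape), axis=-1)
        involved = (labels == 0) | (mode == 0)
        labels = np.where(involved, mode, labels)
    return labels


def simulate_labels(config: SimulationConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Sample the cell-type label grid for the MRF scenarios.

    A symmetric Potts model with ``1 + 6 * n_control_types`` states is
    sampled by ``gibbs_sweeps`` checkerboard Gibbs sweeps at coupling
    ``mrf_interaction`` (near the ordering transition by default, giving
    tissue-like patches; symmetry keeps the state area fractions stable, and
    the state count keeps the target a minority type with small,
    border-dominated patches). State 0 becomes the target and its boundary
    is majority-smoothed for
    ``round(4 * (target_autocorr_boost - 1))`` rounds; the remaining states
    are merged alternately into the control types. Source tiles are then
    seeded from the dilated border zone of the target patches
    (``source_border_radius`` tiles wide) with probability
    ``source_fill_prob`` per tile, split at random between the two source
    types in the multi-source scenario.

    ``mrf_interaction = 0`` degenerates to iid labels with equal type
    frequencies. The ``simple`` scenario is deterministic
    (see :func:`simple_layout`).
    """
    from scipy.ndimage import binary_dilation

    rng = rng or np.random.default_rng(config.seed)
    if config.scenario == "simple":
        labels, _ = simple_layout(config)
        return labels
    side = config.grid_side
    types = config.cell_types
    k = len(types)
    if config.mrf_interaction == 0:
        return rng.integers(0, k, size=(side, side))
    n_states = 1 + 6 * config.n_control_types
    states = _sample_potts(side, n_states, config.mrf_interaction, config.gibbs_sweeps, rng)
    rounds = max(int(round(4.0 * (config.target_autocorr_boost - 1.0))), 0)
    states = _smooth_target_boundary(states, n_states, rounds, rng)
    target_mask = states == 0
    labels = np.empty((side, side), dtype=np.int64)
    labels[target_mask] = 0
    first_control = 1 + config.n_sources
    for s in range(1, n_states):  # merge extra states alternately into controls
        labels[states == s] = first_control + (s - 1) % config.n_control_types
    border = binary_dilation(target_mask, iterations=config.source_border_radius) & ~target_mask
    seeded = border & (rng.random(border.shape) < config.source_fill_prob)
    if config.n_sources == 1:
        labels[seeded] = 1
    else:
        split = rng.random(border.shape) < 0.5
        labels[seeded & split] = 1
        labels[seeded & ~split] = 2
    return labels


def simple_layout(config: SimulationConfig):
    """Deterministic layout: 4x4 target blocks on a 16-tile pitch, with the
    paracrine expression region shifted by (2, 3) tiles so it overlaps the
    target blocks slightly (2 of 16 tiles) and otherwise rings them.

    Returns ``(labels, paracrine_region)``; source-labeled tiles are the
    non-overlapping part of the shifted region.
    """
    side = config.grid_side
    block, pitch, off = 4, 16, 4
    shift = (2, 3)
    target = np.zeros((side, side), dtype=bool)
    for r0 in range(off, side - block + 1, pitch):
        for c0 in range(off, side - block + 1, pitch):
            target[r0 : r0 + block, c0 : c0 + block] = True
    region = np.zeros_like(target)
    rs, cs = np.nonzero(target)
    rs2, cs2 = rs + shift[0], cs + shift[1]
    ok = (rs2 < side) & (cs2 < side)
    region[rs2[ok], cs2[ok]] = True
    types = config.cell_types
    labels = np.empty((side, side), dtype=np.int64)
    half = side // 2
    labels[:, :half] = types.index("control_1")
    labels[:, half:] = types.index("control_2" if config.n_control_types > 1 else "control_1")
    labels[region & ~target] = 1  # source
    labels[target] = 0  # target wins the overlap so its composition is high there
    return labels, region


def _rate_matrix(labels, config: SimulationConfig, rng, paracrine_region=None):
    """Per-tile Poisson rate for every gene, plus gene bookkeeping."""
    side = config.grid_side
    n = side * side
    flat = labels.reshape(n)
    types = config.cell_types
    lo_m, hi_m = config.marker_rate_range
    lo_n, hi_n = config.noise_rate_range
    lo_p, hi_p = config.paracrine_off_rate_range
    gene_ids, rate_cols = [], []
    marker_map = {}
    for t_idx, t in enumerate(types):
        own = flat == t_idx
        for i in range(config.markers_per_type):
            gene = f"mk_{t}_{i + 1}"
            rates = np.full(n, rng.uniform(lo_n, hi_n))
            rates[own] = rng.uniform(lo_m, hi_m)
            gene_ids.append(gene)
            rate_cols.append(rates)
            marker_map[gene] = t
    source_types = types[1 : 1 + config.n_sources]
    if paracrine_region is None:
        region_masks = [flat == types.index(s) for s in source_types]
    else:
        region_masks = [paracrine_region.reshape(n)]
    paracrine = []
    for i in range(config.n_paracrine_genes):
        gene = f"para_{i + 1}"
        rates = np.full(n, rng.uniform(lo_p, hi_p))
        for mask in region_masks:
            rates[mask] = rng.uniform(lo_m, hi_m)
        gene_ids.append(gene)
        rate_cols.append(rates)
        paracrine.append({"gene": gene, "source_types": list(source_types), "target_type": "target"})
    noise_genes = []
    for i in range(config.n_noise_genes):
        gene = f"noise_{i + 1}"
        gene_ids.append(gene)
        rate_cols.append(np.full(n, rng.uniform(lo_n, hi_n)))
        noise_genes.append(gene)
    rates = np.column_stack(rate_cols)
    return gene_ids, rates, marker_map, paracrine, noise_genes


def _tile_ids(side: int) -> list:
    return [f"t{r}_{c}" for r in range(side) for c in range(side)]


def simulate_expression(
    labels: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    paracrine_region: np.ndarray | None = None,
):
    """Draw Poisson counts for markers, paracrine and noise genes.

    Returns ``(expression, marker_map, paracrine_genes)``; the counts matrix
    is tiles x genes with tile ids ``t{row}_{col}``.
    """
    rng = rng or np.random.default_rng(config.seed)
    expr, _, marker_map, paracrine, _ = _simulate_expression_full(labels, config, rng, paracrine_region)
    return expr, marker_map, paracrine


def _simulate_expression_full(labels, config, rng, paracrine_region=None):
    gene_ids, rates, marker_map, paracrine, noise_genes = _rate_matrix(
        labels, config, rng, paracrine_region
    )
    counts = rng.poisson(rates).astype(float)
    expr = ExpressionMatrix(_tile_ids(config.grid_side), gene_ids, counts)
    return expr, rates, marker_map, paracrine, noise_genes


def simulate_compositions(
    expression: ExpressionMatrix,
    marker_map: dict,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    rates: np.ndarray | None = None,
) -> CompositionMatrix:
    """Poisson-sampled per-tile cell counts, normalized to proportions.

    The rate for type ``i`` at a tile is ``alpha * sum_{g in markers(i)}
    lambda_g * y_g`` with ``lambda`` the gene's generative rate there and
    ``y`` its realized count; if the rates are unavailable the counts stand
    in for them. Tiles whose total count is 0 are resampled once and then
    assigned a uniform composition (logged).
    """
    comp, _ = _simulate_compositions_full(expression, marker_map, config, rng, rates)
    return comp


def _simulate_compositions_full(
    expression: ExpressionMatrix,
    marker_map: dict,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    rates: np.ndarray | None = None,
):
    rng = rng or np.random.default_rng(config.seed)
    if rates is None:
        rates = expression.values
    types = config.cell_types
    n = expression.n_spots
    gene_pos = {g: i for i, g in enumerate(expression.gene_ids)}
    cell_rates = np.zeros((len(types), n))
    for gene, t in marker_map.items():
        gi = gene_pos[gene]
        cell_rates[types.index(t)] += rates[:, gi] * expression.values[:, gi]
    cell_rates *= config.alpha
    counts = rng.poisson(cell_rates).astype(float)
    totals = counts.sum(axis=0)
    dead = totals == 0
    if dead.any():
        counts[:, dead] = rng.poisson(cell_rates[:, dead]).astype(float)
        totals = counts.sum(axis=0)
        dead = totals == 0
        if dead.any():
            logger.info("%d tiles with zero sampled cells set to uniform composition", int(dead.sum()))
            counts[:, dead] = 1.0
            totals = counts.sum(axis=0)
    values = counts / totals[np.newaxis, :]
    return CompositionMatrix(types, expression.spot_ids, values), counts


def _prevalence_from_rates(labels, rates, gene_ids, types, cells_per_tile: float) -> PrevalenceMatrix:
    """Expression prevalence per (type, gene) from the generative rates.

    Prevalence is a property of single reference cells, not of multicellular
    tiles: a tile's Poisson rate is spread over the ~``cells_per_tile`` cells
    it contains, and the prevalence of a gene in a type is the expected
    fraction of that type's cells with a nonzero count,
    ``mean over the type's tiles of 1 - exp(-rate / cells_per_tile)``.
    """
    flat = labels.reshape(-1)
    detect = 1.0 - np.exp(-rates / max(cells_per_tile, 1.0))
    values = np.vstack([detect[flat == t_idx].mean(axis=0) for t_idx in range(len(types))])
    return PrevalenceMatrix(types, gene_ids, values)


def make_scenario(config: SimulationConfig) -> SimulationTruth:
    """Generate one complete dataset for the configured scenario."""
    rng = np.random.default_rng(config.seed)
    if config.scenario == "simple":
        labels, region = simple_layout(config)
    else:
        labels = simulate_labels(config, rng)
        region = None
    expr, rates, marker_map, paracrine, noise_genes = _simulate_expression_full(
        labels, config, rng, paracrine_region=region
    )
    comps, cell_counts = _simulate_compositions_full(expr, marker_map, config, rng, rates=rates)
    side = config.grid_side
    rr, cc = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    coords = np.column_stack([cc.reshape(-1), rr.reshape(-1)]).astype(float) * config.tile_spacing_um
    geometry = SpotGeometry(expr.spot_ids, coords, spacing=config.tile_spacing_um)
    cells_per_tile = float(cell_counts.sum(axis=0).mean())
    prevalence = _prevalence_from_rates(
        labels, rates, list(expr.gene_ids), config.cell_types, cells_per_tile
    )
    return SimulationTruth(
        config=config,
        labels=labels,
        cell_type_ids=config.cell_types,
        marker_map=marker_map,
        paracrine_genes=paracrine,
        expression=expr,
        compositions=comps,
        geometry=geometry,
        prevalence=prevalence,
        noise_genes=noise_genes,
    )
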