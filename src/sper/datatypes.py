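"""Core matrix containers and their invariants.

Orientation conventions (stated in names throughout the package):

* :class:`ExpressionMatrix` is **spots x genes** (``n x m``).
* :class:`CompositionMatrix` is **cell types x spots** (``k x n``); every spot
  column lies on the probability simplex.
* :class:`PrevalenceMatrix` is **cell types x genes** (``k x m``), aligned with
  score matrices.

Spot alignment between paired containers is always verified by identifier,
never by position alone.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Simplex deviation below which composition columns are accepted as-is.
SIMPLEX_TOL = 1e-6
#: Simplex deviation up to which composition columns are renormalized (warning).
SIMPLEX_RENORM_TOL = 1e-2
#: Fill value for (cell type, gene) pairs absent from a prevalence reference.
#: 1.0 is the conservative choice: exp(p - 1) = 1, no score boost or penalty.
PREVALENCE_FILL = 1.0


def _as_str_index(ids) -> pd.Index:
    idx = pd.Index([str(x) for x in ids])
    if idx.has_duplicates:
        dup = idx[idx.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate identifiers: {dup}")
    return idx


@dataclass
class ExpressionMatrix:
    """Spot x gene expression, either raw counts or global-mean ratios.

    Parameters
    ----------
    spot_ids, gene_ids
        Ordered identifiers for the rows / columns of ``values``.
    values
        ``(n_spots, n_genes)`` nonnegative array.
    normalized
        If True, each gene column has been divided by its mean over all
        spots, so every nonzero column has mean exactly 1.
    """

    spot_ids: pd.Index
    gene_ids: pd.Index
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        self.spot_ids = _as_str_index(self.spot_ids)
        self.gene_ids = _as_str_index(self.gene_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be 2-D (spots x genes)")
        n, m = self.values.shape
        if n != len(self.spot_ids) or m != len(self.gene_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.spot_ids)} spots x {len(self.gene_ids)} genes"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("expression contains non-finite entries")
        if (self.values < 0).any():
            raise ValueError("expression contains negative entries")

    @property
    def n_spots(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.spot_ids, columns=self.gene_ids)


@dataclass
class CompositionMatrix:
    """Cell type x spot proportions; every spot column sums to 1.

    Columns deviating from the simplex by more than :data:`SIMPLEX_TOL` but at
    most :data:`SIMPLEX_RENORM_TOL` are renormalized with a warning; larger
    deviations raise, naming the offending spots.
    """

    cell_type_ids: pd.Index
    spot_ids: pd.Index
    values: np.ndarray

    def __post_init__(self):
        self.cell_type_ids = _as_str_index(self.cell_type_ids)
        self.spot_ids = _as_str_index(self.spot_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cell_type_ids), len(self.spot_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.cell_type_ids)} types x {len(self.spot_ids)} spots"
            )
        if not np.isfinite(self.values).all() or (self.values < -SIMPLEX_TOL).any():
            raise ValueError("compositions must be finite and nonnegative")
        colsums = self.values.sum(axis=0)
        dev = np.abs(colsums - 1.0)
        bad = dev > SIMPLEX_RENORM_TOL
        if bad.any():
            offenders = self.spot_ids[bad].tolist()[:10]
            raise ValueError(
                f"{bad.sum()} spot columns violate the simplex constraint "
                f"(|sum - 1| > {SIMPLEX_RENORM_TOL}); e.g. spots {offenders}"
            )
        renorm = dev > SIMPLEX_TOL
        if renorm.any():
            warnings.warn(
                f"renormalizing {renorm.sum()} composition columns with "
                f"simplex deviation in ({SIMPLEX_TOL}, {SIMPLEX_RENORM_TOL}]",
                stacklevel=2,
            )
            self.values = self.values / colsums[np.newaxis, :]

    @property
    def n_types(self) -> int:
        return self.values.shape[0]

    @property
    def n_spots(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_type_ids, columns=self.spot_ids)


@dataclass
class SpotGeometry:
    """Spot identifiers with 2-D physical coordinates in micrometers."""

    spot_ids: pd.Index
    coordinates: np.ndarray
    spacing: float | None = None

    def __post_init__(self):
        self.spot_ids = _as_str_index(self.spot_ids)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (len(self.spot_ids), 2):
            raise ValueError("coordinates must be (n_spots, 2)")
        if not np.isfinite(self.coordinates).all():
            raise ValueError("coordinates must be finite")
        if self.spacing is None:
            self.spacing = self._infer_spacing()
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")

    def _infer_spacing(self) -> float:
        """Median nearest-neighbor distance, the nominal adjacent-spot spacing."""
        from scipy.spatial import cKDTree

        if len(self.spot_ids) < 2:
            raise ValueError("cannot infer spacing from fewer than 2 spots")
        tree = cKDTree(self.coordinates)
        d, _ = tree.query(self.coordinates, k=2)
        return float(np.median(d[:, 1]))

    @property
    def n_spots(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class PrevalenceMatrix:
    """Fraction of reference cells of each type expressing each gene.

    Stored cell-types x genes; ``aligned_to`` reindexes against a score
    matrix's axes, filling unknown pairs with :data:`PREVALENCE_FILL`.
    """

    cell_type_ids: pd.Index
    gene_ids: pd.Index
    values: np.ndarray

    def __post_init__(self):
        self.cell_type_ids = _as_str_index(self.cell_type_ids)
        self.gene_ids = _as_str_index(self.gene_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cell_type_ids), len(self.gene_ids)):
            raise ValueError("prevalence shape mismatch")
        if ((self.values < 0) | (self.values > 1)).any() or not np.isfinite(self.values).all():
            raise ValueError("prevalence values must lie in [0, 1]")

    def aligned_to(self, cell_type_ids, gene_ids) -> np.ndarray:
        """Return a dense (k, m) array aligned by label, unknown pairs -> fill."""
        frame = pd.DataFrame(self.values, index=self.cell_type_ids, columns=self.gene_ids)
        out = frame.reindex(
            index=[str(t) for t in cell_type_ids],
            columns=[str(g) for g in gene_ids],
        ).to_numpy()
        missing = np.isnan(out)
        if missing.any():
            logger.info(
                "prevalence: %d (type, gene) pairs missing from reference, "
                "filled with %.1f",
                int(missing.sum()),
                PREVALENCE_FILL,
            )
            out = np.where(missing, PREVALENCE_FILL, out)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_type_ids, columns=self.gene_ids)


@dataclass(frozen=True)
class GeneSet:
    """Named set of gene identifiers (annotation collection, e.g. extracellular)."""

    name: str
    members: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "members", frozenset(str(g) for g in self.members))
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene) -> bool:
        return str(gene) in self.members


@dataclass
class LigandReceptorTable:
    """Two-column (ligand, receptor) interaction table without duplicate pairs."""

    pairs: pd.DataFrame

    def __post_init__(self):
        df = pd.DataFrame(self.pairs)
        if list(df.columns[:2]) != ["ligand", "receptor"]:
            df = df.iloc[:, :2].set_axis(["ligand", "receptor"], axis=1)
        df = df.astype(str)
        if df.duplicated().any():
            raise ValueError("duplicate ligand-receptor pairs")
        self.pairs = df.reset_index(drop=True)

    def receptors_for(self, ligand: str) -> list[str]:
        mask = self.pairs["ligand"] == str(ligand)
        return self.pairs.loc[mask, "receptor"].tolist()

    def __len__(self) -> int:
        return len(self.pairs)


def check_spot_alignment(*objs) -> pd.Index:
    """Verify that all containers share identical, identically ordered spot ids."""
    ids = [o.spot_ids for o in objs if o is not None]
    ref = ids[0]
    for other in ids[1:]:
        if len(other) != len(ref) or not (other == ref).all():
            raise ValueError(
                "spot identifiers are not aligned across inputs; "
                "reorder/subset them to a common spot list first"
            )
    return ref
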