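"""Per-well composition, cell-type colocalization, and tumor-proximity scores.

The proximity score summarizes, for every well, how deep it sits inside the
tumor versus the surrounding tissue.  Two variants:

layered (composition-driven)
    For well ``w`` let ``t_w`` be its count of tumor + reference cells and
    ``p_w`` the tumor fraction among them.  For each concentric layer
    ``l = 1..L`` the layer mean ``p_{w,l}`` is the cell-number-weighted
    average of ``p`` over the layer's wells with ``t > 0``.  The score is the
    decay-weighted combination

        s_w = [u_1 p_w + sum_l u_l p_{w,l}] / (u_1 + sum_{nonempty l} u_l),

    with exponential weights ``u_l = d^-l / u_s`` (``d = 1.05``, ``L = 10``),
    so the well's own composition carries the same weight as its immediate
    neighbours.  The denominator renormalizes over the terms actually
    realized (own term dropped when ``t_w = 0``, empty layers dropped), which
    keeps ``s`` in [0, 1].

seeded linear
    For tissues where the tumor sits at one end, selected seed wells get
    score 1 and the score falls linearly with hexagonal layer distance,
    reaching 0 at layer ``L`` and beyond: ``s = max(0, 1 - l/L)``.

By default ``p`` is the tumor-cell fraction so scores near 1 mark tumor-rich
regions; pass ``orientation='reference'`` for the mirrored convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.stats

from .hexarray import HexWell, WellArray, hex_distance, layer

logger = logging.getLogger(__name__)

__all__ = [
    "WellComposition",
    "DecayWeights",
    "ProximityField",
    "well_composition",
    "colocalization",
    "decay_weights",
    "tumor_proximity",
    "seeded_score",
    "cell_scores",
]

DEFAULT_DECAY = 1.05
DEFAULT_LAYERS = 10


@dataclass
class WellComposition:
    """Per-well cell-type tallies (wells x types), zeros for empty wells."""

    counts: pd.DataFrame  # index well_id, one column per cell type

    @property
    def cell_types(self) -> list[str]:
        return list(self.counts.columns)

    def total(self, types=None) -> pd.Series:
        cols = self.counts.columns if types is None else list(types)
        return self.counts[cols].sum(axis=1)


def well_composition(adata: ad.AnnData, cell_type_key: str = "cell_type",
                     array: WellArray | None = None) -> WellComposition:
    """Tally cells per (well, cell type).

    Every well of ``array`` appears (zero rows for empty wells); a cell whose
    well id is not on the array is an error.
    """
    if "well_id" not in adata.obs:
        raise ValueError("cells lack well assignments (obs['well_id'])")
    tab = pd.crosstab(adata.obs["well_id"], adata.obs[cell_type_key])
    tab.index.name = "well_id"
    tab.columns.name = None
    if array is not None:
        known = {w.well_id for w in array}
        unknown = set(tab.index) - known
        if unknown:
            raise ValueError(f"cells assigned to wells not on the array: "
                             f"{sorted(unknown)[:5]}...")
        tab = tab.reindex([w.well_id for w in array], fill_value=0)
        tab.index.name = "well_id"
    return WellComposition(counts=tab.astype(np.int64))


def colocalization(comp: WellComposition, type_a: str,
                   type_b: str) -> tuple[float, float]:
    """Pearson correlation (r, p) of two cell types' per-well counts.

    A positive r across wells indicates the two types co-occupy wells.
    Returns (nan, nan) with a warning when either vector has zero variance.
    """
    x = comp.counts[type_a].to_numpy(dtype=float)
    y = comp.counts[type_b].to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 wells for a correlation")
    if x.std() == 0 or y.std() == 0:
        logger.warning("zero variance in per-well counts of %s or %s; "
                       "correlation undefined", type_a, type_b)
        return float("nan"), float("nan")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass(frozen=True)
class DecayWeights:
    """Normalized exponential layer weights u_l = d^-l / sum_l d^-l."""

    d: float = DEFAULT_DECAY
    L: int = DEFAULT_LAYERS

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("decay factor d must be positive")
        if self.L < 1:
            raise ValueError("need at least one layer")

    @property
    def u_s(self) -> float:
        return float(sum(self.d ** -l for l in range(1, self.L + 1)))

    @property
    def u(self) -> np.ndarray:
        """Weights for layers 1..L, summing to 1."""
        raw = np.array([self.d ** -l for l in range(1, self.L + 1)])
        return raw / raw.sum()


def decay_weights(d: float = DEFAULT_DECAY, L: int = DEFAULT_LAYERS) -> DecayWeights:
    """Exponential-decay layer weights, truncated at L terms and normalized."""
    return DecayWeights(d=d, L=L)


@dataclass
class ProximityField:
    """Per-well proximity score with the parameters that produced it."""

    scores: pd.Series  # index well_id, values in [0, 1] (NaN = unscored)
    variant: str
    d: float | None = None
    L: int = DEFAULT_LAYERS
    orientation: str = "tumor"

    def to_frame(self, array: WellArray | None = None) -> pd.DataFrame:
        df = self.scores.rename("score").rename_axis("well_id").reset_index()
        if array is not None:
            offsets = {w.well_id: w.offset for w in array}
            df["row"] = [offsets[w][0] for w in df["well_id"]]
            df["col"] = [offsets[w][1] for w in df["well_id"]]
        df["variant"] = self.variant
        df["d"] = self.d
        df["L"] = self.L
        return df


def tumor_proximity(comp: WellComposition, array: WellArray,
                    weights: DecayWeights | None = None,
                    tumor_label: str = "MC38", ref_label: str = "hepatocyte",
                    orientation: str = "tumor",
                    min_cells: int = 1) -> ProximityField:
    """Layered composition-driven proximity score for every well.

    Only cells of ``tumor_label`` and ``ref_label`` enter the composition
    fractions (the reference type is the parenchymal type strictly tied to
    non-tumor tissue).  Wells with fewer than ``min_cells`` cells of any type
    are left unscored; a scored well with no tumor/reference cells of its own
    drops its own-composition term and renormalizes over its layers.
    """
    if weights is None:
        weights = decay_weights()
    if orientation not in ("tumor", "reference"):
        raise ValueError("orientation must be 'tumor' or 'reference'")
    counts = comp.counts
    for lbl in (tumor_label, ref_label):
        if lbl not in counts.columns:
            counts = counts.assign(**{lbl: 0})
    t = (counts[tumor_label] + counts[ref_label]).astype(float)
    numer = counts[tumor_label] if orientation == "tumor" else counts[ref_label]
    with np.errstate(invalid="ignore"):
        p = numer.where(t > 0).div(t.where(t > 0))

    any_cells = comp.counts.sum(axis=1)
    u = weights.u
    u1 = u[0]
    scores: dict[str, float] = {}
    for w in array:
        if w.well_id not in t.index or any_cells.get(w.well_id, 0) < min_cells:
            scores[w.well_id] = np.nan
            continue
        num = 0.0
        den = 0.0
        if t[w.well_id] > 0:
            num += u1 * p[w.well_id]
            den += u1
        for l in range(1, weights.L + 1):
            ring = layer(array, w, l)
            ids = [r.well_id for r in ring if r.well_id in t.index and t[r.well_id] > 0]
            if not ids:
                continue
            tw = t[ids].to_numpy()
            pl = float(np.average(p[ids].to_numpy(), weights=tw))
            num += u[l - 1] * pl
            den += u[l - 1]
        if den == 0:
            logger.warning("well %s has no composition in any layer; unscored",
                           w.well_id)
            scores[w.well_id] = np.nan
        else:
            scores[w.well_id] = num / den
    series = pd.Series(scores, name="score").reindex([w.well_id for w in array])
    return ProximityField(scores=series, variant="layered", d=weights.d,
                          L=weights.L, orientation=orientation)


def seeded_score(array: WellArray, seed_wells, L: int = DEFAULT_LAYERS) -> ProximityField:
    """Linear-decay score from manually chosen seed wells.

    Seeds score 1; the score drops by 1/L per hexagonal layer away from the
    nearest seed, reaching 0 at layer L and beyond.
    """
    seeds = [array.well(s) if isinstance(s, str) else s for s in seed_wells]
    if not seeds:
        raise ValueError("need at least one seed well")
    for s in seeds:
        if s not in array:
            raise ValueError(f"seed well {s.well_id!r} not on array")
    scores = {}
    for w in array:
        l = min(hex_distance(w, s) for s in seeds)
        scores[w.well_id] = max(0.0, 1.0 - l / L)
    series = pd.Series(scores, name="score").reindex([w.well_id for w in array])
    return ProximityField(scores=series, variant="seeded_linear", d=None, L=L)


def cell_scores(field: ProximityField, adata: ad.AnnData,
                key: str = "proximity_score") -> pd.Series:
    """Propagate well scores to cells; cells in unscored wells get NaN."""
    if "well_id" not in adata.obs:
        raise ValueError("cells lack well assignments (obs['well_id'])")
    per_cell = adata.obs["well_id"].map(field.scores).astype(float)
    per_cell.name = key
    adata.obs[key] = per_cell.values
    n_null = int(per_cell.isna().sum())
    if n_null:
        logger.info("%d cells sit in unscored wells (null score)", n_null)
    return per_cell
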