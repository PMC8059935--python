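"""Mixed-species ("barnyard") quality control.

A barnyard run deposits known human/mouse cell mixtures on the chip; cell
barcodes whose UMIs map substantially to both genomes betray barcode
collisions (two cells sharing one combinatorial barcode) or ambient
contamination.  A cell is called for a species when at least 66% of its UMIs
align to that species; otherwise it is a collision.

The mixing experiment prints an 11-ratio human:mouse gradient over the 21
columns of the chip (100/0, 90/10, ..., 0/100, ..., 90/10, 100/0 — human at
the flanks, mouse at the center), so observed per-column species proportions
can be checked against the design with Lin's concordance correlation
coefficient (CCC), which measures agreement with the identity line.
"""

from __future__ import annotations

import logging

import anndata as ad
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GRADIENT_HUMAN_FRACTIONS",
    "gradient_design",
    "call_species",
    "annotate_species_calls",
    "collision_rate",
    "lin_ccc",
    "gradient_concordance",
    "barnyard_report",
]

SPECIES_THRESHOLD = 0.66

#: Human cell fraction per column of the 21-column mixing gradient:
#: 100/0, 90/10, ..., 0/100 at the center, mirrored back to 100/0.
GRADIENT_HUMAN_FRACTIONS = tuple(round(abs(10 - i) * 0.1, 1) for i in range(21))


def gradient_design(n_columns: int = 21) -> pd.Series:
    """Expected human fraction per chip column for the mixing gradient.

    The 21-column pattern holds 11 distinct ratios; human-only columns flank
    the array and the mouse-only column sits at the center.
    """
    if n_columns != 21:
        raise ValueError("the mixing gradient is defined over 21 columns")
    return pd.Series(GRADIENT_HUMAN_FRACTIONS,
                     index=pd.RangeIndex(n_columns, name="col"),
                     name="human_fraction")


def call_species(human_umis: int, mouse_umis: int,
                 threshold: float = SPECIES_THRESHOLD) -> str:
    """Call a cell 'human', 'mouse', or 'collision' by UMI majority.

    The majority species must hold at least ``threshold`` of the UMIs
    (boundary inclusive); cells below the threshold for both species are
    collisions.  Zero-UMI cells are undefined.
    """
    total = human_umis + mouse_umis
    if total <= 0:
        raise ValueError("cell has no human or mouse UMIs; call undefined")
    if human_umis / total >= threshold:
        return "human"
    if mouse_umis / total >= threshold:
        return "mouse"
    return "collision"


def annotate_species_calls(adata: ad.AnnData,
                           threshold: float = SPECIES_THRESHOLD) -> ad.AnnData:
    """Vectorised species call for every cell, stored in obs['species_call'].

    Cells with zero human+mouse UMIs get 'undefined' and are excluded from
    collision statistics.
    """
    h = adata.obs["human_umis"].to_numpy(dtype=float)
    m = adata.obs["mouse_umis"].to_numpy(dtype=float)
    total = h + m
    call = np.full(adata.n_obs, "collision", dtype=object)
    with np.errstate(invalid="ignore"):
        frac_h = np.divide(h, total, out=np.zeros_like(h), where=total > 0)
        frac_m = np.divide(m, total, out=np.zeros_like(m), where=total > 0)
    call[frac_h >= threshold] = "human"
    call[frac_m >= threshold] = "mouse"
    call[total == 0] = "undefined"
    adata.obs["species_call"] = call
    adata.obs["fraction_major"] = np.maximum(frac_h, frac_m)
    return adata


def collision_rate(calls) -> float:
    """Fraction of defined cells called as collisions."""
    calls = pd.Series(list(calls), dtype=object)
    calls = calls[calls != "undefined"]
    if calls.empty:
        raise ValueError("no cells with defined species calls")
    return float((calls == "collision").mean())


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient.

    CCC = 2 cov(x, y) / (var(x) + var(y) + (mean x - mean y)^2), with
    population (1/n) moments as in Lin's original definition.  Equals 1 only
    for y = x; attenuated by both decorrelation and location/scale shift.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 2:
        raise ValueError("need at least two observations")
    vx, vy = x.var(), y.var()
    if vx == 0 and vy == 0 and x.mean() == y.mean():
        return 1.0
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(2.0 * cov / (vx + vy + (x.mean() - y.mean()) ** 2))


def gradient_concordance(adata: ad.AnnData, design: pd.Series,
                         col_key: str = "col") -> tuple[pd.DataFrame, float]:
    """Observed vs designed per-column human fractions, and their CCC.

    Cells must carry species calls and a chip-column assignment in
    ``obs[col_key]``.  Collision/undefined cells are excluded; columns with no
    called cells are dropped with a warning.
    """
    if "species_call" not in adata.obs:
        annotate_species_calls(adata)
    obs = adata.obs
    called = obs[obs["species_call"].isin(["human", "mouse"])]
    frac = (called.groupby(col_key, observed=True)["species_call"]
            .apply(lambda s: float((s == "human").mean())))
    table = pd.DataFrame({"expected": design})
    table["observed"] = frac
    missing = table.index[table["observed"].isna()]
    if len(missing):
        logger.warning("columns with no called cells excluded: %s", list(missing))
        table = table.dropna(subset=["observed"])
    ccc = lin_ccc(table["observed"].to_numpy(), table["expected"].to_numpy())
    return table, ccc


def barnyard_report(adata: ad.AnnData) -> pd.DataFrame:
    """Per-cell barnyard table: UMIs per species, majority fraction, call."""
    if "species_call" not in adata.obs:
        annotate_species_calls(adata)
    return adata.obs[["human_umis", "mouse_umis",
                      "fraction_major", "species_call"]].reset_index(names="cell")
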