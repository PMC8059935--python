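"""Ground-truthed synthetic data for every pipeline stage.

Emulates the study conditions of a microwell spatial scRNA-seq run on a
heterotopic tumor model: a hexagonal chip whose wells fall into tumor and
tissue domains, per-well cell counts ~ Poisson (mean 13, the chip's expected
occupancy), cell types drawn per domain (tumor wells dominated by MC38 cancer
cells, tissue wells by hepatocytes, with mesenchymal stem cells and myeloid
cells mixed in), and per-gene negative binomial counts with cell-type marker
programs (log-fold-change boosts on disjoint marker blocks).

Also generated: the 21-column human/mouse mixing gradient (11 distinct
ratios, human flanks, mouse center) for barnyard QC; beta-distributed ambient
contamination planted by resampling a fraction of each cell's counts from the
pooled other-population profile (totals preserved); and raw FASTQ reads in
the assay's library layout (read 1 = 10-nt UMI + 16-nt spatial barcode, read
2 = synthetic gene tag, i5 = PCR index) for demultiplexing round trips.

All generators are pure functions of (design, seed).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import hexarray
from .demux import READ1_LENGTH, annotate_qc
from .hexarray import WellArray
from .species_qc import gradient_design

__all__ = [
    "CellTypeProgram",
    "SimulationDesign",
    "GroundTruth",
    "simulate_tissue",
    "simulate_barnyard",
    "inject_ambient",
    "emit_fastq",
    "gene_codebook",
]

R2_LENGTH = 98
INDEX_LENGTH = 8
GENE_TAG_LENGTH = 16
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class CellTypeProgram:
    """A cell type's marker program: which genes it boosts and by how much."""

    name: str
    n_markers: int = 40
    log2_fold_change: float = 3.0


@dataclass
class SimulationDesign:
    """Study-condition parameters for the tissue simulation.

    Defaults mirror the assayed chip: 24 x 32 wells, ~13 cells per well, a
    half-plane tumor/tissue split, four murine cell types with 8-fold marker
    programs, NB dispersion 0.5, and Beta(2, 8) ambient contamination
    (mean 20%) when contamination is planted.
    """

    n_rows: int = 24
    n_cols: int = 32
    geometry: str = "half_plane"       # or "disk"
    disk_radius: int = 6               # layers, for the disk geometry
    cells_per_well: float = 13.0
    n_genes: int = 400
    base_mean: float = 2.0             # mean NB counts/gene before boosts
    dispersion: float = 0.5            # NB2 alpha
    contamination: tuple[float, float] = (2.0, 8.0)
    cell_types: tuple[CellTypeProgram, ...] = (
        CellTypeProgram("hepatocyte"),
        CellTypeProgram("MC38"),
        CellTypeProgram("MSC"),
        CellTypeProgram("myeloid"),
    )
    #: P(cell type | domain); tumor wells MC38-dominated, tissue wells
    #: hepatocyte-dominated, MSC/myeloid mixed into both.
    domain_type_probs: dict = dc_field(default_factory=lambda: {
        "tumor": {"hepatocyte": 0.05, "MC38": 0.75, "MSC": 0.10, "myeloid": 0.10},
        "tissue": {"hepatocyte": 0.75, "MC38": 0.00, "MSC": 0.10, "myeloid": 0.15},
    })

    def validate(self) -> None:
        if self.cells_per_well <= 0 or self.n_genes <= 0:
            raise ValueError("degenerate design: no cells or genes")
        if self.geometry not in ("half_plane", "disk"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        for dom, probs in self.domain_type_probs.items():
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"type probabilities for {dom!r} must sum to 1")


@dataclass
class GroundTruth:
    """Planted truth tables aligned with the emitted matrix."""

    cells: pd.DataFrame    # cell, cell_type, well_id, species, theta
    genes: pd.DataFrame    # gene_id, species, marker_of
    wells: pd.DataFrame    # well_id, row, col, domain


def _domain_of_wells(array: WellArray, design: SimulationDesign) -> pd.Series:
    if design.geometry == "half_plane":
        domains = {w.well_id: ("tumor" if w.offset[1] < design.n_cols // 2
                               else "tissue") for w in array}
    else:
        center = array.at_axial(*hexarray.axial_from_offset(
            design.n_rows // 2, design.n_cols // 2))
        domains = {w.well_id: ("tumor" if hexarray.hex_distance(w, center)
                               <= design.disk_radius else "tissue")
                   for w in array}
    return pd.Series(domains, name="domain")


def _gene_table(design: SimulationDesign, species: str = "mouse",
                prefix: str = "mm10_") -> pd.DataFrame:
    """Gene ids, species, and marker-block assignment for the tissue sim."""
    names = [f"{prefix}g{j:04d}" for j in range(design.n_genes)]
    marker_of = np.full(design.n_genes, "", dtype=object)
    start = 0
    for prog in design.cell_types:
        stop = start + prog.n_markers
        if stop > design.n_genes:
            raise ValueError("marker blocks exceed the number of genes")
        marker_of[start:stop] = prog.name
        start = stop
    return pd.DataFrame({"gene_id": names, "species": species,
                         "marker_of": marker_of})


def _nb_counts(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    """NB2 sampling: gamma-Poisson mixture with Var = mu + alpha mu^2."""
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_tissue(design: SimulationDesign, seed: int
                    ) -> tuple[ad.AnnData, GroundTruth, WellArray]:
    """Simulate a tissue slice on the chip.

    Returns (counts AnnData with per-cell well/type annotations, planted
    truth, the well array used).  Reproducible: identical output for
    identical (design, seed).
    """
    design.validate()
    rng = np.random.default_rng(seed)
    array = hexarray.default_array(design.n_rows, design.n_cols, seed=seed)
    domains = _domain_of_wells(array, design)
    genes = _gene_table(design)

    type_names = [p.name for p in design.cell_types]
    # per-type per-gene mean with marker boosts
    base = rng.lognormal(mean=np.log(design.base_mean), sigma=0.5,
                         size=design.n_genes)
    means = {}
    for prog in design.cell_types:
        mu = base.copy()
        mu[(genes["marker_of"] == prog.name).to_numpy()] *= 2.0 ** prog.log2_fold_change
        means[prog.name] = mu / mu.sum()  # relative expression profile

    per_cell_depth_mean = design.base_mean * design.n_genes

    cells_rows = []
    count_blocks = []
    for w in array:
        dom = domains[w.well_id]
        n_cells = rng.poisson(design.cells_per_well)
        if n_cells == 0:
            continue
        probs = np.array([design.domain_type_probs[dom].get(t, 0.0)
                          for t in type_names])
        types = rng.choice(type_names, size=n_cells, p=probs / probs.sum())
        for t in types:
            depth = max(int(rng.lognormal(np.log(per_cell_depth_mean), 0.3)), 50)
            mu = means[t] * depth
            counts = _nb_counts(rng, mu, design.dispersion)
            count_blocks.append(counts)
            cells_rows.append((t, w.well_id))
    if not cells_rows:
        raise ValueError("simulation produced zero cells")

    X = sp.csr_matrix(np.vstack(count_blocks))
    obs = pd.DataFrame(cells_rows, columns=["cell_type", "well_id"])
    obs.index = [f"cell{i:05d}" for i in range(len(obs))]
    offsets = {w.well_id: w.offset for w in array}
    obs["row"] = [offsets[w][0] for w in obs["well_id"]]
    obs["col"] = [offsets[w][1] for w in obs["well_id"]]
    obs["species"] = "mouse"
    var = genes.set_index("gene_id")[["species"]]
    adata = ad.AnnData(X=X, obs=obs, var=var)
    annotate_qc(adata)

    wells_df = pd.DataFrame({
        "well_id": [w.well_id for w in array],
        "row": [w.offset[0] for w in array],
        "col": [w.offset[1] for w in array],
        "domain": [domains[w.well_id] for w in array],
    })
    truth = GroundTruth(
        cells=pd.DataFrame({"cell": obs.index, "cell_type": obs["cell_type"].values,
                            "well_id": obs["well_id"].values, "species": "mouse",
                            "theta": 0.0}),
        genes=genes, wells=wells_df)
    return adata, truth, array


def simulate_barnyard(seed: int, n_rows: int = 24, cells_per_well: float = 13.0,
                      n_genes_per_species: int = 150, base_mean: float = 2.0,
                      dispersion: float = 0.5, collision_rate: float = 0.0,
                      exact_fractions: bool = False
                      ) -> tuple[ad.AnnData, GroundTruth, WellArray]:
    """Simulate the 21-column human/mouse mixing-gradient experiment.

    Column c's cells are human with the designed gradient probability; a
    planted ``collision_rate`` fraction of barcodes are co-encapsulations
    (one human + one mouse transcriptome summed at a shared depth, the two
    cells splitting one library).  Human cells express only human genes and
    mouse cells only mouse genes, so species calls are exact absent
    collisions/contamination.  With ``exact_fractions`` each well holds
    exactly ``int(cells_per_well)`` cells at exactly the designed species
    ratio (the noiseless design realization).
    """
    rng = np.random.default_rng(seed)
    array = hexarray.default_array(n_rows, 21, seed=seed)
    design_frac = gradient_design()

    genes = pd.DataFrame({
        "gene_id": [f"hg38_g{j:04d}" for j in range(n_genes_per_species)]
                   + [f"mm10_g{j:04d}" for j in range(n_genes_per_species)],
        "species": ["human"] * n_genes_per_species + ["mouse"] * n_genes_per_species,
        "marker_of": "",
    })
    base_h = rng.lognormal(np.log(base_mean), 0.5, n_genes_per_species)
    base_m = rng.lognormal(np.log(base_mean), 0.5, n_genes_per_species)
    depth_mean = base_mean * n_genes_per_species

    def species_counts(species: str, depth: int | None = None) -> np.ndarray:
        if depth is None:
            depth = max(int(rng.lognormal(np.log(depth_mean), 0.3)), 50)
        out = np.zeros(2 * n_genes_per_species, dtype=np.int64)
        if species == "human":
            mu = base_h / base_h.sum() * depth
            out[:n_genes_per_species] = _nb_counts(rng, mu, dispersion)
        else:
            mu = base_m / base_m.sum() * depth
            out[n_genes_per_species:] = _nb_counts(rng, mu, dispersion)
        return out

    rows, blocks = [], []
    for w in array:
        col = w.offset[1]
        p_human = float(design_frac[col])
        if exact_fractions:
            n_cells = int(cells_per_well)
            n_human = round(p_human * n_cells)
            species_seq = ["human"] * n_human + ["mouse"] * (n_cells - n_human)
        else:
            n_cells = rng.poisson(cells_per_well)
            species_seq = ["human" if rng.random() < p_human else "mouse"
                           for _ in range(n_cells)]
        for species in species_seq:
            if collision_rate > 0 and rng.random() < collision_rate:
                # a co-encapsulated pair splits one library's depth
                depth = max(int(rng.lognormal(np.log(depth_mean), 0.3)), 100)
                blocks.append(species_counts("human", depth // 2)
                              + species_counts("mouse", depth - depth // 2))
                rows.append(("collision", w.well_id, col))
            else:
                blocks.append(species_counts(species))
                rows.append((species, w.well_id, col))
    X = sp.csr_matrix(np.vstack(blocks))
    obs = pd.DataFrame(rows, columns=["true_species", "well_id", "col"])
    obs.index = [f"cell{i:05d}" for i in range(len(obs))]
    var = genes.set_index("gene_id")[["species"]]
    adata = ad.AnnData(X=X, obs=obs, var=var)
    annotate_qc(adata)
    wells_df = pd.DataFrame({
        "well_id": [w.well_id for w in array],
        "row": [w.offset[0] for w in array],
        "col": [w.offset[1] for w in array],
        "domain": "",
    })
    truth = GroundTruth(
        cells=pd.DataFrame({"cell": obs.index,
                            "cell_type": obs["true_species"].values,
                            "well_id": obs["well_id"].values,
                            "species": obs["true_species"].values,
                            "theta": 0.0}),
        genes=genes, wells=wells_df)
    return adata, truth, array


def inject_ambient(adata: ad.AnnData, alpha: float, beta: float, seed: int,
                   group_key: str = "true_species"
                   ) -> tuple[ad.AnnData, pd.Series]:
    """Plant beta-distributed ambient contamination into a count matrix.

    Per cell, theta ~ Beta(alpha, beta); a Binomial(total, theta) number of
    its molecules (drawn without replacement across genes) are replaced by
    draws from the pooled profile of the *other* populations, so per-cell
    totals are preserved.  Returns (contaminated matrix, planted theta).
    """
    rng = np.random.default_rng(seed)
    X = sp.csr_matrix(adata.X).astype(np.int64).toarray()
    groups = adata.obs[group_key].to_numpy()
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need >= 2 populations to define an ambient pool")
    totals_by_group = {g: X[groups == g].sum(axis=0) for g in labels}
    grand = sum(totals_by_group.values())
    theta = rng.beta(alpha, beta, size=adata.n_obs) if alpha > 0 else np.zeros(adata.n_obs)
    out = X.copy()
    for i in range(adata.n_obs):
        total = int(X[i].sum())
        if total == 0:
            continue
        n_move = rng.binomial(total, theta[i])
        if n_move == 0:
            continue
        removed = rng.multivariate_hypergeometric(X[i], n_move)
        pool = grand - totals_by_group[groups[i]]
        p = pool / pool.sum()
        added = rng.multinomial(n_move, p)
        out[i] = X[i] - removed + added
    new = adata.copy()
    new.X = sp.csr_matrix(out)
    annotate_qc(new)
    theta_s = pd.Series(theta, index=adata.obs_names, name="theta_true")
    new.obs["theta_true"] = theta
    return new, theta_s


def gene_codebook(gene_ids) -> dict[str, str]:
    """Deterministic nucleotide tag per gene for the synthetic read-2 path.

    Gene index encoded base-4 over a fixed 16-nt tag; decoding is exact
    lookup (sequencing errors are applied to read 1 only).
    """
    tags = {}
    for idx, gid in enumerate(gene_ids):
        digits = []
        v = idx
        for _ in range(GENE_TAG_LENGTH):
            digits.append(v % 4)
            v //= 4
        tags["".join(_BASES[d] for d in reversed(digits))] = gid
    return tags


def _random_distinct_kmers(rng: np.random.Generator, n: int, k: int) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        kmer = "".join(_BASES[rng.integers(0, 4, size=k)])
        if kmer not in seen:
            seen.add(kmer)
            out.append(kmer)
    return out


def _mutate(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < error_rate)[0]
    for pos in hits:
        choices = [b for b in b"ACGT" if b != arr[pos]]
        arr[pos] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def assign_pcr_indices(adata: ad.AnnData, pcr_whitelist, seed: int) -> None:
    """Give each cell a PCR index, distinct within its well (obs['pcr_index']).

    Requires the plate to hold at least as many indices as the fullest well;
    this makes (spatial barcode, PCR index) a bijection onto cells, the
    collision-free regime.
    """
    rng = np.random.default_rng(seed)
    whitelist = list(pcr_whitelist)
    out = np.empty(adata.n_obs, dtype=object)
    for _, idx in adata.obs.groupby("well_id", observed=True).groups.items():
        pos = adata.obs.index.get_indexer(idx)
        if len(pos) > len(whitelist):
            raise ValueError("PCR plate smaller than the fullest well")
        chosen = rng.choice(len(whitelist), size=len(pos), replace=False)
        out[pos] = [whitelist[c] for c in chosen]
    adata.obs["pcr_index"] = out


def emit_fastq(adata: ad.AnnData, array: WellArray, outdir, seed: int,
               error_rate: float = 0.0, mean_reads_per_umi: float = 2.0,
               library_index: str = "ACGTACGT", gzip_output: bool = True
               ) -> dict[str, Path]:
    """Write synthetic FASTQ (R1/R2/I1/I2) realizing the count matrix.

    Per molecule: a UMI distinct within its (cell, gene), read 1 = UMI +
    spatial barcode (26 cycles) with optional per-base substitution errors,
    read 2 = the gene's synthetic tag padded to 98 cycles, index reads = the
    library and PCR indices.  Reads per molecule are geometric with mean
    ``mean_reads_per_umi`` (PCR duplication; drives reported saturation).
    Requires obs['pcr_index'] (see :func:`assign_pcr_indices`).
    """
    if "pcr_index" not in adata.obs:
        raise ValueError("cells need PCR indices; run assign_pcr_indices first")
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    suffix = ".fastq.gz" if gzip_output else ".fastq"
    paths = {name: outdir / f"{name}{suffix}" for name in ("R1", "R2", "I1", "I2")}
    opener = gzip.open if gzip_output else open

    codebook = gene_codebook(adata.var_names)
    tag_of = {gid: tag for tag, gid in codebook.items()}
    barcode_of = {w.well_id: w.spatial_barcode for w in array}
    X = sp.coo_matrix(adata.X)
    p_dup = 1.0 / max(mean_reads_per_umi, 1.0)

    handles = {name: opener(path, "wt") for name, path in paths.items()}
    try:
        read_no = 0
        for i, j, count in zip(X.row, X.col, X.data):
            cell = adata.obs.index[i]
            bc = barcode_of[adata.obs["well_id"].iloc[i]]
            pcr = adata.obs["pcr_index"].iloc[i]
            tag = tag_of[adata.var_names[j]]
            r2 = tag + "A" * (R2_LENGTH - len(tag))
            umis = _random_distinct_kmers(rng, int(count), 10)
            for umi in umis:
                n_reads = rng.geometric(p_dup)
                for _ in range(n_reads):
                    read_no += 1
                    rid = f"read{read_no:09d}"
                    r1 = _mutate(rng, umi + bc, error_rate)
                    for name, seq in (("R1", r1), ("R2", r2),
                                      ("I1", library_index), ("I2", pcr)):
                        handles[name].write(
                            f"@{rid} {name}\n{seq}\n+\n{'I' * len(seq)}\n")
    finally:
        for h in handles.values():
            h.close()
    assert READ1_LENGTH == 26
    return paths
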