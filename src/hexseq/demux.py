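"""Demultiplexing gene-tagged reads into a spatially annotated count matrix.

Library structure (read 1, 26 cycles): a 10-nt unique molecular identifier
(UMI) followed by the 16-nt spatial barcode of the microwell where reverse
transcription happened.  The second combinatorial index is the i5 PCR-plate
well index.  A cell is keyed by the pair (spatial barcode, PCR index); with a
full chip of 768 spatial barcodes and 384 PCR indices the design addresses
768 x 384 = 294,912 distinct cell barcodes.

Alignment and gene assignment happen upstream; this module consumes
gene-tagged reads (read id, read-1 sequence, PCR index, gene id) either from
a TSV or from synthetic FASTQ via a gene-tag codebook, corrects barcodes at
Hamming distance <= 1 against the well map, deduplicates UMIs exactly within
(cell, gene), and emits an :class:`anndata.AnnData` counts matrix with per-cell
spatial metadata plus a demultiplexing report.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .hexarray import WellArray

logger = logging.getLogger(__name__)

__all__ = [
    "ReadRecord",
    "DemuxReport",
    "parse_read1",
    "correct_barcode",
    "build_hamming1_index",
    "build_matrix",
    "annotate_qc",
    "filter_cells",
    "read_tagged_tsv",
    "reads_from_fastq",
    "write_counts",
    "read_counts",
]

UMI_LENGTH = 10
BARCODE_LENGTH = 16
READ1_LENGTH = UMI_LENGTH + BARCODE_LENGTH  # 26 cycles

# gene-id namespaces of the joint human/mouse reference
DEFAULT_SPECIES_PREFIXES = {"human": "hg38_", "mouse": "mm10_"}
DEFAULT_MITO_PREFIXES = ("mt-", "MT-")


@dataclass(frozen=True)
class ReadRecord:
    """One gene-tagged read: raw read-1 sequence plus upstream annotations."""

    read_id: str
    read1_seq: str
    pcr_index: str
    gene_id: str | None  # None = unassigned by the aligner


@dataclass
class DemuxReport:
    """Tallies of read fate during demultiplexing."""

    reads_in: int = 0
    too_short: int = 0
    barcode_exact: int = 0
    barcode_corrected: int = 0
    barcode_discarded: int = 0
    pcr_discarded: int = 0
    unassigned_gene: int = 0
    reads_used: int = 0
    umis: int = 0

    @property
    def saturation(self) -> float:
        """Sequencing saturation, 1 - UMIs/reads (reads that made it to dedup)."""
        return 1.0 - self.umis / self.reads_used if self.reads_used else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("reads_in", self.reads_in),
            ("too_short", self.too_short),
            ("barcode_exact", self.barcode_exact),
            ("barcode_corrected", self.barcode_corrected),
            ("barcode_discarded", self.barcode_discarded),
            ("pcr_discarded", self.pcr_discarded),
            ("unassigned_gene", self.unassigned_gene),
            ("reads_used", self.reads_used),
            ("umis", self.umis),
            ("saturation", round(self.saturation, 6)),
        ]
        return pd.DataFrame(rows, columns=["metric", "value"])


def parse_read1(seq: str) -> tuple[str, str] | None:
    """Split a read-1 sequence into (UMI, spatial barcode).

    Positions 1-10 are the UMI, 11-26 the spatial barcode; any trailing cycles
    are ignored.  Returns ``None`` for reads shorter than 26 nt (callers tally
    these as skipped).
    """
    if len(seq) < READ1_LENGTH:
        return None
    return seq[:UMI_LENGTH], seq[UMI_LENGTH:READ1_LENGTH]


def build_hamming1_index(whitelist: set[str]) -> dict[str, str | None]:
    """Map every sequence within Hamming distance 1 of the whitelist to its
    unique whitelist entry, or to ``None`` where two entries tie.

    Exact whitelist members always map to themselves (a whitelist with
    pairwise distance >= 2 is assumed; the well-map loader checks >= 3).
    """
    index: dict[str, str | None] = {}
    for bc in whitelist:
        for pos in range(len(bc)):
            for base in "ACGT":
                if base == bc[pos]:
                    continue
                mut = bc[:pos] + base + bc[pos + 1:]
                index[mut] = None if mut in index else bc
    for bc in whitelist:  # exact hits win over being a neighbour of another
        index[bc] = bc
    return index


def correct_barcode(observed: str, whitelist: set[str], max_hamming: int = 1,
                    _index: dict[str, str | None] | None = None) -> str | None:
    """Correct an observed barcode against a whitelist.

    Returns the unique whitelist entry within ``max_hamming`` substitutions,
    or ``None`` when no entry (or more than one equidistant entry) qualifies.
    """
    if observed in whitelist:
        return observed
    if max_hamming == 0:
        return None
    if max_hamming == 1:
        index = _index if _index is not None else build_hamming1_index(whitelist)
        return index.get(observed)
    best, best_d, ties = None, max_hamming + 1, 0
    for bc in whitelist:
        if len(bc) != len(observed):
            continue
        d = sum(a != b for a, b in zip(observed, bc))
        if d < best_d:
            best, best_d, ties = bc, d, 1
        elif d == best_d:
            ties += 1
    return best if best_d <= max_hamming and ties == 1 else None


def build_matrix(records, well_map: WellArray, pcr_whitelist,
                 max_hamming: int = 1) -> tuple[ad.AnnData, DemuxReport]:
    """Demultiplex a stream of :class:`ReadRecord` into a cell x gene matrix.

    One count per distinct (cell, gene, UMI) triple; cells are keyed by
    (spatial barcode, PCR index) and carry the well id resolved from the
    spatial barcode.  Reads failing barcode or PCR-index correction are
    discarded and tallied in the report.
    """
    if well_map.min_pairwise_barcode_distance() < 3 and max_hamming >= 1:
        logger.warning("well-map barcodes closer than Hamming 3; "
                       "distance-1 correction may be ambiguous")
    pcr_whitelist = set(pcr_whitelist)
    bc_index = build_hamming1_index(well_map.whitelist()) if max_hamming == 1 else None
    pcr_index_map = build_hamming1_index(pcr_whitelist) if max_hamming == 1 else None

    report = DemuxReport()
    molecules: set[tuple[str, str, str, str]] = set()  # (bc, pcr, gene, umi)
    for rec in records:
        report.reads_in += 1
        parsed = parse_read1(rec.read1_seq)
        if parsed is None:
            report.too_short += 1
            continue
        umi, bc_obs = parsed
        if bc_obs in well_map.barcode_index:
            bc = bc_obs
            report.barcode_exact += 1
        else:
            bc = correct_barcode(bc_obs, well_map.whitelist(), max_hamming,
                                 _index=bc_index)
            if bc is None:
                report.barcode_discarded += 1
                continue
            report.barcode_corrected += 1
        pcr = correct_barcode(rec.pcr_index, pcr_whitelist, max_hamming,
                              _index=pcr_index_map)
        if pcr is None:
            report.pcr_discarded += 1
            continue
        if rec.gene_id is None:
            report.unassigned_gene += 1
            continue
        report.reads_used += 1
        molecules.add((bc, pcr, rec.gene_id, umi))

    report.umis = len(molecules)

    cells = sorted({(bc, pcr) for bc, pcr, _, _ in molecules})
    genes = sorted({g for _, _, g, _ in molecules})
    cell_idx = {c: i for i, c in enumerate(cells)}
    gene_idx = {g: j for j, g in enumerate(genes)}
    counts = sp.dok_matrix((len(cells), len(genes)), dtype=np.int64)
    for bc, pcr, g, _umi in molecules:
        counts[cell_idx[(bc, pcr)], gene_idx[g]] += 1

    obs = pd.DataFrame({
        "spatial_barcode": [bc for bc, _ in cells],
        "pcr_index": [pcr for _, pcr in cells],
        "well_id": [well_map.barcode_index[bc].well_id for bc, _ in cells],
    }, index=[f"{bc}+{pcr}" for bc, pcr in cells])
    var = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    adata = ad.AnnData(X=counts.tocsr(), obs=obs, var=var)
    annotate_qc(adata)
    return adata, report


def gene_species(gene_ids, prefixes: dict[str, str] | None = None) -> pd.Series:
    """Species of each gene from its id-namespace prefix ('other' if neither)."""
    prefixes = prefixes or DEFAULT_SPECIES_PREFIXES
    out = pd.Series("other", index=pd.Index(gene_ids), dtype=object)
    for species, pref in prefixes.items():
        out[out.index.str.startswith(pref)] = species
    return out


def annotate_qc(adata: ad.AnnData,
                species_prefixes: dict[str, str] | None = None,
                mito_prefixes=DEFAULT_MITO_PREFIXES) -> ad.AnnData:
    """Fill per-gene species and per-cell QC columns in place.

    Adds var['species'] (namespace prefix), var['mito'] (gene name after the
    namespace starts with a mitochondrial prefix), and obs total_umis,
    n_genes, mito_frac, human_umis, mouse_umis.
    """
    species_prefixes = species_prefixes or DEFAULT_SPECIES_PREFIXES
    adata.var["species"] = gene_species(adata.var_names, species_prefixes).values
    stripped = pd.Series(adata.var_names, index=adata.var_names, dtype=object)
    for pref in species_prefixes.values():
        mask = stripped.index.str.startswith(pref)
        stripped[mask] = stripped[mask].str.slice(len(pref))
    adata.var["mito"] = np.array(
        [any(name.startswith(p) for p in mito_prefixes) for name in stripped])

    X = sp.csr_matrix(adata.X)
    totals = np.asarray(X.sum(axis=1)).ravel()
    adata.obs["total_umis"] = totals.astype(np.int64)
    adata.obs["n_genes"] = np.asarray((X > 0).sum(axis=1)).ravel().astype(np.int64)
    mito_counts = np.asarray(X[:, adata.var["mito"].values].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        adata.obs["mito_frac"] = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
    for species in ("human", "mouse"):
        mask = (adata.var["species"] == species).values
        adata.obs[f"{species}_umis"] = np.asarray(
            X[:, mask].sum(axis=1)).ravel().astype(np.int64)
    return adata


def filter_cells(adata: ad.AnnData, umi_min: int = 500, umi_max: int = 10_000,
                 gene_min: int = 100, gene_max: int = 15_000,
                 mito_max: float = 0.01) -> ad.AnnData:
    """Apply cell-level QC: UMI bounds, detected-gene bounds, mitochondrial cap.

    Defaults follow the microwell assay's processing (500-10,000 UMIs,
    100-15,000 genes, <=1% mitochondrial); bounds are inclusive.  Pass the
    droplet-platform values for 10x-style data.
    """
    if not {"total_umis", "n_genes", "mito_frac"}.issubset(adata.obs.columns):
        annotate_qc(adata)
    obs = adata.obs
    keep = ((obs["total_umis"] >= umi_min) & (obs["total_umis"] <= umi_max)
            & (obs["n_genes"] >= gene_min) & (obs["n_genes"] <= gene_max)
            & (obs["mito_frac"] <= mito_max))
    if not keep.any():
        logger.warning("filter_cells removed every cell")
    return adata[keep.values].copy()


# ---------------------------------------------------------------------------
# ingest paths


def read_tagged_tsv(path) -> list[ReadRecord]:
    """Read gene-tagged reads from a TSV: read_id, read1_seq, pcr_index, gene_id.

    An empty or 'NA' gene_id marks an unassigned read.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["read_id", "read1_seq", "pcr_index", "gene_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"tagged-read TSV missing columns: {missing}")
    return [
        ReadRecord(r.read_id, r.read1_seq, r.pcr_index,
                   None if r.gene_id in ("", "NA") else r.gene_id)
        for r in df.itertuples(index=False)
    ]


def _open_maybe_gz(path):
    path = Path(path)
    return gzip.open(path, "rt") if path.suffix == ".gz" else open(path)


def _iter_fastq(path):
    with _open_maybe_gz(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            yield header.strip().lstrip("@").split()[0], seq


def reads_from_fastq(r1_path, r2_path, i2_path, gene_codebook: dict[str, str],
                     tag_length: int | None = None) -> list[ReadRecord]:
    """Pair synthetic FASTQ files into :class:`ReadRecord` objects.

    ``gene_codebook`` maps the nucleotide tag carried at the start of read 2
    (the synthetic stand-in for alignment) back to a gene id; tags that do not
    decode leave the read unassigned.  The i2 read is the PCR well index.
    """
    if tag_length is None:
        tag_length = len(next(iter(gene_codebook)))
    records = []
    for (rid1, s1), (rid2, s2), (ridi, si) in zip(
            _iter_fastq(r1_path), _iter_fastq(r2_path), _iter_fastq(i2_path)):
        if not (rid1 == rid2 == ridi):
            raise ValueError(f"FASTQ read ids out of sync: {rid1}/{rid2}/{ridi}")
        gene = gene_codebook.get(s2[:tag_length])
        records.append(ReadRecord(rid1, s1, si, gene))
    return records


# ---------------------------------------------------------------------------
# Matrix Market + TSV sidecar I/O


def write_counts(adata: ad.AnnData, outdir) -> None:
    """Write counts as matrix.mtx with barcodes.tsv / features.tsv sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), sp.coo_matrix(adata.X))
    obs = adata.obs.reset_index(names="cell")
    obs.to_csv(outdir / "barcodes.tsv", sep="\t", index=False)
    var = adata.var.reset_index(names="gene_id")
    var.to_csv(outdir / "features.tsv", sep="\t", index=False)


def read_counts(outdir) -> ad.AnnData:
    """Read a matrix written by :func:`write_counts`."""
    outdir = Path(outdir)
    X = sp.csr_matrix(scipy.io.mmread(str(outdir / "matrix.mtx")))
    obs = pd.read_csv(outdir / "barcodes.tsv", sep="\t", dtype={"cell": str})
    obs = obs.set_index("cell")
    obs.index.name = None
    var = pd.read_csv(outdir / "features.tsv", sep="\t", dtype={"gene_id": str})
    var = var.set_index("gene_id")
    return ad.AnnData(X=X, obs=obs, var=var)
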