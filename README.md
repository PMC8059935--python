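# hexseq

Analysis toolkit for **spatially barcoded microwell combinatorial-indexing
scRNA-seq** — assays in which a fixed tissue slice is sealed onto a hexagonal
array of microwells (500 µm pitch), each well's reverse-transcription primer
carries a distinct 16-nt spatial barcode, and a second round of PCR-plate
indexing turns (spatial barcode, PCR index) pairs into single-cell barcodes.
With 768 spatial and 384 PCR barcodes the design addresses 294,912 cells
while recording every cell's well of origin.

It is written for computational biologists processing such libraries (or
building on their outputs) and covers everything after alignment:

- **demux** — read-1 parsing (10-nt UMI + 16-nt spatial barcode), Hamming-1
  barcode correction, exact UMI deduplication, cell QC filters
  (500–10,000 UMIs, 100–15,000 genes, ≤1% mitochondrial), Matrix Market +
  TSV output, demultiplexing report with sequencing saturation.
- **species_qc** — barnyard (human/mouse) quality control: a cell is called
  for a species when ≥66% of its UMIs map to it, otherwise it is a barcode
  collision; collision rate; Lin's concordance correlation coefficient
  CCC = 2·cov(x,y) / (σ²ₓ + σ²ᵧ + (μₓ − μᵧ)²) against the 21-column,
  11-ratio species mixing gradient.
- **decontam** — ambient-RNA removal. Counts of cell *c* in cluster *k* are
  modeled as a mixture: each transcript comes from the cluster's native
  expression distribution φₖ with probability 1 − θ꜀ or from a contamination
  distribution ηₖ (aggregated from the other clusters) with probability θ꜀,
  with θ꜀ ~ Beta(α, β). Fitted by EM; corrected counts are the posterior
  expected native component.
- **spatial** — per-well cell-type composition, colocalization (Pearson r
  across wells), and the tumor-proximity score: with p_w the tumor fraction
  among tumor + reference cells in well w and p_{w,l} its cell-weighted mean
  over the l-th concentric hexagonal layer,
  s_w = [u₁ p_w + Σ_{l=1..10} u_l p_{w,l}] / (u₁ + Σ u_l),
  u_l ∝ d^{−l}, d = 1.05 — plus a seeded linear variant
  s = max(0, 1 − l/10) from manually chosen seed wells.
- **modules_nmf** — rank-20 NMF gene modules by seeded multiplicative
  updates, top-contributing-gene selection (longest strictly dominating
  prefix), cross-tissue module matching (top-200 overlap, ≥25% kept),
  per-module cell-type fractions, and well-level high/low projection.
- **spatial_de** — genes whose expression in a chosen cell type tracks the
  continuous proximity score: NB GLM on a cubic B-spline basis of the score
  with a log library-size offset, Wald test on the joint spline
  coefficients, Benjamini-Hochberg correction, and intratumor / boundary /
  intratissue classification by fitted-curve peak.
- **simulate** — ground-truthed generators for every stage: tissue-on-array
  count matrices, the species mixing gradient, beta-distributed ambient
  contamination, and raw FASTQ for demultiplexing round trips.

## Worked example

```python
import numpy as np
from hexseq import decontam, demux, simulate, species_qc

# mixing-gradient run with planted ambient contamination
adata, truth, array = simulate.simulate_barnyard(seed=0, n_rows=12,
                                                 cells_per_well=10)
adata, theta_true = simulate.inject_ambient(adata, alpha=2, beta=8, seed=1,
                                            group_key="true_species")
species_qc.annotate_species_calls(adata)
before = species_qc.collision_rate(adata.obs["species_call"])
print(f"cells: {adata.n_obs}, collision rate before decontamination: {before:.3f}")

majority = np.where(adata.obs["human_umis"] >= adata.obs["mouse_umis"],
                    "human", "mouse")
model = decontam.fit(adata, majority)
print(f"median estimated contamination: {model.theta.median():.3f} "
      f"(planted median {theta_true.median():.3f})")

clean = decontam.decontaminate(adata, model)
demux.annotate_qc(clean)
species_qc.annotate_species_calls(clean)
after = species_qc.collision_rate(clean.obs["species_call"])
print(f"collision rate after decontamination: {after:.3f}")

table, ccc = species_qc.gradient_concordance(clean, species_qc.gradient_design())
print(f"column-gradient concordance (Lin's CCC): {ccc:.3f}")
```

Output:

```
cells: 2593, collision rate before decontamination: 0.142
median estimated contamination: 0.180 (planted median 0.178)
collision rate after decontamination: 0.000
column-gradient concordance (Lin's CCC): 0.994
```

The planted 18% ambient contamination makes 14% of barcodes look like
cross-species collisions; the EM recovers the contamination proportion
almost exactly, and after subtracting the expected contamination the
collision rate collapses and the observed per-column species proportions
agree with the printed gradient design.

## Command line

The same stages are exposed as a CLI (`hexseq simulate | demux | qc |
decontam | spatial | modules | de | pipeline`); every run writes a resolved
config, a run log, and a checksummed artifact manifest:

```sh
hexseq pipeline --seed 3 --out runs/demo
```

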