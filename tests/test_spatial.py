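"""Well composition, colocalization, and proximity scores."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from hexseq import hexarray, spatial
from hexseq.spatial import (WellComposition, cell_scores, colocalization,
                            decay_weights, seeded_score, tumor_proximity,
                            well_composition)


def _cells(well_types):
    """AnnData with one row per (well, type) pair in the list."""
    obs = pd.DataFrame(well_types, columns=["well_id", "cell_type"])
    obs.index = [f"c{i}" for i in range(len(obs))]
    X = sp.csr_matrix((len(obs), 1), dtype=np.int64)
    return ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=["g"]))


def _uniform_comp(array, tumor_cols, cells=10):
    rows = []
    for w in array:
        col = w.offset[1]
        mc = cells if col in tumor_cols else 0
        rows.append((w.well_id, cells - mc, mc))
    df = pd.DataFrame(rows, columns=["well_id", "hepatocyte", "MC38"])
    return WellComposition(df.set_index("well_id"))


class TestWellComposition:
    def test_tallies(self, small_array):
        w0 = list(small_array)[0].well_id
        adata = _cells([(w0, "hepatocyte"), (w0, "hepatocyte"), (w0, "MC38")])
        comp = well_composition(adata, array=small_array)
        assert comp.counts.loc[w0, "hepatocyte"] == 2
        assert comp.counts.loc[w0, "MC38"] == 1
        t = comp.counts.loc[w0, ["hepatocyte", "MC38"]].sum()
        assert comp.counts.loc[w0, "MC38"] / t == pytest.approx(1 / 3)

    def test_empty_wells_present_as_zero(self, small_array):
        w0 = list(small_array)[0].well_id
        adata = _cells([(w0, "MC38")])
        comp = well_composition(adata, array=small_array)
        assert len(comp.counts) == len(small_array)
        assert comp.counts.drop(index=w0).to_numpy().sum() == 0

    def test_totals_conserved(self, small_tissue):
        adata, _, array = small_tissue
        comp = well_composition(adata, array=array)
        assert comp.counts.to_numpy().sum() == adata.n_obs

    def test_unknown_well_errors(self, small_array):
        adata = _cells([("nope", "MC38")])
        with pytest.raises(ValueError):
            well_composition(adata, array=small_array)


class TestColocalization:
    def test_identical_counts_r_one(self, small_array):
        rows = [(w.well_id, i % 4, i % 4) for i, w in enumerate(small_array)]
        comp = WellComposition(pd.DataFrame(
            rows, columns=["well_id", "A", "B"]).set_index("well_id"))
        r, p = colocalization(comp, "A", "B")
        assert r == pytest.approx(1.0)

    def test_hand_computed_four_wells(self):
        comp = WellComposition(pd.DataFrame(
            {"A": [1, 2, 3, 4], "B": [2, 1, 4, 3]},
            index=["w1", "w2", "w3", "w4"]))
        r, _ = colocalization(comp, "A", "B")
        # direct formula: cov = 1.0, sd_A = sd_B = sqrt(5/3) (sample moments)
        assert r == pytest.approx(0.6)

    def test_zero_variance_flagged(self):
        comp = WellComposition(pd.DataFrame(
            {"A": [1, 1, 1], "B": [1, 2, 3]}, index=["w1", "w2", "w3"]))
        r, p = colocalization(comp, "A", "B")
        assert np.isnan(r) and np.isnan(p)

    def test_planted_colocalization_positive(self, rng):
        shared = rng.poisson(5, 60)
        comp = WellComposition(pd.DataFrame(
            {"A": shared + rng.poisson(1, 60), "B": shared + rng.poisson(1, 60)},
            index=[f"w{i}" for i in range(60)]))
        r, p = colocalization(comp, "A", "B")
        assert r > 0.5 and p < 0.01


class TestDecayWeights:
    def test_weights_sum_to_one(self):
        assert decay_weights(1.05, 10).u.sum() == pytest.approx(1.0)

    def test_weight_ratio_closed_form(self):
        w = decay_weights(1.05, 10).u
        assert w[0] / w[9] == pytest.approx(1.05 ** 9)

    def test_uniform_limit(self):
        assert np.allclose(decay_weights(1.0, 10).u, 0.1)

    def test_monotone_decreasing(self):
        u = decay_weights(1.05, 10).u
        assert np.all(np.diff(u) < 0)

    def test_invalid_decay(self):
        with pytest.raises(ValueError):
            decay_weights(0.0, 10)


class TestTumorProximity:
    def test_all_tumor_scores_one(self, small_array):
        comp = _uniform_comp(small_array, tumor_cols=set(range(8)))
        field = tumor_proximity(comp, small_array)
        assert np.allclose(field.scores.to_numpy(), 1.0)

    def test_all_reference_scores_zero(self, small_array):
        comp = _uniform_comp(small_array, tumor_cols=set())
        field = tumor_proximity(comp, small_array)
        assert np.allclose(field.scores.to_numpy(), 0.0)

    def test_uniform_composition_invariance(self, small_array):
        """If every well has tumor fraction c, the score is c everywhere."""
        rows = [(w.well_id, 7, 3) for w in small_array]
        comp = WellComposition(pd.DataFrame(
            rows, columns=["well_id", "hepatocyte", "MC38"]).set_index("well_id"))
        field = tumor_proximity(comp, small_array)
        assert np.allclose(field.scores.to_numpy(), 0.3)

    def test_half_plane_boundary_near_half_and_monotone(self):
        array = hexarray.default_array(12, 16, seed=2)
        comp = _uniform_comp(array, tumor_cols=set(range(8)))
        field = tumor_proximity(comp, array)
        pair_means = [(field.scores[f"W{r}_7"] + field.scores[f"W{r}_8"]) / 2
                      for r in range(12)]
        assert abs(np.mean(pair_means) - 0.5) < 0.1
        for r in range(12):
            row = [field.scores[f"W{r}_{c}"] for c in range(16)]
            assert all(a >= b - 1e-12 for a, b in zip(row, row[1:]))

    def test_label_swap_reflects_score(self, small_array):
        comp = _uniform_comp(small_array, tumor_cols=set(range(4)))
        field = tumor_proximity(comp, small_array)
        swapped = tumor_proximity(comp, small_array, tumor_label="hepatocyte",
                                  ref_label="MC38")
        assert np.allclose(field.scores.to_numpy(),
                           1.0 - swapped.scores.to_numpy())

    def test_orientation_flag_mirrors(self, small_array):
        comp = _uniform_comp(small_array, tumor_cols=set(range(4)))
        tum = tumor_proximity(comp, small_array, orientation="tumor")
        ref = tumor_proximity(comp, small_array, orientation="reference")
        assert np.allclose(tum.scores.to_numpy(), 1.0 - ref.scores.to_numpy())

    def test_empty_wells_unscored(self, small_array):
        rows = [(w.well_id, 5, 5) for w in list(small_array)[:10]]
        comp = WellComposition(
            pd.DataFrame(rows, columns=["well_id", "hepatocyte", "MC38"])
            .set_index("well_id").reindex([w.well_id for w in small_array],
                                          fill_value=0))
        field = tumor_proximity(comp, small_array)
        assert field.scores.notna().sum() == 10


class TestSeededScore:
    def test_linear_rule(self, grid12):
        seed = grid12.well("W6_6")
        field = seeded_score(grid12, [seed])
        assert field.scores[seed.well_id] == 1.0
        for w in grid12:
            l = hexarray.hex_distance(seed, w)
            expected = max(0.0, 1.0 - l / 10)
            assert field.scores[w.well_id] == pytest.approx(expected)

    def test_matches_bfs_brute_force(self, grid12):
        from _oracles import bfs_distances
        seeds = [grid12.well("W0_0"), grid12.well("W11_11")]
        field = seeded_score(grid12, seeds)
        dmaps = [bfs_distances(grid12, s) for s in seeds]
        for w in grid12:
            l = min(d[(w.q, w.r)] for d in dmaps)
            assert field.scores[w.well_id] == pytest.approx(max(0.0, 1 - l / 10))

    def test_empty_seed_set_errors(self, grid12):
        with pytest.raises(ValueError):
            seeded_score(grid12, [])


class TestCellScores:
    def test_cells_inherit_well_score(self, small_array):
        w0 = list(small_array)[0]
        adata = _cells([(w0.well_id, "MSC")] * 3)
        field = seeded_score(small_array, [w0])
        scores = cell_scores(field, adata)
        assert np.allclose(scores.to_numpy(), 1.0)

    def test_distribution_identity(self, small_tissue):
        """Cell-score histogram equals the well histogram weighted by
        cells per well."""
        adata, _, array = small_tissue
        comp = well_composition(adata, array=array)
        field = tumor_proximity(comp, array)
        per_cell = cell_scores(field, adata)
        wells = adata.obs["well_id"].value_counts()
        expect = sum(field.scores[w] * n for w, n in wells.items()
                     if not np.isnan(field.scores[w]))
        got = per_cell.dropna().sum()
        assert got == pytest.approx(expect)
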