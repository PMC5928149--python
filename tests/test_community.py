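"""Community statistics: filtering, rarefaction, Chao1, Bray-Curtis,
ordination, PERMANOVA (cross-checked against vegan's adonis2) and
isolate fold changes."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from coocnet.community import (bray_curtis, chao1, diversity_report,
                               filter_low_read_otus, fold_change, pcoa,
                               permanova, rarefy, recolonization_dose)
from coocnet.otu_table import OtuTable
from coocnet.synthetic import BasisSpec, simulate_counts, spike_isolate


def _table(counts, metadata=None):
    counts = np.asarray(counts)
    return OtuTable(counts,
                    [f"OTU{i}" for i in range(counts.shape[1])],
                    [f"S{i}" for i in range(counts.shape[0])],
                    metadata=metadata)


class TestFilter:
    def test_total_read_cutoff_is_strict(self):
        # totals per OTU: 10, 49, 50, 500, 0 -> two survive
        counts = np.array([[10, 24, 25, 250, 0],
                           [0, 25, 25, 250, 0]])
        out = filter_low_read_otus(_table(counts), min_reads=50)
        assert out.otu_ids == ["OTU2", "OTU3"]
        assert out.counts.shape == (2, 2)

    def test_zero_cutoff_is_identity(self):
        counts = np.array([[1, 2], [3, 4]])
        out = filter_low_read_otus(_table(counts), min_reads=0)
        assert np.array_equal(out.counts, counts)

    def test_everything_removed_is_an_error(self):
        with pytest.raises(ValueError, match="every OTU"):
            filter_low_read_otus(_table(np.array([[1, 1], [1, 1]])),
                                 min_reads=1000)


class TestRarefy:
    def test_exact_depth_sample_unchanged(self):
        counts = np.array([[600, 400], [90, 20]])
        with pytest.warns(UserWarning):
            out = rarefy(_table(counts), depth=1000, seed=1)
        assert out.sample_ids == ["S0"]
        assert np.array_equal(out.counts, [[600, 400]])

    def test_below_depth_dropped_with_warning(self):
        counts = np.array([[9999, 0], [6000, 5000]])
        with pytest.warns(UserWarning, match="below depth"):
            out = rarefy(_table(counts), depth=10_000, seed=2)
        assert out.sample_ids == ["S1"]
        assert out.counts.sum() == 10_000

    def test_hypergeometric_moments(self):
        # 1M reads, one OTU at 50%: rarefied count ~ 5000 +- ~50
        counts = np.array([[500_000, 300_000, 200_000]] * 2)
        out = rarefy(_table(counts), depth=10_000, seed=3)
        sd = np.sqrt(10_000 * 0.5 * 0.5)   # binomial upper bound on sd
        assert abs(out.counts[0, 0] - 5000) < 5 * sd

    def test_expected_proportions_preserved(self):
        counts = np.array([[120, 60, 20, 0]])
        reps = []
        for s in range(200):
            out = rarefy(_table(counts), depth=50, seed=s)
            reps.append(out.counts[0])
        mean = np.mean(reps, axis=0)
        expected = 50 * counts[0] / counts.sum()
        assert np.allclose(mean, expected, atol=1.0)

    def test_determinism(self):
        counts = np.array([[300, 300, 400], [500, 100, 400]])
        a = rarefy(_table(counts), depth=100, seed=11)
        b = rarefy(_table(counts), depth=100, seed=11)
        assert np.array_equal(a.counts, b.counts)


class TestChao1:
    def test_no_singletons_equals_observed_richness(self):
        assert chao1(np.array([5, 3, 2, 7])) == 4.0

    def test_hand_computed_bias_corrected_value(self):
        # S_obs = 10, F1 = 4, F2 = 2 -> 10 + 4*3 / (2*3) = 12
        counts = np.array([1, 1, 1, 1, 2, 2, 3, 4, 5, 6])
        assert chao1(counts) == pytest.approx(12.0)

    def test_all_counts_at_least_three(self):
        counts = np.array([3, 3, 4, 9, 100])
        assert chao1(counts) == 5.0

    def test_adding_singleton_never_decreases(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            counts = rng.integers(0, 6, size=12)
            counts[0] += 1            # non-empty
            plus = np.append(counts, 1)
            assert chao1(plus) >= chao1(counts)

    def test_rarefaction_averaging_deterministic(self):
        counts = np.arange(1, 30)
        a = chao1(counts, n_rarefaction_reps=10, depth=200, seed=4)
        b = chao1(counts, n_rarefaction_reps=10, depth=200, seed=4)
        assert a == b
        assert a >= 0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            chao1(np.zeros(5, dtype=int))

    def test_diversity_report_lower_bound(self, small_table):
        df = diversity_report(small_table, seed=5)
        assert (df["chao1"] >= df["observed_otus"] - 1e-9).all()


class TestBrayCurtis:
    def test_identical_and_disjoint_samples(self):
        counts = np.array([[5, 5, 0, 0],
                           [5, 5, 0, 0],
                           [0, 0, 3, 7]])
        dm = bray_curtis(_table(counts))
        assert dm["S0", "S1"] == pytest.approx(0.0)
        assert dm["S0", "S2"] == pytest.approx(1.0)

    def test_hand_computed_value(self):
        dm = bray_curtis(_table(np.array([[6, 4, 0], [2, 4, 4]])))
        assert dm["S0", "S1"] == pytest.approx(0.4)

    def test_bounds_and_symmetry(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 50, size=(8, 10))
        counts[:, 0] += 1
        dm = bray_curtis(_table(counts)).data
        assert np.allclose(dm, dm.T)
        assert np.all((dm >= 0) & (dm <= 1))
        assert np.all(np.diag(dm) == 0)


class TestPcoa:
    def test_two_points_embed_at_half_distance(self):
        coords, explained = pcoa(np.array([[0.0, 0.6], [0.6, 0.0]]))
        assert sorted(coords.ravel()) == pytest.approx([-0.3, 0.3])
        assert explained == pytest.approx([1.0])

    def test_euclidean_round_trip(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(10, 2))
        dm = squareform(pdist(pts))
        coords, explained = pcoa(dm)
        # two positive eigenvalues reconstruct the distances exactly
        back = squareform(pdist(coords[:, :2]))
        assert np.allclose(back, dm, atol=1e-8)
        assert explained[0] >= explained[-1]

    def test_identical_samples_give_no_axes(self):
        coords, explained = pcoa(np.zeros((3, 3)))
        assert coords.shape[1] == 0
        assert explained.size == 0

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            pcoa(np.array([[0.0, 0.5], [0.4, 0.0]]))


class TestPermanova:
    def test_strong_group_structure_detected(self):
        rng = np.random.default_rng(4)
        a = rng.integers(50, 100, size=(8, 6))
        b = rng.integers(50, 100, size=(8, 6))
        b[:, :3] += 400                      # large compositional offset
        table = _table(np.vstack([a, b]))
        dm = bray_curtis(table)
        grouping = np.repeat(["a", "b"], 8)
        r2, p = permanova(dm, grouping, n_perm=999, seed=5)
        assert p <= 0.005
        assert 0 < r2 <= 1

    def test_matches_vegan_adonis2_r2(self, tmp_path):
        rng = np.random.default_rng(6)
        counts = rng.integers(1, 100, size=(12, 8))
        dm = bray_curtis(_table(counts))
        grouping = np.repeat(["g1", "g2", "g3"], 4)
        r2, _ = permanova(dm, grouping, n_perm=99, seed=7)
        dmat = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
        dmat.to_csv(tmp_path / "dm.csv")
        script = textwrap.dedent(f"""
            suppressMessages(library(vegan))
            m <- as.matrix(read.csv("{tmp_path}/dm.csv", row.names = 1))
            g <- factor(rep(c("g1", "g2", "g3"), each = 4))
            res <- adonis2(as.dist(m) ~ g, permutations = 99)
            cat(sprintf("%.12f", res$R2[1]))
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        assert r2 == pytest.approx(float(out.stdout.strip()), abs=1e-9)

    def test_degenerate_equal_distances_reports_without_crash(self):
        dm = np.full((6, 6), 0.5)
        np.fill_diagonal(dm, 0.0)
        r2, p = permanova(dm, np.repeat(["a", "b"], 3), n_perm=99, seed=8)
        assert 0 <= r2 <= 1
        assert p > 0.5

    def test_single_group_rejected(self):
        dm = np.zeros((4, 4))
        with pytest.raises(ValueError):
            permanova(dm, ["a"] * 4)


class TestFoldChange:
    def test_identical_tables_give_unity(self):
        counts = np.array([[5000, 5000]] * 4)
        t = _table(counts)
        fc = fold_change(t, t, "OTU0", depth=10_000, seed=9)
        assert fc.fc == pytest.approx(1.0)

    def test_tenfold_arithmetic(self):
        control = _table(np.array([[50, 9950]] * 5))       # 0.5%
        treatment = _table(np.array([[500, 9500]] * 5))    # 5%
        fc = fold_change(treatment, control, "OTU0", depth=10_000, seed=10,
                         timepoint_label="3dpr")
        assert fc.fc == pytest.approx(10.0, rel=0.05)
        assert fc.timepoint_label == "3dpr"

    def test_absent_from_both_rejected(self):
        t = _table(np.array([[10, 10]] * 2))
        with pytest.raises(ValueError):
            fold_change(t, t, "OTUxx")

    def test_spiked_isolate_recovered_in_band(self):
        base = simulate_counts(BasisSpec(n_otus=50, seed=21), 5, 10_000)
        fr = base.counts.mean(axis=0) / 10_000
        otu = int(np.argmin(np.abs(fr - 0.005)))
        spiked = spike_isolate(base, otu, 10.0, seed=22)
        fc = fold_change(spiked.to_otu_table(), base.to_otu_table(),
                         base.otu_ids[otu], depth=10_000, seed=23)
        assert 5.0 <= fc.fc <= 20.0


def test_recolonization_dose():
    assert recolonization_dose(2000) == 4000
    assert recolonization_dose(200) == 400
    with pytest.raises(ValueError):
        recolonization_dose(0)


def test_pipeline_determinism(tmp_path):
    """filter -> rarefy -> Bray-Curtis reproduces byte-identical output."""
    rng = np.random.default_rng(30)
    counts = rng.integers(0, 400, size=(10, 25))
    counts[:, 0] += 200
    meta = pd.DataFrame({"stage": ["larva"] * 5 + ["adult"] * 5},
                        index=[f"S{i}" for i in range(10)])
    outputs = []
    for run in range(2):
        tab = _table(counts, metadata=meta)
        tab = filter_low_read_otus(tab, min_reads=50)
        tab = rarefy(tab, depth=1000, seed=99)
        dm = bray_curtis(tab)
        path = tmp_path / f"dm{run}.tsv"
        pd.DataFrame(dm.data, index=dm.ids,
                     columns=dm.ids).to_csv(path, sep="\t")
        outputs.append(path.read_bytes())
    assert outputs[0] == outputs[1]
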