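import numpy as np
import pandas as pd
import pytest
from scipy import stats

from saltgrip.core import SyntheticTruth
from saltgrip.genomic_io import write_fragments
from saltgrip.simulate import (
    C_MOTIF,
    SimConfig,
    occupancy_probability,
    simulate_contact_maps,
    simulate_fragment_library,
    simulate_truth,
)

SMALL = dict(genome_length=60_000, n_chroms=1, n_motifs=100, min_spacing=300,
             depth=20_000)


def _one_motif_truth(r=1.0, t=0.0):
    catalog = pd.DataFrame(
        {
            "motif_id": ["m0"],
            "chrom": ["chr1"],
            "start": [5000],
            "end": [5000 + len(C_MOTIF)],
            "strand": ["+"],
        }
    )
    truth = SyntheticTruth(
        motifs=pd.DataFrame(
            {"motif_id": ["m0"], "retention": [r], "transient": [t],
             "has_U": [False], "has_D": [False]}
        )
    )
    return catalog, truth


class TestSimulateTruth:
    def test_deterministic_under_fixed_seed(self):
        cfg = SimConfig(seed=7, **SMALL)
        c1, t1, g1 = simulate_truth(cfg)
        c2, t2, g2 = simulate_truth(cfg)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(t1.motifs, t2.motifs)
        assert g1 == g2

    def test_motif_spacing_and_planting(self):
        cfg = SimConfig(seed=3, **SMALL)
        catalog, _, genome = simulate_truth(cfg)
        for _, grp in catalog.groupby("chrom"):
            starts = grp["start"].to_numpy()
            assert np.all(np.diff(starts) >= cfg.min_spacing)
        row = catalog.iloc[0]
        seq = genome[row.chrom][row.start : row.end]
        expect = C_MOTIF if row.strand == "+" else C_MOTIF.translate(
            str.maketrans("ACGT", "TGCA")
        )[::-1]
        assert seq == expect

    def test_zero_aux_slope_gives_retention_independent_flags(self):
        cfg = SimConfig(seed=5, aux_logit_slope=0.0)
        _, truth, _ = simulate_truth(cfg)
        frac = truth.motifs["has_U"].mean()
        n = len(truth.motifs)
        ci = 3 * np.sqrt(0.25 / n)
        assert abs(frac - 0.5) < ci

    def test_aux_slope_couples_flags_to_retention(self):
        cfg = SimConfig(seed=5, aux_logit_slope=4.0)
        _, truth, _ = simulate_truth(cfg)
        rho = stats.spearmanr(
            truth.motifs["retention"], truth.motifs["has_U"]
        )
        assert rho.statistic > 0 and rho.pvalue < 0.01

    def test_infeasible_placement_raises(self):
        with pytest.raises(ValueError, match="cannot place"):
            simulate_truth(SimConfig(seed=0, genome_length=10_000, n_chroms=1,
                                     n_motifs=100, min_spacing=300))


class TestFragmentLibrary:
    def test_unknown_condition_raises(self):
        cfg = SimConfig(seed=0, **SMALL)
        catalog, truth, _ = simulate_truth(cfg)
        with pytest.raises(ValueError, match="unknown condition"):
            simulate_fragment_library(truth, catalog, "300mM", cfg)

    def test_zero_depth_gives_empty_valid_library(self, tmp_path):
        cfg = SimConfig(seed=0, genome_length=60_000, n_chroms=1, n_motifs=10,
                        min_spacing=300, depth=0, frags_per_site=1e-9)
        catalog, truth, _ = simulate_truth(cfg)
        lib = simulate_fragment_library(truth, catalog, "xchip", cfg)
        assert lib.total == 0
        out = tmp_path / "empty.bed"
        write_fragments(lib, out)
        assert out.exists()

    def test_occupancy_monotone_in_salt_threshold(self):
        cfg = SimConfig(seed=0, **SMALL)
        _, truth, _ = simulate_truth(cfg)
        probs = np.stack(
            [occupancy_probability(truth, c, cfg) for c in cfg.salt_labels]
        )
        assert np.all(np.diff(probs, axis=0) <= 0)

    def test_saturated_motif_signal_dominates_background(
        self, default_config, default_dataset, salt_libraries
    ):
        """Motifs with near-saturated occupancy carry > 5x the window signal
        of motif-free background under the default study conditions."""
        catalog, truth, _ = default_dataset
        cond = default_config.salt_labels[1]  # theta = 0.5
        lib = salt_libraries[cond]
        sat = catalog[truth.motifs["retention"].to_numpy() > 0.95]
        from saltgrip.occupancy import quantify_signal_matrix

        sig = quantify_signal_matrix({cond: lib}, sat)[cond].mean()
        # background windows at positions far from every motif
        rng = np.random.default_rng(0)
        centers = ((catalog["start"] + catalog["end"]) // 2).to_numpy()
        cand = rng.integers(1000, default_config.genome_length - 1000, size=2000)
        far = cand[
            np.min(np.abs(cand[:, None] - centers[None, :1000]), axis=1) > 200
        ][:300]
        bg_sites = pd.DataFrame(
            {
                "motif_id": [f"bg{i}" for i in range(len(far))],
                "chrom": "chr1",
                "start": far - 7,
                "end": far + 7,
                "strand": "+",
            }
        )
        bg = quantify_signal_matrix({cond: lib}, bg_sites)[cond].mean()
        assert sig > 5 * bg

    def test_library_size_equals_depth(self, salt_libraries, default_config):
        for lib in salt_libraries.values():
            assert lib.total == default_config.depth

    def test_deterministic_per_condition(self):
        cfg = SimConfig(seed=4, **SMALL)
        catalog, truth, _ = simulate_truth(cfg)
        a = simulate_fragment_library(truth, catalog, "75mM", cfg)
        b = simulate_fragment_library(truth, catalog, "75mM", cfg)
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_crosslinking_compresses_retention_spectrum(
        self, default_dataset, salt_libraries, default_config
    ):
        """X-ChIP signal orders motifs by retention worse than the
        highest-salt native library (crosslink accumulation of transient
        binding scrambles the spectrum)."""
        from saltgrip.occupancy import quantify_signal_matrix

        catalog, truth, _ = default_dataset
        high = default_config.salt_labels[-1]
        mat = quantify_signal_matrix(
            {c: salt_libraries[c] for c in (high, "xchip")}, catalog
        )
        r = truth.motifs["retention"].to_numpy()
        rho_x = stats.spearmanr(mat["xchip"], r).statistic
        rho_n = stats.spearmanr(mat[high], r).statistic
        assert rho_x < rho_n


class TestContactMaps:
    def test_background_only_decay(self):
        cfg = SimConfig(seed=2, loop_count=0, boundary_count=0)
        _, truth, _ = simulate_truth(cfg)
        cm = simulate_contact_maps(truth, "dmso", cfg)
        from saltgrip.structure import expected_by_distance

        e, _ = expected_by_distance(cm)
        d = np.arange(1, 40)
        expect = cfg.contact_intensity / (d + 1)
        # Poisson error on the diagonal mean of ~n counts
        n_per_diag = cm.nbins - d
        se = np.sqrt(expect / n_per_diag)
        assert np.all(np.abs(e[d] - expect) < 6 * se)

    def test_symmetric_and_deterministic(self):
        cfg = SimConfig(seed=2)
        _, truth, _ = simulate_truth(cfg)
        a = simulate_contact_maps(truth, "tpa", cfg)
        b = simulate_contact_maps(truth, "tpa", cfg)
        np.testing.assert_array_equal(a.matrix, a.matrix.T)
        np.testing.assert_array_equal(a.matrix, b.matrix)

    def test_saturated_anchors_unaffected_by_tpa(self):
        """Loops anchored at full-retention motifs keep their strength."""
        cfg = SimConfig(seed=6)
        _, truth, _ = simulate_truth(cfg)
        truth.motifs["retention"] = 1.0
        truth.loops["anchor_retention"] = 1.0
        truth.boundaries["anchor_retention"] = 1.0
        from saltgrip.simulate import expected_contacts

        e_d = expected_contacts(truth, "dmso", cfg)
        e_t = expected_contacts(truth, "tpa", cfg)
        np.testing.assert_allclose(e_d, e_t)

    def test_low_retention_loops_weaken_most(self):
        """TPA/DMSO loop-score ratio is lower for low-retention anchors
        (sign test over seeds)."""
        from saltgrip.structure import apa, oe_normalize

        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cfg = SimConfig(seed=seed)
            _, truth, _ = simulate_truth(cfg)
            lo = truth.loops["anchor_retention"] < 0.3
            hi = truth.loops["anchor_retention"] > 0.7
            if lo.sum() < 2 or hi.sum() < 2:
                continue
            oe_d = oe_normalize(simulate_contact_maps(truth, "dmso", cfg))
            oe_t = oe_normalize(simulate_contact_maps(truth, "tpa", cfg))
            s_d = apa(oe_d, truth.loops, flank_bins=8)["scores"]
            s_t = apa(oe_t, truth.loops, flank_bins=8)["scores"]
            ratio = s_t / s_d
            idx = ratio.index
            if ratio[lo.loc[idx]].mean() < ratio[hi.loc[idx]].mean():
                wins += 1
        assert stats.binomtest(wins, n_seeds, 0.5, alternative="greater").pvalue < 0.01
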