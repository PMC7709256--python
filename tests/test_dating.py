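"""Clock calibration, WGD dating arithmetic, and mixture peak fitting."""

import numpy as np
import pytest

from paleowgd.dating import (
    KsDistribution,
    RateCalibration,
    calibrate_rate,
    compare_distributions,
    date_event,
    fit_peaks,
    orthologous_ks_window,
    round_my,
)


class TestCalibration:
    def test_trochodendraceae_rate(self):
        # median ortholog Ks 0.2 at a 30.7 MY divergence
        cal = calibrate_rate(0.2, 30.7)
        assert cal.r == pytest.approx(0.2 / (2 * 30.7e6))
        assert cal.r == pytest.approx(3.25e-9, rel=3e-3)

    @pytest.mark.parametrize("ks,t", [(0.0, 30.7), (-0.1, 30.7), (0.2, 0.0)])
    def test_nonpositive_inputs_rejected(self, ks, t):
        with pytest.raises(ValueError):
            calibrate_rate(ks, t)

    def test_algebraic_identity(self):
        for r, t in [(3.25e-9, 40.0), (1e-9, 7.3), (8e-9, 123.4)]:
            cal = calibrate_rate(2 * r * t * 1e6, t)
            assert cal.r == pytest.approx(r)

    def test_round_trip_recovers_time(self):
        cal = calibrate_rate(0.41, 55.5)
        assert date_event(0.41, cal) == pytest.approx(55.5)

    def test_date_event_accepts_bare_rate(self):
        assert date_event(0.532, 3.25e-9) == pytest.approx(81.85, abs=0.01)

    def test_nonpositive_peak_rejected(self):
        with pytest.raises(ValueError):
            date_event(0.0, calibrate_rate(0.2, 30.7))


class TestRounding:
    @pytest.mark.parametrize("x,expected", [(53.5, 54), (81.8, 82), (58.6, 59),
                                            (78.0, 78), (53.4, 53)])
    def test_half_up_display(self, x, expected):
        assert round_my(x) == expected


class TestFitPeaks:
    def test_single_lognormal_component(self):
        rng = np.random.default_rng(0)
        vals = np.exp(rng.normal(np.log(0.4), 0.15, size=500))
        d = KsDistribution("x", vals.tolist())
        peaks = fit_peaks(d, seed=0)
        assert len(peaks) == 1
        # 3 standard errors of the log-mean: 3*0.15/sqrt(500) ~ 2%
        assert 0.36 <= peaks[0].location <= 0.44

    def test_two_overlapping_components(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate([
            np.exp(rng.normal(np.log(0.38), 0.12, size=400)),
            np.exp(rng.normal(np.log(0.53), 0.12, size=400)),
        ])
        d = KsDistribution("x", vals.tolist())
        peaks = fit_peaks(d, max_components=4, seed=0)
        assert len(peaks) == 2
        assert peaks[0].location == pytest.approx(0.38, rel=0.10)
        assert peaks[1].location == pytest.approx(0.53, rel=0.10)
        assert sum(p.weight for p in peaks) == pytest.approx(1.0)

    def test_degenerate_identical_values(self):
        d = KsDistribution("x", [0.25] * 30)
        peaks = fit_peaks(d, seed=0)
        assert len(peaks) == 1
        assert peaks[0].location == pytest.approx(0.25)
        assert peaks[0].width == 0.0

    def test_too_few_values_rejected(self):
        d = KsDistribution("x", [0.1] * 5)
        with pytest.raises(ValueError, match=">= 20"):
            fit_peaks(d)

    def test_values_filtered_to_ks_max(self):
        d = KsDistribution("x", [0.5, 3.5, -1.0, 2.9])
        assert d.values == [0.5, 2.9]

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(3)
        vals = np.exp(rng.normal(np.log(0.4), 0.3, size=300)).tolist()
        p1 = fit_peaks(KsDistribution("x", vals), seed=5)
        p2 = fit_peaks(KsDistribution("x", vals), seed=5)
        assert [p.location for p in p1] == [p.location for p in p2]


class TestCompareDistributions:
    def _dist(self, label, locs, kind):
        rng = np.random.default_rng(hash(label) % 2**31)
        vals = np.concatenate(
            [np.exp(rng.normal(np.log(m), 0.1, size=200)) for m in locs]
        )
        d = KsDistribution(label, vals.tolist(), kind)
        fit_peaks(d, seed=0)
        return d

    def test_paralog_peaks_below_ortholog_flagged_post_divergence(self):
        para = self._dist("para", [0.38, 0.53], "paralog")
        orth = self._dist("orth", [0.9], "ortholog")
        table = compare_distributions([para, orth])
        flags = table[table.label == "para"].flag.tolist()
        assert flags == ["post-divergence"] * len(flags)

    def test_paralog_peak_above_ortholog_flagged_pre_divergence(self):
        para = self._dist("para2", [1.2], "paralog")
        orth = self._dist("orth2", [0.9], "ortholog")
        table = compare_distributions([para, orth])
        assert "pre-divergence" in set(table[table.label == "para2"].flag)

    def test_unfitted_distribution_rejected(self):
        d = KsDistribution("x", [0.5] * 30)
        with pytest.raises(ValueError, match="no fitted peaks"):
            compare_distributions([d])


class TestOrthologWindow:
    def test_window_covers_low_component_only(self):
        rng = np.random.default_rng(4)
        low = np.exp(rng.normal(np.log(0.2), 0.1, size=300))
        high = np.exp(rng.normal(np.log(0.8), 0.1, size=300))
        lo, hi = orthologous_ks_window(np.concatenate([low, high]).tolist(), seed=0)
        assert lo == 0.0
        assert np.quantile(low, 0.9) < hi < np.min(high) * 1.3


class TestPeakOrderingOnSimulation:
    def test_lineage_specific_wgd_peaks_sit_below_ortholog_peak(self):
        """WGDs that postdate the outgroup split leave paralog Ks peaks below
        the ortholog-divergence peak, so both are flagged post-divergence."""
        import paleowgd as pw
        from paleowgd.simulate import outgroup_ingroup_scenario, run_scenario

        scen = outgroup_ingroup_scenario(n_genes=300, loss_fraction=0.2, seed=55)
        genomes, _ = run_scenario(scen)
        out_g, in_g = genomes["out"], genomes["in"]
        pairs = pw.find_homolog_pairs(
            [out_g, in_g], genome_pairs=[("out", "in"), ("in", "in")]
        )
        cross = pw.detect_blocks(pairs, out_g, in_g)
        para = pw.detect_blocks(pairs, in_g, in_g)
        est = pw.anchor_ks(cross + para, {"out": out_g, "in": in_g})
        pw.annotate_block_ks(cross, est)
        pw.annotate_block_ks(para, est)
        d_para = KsDistribution(
            "in-paralogs",
            [b.median_ks for b in para if b.median_ks is not None],
            "paralog",
        )
        d_orth = KsDistribution(
            "out-in-orthologs",
            [b.median_ks for b in cross if b.median_ks is not None],
            "ortholog",
        )
        fit_peaks(d_para, seed=0)
        fit_peaks(d_orth, seed=0)
        table = compare_distributions([d_para, d_orth])
        para_flags = table[table.label == "in-paralogs"].flag.tolist()
        assert para_flags and all(f == "post-divergence" for f in para_flags)
        # and the ortholog peak indeed sits near 2*r*T_split = 0.78
        ortho_peak = table[table.label == "out-in-orthologs"].peak_ks.min()
        assert ortho_peak == pytest.approx(2 * 3.25e-9 * 120e6, rel=0.15)
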