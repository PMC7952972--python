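"""QC, normalization, segmentation and copy-number calling."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pgtcnv as P
from pgtcnv.bins import BinGrid
from pgtcnv.cnvcall import CallerConfig, NormalizedProfile, estimate_sigma
from pgtcnv.meiosis import ImbalanceRegion
from pgtcnv.simulate import _gc_bias


def toy_grid(n_bins: int, chrom: str = "1") -> BinGrid:
    M = 1_000_000
    starts = np.arange(n_bins, dtype=np.int64) * M
    return BinGrid((chrom,) * n_bins, starts, starts + M,
                   np.full(n_bins, 0.40), M, {chrom: n_bins * M})


def toy_profile(x, grid) -> NormalizedProfile:
    x = np.asarray(x, dtype=float)
    return NormalizedProfile("toy", x, np.zeros(len(x), dtype=bool), "XX")


def oracle_changepoints(x) -> list[int]:
    """Exhaustive oracle for noiseless data: every position where the
    value changes is a changepoint, and no others exist."""
    x = np.asarray(x, dtype=float)
    return (np.flatnonzero(np.diff(x) != 0) + 1).tolist()


class TestQC:
    def test_clean_sample_informative(self, reduced_grid, sim_config):
        c = P.simulate_blastomere_counts([], "XX", reduced_grid, sim_config, 1)
        qc = P.qc_assess(c, reduced_grid)
        assert qc.informative and not qc.reasons

    def test_failed_sample_flagged_for_noise(self, reduced_grid, sim_config):
        c = P.simulate_blastomere_counts([], "XX", reduced_grid, sim_config, 1,
                                         failed=True)
        qc = P.qc_assess(c, reduced_grid)
        assert not qc.informative
        assert "noise" in qc.reasons

    def test_all_zero_counts_flagged_for_reads(self, reduced_grid):
        c = P.BinCounts("empty", np.zeros(len(reduced_grid), dtype=int), 0)
        qc = P.qc_assess(c, reduced_grid)
        assert not qc.informative
        assert "reads" in qc.reasons

    def test_length_mismatch_rejected(self, reduced_grid):
        c = P.BinCounts("short", np.ones(10, dtype=int), 10)
        with pytest.raises(ValueError, match="length"):
            P.qc_assess(c, reduced_grid)

    def test_qc_monotone_in_dispersion(self, reduced_grid, sim_config):
        """More overdispersion never turns a failing sample informative."""
        flags = []
        for disp in (0.02, 0.2, 0.6, 1.5, 3.0, 6.0):
            cfg = dataclasses.replace(sim_config, overdispersion=disp)
            c = P.simulate_blastomere_counts([], "XX", reduced_grid, cfg, 5)
            flags.append(P.qc_assess(c, reduced_grid).informative)
        # once failing, stays failing
        assert flags == sorted(flags, reverse=True)


class TestReferencePanel:
    def test_identical_flat_samples_give_unit_factors(self, reduced_grid):
        flat = P.BinCounts("f", np.full(len(reduced_grid), 500), 10**9)
        panel = P.build_reference([flat] * 5, reduced_grid)
        auto = reduced_grid.autosomal
        assert np.allclose(panel.factors[auto], 1.0)

    def test_bin_zero_in_all_normals_is_masked(self, reduced_grid):
        counts = np.full(len(reduced_grid), 500)
        counts[7] = 0
        s = P.BinCounts("z", counts, 10**9)
        panel = P.build_reference([s] * 5, reduced_grid)
        assert panel.mask[7]

    def test_too_few_samples_rejected(self, reduced_grid):
        flat = P.BinCounts("f", np.full(len(reduced_grid), 500), 10**9)
        with pytest.raises(ValueError, match="panel"):
            P.build_reference([flat, flat], reduced_grid)

    def test_factors_track_gc_bias_shape(self, reduced_grid, sim_config):
        """Per-GC-stratum mean panel factors follow the simulator's known
        multiplicative bias curve (stratum averaging removes the
        per-bin sampling noise of a finite panel)."""
        rng = np.random.default_rng(3)
        normals = [P.simulate_blastomere_counts([], "XX", reduced_grid,
                                                sim_config, rng,
                                                sample_id=f"n{i}")
                   for i in range(40)]
        panel = P.build_reference(normals, reduced_grid)
        bias = _gc_bias(reduced_grid, sim_config)
        auto = reduced_grid.autosomal
        strata = np.floor(reduced_grid.gc / 0.02).astype(int)
        f_means, b_means = [], []
        for s in np.unique(strata[auto]):
            sel = auto & (strata == s)
            if sel.sum() >= 8:
                f_means.append(panel.factors[sel].mean())
                b_means.append(bias[sel].mean())
        assert len(f_means) >= 4
        r = np.corrcoef(f_means, b_means)[0, 1]
        assert r > 0.9


class TestNormalize:
    def test_trisomy_mean_ratio_up_50pct(self, reduced_grid, reduced_map,
                                         reduced_panel, sim_config):
        tri = [ImbalanceRegion("2", 0, reduced_map.lengths["2"], +1)]
        c = P.simulate_blastomere_counts(tri, "XX", reduced_grid, sim_config, 2)
        prof = P.normalize(c, reduced_panel, reduced_grid)
        i2 = reduced_grid.chrom_index("2")
        assert np.nanmean(prof.ratios[i2]) == pytest.approx(1.5, abs=0.08)

    def test_monosomy_mean_ratio_down_50pct(self, reduced_grid, reduced_map,
                                            reduced_panel, sim_config):
        mono = [ImbalanceRegion("2", 0, reduced_map.lengths["2"], -1)]
        c = P.simulate_blastomere_counts(mono, "XX", reduced_grid, sim_config, 2)
        prof = P.normalize(c, reduced_panel, reduced_grid)
        i2 = reduced_grid.chrom_index("2")
        assert np.nanmean(prof.ratios[i2]) == pytest.approx(0.5, abs=0.08)

    def test_euploid_chromosome_medians_near_one(self, reduced_grid,
                                                 reduced_panel, sim_config):
        c = P.simulate_blastomere_counts([], "XX", reduced_grid, sim_config, 4)
        prof = P.normalize(c, reduced_panel, reduced_grid)
        chroms = np.asarray(reduced_grid.chroms)
        for chrom in ("1", "2", "3", "X"):
            med = np.nanmedian(prof.ratios[chroms == chrom])
            assert med == pytest.approx(1.0, abs=0.08)

    def test_failed_sample_requires_force(self, reduced_grid, reduced_panel,
                                          sim_config):
        c = P.simulate_blastomere_counts([], "XX", reduced_grid, sim_config, 1,
                                         failed=True)
        with pytest.raises(ValueError, match="failed QC"):
            P.normalize(c, reduced_panel, reduced_grid)
        prof = P.normalize(c, reduced_panel, reduced_grid, force=True)
        assert prof.sample_id == c.sample_id

    def test_sex_inference(self, reduced_grid, reduced_panel, sim_config):
        rng = np.random.default_rng(12)
        for seed, sex in ((1, "XY"), (2, "XX"), (3, "XY"), (4, "XX")):
            c = P.simulate_blastomere_counts([], sex, reduced_grid,
                                             sim_config, rng)
            prof = P.normalize(c, reduced_panel, reduced_grid)
            assert prof.sex == sex
            x = np.nanmedian(prof.ratios[reduced_grid.chrom_index("X")])
            y_idx = reduced_grid.chrom_index("Y")
            y_ok = prof.ratios[y_idx][~np.isnan(prof.ratios[y_idx])]
            y = np.median(y_ok) if y_ok.size else 0.0
            if sex == "XY":
                assert x == pytest.approx(0.5, abs=0.15)
                assert y > 0.25
            else:
                assert x == pytest.approx(1.0, abs=0.15)
                assert y < 0.1


class TestSegmentation:
    def test_noiseless_piecewise_constant_exact(self):
        x = np.concatenate([np.ones(20), np.full(6, 0.5), np.ones(24)])
        grid = toy_grid(len(x))
        segs = P.segment(toy_profile(x, grid), grid)
        bounds = sorted(s.bin_start for s in segs)[1:]
        assert bounds == oracle_changepoints(x)

    def test_single_bin_spike_isolated(self):
        # a lone full-amplitude bin on an otherwise flat chromosome is
        # split out and reported (1 Mb resolution at amplitude >= 0.8)
        x = np.ones(48)
        x[30] = 0.45
        grid = toy_grid(48)
        prof = toy_profile(x, grid)
        cs = P.call_segments(P.segment(prof, grid), prof, grid)
        (seg,) = cs.segments
        assert (seg.bin_start, seg.bin_end) == (30, 31)
        assert seg.call == 1 or seg.call == 0

    def test_flat_profile_single_segment(self):
        grid = toy_grid(50)
        segs = P.segment(toy_profile(np.ones(50), grid), grid)
        assert len(segs) == 1
        callset = P.call_segments(segs, toy_profile(np.ones(50), grid), grid)
        assert callset.segments == ()

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_exhaustive_oracle_on_small_instances(self, data):
        """Recursive binary splitting recovers exactly the true
        changepoints of any noiseless piecewise-constant profile up to
        50 bins (levels well separated)."""
        n = data.draw(st.integers(8, 50))
        n_cp = data.draw(st.integers(0, min(4, n - 5)))
        raw = sorted(data.draw(
            st.lists(st.integers(3, max(3, n - 3)), min_size=n_cp,
                     max_size=n_cp, unique=True)))
        # segments of >= 3 bins: the noise scale is estimated from
        # adjacent-bin differences, which requires changes to be sparse
        cps = []
        for p in raw:
            if p <= n - 3 and (not cps or p - cps[-1] >= 3):
                cps.append(p)
        levels = [0.5, 1.0, 1.5, 2.0]
        seq = []
        prev = None
        for _ in range(len(cps) + 1):
            choices = [l for l in levels if l != prev]
            prev = data.draw(st.sampled_from(choices))
            seq.append(prev)
        x = np.empty(n)
        edges = [0] + cps + [n]
        for lvl, lo, hi in zip(seq, edges[:-1], edges[1:]):
            x[lo:hi] = lvl
        grid = toy_grid(n)
        segs = P.segment(toy_profile(x, grid), grid)
        bounds = sorted(s.bin_start for s in segs)[1:]
        assert bounds == oracle_changepoints(x)


class TestCalling:
    def _one_segment_call(self, ratio, n=20):
        grid = toy_grid(n)
        x = np.full(n, float(ratio))
        prof = toy_profile(x, grid)
        return P.call_segments(P.segment(prof, grid), prof, grid)

    def test_full_trisomy_called_3_with_f_capped(self):
        cs = self._one_segment_call(1.5)
        (seg,) = cs.segments
        assert seg.call == 3
        assert seg.mosaic_fraction == pytest.approx(1.0)
        assert not seg.mosaic

    def test_intermediate_ratio_called_mosaic(self):
        cs = self._one_segment_call(1.25)
        (seg,) = cs.segments
        assert seg.mosaic
        assert seg.mosaic_fraction == pytest.approx(0.5, abs=0.01)
        assert seg.call == 3

    def test_small_shift_not_called(self):
        cs = self._one_segment_call(1.1)
        assert cs.segments == ()

    def test_shift_at_exactly_40pct_not_called(self):
        cs = self._one_segment_call(1.2)
        assert cs.segments == ()

    def test_min_segment_rule(self):
        # 2-bin event at mosaic amplitude is suppressed; at full
        # amplitude it is reported
        grid = toy_grid(30)
        for level, expected in ((1.3, 0), (1.6, 1)):
            x = np.ones(30)
            x[10:12] = level
            prof = toy_profile(x, grid)
            cs = P.call_segments(P.segment(prof, grid), prof, grid)
            assert len(cs.segments) == expected

    def test_copy_number_linearity(self, reduced_grid, reduced_map,
                                   reduced_panel, sim_config):
        """Across true copy numbers 1..3 the estimate is within 0.1,
        averaged over 20 seeds."""
        i2 = reduced_grid.chrom_index("2")
        for true_c, delta, frac in ((1.0, -1, None), (1.5, -1, 0.5),
                                    (2.0, 0, None), (2.5, 1, 0.5),
                                    (3.0, 1, None)):
            est = []
            for seed in range(20):
                regions = []
                if delta:
                    regions = [ImbalanceRegion(
                        "2", 0, reduced_map.lengths["2"], delta,
                        mosaic_fraction=frac)]
                c = P.simulate_blastomere_counts(regions, "XX", reduced_grid,
                                                 sim_config, 9000 + seed)
                prof = P.normalize(c, reduced_panel, reduced_grid)
                est.append(2.0 * np.nanmean(prof.ratios[i2]))
            assert np.mean(est) == pytest.approx(true_c, abs=0.1)


class TestEstimator:
    def test_sklearn_protocol(self, reduced_grid):
        from sklearn.base import clone
        est = P.CopyNumberCaller(grid=reduced_grid, mosaic_threshold=0.4)
        params = est.get_params()
        assert params["mosaic_threshold"] == 0.4
        est2 = clone(est)
        assert est2.get_params()["mosaic_threshold"] == 0.4

    def test_fit_predict_matches_functions(self, reduced_grid, reduced_map,
                                           sim_config):
        rng = np.random.default_rng(31)
        normals = [P.simulate_blastomere_counts([], "XX" if i % 2 else "XY",
                                                reduced_grid, sim_config, rng,
                                                sample_id=f"n{i}")
                   for i in range(10)]
        tri = [ImbalanceRegion("2", 0, reduced_map.lengths["2"], +1)]
        sample = P.simulate_blastomere_counts(tri, "XX", reduced_grid,
                                              sim_config, 8, sample_id="t")
        est = P.CopyNumberCaller(grid=reduced_grid).fit(normals)
        assert hasattr(est, "reference_panel_")
        (pred,) = est.predict([sample])
        direct = P.call_sample(sample, est.reference_panel_, reduced_grid)
        assert [(s.chrom, s.start, s.end, s.call) for s in pred.segments] == \
               [(s.chrom, s.start, s.end, s.call) for s in direct.segments]
        ratios = est.transform([sample])
        assert ratios.shape == (1, len(reduced_grid))
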