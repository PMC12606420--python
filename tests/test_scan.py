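"""ANOVA scan, LOESS smoothing, peak calling and frequency-change reporting."""

import numpy as np
import pandas as pd
import pytest

import xqtlmap as xm
from xqtlmap.haplotypes import HaplotypeFreqTable, Window
from xqtlmap.scan import loess_smooth, peaks_to_dataframe
from xqtlmap.simdata import ConfigError

from oracles import anova_projection_oracle, loess_direct_oracle

# ---------------------------------------------------------------------------


class TestASF:
    def test_boundary_and_closed_form_values(self):
        assert xm.asf_transform(0.0) == 0.0
        assert xm.asf_transform(1.0) == pytest.approx(np.pi / 2)
        assert xm.asf_transform(0.25) == pytest.approx(np.pi / 6)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            xm.asf_transform(1.2)
        with pytest.raises(ValueError):
            xm.asf_transform(-0.1)


class TestWindowAnova:
    def test_null_by_construction(self, rng):
        base = rng.normal(0.5, 0.1, size=(5, 1, 4))
        table = np.concatenate([base, base], axis=1)  # treatments identical
        F, df1, df2, p, neglog = xm.window_anova(table)
        assert F == 0.0
        assert p == 1.0
        assert neglog == 0.0

    def test_degrees_of_freedom_at_study_design(self, rng):
        table = rng.normal(size=(12, 2, 8))
        _, df1, df2, _, _ = xm.window_anova(table)
        assert (df1, df2) == (7, 77)

    def test_df_ratio_identity(self, rng):
        for r, t, f in [(3, 2, 3), (5, 2, 8), (12, 2, 4)]:
            _, df1, df2, _, _ = xm.window_anova(rng.normal(size=(r, t, f)))
            assert df2 == (r - 1) * df1

    def test_matches_projection_oracle(self, rng):
        for _ in range(100):
            r = rng.integers(2, 5)
            f = rng.integers(2, 5)
            y = rng.normal(size=(r, 2, f))
            F, *_ = xm.window_anova(y)
            assert F == pytest.approx(anova_projection_oracle(y), abs=1e-10, rel=1e-10)

    def test_unbalanced_table_names_missing_cells(self, rng):
        table = rng.normal(size=(3, 2, 3))
        table[1, 0, 2] = np.nan
        with pytest.raises(ValueError, match=r"\[1, 0, 2\]"):
            xm.window_anova(table)

    def test_treatment_label_swap_leaves_p_unchanged(self, rng):
        table = rng.normal(size=(6, 2, 5))
        _, _, _, p1, _ = xm.window_anova(table)
        _, _, _, p2, _ = xm.window_anova(table[:, ::-1, :])
        assert p1 == pytest.approx(p2, rel=1e-12)


class TestLoess:
    def test_reproduces_constants(self):
        x = np.linspace(0, 10, 40)
        y = np.full(40, 3.3)
        assert np.allclose(loess_smooth(x, y, span=0.4), 3.3)

    def test_reproduces_lines_with_degree_ge_1(self):
        x = np.linspace(0, 10, 40)
        y = 2.0 * x - 1.0
        for degree in (1, 2):
            assert np.allclose(loess_smooth(x, y, span=0.5, degree=degree), y,
                               atol=1e-9)

    def test_spike_matches_direct_oracle(self, rng):
        x = np.sort(rng.uniform(0, 50, 80))
        y = np.zeros(80)
        y[40] = 6.0
        for span, degree in [(0.2, 1), (0.3, 2)]:
            ours = loess_smooth(x, y, span=span, degree=degree)
            oracle = loess_direct_oracle(x, y, span, degree)
            assert np.allclose(ours, oracle, atol=1e-9)

    def test_span_too_small_for_degree(self):
        x = np.linspace(0, 1, 20)
        with pytest.raises(ConfigError):
            loess_smooth(x, x, span=0.05, degree=2)


def _scan_frame(values, chrom="chr1", step=0.5):
    centers = 0.75 + np.arange(len(values)) * step
    return pd.DataFrame({
        "chrom": chrom, "center_cM": centers,
        "center_bp": (centers * 5e5).astype(int),
        "F": 1.0, "df1": 7, "df2": 77, "p": 10.0 ** (-np.asarray(values)),
        "neglog10p_raw": values, "neglog10p_smooth": values, "flag": "ok"})


class TestCallPeaks:
    def setup_method(self):
        self.gmap = xm.GeneticMap.linear({"chr1": 60.0})

    def test_subthreshold_series_yields_no_peaks(self):
        scan = _scan_frame(np.full(100, 3.9))
        assert xm.call_peaks(scan, self.gmap) == []

    def test_triangular_peak_interval_matches_drop_rule(self):
        vals = np.zeros(101)
        for i in range(101):
            vals[i] = max(0.0, 6.0 - 0.3 * abs(i - 50))
        scan = _scan_frame(vals)
        peaks = xm.call_peaks(scan, self.gmap, threshold=4.0, drop=3.0)
        assert len(peaks) == 1
        pk = peaks[0]
        centers = scan["center_cM"].to_numpy()
        assert pk.peak_cm == pytest.approx(centers[50])
        # first windows at/below 6-3=3 are 10 steps out
        assert pk.start_cm == pytest.approx(centers[40])
        assert pk.end_cm == pytest.approx(centers[60])

    def test_threshold_is_inclusive(self):
        vals = np.zeros(50)
        vals[25] = 4.0
        peaks = xm.call_peaks(_scan_frame(vals), self.gmap)
        assert len(peaks) == 1
        assert peaks[0].peak_value == 4.0

    def test_nested_candidates_merge_into_stronger_peak(self):
        vals = np.zeros(101)
        for i in range(101):
            vals[i] = max(0.0, 7.0 - 0.2 * abs(i - 50))
        vals[55] += 0.3  # secondary local bump inside the main interval
        peaks = xm.call_peaks(_scan_frame(vals), self.gmap)
        assert len(peaks) == 1

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ConfigError):
            xm.call_peaks(_scan_frame(np.zeros(20)), self.gmap, threshold=-1.0)

    def test_low_recombination_interval_flagged(self):
        gmap = xm.GeneticMap({"chr1": (
            np.array([1.0, 1e6, 6e7]), np.array([0.0, 5.0, 31.0]))})
        vals = np.zeros(60)
        vals[30] = 5.0  # peak where the local rate is ~0.44 cM/Mb
        peaks = xm.call_peaks(_scan_frame(vals, step=0.5), gmap)
        assert len(peaks) == 1
        assert peaks[0].low_recombination

    def test_peaks_dataframe_sizes(self):
        vals = np.zeros(101)
        vals[48:53] = [4.5, 5.5, 6.0, 5.5, 4.5]
        df = peaks_to_dataframe(xm.call_peaks(_scan_frame(vals), self.gmap))
        assert df.loc[0, "size_kb"] == pytest.approx(
            (df.loc[0, "interval_end_bp"] - df.loc[0, "interval_start_bp"]) / 1e3)


def _toy_hap_table(est, pool_ids, chrom="chr1"):
    W, P, F = est.shape
    windows = [Window(chrom, 0.75 + 0.5 * w, 0.5 * w, 1.5 + 0.5 * w,
                      np.arange(30)) for w in range(W)]
    return HaplotypeFreqTable(windows=windows, pool_ids=pool_ids, est=est,
                              n_snps=np.full((W, P), 30),
                              residual=np.zeros((W, P)),
                              identifiable=np.ones((W, P), dtype=bool),
                              founders=[f"F{i+1}" for i in range(F)])


class TestFrequencyChange:
    def test_single_replicate_arithmetic(self):
        est = np.zeros((1, 2, 4))
        est[0, 0] = [0.6, 0.4, 0.0, 0.0]   # selected
        est[0, 1] = [0.5, 0.5, 0.0, 0.0]   # control
        hap = _toy_hap_table(est, ["R1Z", "R1C"])
        meta = pd.DataFrame({"pool_id": ["R1Z", "R1C"], "replicate": [1, 1],
                             "treatment": ["selected", "control"],
                             "duplicate_label": ["NA", "NA"]})
        delta = xm.haplotype_frequency_change(hap, meta)
        assert np.allclose(delta[0], [0.1, -0.1, 0.0, 0.0])

    def test_identical_treatments_give_zero(self, rng):
        h = rng.dirichlet(np.ones(5), size=3)
        est = np.stack([h, h], axis=1)
        hap = _toy_hap_table(est, ["R1Z", "R1C"])
        meta = pd.DataFrame({"pool_id": ["R1Z", "R1C"], "replicate": [1, 1],
                             "treatment": ["selected", "control"],
                             "duplicate_label": ["NA", "NA"]})
        assert np.allclose(xm.haplotype_frequency_change(hap, meta), 0.0)

    def test_deltas_sum_to_zero(self, small_experiment):
        pools, _, panel, gmap = small_experiment
        _, hap, _ = xm.run_scan(pools, panel, gmap)
        delta = xm.haplotype_frequency_change(hap, xm.pool_metadata(pools))
        sums = np.nansum(delta, axis=1)
        assert np.all(np.abs(sums) < 1e-6)


class TestDuplicateControlContrast:
    def _dup_meta(self, pool_ids):
        rows = []
        for pid in pool_ids:
            rep = int(pid[1])
            rows.append({"pool_id": pid, "replicate": rep,
                         "treatment": "control", "duplicate_label": pid[-1]})
        return pd.DataFrame(rows)

    def test_literal_copies_give_zero_F_everywhere(self, rng):
        gmap = xm.GeneticMap.linear({"chr1": 20.0})
        h = rng.dirichlet(np.ones(8), size=(30, 3))
        est = np.repeat(h, 2, axis=1)  # A and B identical per replicate
        pool_ids = [f"R{r}C{lab}" for r in (1, 2, 3) for lab in "AB"]
        hap = _toy_hap_table(est, pool_ids)
        scan = xm.duplicate_control_contrast(hap, self._dup_meta(pool_ids), gmap)
        assert np.allclose(scan["F"].to_numpy(), 0.0)
        assert np.allclose(scan["p"].to_numpy(), 1.0)

    def test_requires_two_duplicate_replicates(self, rng):
        gmap = xm.GeneticMap.linear({"chr1": 20.0})
        est = rng.dirichlet(np.ones(8), size=(30, 2))
        pool_ids = ["R1CA", "R1CB"]
        hap = _toy_hap_table(est, pool_ids)
        with pytest.raises(ValueError, match="duplicate"):
            xm.duplicate_control_contrast(hap, self._dup_meta(pool_ids), gmap)

    def test_runs_with_five_replicates(self, rng):
        gmap = xm.GeneticMap.linear({"chr1": 20.0})
        est = rng.dirichlet(np.ones(8), size=(30, 10))
        pool_ids = [f"R{r}C{lab}" for r in range(1, 6) for lab in "AB"]
        hap = _toy_hap_table(est, pool_ids)
        scan = xm.duplicate_control_contrast(hap, self._dup_meta(pool_ids), gmap)
        assert scan["p"].notna().sum() > 0
        assert (scan["df2"] == 4 * scan["df1"]).all()  # r = 5 replicates
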