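"""Repeated-simulation studies: null calibration, power, duplicate-pool nulls.

These drive the full pipeline (simulate -> deconvolve -> scan -> smooth ->
call peaks) over many independently seeded synthetic experiments and report
the operating characteristics of the fixed genome-wide threshold: how often
a neutral experiment produces a spurious peak, how often and how precisely a
planted QTL is recovered, and how quiet the duplicate-control contrast is.

Study scales (one 50-cM chromosome, ~2,000 informative SNPs, pools of 300,
12 replicates) are desk-scale stand-ins for the full design: small enough to
repeat hundreds of times on one CPU, large enough that the windowed ANOVA
operates in the same regime (same factor structure and df) as the full-size
experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scan import call_peaks, duplicate_control_contrast, haplotype_frequency_change, run_scan
from .simdata import QTLEffectModel, SimConfig, pool_metadata, simulate_experiment

__all__ = ["null_calibration_study", "power_study", "duplicate_null_study",
           "PowerResult"]

THRESHOLD = 4.0


def _neutral_config(seed: int, mean_coverage: float = 40.0,
                    snps_per_cm: float = 40.0, pool_size: int = 300,
                    n_replicates: int = 12,
                    duplicates: tuple[int, ...] = ()) -> SimConfig:
    return SimConfig(seed=seed, n_replicates=n_replicates,
                     pool_size_range=(pool_size, pool_size),
                     mean_coverage=mean_coverage, survival_target=0.07,
                     duplicate_control_replicates=duplicates,
                     chrom_lengths_cm={"chr1": 50.0}, snps_per_cm=snps_per_cm)


def _experiment_seeds(master_seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(master_seed).generate_state(n) % (2**31)


def null_calibration_study(n_experiments: int = 200, master_seed: int = 0,
                           mean_coverage: float = 40.0) -> np.ndarray:
    """Max smoothed -log10(P) of each neutral (no-QTL) experiment.

    The fraction of entries at or above the threshold of 4 estimates the
    genome-wide false-positive rate of the scan.
    """
    maxima = np.empty(n_experiments)
    for i, seed in enumerate(_experiment_seeds(master_seed, n_experiments)):
        cfg = _neutral_config(int(seed), mean_coverage=mean_coverage)
        pools, _, panel = simulate_experiment(cfg)
        scan, _, _ = run_scan(pools, panel, cfg.genetic_map())
        maxima[i] = np.nanmax(scan["neglog10p_smooth"].to_numpy())
    return maxima


@dataclass
class PowerResult:
    detected: list[bool] = field(default_factory=list)
    localized: list[bool] = field(default_factory=list)   # peak within 1 cM
    delta_positive: list[bool] = field(default_factory=list)


def power_study(n_sims: int = 100, master_seed: int = 0, s: float = 0.5,
                base_freq: float = 0.25, qtl_cm: float = 25.0,
                mean_coverage: float = 67.0, tol_cm: float = 1.0) -> PowerResult:
    """Recovery of one planted viability QTL (one favoured founder).

    Per simulation: does any called peak reach the threshold, does the
    strongest peak fall within ``tol_cm`` of the true position, and is the
    favoured founder's (selected - control) frequency change positive at the
    peak window?
    """
    F = 8
    effects = np.zeros(F)
    effects[0] = s
    weights = np.array([base_freq] + [(1 - base_freq) / (F - 1)] * (F - 1))
    model = QTLEffectModel(loci=[("chr1", qtl_cm, effects)])
    result = PowerResult()
    for seed in _experiment_seeds(master_seed, n_sims):
        cfg = _neutral_config(int(seed), mean_coverage=mean_coverage)
        cfg.founder_weights = {"chr1": weights}
        pools, _, panel = simulate_experiment(cfg, model)
        gmap = cfg.genetic_map()
        scan, hap, windows = run_scan(pools, panel, gmap)
        peaks = call_peaks(scan, gmap, threshold=THRESHOLD)
        if not peaks:
            result.detected.append(False)
            result.localized.append(False)
            continue
        best = max(peaks, key=lambda p: p.peak_value)
        result.detected.append(True)
        result.localized.append(abs(best.peak_cm - qtl_cm) <= tol_cm)
        delta = haplotype_frequency_change(hap, pool_metadata(pools))
        centers = np.array([w.center_cm for w in windows])
        w_idx = int(np.argmin(np.abs(centers - best.peak_cm)))
        result.delta_positive.append(bool(delta[w_idx, 0] > 0))
    return result


def duplicate_null_study(n_sims: int = 100, master_seed: int = 0,
                         n_replicates: int = 5,
                         mean_coverage: float = 40.0) -> np.ndarray:
    """Max smoothed -log10(P) of the duplicate (A/B) control-pool contrast.

    Every replicate carries two independent control pools from the same base
    population; the scan pipeline is re-run with the A/B label as the
    treatment factor. Under an accurate pipeline the contrast should stay
    far below the threshold.
    """
    from .haplotypes import compute_snp_frequencies, define_windows, scan_haplotypes

    maxima = np.empty(n_sims)
    for i, seed in enumerate(_experiment_seeds(master_seed, n_sims)):
        cfg = _neutral_config(int(seed), mean_coverage=mean_coverage,
                              n_replicates=n_replicates,
                              duplicates=tuple(range(1, n_replicates + 1)))
        cfg.survival_target = 0.5  # selected pools are unused in this contrast
        pools, _, panel = simulate_experiment(cfg)
        controls = [p for p in pools if p.treatment == "control"]
        gmap = cfg.genetic_map()
        freqs = compute_snp_frequencies(controls, panel)
        windows = define_windows(gmap, panel)
        hap = scan_haplotypes(freqs, panel, windows)
        scan = duplicate_control_contrast(hap, pool_metadata(controls), gmap)
        maxima[i] = np.nanmax(scan["neglog10p_smooth"].to_numpy())
    return maxima
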