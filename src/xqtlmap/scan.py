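"""Replicated interaction genome scan on founder haplotype frequencies.

Per window, estimated founder frequencies are arcsine square-root transformed
(ASF) and tested for treatment differentiation with the balanced three-way
ANOVA ``ASF ~ Treatment + Haplotype + Treatment x Haplotype``, where the
Treatment x Haplotype interaction mean square is tested against the
Replicate x Treatment x Haplotype mean square (replicates act as blocks):

    F = MS(TxH) / MS(RxTxH),  df1 = (t-1)(f-1),  df2 = (r-1)(t-1)(f-1)

The genome-wide -log10(P) series is LOESS smoothed (tricube weights, local
polynomial) per chromosome in cM coordinates, QTL peaks are called above a
fixed threshold (default 4, inclusive) and assigned 3-unit-drop confidence
intervals, and per-founder frequency changes (selected minus control) are
reported at any window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genmap import GeneticMap
from .haplotypes import HaplotypeFreqTable
from .simdata import ConfigError

__all__ = [
    "asf_transform", "window_anova", "anova_scan", "assemble_asf_table",
    "loess_smooth", "smooth_scan", "call_peaks", "QTLPeak",
    "haplotype_frequency_change", "duplicate_control_contrast", "run_scan",
]

_P_FLOOR = 1e-300  # p reported when the error mean square vanishes


def asf_transform(h) -> np.ndarray | float:
    """Arcsine square-root (variance stabilizing) transform of a frequency."""
    h_arr = np.asarray(h, dtype=float)
    if np.any(h_arr < -1e-9) or np.any(h_arr > 1 + 1e-9):
        raise ValueError("frequencies must lie in [0, 1]")
    out = np.arcsin(np.sqrt(np.clip(h_arr, 0.0, 1.0)))
    return float(out) if np.isscalar(h) else out


# ---------------------------------------------------------------------------
# ANOVA


def _anova_arrays(y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Balanced 3-way interaction F test, vectorized over leading axes.

    ``y`` has shape (..., r, t, f). Returns (F, p, df1, df2) with the
    Treatment x Haplotype mean square tested against the
    Replicate x Treatment x Haplotype mean square.
    """
    r, t, f = y.shape[-3:]
    if r < 2 or t < 2 or f < 2:
        raise ValueError("need >= 2 replicates, treatments and haplotypes")
    m = y.mean(axis=(-3, -2, -1), keepdims=True)
    y_r = y.mean(axis=(-2, -1), keepdims=True)    # replicate means
    y_t = y.mean(axis=(-3, -1), keepdims=True)
    y_f = y.mean(axis=(-3, -2), keepdims=True)
    y_tf = y.mean(axis=-3, keepdims=True)
    y_rt = y.mean(axis=-1, keepdims=True)
    y_rf = y.mean(axis=-2, keepdims=True)
    int_tf = y_tf - y_t - y_f + m
    resid = y - y_rt - y_rf - y_tf + y_r + y_t + y_f - m
    ss_th = r * np.sum(int_tf ** 2, axis=(-3, -2, -1))
    ss_rth = np.sum(resid ** 2, axis=(-3, -2, -1))
    df1 = (t - 1) * (f - 1)
    df2 = (r - 1) * (t - 1) * (f - 1)
    # rounding floor: sums of squares below ~machine precision of the total
    # variation are structural zeros, not signal
    tol = 1e-20 * np.maximum(np.sum((y - m) ** 2, axis=(-3, -2, -1)), 1e-300)
    ss_th = np.where(ss_th <= tol, 0.0, ss_th)
    ss_rth = np.where(ss_rth <= tol, 0.0, ss_rth)
    ms_th = ss_th / df1
    ms_rth = ss_rth / df2
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(ss_th <= 0, 0.0, ms_th / np.where(ms_rth > 0, ms_rth, np.nan))
    p = np.where(ss_th <= 0, 1.0, stats.f.sf(F, df1, df2))
    degenerate = (ss_rth <= 0) & (ss_th > 0)
    if np.any(degenerate):
        warnings.warn("zero error mean square in some windows; p floored")
        F = np.where(degenerate, np.inf, F)
        p = np.where(degenerate, _P_FLOOR, p)
    return F, p, df1, df2


def window_anova(table: np.ndarray) -> tuple[float, int, int, float, float]:
    """Interaction ANOVA for one window.

    Parameters
    ----------
    table
        Balanced ASF array of shape (replicates, treatments, haplotypes).

    Returns
    -------
    (F, df1, df2, p, -log10 p)
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 3:
        raise ValueError("table must be (replicate, treatment, haplotype)")
    if np.any(np.isnan(table)):
        bad = np.argwhere(np.isnan(table))
        raise ValueError(f"unbalanced table: missing cells at (r,t,f) {bad.tolist()}")
    F, p, df1, df2 = _anova_arrays(table)
    return float(F), df1, df2, float(p), float(-np.log10(p))


def assemble_asf_table(hap: HaplotypeFreqTable, meta: pd.DataFrame,
                       treatment_field: str = "treatment",
                       duplicate_policy: str = "average"
                       ) -> tuple[np.ndarray, np.ndarray, list, list]:
    """Build the (W, r, t, f) ASF array from per-pool estimates.

    Pools sharing (replicate, treatment level) — the duplicate A/B control
    pools — are combined according to ``duplicate_policy``: their frequency
    estimates are averaged ("average"), the first is kept ("first"), or an
    error is raised ("error"). Returns (asf, valid_window_mask, replicates,
    treatment_levels).
    """
    if duplicate_policy not in {"average", "first", "error"}:
        raise ConfigError(f"unknown duplicate policy {duplicate_policy!r}")
    meta = meta.set_index("pool_id").loc[hap.pool_ids].reset_index()
    reps = sorted(meta["replicate"].unique())
    levels = sorted(meta[treatment_field].unique())
    if len(levels) != 2:
        raise ValueError(f"expected 2 treatment levels, got {levels}")
    W, _, F = hap.est.shape
    freq = np.full((W, len(reps), len(levels), F), np.nan)
    for ri, r in enumerate(reps):
        for ti, t in enumerate(levels):
            cols = np.flatnonzero((meta["replicate"] == r).to_numpy()
                                  & (meta[treatment_field] == t).to_numpy())
            if cols.size == 0:
                continue
            if cols.size > 1 and duplicate_policy == "error":
                raise ValueError(f"multiple pools for replicate {r}, level {t}")
            if duplicate_policy == "first":
                cols = cols[:1]
            freq[:, ri, ti, :] = np.nanmean(hap.est[:, cols, :], axis=1)
    valid = ~np.isnan(freq).any(axis=(1, 2, 3))
    asf = np.arcsin(np.sqrt(np.clip(freq, 0.0, 1.0)))
    return asf, valid, reps, levels


def anova_scan(hap: HaplotypeFreqTable, meta: pd.DataFrame, gmap: GeneticMap,
               treatment_field: str = "treatment",
               duplicate_policy: str = "average") -> pd.DataFrame:
    """Per-window interaction ANOVA over all windows; returns a ScanTable.

    Windows flagged low-SNP, non-identifiable in any pool, or with missing
    estimates carry NaN statistics but stay on the grid (annotated in
    ``flag``).
    """
    asf, valid, reps, levels = assemble_asf_table(hap, meta, treatment_field,
                                                  duplicate_policy)
    W = len(hap.windows)
    usable = valid & np.array([not w.low_snp for w in hap.windows])
    Fstat = np.full(W, np.nan)
    p = np.full(W, np.nan)
    df1 = df2 = 0
    if usable.any():
        Fs, ps, df1, df2 = _anova_arrays(asf[usable])
        Fstat[usable] = Fs
        p[usable] = ps
    flags = []
    for w, win in enumerate(hap.windows):
        notes = []
        if win.low_snp:
            notes.append("low_snp")
        if not hap.identifiable[w].all():
            notes.append("rank_deficient")
        if not valid[w]:
            notes.append("missing")
        flags.append(",".join(notes) if notes else "ok")
    with np.errstate(divide="ignore"):
        neglog = -np.log10(p)
    return pd.DataFrame({
        "chrom": [w.chrom for w in hap.windows],
        "center_cM": [w.center_cm for w in hap.windows],
        "center_bp": [int(np.round(gmap.bp(w.chrom, w.center_cm)))
                      for w in hap.windows],
        "F": Fstat, "df1": df1, "df2": df2, "p": p,
        "neglog10p_raw": neglog,
        "neglog10p_smooth": np.nan,
        "flag": flags,
    })


# ---------------------------------------------------------------------------
# LOESS


def loess_smooth(x: np.ndarray, y: np.ndarray, span: float = 0.3,
                 degree: int = 2) -> np.ndarray:
    """Locally weighted polynomial regression (tricube weights).

    For each point the nearest ``ceil(span * n)`` neighbours get tricube
    weights scaled by the neighbourhood radius, and a degree-``degree``
    weighted polynomial is evaluated at the point.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    q = int(np.ceil(span * n))
    if q < degree + 1:
        raise ConfigError(
            f"span {span} gives {q} local points < {degree + 1} coefficients")
    q = min(q, n)
    out = np.empty(n)
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    for i in range(n):
        d = np.abs(xs - xs[i])
        idx = np.argpartition(d, q - 1)[:q]
        dmax = d[idx].max()
        if dmax == 0:
            out[i] = ys[idx].mean()
            continue
        w = (1 - (d[idx] / dmax) ** 3) ** 3
        xc = xs[idx] - xs[i]
        X = np.vander(xc, degree + 1, increasing=True)
        sw = np.sqrt(np.maximum(w, 0))
        beta, *_ = np.linalg.lstsq(X * sw[:, None], ys[idx] * sw, rcond=None)
        out[i] = beta[0]
    inv = np.empty(n, dtype=int)
    inv[order] = np.arange(n)
    return out[inv]


def smooth_scan(scan: pd.DataFrame, span_cm: float = 5.0,
                degree: int = 2) -> pd.DataFrame:
    """LOESS smooth the -log10(P) series per chromosome in cM coordinates.

    ``span_cm`` is converted per chromosome into the fraction of windows a
    genetic distance of that many cM covers.
    """
    scan = scan.copy()
    for chrom, sub in scan.groupby("chrom", sort=False):
        ok = sub["neglog10p_raw"].notna()
        x = sub.loc[ok, "center_cM"].to_numpy()
        y = sub.loc[ok, "neglog10p_raw"].to_numpy()
        if x.size < 10:
            warnings.warn(f"{chrom}: <10 windows, smoothing skipped")
            scan.loc[sub.index[ok], "neglog10p_smooth"] = y
            continue
        extent = x.max() - x.min()
        frac = 1.0 if extent == 0 else min(1.0, span_cm / extent)
        scan.loc[sub.index[ok], "neglog10p_smooth"] = loess_smooth(
            x, y, span=frac, degree=degree)
    return scan


# ---------------------------------------------------------------------------
# peaks


@dataclass
class QTLPeak:
    """A called QTL: peak plus drop-based confidence interval."""

    id: str
    chrom: str
    peak_cm: float
    peak_bp: int
    start_cm: float
    end_cm: float
    start_bp: int
    end_bp: int
    peak_value: float
    low_recombination: bool = False


def call_peaks(scan: pd.DataFrame, gmap: GeneticMap, threshold: float = 4.0,
               drop: float = 3.0, lowrec_cutoff: float = 0.5) -> list[QTLPeak]:
    """Call QTL peaks on the smoothed scan.

    Local maxima with smoothed value >= ``threshold`` (inclusive) become
    peaks; each interval extends outward to the first window center whose
    smoothed value falls to ``peak - drop`` or below (or to the terminal
    window). Candidate peaks inside a stronger peak's interval are merged
    into it. Peaks whose intervals mostly lie in regions with local
    recombination rate < ``lowrec_cutoff`` cM/Mb are flagged.
    """
    if threshold <= 0:
        raise ConfigError("threshold must be positive")
    peaks: list[QTLPeak] = []
    for chrom, sub in scan.groupby("chrom", sort=False):
        sub = sub.sort_values("center_cM")
        ok = sub["neglog10p_smooth"].notna()
        y = sub.loc[ok, "neglog10p_smooth"].to_numpy()
        cm = sub.loc[ok, "center_cM"].to_numpy()
        if y.size == 0:
            continue
        is_max = np.ones(y.size, dtype=bool)
        if y.size > 1:
            is_max[:-1] &= y[:-1] >= y[1:]
            is_max[1:] &= y[1:] >= y[:-1]
        cand = np.flatnonzero(is_max & (y >= threshold))
        cand = cand[np.argsort(y[cand])[::-1]]
        intervals: list[tuple[int, int]] = []
        for c in cand:
            if any(lo <= c <= hi for lo, hi in intervals):
                continue  # merged into a stronger peak
            lo = c
            while lo > 0 and y[lo] > y[c] - drop:
                lo -= 1
            hi = c
            while hi < y.size - 1 and y[hi] > y[c] - drop:
                hi += 1
            intervals.append((lo, hi))
            rates = gmap.recomb_rate(chrom, gmap.bp(chrom, cm[lo:hi + 1]))
            flagged = np.mean(rates < lowrec_cutoff) > 0.5
            peaks.append(QTLPeak(
                id="", chrom=chrom,
                peak_cm=float(cm[c]),
                peak_bp=int(np.round(gmap.bp(chrom, cm[c]))),
                start_cm=float(cm[lo]), end_cm=float(cm[hi]),
                start_bp=int(np.round(gmap.bp(chrom, cm[lo]))),
                end_bp=int(np.round(gmap.bp(chrom, cm[hi]))),
                peak_value=float(y[c]), low_recombination=bool(flagged)))
    peaks.sort(key=lambda p: (p.chrom, p.peak_cm))
    for i, p in enumerate(peaks):
        p.id = f"QTL-{chr(ord('A') + i)}" if i < 26 else f"QTL-{i + 1}"
    return peaks


_PEAK_COLUMNS = ["id", "chrom", "peak_bp", "peak_cM", "interval_start_bp",
                 "interval_end_bp", "size_kb", "size_cM", "peak_neglog10p",
                 "low_recombination"]


def peaks_to_dataframe(peaks: list[QTLPeak]) -> pd.DataFrame:
    if not peaks:
        return pd.DataFrame(columns=_PEAK_COLUMNS)
    return pd.DataFrame([{
        "id": p.id, "chrom": p.chrom, "peak_bp": p.peak_bp, "peak_cM": p.peak_cm,
        "interval_start_bp": p.start_bp, "interval_end_bp": p.end_bp,
        "size_kb": (p.end_bp - p.start_bp) / 1e3,
        "size_cM": p.end_cm - p.start_cm,
        "peak_neglog10p": p.peak_value,
        "low_recombination": p.low_recombination,
    } for p in peaks])


# ---------------------------------------------------------------------------
# frequency change and duplicate-control null


def haplotype_frequency_change(hap: HaplotypeFreqTable, meta: pd.DataFrame
                               ) -> np.ndarray:
    """(W, F) mean over replicates of (selected - control) founder frequency.

    Duplicate control pools are averaged within replicate first. Rows are NaN
    where either treatment is missing; valid rows sum to 0.
    """
    asf_unused, valid, reps, levels = assemble_asf_table(hap, meta)  # noqa: F841
    meta = meta.set_index("pool_id").loc[hap.pool_ids].reset_index()
    W, _, F = hap.est.shape
    delta = np.full((W, F), np.nan)
    per_rep = np.full((W, len(reps), F), np.nan)
    for ri, r in enumerate(reps):
        sel = np.flatnonzero(((meta["replicate"] == r)
                              & (meta["treatment"] == "selected")).to_numpy())
        ctl = np.flatnonzero(((meta["replicate"] == r)
                              & (meta["treatment"] == "control")).to_numpy())
        if sel.size == 0 or ctl.size == 0:
            warnings.warn(f"replicate {r}: missing a treatment; skipped")
            continue
        per_rep[:, ri, :] = (np.nanmean(hap.est[:, sel, :], axis=1)
                             - np.nanmean(hap.est[:, ctl, :], axis=1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        delta = np.nanmean(per_rep, axis=1)
    return delta


def duplicate_control_contrast(hap: HaplotypeFreqTable, meta: pd.DataFrame,
                               gmap: GeneticMap, span_cm: float = 5.0,
                               degree: int = 2) -> pd.DataFrame:
    """Empirical-null scan contrasting duplicate (A/B) control pools.

    Restricts to replicates with both an A and a B control pool, relabels the
    duplicate tag as the treatment factor, and runs the identical ANOVA +
    smoothing pipeline.
    """
    meta = meta.set_index("pool_id").loc[hap.pool_ids].reset_index()
    dup = meta[(meta["treatment"] == "control")
               & meta["duplicate_label"].isin(["A", "B"])]
    good_reps = [r for r, g in dup.groupby("replicate")
                 if {"A", "B"} <= set(g["duplicate_label"])]
    if len(good_reps) < 2:
        raise ValueError("need >= 2 replicates with A/B duplicate control pools")
    keep = dup[dup["replicate"].isin(good_reps)]
    idx = [hap.pool_ids.index(p) for p in keep["pool_id"]]
    sub = HaplotypeFreqTable(windows=hap.windows,
                             pool_ids=[hap.pool_ids[i] for i in idx],
                             est=hap.est[:, idx, :], n_snps=hap.n_snps[:, idx],
                             residual=hap.residual[:, idx],
                             identifiable=hap.identifiable[:, idx],
                             founders=hap.founders)
    submeta = keep[["pool_id", "replicate", "duplicate_label"]].copy()
    submeta["treatment"] = submeta["duplicate_label"]
    scan = anova_scan(sub, submeta, gmap, treatment_field="treatment",
                      duplicate_policy="error")
    return smooth_scan(scan, span_cm=span_cm, degree=degree)


# ---------------------------------------------------------------------------
# one-call pipeline


def run_scan(pools, panel, gmap, *, width_cm: float = 1.5, step_cm: float = 0.5,
             min_depth: int = 5, min_snps: int = 25, span_cm: float = 5.0,
             degree: int = 2, duplicate_policy: str = "average"):
    """counts -> SNP frequencies -> haplotypes -> ANOVA -> smoothing.

    Returns ``(scan_table, hap_table, windows)``.
    """
    from .haplotypes import compute_snp_frequencies, define_windows, scan_haplotypes
    from .simdata import pool_metadata

    freqs = compute_snp_frequencies(pools, panel, min_depth=min_depth)
    windows = define_windows(gmap, panel, width_cm=width_cm, step_cm=step_cm,
                             min_snps=min_snps)
    hap = scan_haplotypes(freqs, panel, windows)
    meta = pool_metadata(pools)
    scan = anova_scan(hap, meta, gmap, duplicate_policy=duplicate_policy)
    scan = smooth_scan(scan, span_cm=span_cm, degree=degree)
    return scan, hap, windows
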