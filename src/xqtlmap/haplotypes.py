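"""Founder haplotype frequency deconvolution from pooled SNP frequencies.

Pool-seq read counts are converted to per-SNP REF allele frequencies, the
genome is tiled with overlapping genetic-distance windows (default 1.5 cM
wide, 0.5 cM step), and within each window the 8-founder haplotype frequency
vector ``h`` of each pool is recovered by constrained least squares:

    minimize ||A h - y||^2   subject to   h >= 0,  sum(h) = 1

where row i of ``A`` is the founders' REF indicator at SNP i and ``y_i`` is
the pool's observed REF frequency.  The program is solved by non-negative
least squares on an augmented system (the sum constraint enters as a heavily
weighted extra row); when the window design matrix is rank-deficient a tiny
ridge is added so the returned vector is the minimum-norm minimizer, and the
window x pool estimate is flagged as non-identifiable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .genmap import GeneticMap
from .simdata import ConfigError, FounderPanel, PoolCounts

__all__ = [
    "SNPFrequencyTable", "Window", "HaplotypeFreqVector", "HaplotypeFreqTable",
    "compute_snp_frequencies", "define_windows", "estimate_window_haplotypes",
    "scan_haplotypes", "solve_simplex_lsq",
]

logger = logging.getLogger(__name__)

# weight of the sum-to-one row in the augmented NNLS system, and the ridge
# applied only to rank-deficient windows (selects the minimum-norm minimizer)
_SUM_WEIGHT = 1e6
_RIDGE = 1e-6


@dataclass
class SNPFrequencyTable:
    """Per-(SNP, pool) REF frequencies; NaN marks depth below the minimum."""

    freq: np.ndarray          # (S, P) float, NaN = missing
    depth: np.ndarray         # (S, P) int
    pool_ids: list[str]
    informative: np.ndarray   # (S,) bool — panel-informative and fully called
    min_depth: int

    @property
    def n_pools(self) -> int:
        return len(self.pool_ids)


@dataclass
class Window:
    """One genetic-distance window and its usable member SNPs."""

    chrom: str
    center_cm: float
    start_cm: float
    end_cm: float
    snp_indices: np.ndarray   # indices into the panel (informative members)
    low_snp: bool = False     # fewer members than the configured minimum

    @property
    def n_snps(self) -> int:
        return self.snp_indices.size


@dataclass
class HaplotypeFreqVector:
    """Estimated founder-frequency simplex for one (window, pool)."""

    pool_id: str
    window: Window
    frequencies: np.ndarray | None   # (F,) on the simplex, or None if MISSING
    residual: float = np.nan         # ||A h - y||
    n_snps: int = 0
    identifiable: bool = True

    @property
    def missing(self) -> bool:
        return self.frequencies is None


@dataclass
class HaplotypeFreqTable:
    """Dense window x pool x founder estimate array with fit diagnostics."""

    windows: list[Window]
    pool_ids: list[str]
    est: np.ndarray          # (W, P, F), NaN rows where estimation failed
    n_snps: np.ndarray       # (W, P) int
    residual: np.ndarray     # (W, P)
    identifiable: np.ndarray  # (W, P) bool
    founders: list[str] = field(default_factory=list)

    def to_dataframe(self, gmap: GeneticMap | None = None) -> pd.DataFrame:
        rows = []
        for w, win in enumerate(self.windows):
            bp = int(np.round(gmap.bp(win.chrom, win.center_cm))) if gmap else -1
            for p, pid in enumerate(self.pool_ids):
                rows.append({
                    "chrom": win.chrom, "window_center_cM": win.center_cm,
                    "window_center_bp": bp, "pool_id": pid,
                    **{f"h{f+1}": self.est[w, p, f] for f in range(self.est.shape[2])},
                    "n_snps": int(self.n_snps[w, p]),
                    "residual": self.residual[w, p],
                    "flag": "ok" if self.identifiable[w, p] else "rank_deficient",
                })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------


def compute_snp_frequencies(pools: list[PoolCounts], panel: FounderPanel,
                            min_depth: int = 5,
                            require_informative: bool = True) -> SNPFrequencyTable:
    """REF allele frequency of every SNP in every pool.

    Sites with depth below ``min_depth`` are NaN per pool; sites that carry no
    haplotype information (all founders identical, or any founder call
    missing) are masked globally when ``require_informative`` is set.
    """
    S = panel.n_snps
    freq = np.full((S, len(pools)), np.nan)
    depth = np.zeros((S, len(pools)), dtype=np.int64)
    panel_pos = panel.snps["pos"].to_numpy()
    panel_chrom = panel.snps["chrom"].to_numpy()
    for j, pool in enumerate(pools):
        if pool.pos.shape != panel_pos.shape or np.any(pool.pos != panel_pos) \
                or np.any(pool.chrom != panel_chrom):
            k = 0
            if pool.pos.shape == panel_pos.shape:
                bad = (pool.pos != panel_pos) | (pool.chrom != panel_chrom)
                k = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"pool {pool.pool_id!r} coordinates disagree with panel "
                f"(first offending site index {k}: "
                f"{pool.chrom[k] if k < len(pool.chrom) else '?'}:"
                f"{pool.pos[k] if k < len(pool.pos) else '?'})")
        d = pool.depth
        depth[:, j] = d
        ok = d >= max(min_depth, 1)
        freq[ok, j] = pool.ref_count[ok] / d[ok]
    informative = panel.informative_mask() & panel.fully_called_mask()
    if require_informative:
        freq[~informative, :] = np.nan
    logger.info("SNP frequencies: %d sites, %d informative, %d pools",
                S, int(informative.sum()), len(pools))
    return SNPFrequencyTable(freq=freq, depth=depth,
                             pool_ids=[p.pool_id for p in pools],
                             informative=informative, min_depth=min_depth)


def define_windows(gmap: GeneticMap, panel: FounderPanel, width_cm: float = 1.5,
                   step_cm: float = 0.5, min_snps: int = 25) -> list[Window]:
    """Tile each chromosome with overlapping windows of informative SNPs.

    Window centers run from ``width/2`` to ``length - width/2`` in steps of
    ``step_cm``. Windows holding fewer than ``min_snps`` usable SNPs are
    flagged (and excluded from the scan downstream).
    """
    if step_cm <= 0:
        raise ConfigError("step_cm must be positive")
    if step_cm >= width_cm:
        warnings.warn("step >= width: windows no longer overlap")
    usable = panel.informative_mask() & panel.fully_called_mask()
    windows: list[Window] = []
    for chrom, sl in panel.chrom_slices().items():
        length = gmap.length_cm(chrom)
        snp_cm = gmap.cm(chrom, panel.snps["pos"].to_numpy()[sl])
        local_usable = np.flatnonzero(usable[sl])
        usable_cm = snp_cm[local_usable]
        first, last = width_cm / 2.0, length - width_cm / 2.0
        if last < first:
            continue
        n = int(np.floor((last - first) / step_cm + 1e-9)) + 1
        for center in first + np.arange(n) * step_cm:
            lo, hi = center - width_cm / 2.0, center + width_cm / 2.0
            inside = local_usable[(usable_cm >= lo) & (usable_cm <= hi)]
            windows.append(Window(chrom=chrom, center_cm=float(center),
                                  start_cm=lo, end_cm=hi,
                                  snp_indices=inside + sl.start,
                                  low_snp=inside.size < min_snps))
    logger.info("defined %d windows (%d flagged low-SNP)",
                len(windows), sum(w.low_snp for w in windows))
    return windows


def solve_simplex_lsq(A: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """Solve min ||A h - y||^2 s.t. h >= 0, sum(h) = 1.

    Returns ``(h, residual_norm, identifiable)``. The equality constraint is
    enforced through a heavily weighted augmented row; for rank-deficient
    ``A`` (stacked with the sum row) a tiny ridge picks the minimum-norm
    minimizer and ``identifiable`` is False.
    """
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float)
    n, F = A.shape
    ones = np.ones((1, F))
    identifiable = np.linalg.matrix_rank(np.vstack([A, ones])) >= F
    blocks_A = [A, _SUM_WEIGHT * ones]
    blocks_y = [y, np.array([_SUM_WEIGHT])]
    if not identifiable:
        blocks_A.append(np.sqrt(_RIDGE) * np.eye(F))
        blocks_y.append(np.zeros(F))
    h, _ = nnls(np.vstack(blocks_A), np.concatenate(blocks_y))
    h = np.clip(h, 0.0, None)
    total = h.sum()
    h = h / total if total > 0 else np.full(F, 1.0 / F)
    residual = float(np.linalg.norm(A @ h - y))
    return h, residual, identifiable


def estimate_window_haplotypes(window: Window, freqs: SNPFrequencyTable,
                               panel: FounderPanel, pool_id: str) -> HaplotypeFreqVector:
    """Deconvolve one pool's founder frequencies in one window."""
    j = freqs.pool_ids.index(pool_id)
    y_all = freqs.freq[window.snp_indices, j]
    ok = ~np.isnan(y_all)
    if not ok.any():
        logger.warning("window %s:%.2f pool %s: no usable SNPs",
                       window.chrom, window.center_cm, pool_id)
        return HaplotypeFreqVector(pool_id=pool_id, window=window, frequencies=None)
    A = (panel.alleles[window.snp_indices[ok]] == 1).astype(float)
    h, resid, ident = solve_simplex_lsq(A, y_all[ok])
    return HaplotypeFreqVector(pool_id=pool_id, window=window, frequencies=h,
                               residual=resid, n_snps=int(ok.sum()),
                               identifiable=ident)


def scan_haplotypes(freqs: SNPFrequencyTable, panel: FounderPanel,
                    windows: list[Window],
                    pool_ids: list[str] | None = None) -> HaplotypeFreqTable:
    """Estimate founder frequencies for every (window, pool) combination."""
    pool_ids = pool_ids or freqs.pool_ids
    cols = [freqs.pool_ids.index(p) for p in pool_ids]
    W, P, F = len(windows), len(pool_ids), panel.n_founders
    est = np.full((W, P, F), np.nan)
    n_snps = np.zeros((W, P), dtype=np.int64)
    residual = np.full((W, P), np.nan)
    ident = np.ones((W, P), dtype=bool)
    ref_ind = (panel.alleles == 1).astype(float)
    last_chrom = None
    for w, win in enumerate(windows):
        if win.chrom != last_chrom:
            logger.info("estimating haplotypes on %s", win.chrom)
            last_chrom = win.chrom
        if win.snp_indices.size == 0:
            continue
        A_full = ref_ind[win.snp_indices]
        Y = freqs.freq[win.snp_indices][:, cols]
        finite = ~np.isnan(Y)
        all_ok = finite.all(axis=0)
        # pools with complete data in this window share the design matrix
        shared = None
        for p in range(P):
            if not finite[:, p].any():
                continue
            if all_ok[p]:
                if shared is None:
                    shared = A_full
                h, r, flag = solve_simplex_lsq(shared, Y[:, p])
                n = A_full.shape[0]
            else:
                m = finite[:, p]
                h, r, flag = solve_simplex_lsq(A_full[m], Y[m, p])
                n = int(m.sum())
            est[w, p] = h
            residual[w, p] = r
            n_snps[w, p] = n
            ident[w, p] = flag
    return HaplotypeFreqTable(windows=windows, pool_ids=list(pool_ids), est=est,
                              n_snps=n_snps, residual=residual, identifiable=ident,
                              founders=list(panel.founders))
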