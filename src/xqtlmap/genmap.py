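"""Genetic maps: bp <-> cM interpolation and local recombination rate.

A map is a per-chromosome list of (bp, cM) anchors.  Physical positions are
1-based. Between anchors both coordinates are interpolated linearly, so the
bp->cM conversion is piecewise linear and invertible wherever cM is strictly
increasing (in flat stretches the inverse returns the left edge).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GeneticMap"]


@dataclass
class GeneticMap:
    """Piecewise-linear genetic map.

    Parameters
    ----------
    anchors
        Mapping of chromosome name to ``(bp, cM)`` arrays. ``bp`` must be
        strictly increasing and ``cM`` non-decreasing.
    """

    anchors: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (bp, cm) in self.anchors.items():
            bp = np.asarray(bp, dtype=float)
            cm = np.asarray(cm, dtype=float)
            if bp.size < 2:
                raise ValueError(f"map for {chrom!r} needs >= 2 anchors")
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"bp positions not strictly increasing on {chrom!r}")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"cM positions decrease on {chrom!r}")
            if np.any(cm < 0):
                raise ValueError(f"negative cM on {chrom!r}")
            clean[chrom] = (bp, cm)
        self.anchors = clean

    # -- constructors ---------------------------------------------------
    @classmethod
    def linear(cls, chrom_lengths_cm: dict[str, float],
               rate_cm_per_mb: float = 2.0) -> "GeneticMap":
        """Uniform-rate map: ``rate_cm_per_mb`` cM per megabase everywhere."""
        anchors = {}
        for chrom, length_cm in chrom_lengths_cm.items():
            length_bp = length_cm / rate_cm_per_mb * 1e6
            anchors[chrom] = (np.array([1.0, length_bp]),
                             np.array([0.0, float(length_cm)]))
        return cls(anchors)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GeneticMap":
        anchors = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            sub = sub.sort_values("bp")
            anchors[str(chrom)] = (sub["bp"].to_numpy(float), sub["cM"].to_numpy(float))
        return cls(anchors)

    @classmethod
    def read_tsv(cls, path) -> "GeneticMap":
        df = pd.read_csv(path, sep="\t")
        missing = {"chrom", "bp", "cM"} - set(df.columns)
        if missing:
            raise ValueError(f"genetic map file missing columns: {sorted(missing)}")
        return cls.from_dataframe(df)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for chrom, (bp, cm) in self.anchors.items():
            rows.append(pd.DataFrame({"chrom": chrom, "bp": bp.astype(int), "cM": cm}))
        return pd.concat(rows, ignore_index=True)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    # -- queries --------------------------------------------------------
    @property
    def chroms(self) -> list[str]:
        return list(self.anchors)

    def length_cm(self, chrom: str) -> float:
        return float(self.anchors[chrom][1][-1])

    def length_bp(self, chrom: str) -> float:
        return float(self.anchors[chrom][0][-1])

    def cm(self, chrom: str, bp) -> np.ndarray:
        """Interpolate genetic position (cM) at physical position(s)."""
        b, c = self.anchors[chrom]
        return np.interp(np.asarray(bp, dtype=float), b, c)

    def bp(self, chrom: str, cm) -> np.ndarray:
        """Interpolate physical position (bp) at genetic position(s)."""
        b, c = self.anchors[chrom]
        return np.interp(np.asarray(cm, dtype=float), c, b)

    def recomb_rate(self, chrom: str, bp) -> np.ndarray:
        """Local recombination rate (cM/Mb) from finite differences on anchors."""
        b, c = self.anchors[chrom]
        rates = np.diff(c) / np.diff(b) * 1e6  # per anchor interval
        idx = np.clip(np.searchsorted(b, np.asarray(bp, dtype=float), side="right") - 1,
                      0, rates.size - 1)
        return rates[idx]
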