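"""Readers, writers, run configuration and the end-to-end pipeline.

Formats (all plain text):

* Founder panel TSV: ``CHROM POS REF ALT`` then one column per founder with
  ``R``/``A``/``N`` codes (REF, ALT, missing). VCF input (founders as
  samples) is also accepted; multi-allelic records are rejected site-wise.
* Pool counts: sync-style TSV ``CHROM POS REF`` then one ``ref:alt`` column
  per pool, with a companion metadata TSV
  (``pool_id replicate treatment duplicate_label``). The explicit ``ref:alt``
  dialect (rather than 6-field nucleotide sync) is used because sites are
  biallelic and founder-typed.
* Genetic map TSV: ``chrom bp cM``. Scan TSV / peaks TSV use 1-based
  inclusive coordinates; peaks BED is 0-based half-open.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genmap import GeneticMap
from .simdata import (MISSING, ConfigError, FounderPanel, PoolCounts, QTLEffectModel,
                      SimConfig, SimTruth, pool_metadata, simulate_experiment)

__all__ = [
    "read_founder_panel", "write_founder_panel", "read_pool_counts",
    "write_pool_counts", "write_sim_truth", "write_peaks_bed", "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

_CODE_TO_ALLELE = {"R": 1, "A": 0, "N": MISSING}
_ALLELE_TO_CODE = {1: "R", 0: "A", MISSING: "N"}


# ---------------------------------------------------------------------------
# founder panel


def read_founder_panel(path, format: str = "tsv") -> FounderPanel:
    if format == "tsv":
        return _read_panel_tsv(path)
    if format == "vcf":
        return _read_panel_vcf(path)
    raise ConfigError(f"unknown panel format {format!r}")


def _read_panel_tsv(path) -> FounderPanel:
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str})
    if df.empty:
        raise ValueError(f"{path}: empty founder panel file")
    fixed = ["CHROM", "POS", "REF", "ALT"]
    missing = set(fixed) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    founders = [c for c in df.columns if c not in fixed]
    if not founders:
        raise ValueError(f"{path}: no founder columns")
    alleles = np.empty((len(df), len(founders)), dtype=np.int8)
    for j, f in enumerate(founders):
        codes = df[f].astype(str).str.upper()
        bad = ~codes.isin(_CODE_TO_ALLELE)
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
            raise ValueError(f"{path}:{line}: illegal allele code "
                             f"{codes.iloc[line - 2]!r} for founder {f!r}")
        alleles[:, j] = codes.map(_CODE_TO_ALLELE).to_numpy()
    for i, (r, a) in enumerate(zip(df["REF"], df["ALT"])):
        if r == a or len(str(r)) != 1 or len(str(a)) != 1:
            raise ValueError(f"{path}:{i + 2}: site not biallelic SNP ({r}/{a})")
    snps = df[fixed].rename(columns={"CHROM": "chrom", "POS": "pos",
                                     "REF": "ref", "ALT": "alt"})
    for chrom, sub in snps.groupby("chrom", sort=False):
        d = np.diff(sub["pos"].to_numpy())
        if np.any(d <= 0):
            line = int(sub.index[np.flatnonzero(d <= 0)[0] + 1]) + 2
            raise ValueError(f"{path}:{line}: positions not sorted on {chrom}")
    return FounderPanel(snps.reset_index(drop=True), alleles, founders)


def _read_panel_vcf(path) -> FounderPanel:
    import pysam
    vf = pysam.VariantFile(str(path))
    founders = list(vf.header.samples)
    if not founders:
        raise ValueError(f"{path}: VCF has no founder samples")
    rows, allele_rows = [], []
    n_rejected = 0
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1 or len(rec.ref) != 1 \
                or len(rec.alts[0]) != 1:
            n_rejected += 1
            logger.warning("%s:%s rejected: not a biallelic SNP", rec.chrom, rec.pos)
            continue
        codes = []
        for f in founders:
            gt = rec.samples[f].get("GT", (None,))
            seen = {g for g in gt if g is not None}
            if not seen or len(seen) > 1:   # missing or heterozygous -> missing
                codes.append(MISSING)
            else:
                codes.append(1 if seen.pop() == 0 else 0)
        rows.append({"chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref,
                     "alt": rec.alts[0]})
        allele_rows.append(codes)
    vf.close()
    if not rows:
        raise ValueError(f"{path}: no usable biallelic SNP records")
    if n_rejected:
        logger.info("%s: rejected %d non-biallelic records", path, n_rejected)
    return FounderPanel(pd.DataFrame(rows), np.array(allele_rows, dtype=np.int8),
                        founders)


def write_founder_panel(panel: FounderPanel, path) -> None:
    df = panel.snps.rename(columns={"chrom": "CHROM", "pos": "POS",
                                    "ref": "REF", "alt": "ALT"}).copy()
    for j, f in enumerate(panel.founders):
        df[f] = [_ALLELE_TO_CODE[int(a)] for a in panel.alleles[:, j]]
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pool counts


def write_pool_counts(pools: list[PoolCounts], counts_path, metadata_path) -> None:
    first = pools[0]
    df = pd.DataFrame({"CHROM": first.chrom, "POS": first.pos,
                       "REF": ["."] * len(first.pos)})
    for p in pools:
        df[p.pool_id] = [f"{r}:{a}" for r, a in zip(p.ref_count, p.alt_count)]
    df.to_csv(counts_path, sep="\t", index=False)
    pool_metadata(pools).to_csv(metadata_path, sep="\t", index=False)


def read_pool_counts(counts_path, metadata_path) -> list[PoolCounts]:
    df = pd.read_csv(counts_path, sep="\t", dtype={"CHROM": str})
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"pool_id": str})
    pool_cols = [c for c in df.columns if c not in ("CHROM", "POS", "REF")]
    meta_ids = list(meta["pool_id"])
    orphans = set(pool_cols) ^ set(meta_ids)
    if orphans:
        raise ValueError(f"pool columns and metadata disagree; orphan ids: "
                         f"{sorted(orphans)}")
    chrom = df["CHROM"].to_numpy()
    pos = df["POS"].to_numpy()
    pools = []
    for _, row in meta.iterrows():
        pid = row["pool_id"]
        pairs = df[pid].str.split(":", expand=True).to_numpy(dtype=np.int64)
        if np.any(pairs < 0):
            i = int(np.flatnonzero((pairs < 0).any(axis=1))[0])
            raise ValueError(f"{counts_path}:{i + 2}: negative count in pool {pid!r}")
        dup = row.get("duplicate_label", "NA")
        pools.append(PoolCounts(
            pool_id=pid, replicate=int(row["replicate"]),
            treatment=str(row["treatment"]),
            duplicate_label=None if pd.isna(dup) or dup == "NA" else str(dup),
            chrom=chrom, pos=pos,
            ref_count=pairs[:, 0], alt_count=pairs[:, 1]))
    return pools


def write_sim_truth(truth: SimTruth, path) -> None:
    truth.to_dataframe().to_csv(path, sep="\t", index=False)


def write_peaks_bed(peaks, path) -> None:
    """Peak intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start_bp - 1}\t{p.end_bp}\t{p.id}\t"
                     f"{p.peak_value:.3f}\n")


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Everything one pipeline run needs; serializable and echoed to outputs."""

    # inputs (None => simulate)
    panel_path: str | None = None
    counts_path: str | None = None
    metadata_path: str | None = None
    map_path: str | None = None
    output_dir: str = "xqtl_out"
    # analysis parameters
    width_cm: float = 1.5
    step_cm: float = 0.5
    min_depth: int = 5
    min_snps: int = 25
    span_cm: float = 5.0
    degree: int = 2
    threshold: float = 4.0
    drop: float = 3.0
    lowrec_cutoff: float = 0.5
    duplicate_policy: str = "average"
    # simulation parameters
    sim: SimConfig = field(default_factory=SimConfig)
    version: str = "0.1.0"

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ConfigError("threshold must be positive")
        if self.drop <= 0:
            raise ConfigError("drop must be positive")
        if self.step_cm <= 0 or self.width_cm <= 0:
            raise ConfigError("window width and step must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        sim_raw = raw.pop("sim", {})
        sim_known = {f.name for f in dataclasses.fields(SimConfig)}
        sim_unknown = set(sim_raw) - sim_known
        if sim_unknown:
            raise ConfigError(f"unknown sim config keys: {sorted(sim_unknown)}")
        if "pool_size_range" in sim_raw:
            sim_raw["pool_size_range"] = tuple(sim_raw["pool_size_range"])
        if "duplicate_control_replicates" in sim_raw:
            sim_raw["duplicate_control_replicates"] = tuple(
                sim_raw["duplicate_control_replicates"])
        return cls(sim=SimConfig(**sim_raw), **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["founder_weights"] = (
            None if self.sim.founder_weights is None
            else {k: list(map(float, v)) for k, v in self.sim.founder_weights.items()})
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(config: RunConfig,
                 qtl_model: QTLEffectModel | None = None) -> Path:
    """simulate/load -> estimate -> scan -> peaks; write everything to disk.

    Emits ``scan.tsv``, ``peaks.tsv``/``peaks.bed``, ``delta_freq.tsv``,
    ``haplotypes.tsv`` and the echoed config (with its hash) in
    ``config.output_dir``.
    """
    from .haplotypes import compute_snp_frequencies  # noqa: F401 (stage imports)
    from .scan import (call_peaks, haplotype_frequency_change, peaks_to_dataframe,
                       run_scan)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    logging.basicConfig(level=logging.INFO)

    if config.counts_path is None:
        logger.info("[simulate] generating synthetic experiment (seed=%d)",
                    config.sim.seed)
        pools, truth, panel = simulate_experiment(config.sim, qtl_model)
        gmap = config.sim.genetic_map()
        write_founder_panel(panel, out / "founder_panel.tsv")
        write_pool_counts(pools, out / "counts.tsv", out / "pool_metadata.tsv")
        write_sim_truth(truth, out / "sim_truth.tsv")
        gmap.write_tsv(out / "genetic_map.tsv")
    else:
        logger.info("[load] reading inputs")
        fmt = "vcf" if str(config.panel_path).endswith((".vcf", ".vcf.gz")) else "tsv"
        panel = read_founder_panel(config.panel_path, format=fmt)
        pools = read_pool_counts(config.counts_path, config.metadata_path)
        gmap = GeneticMap.read_tsv(config.map_path)

    logger.info("[scan] estimating haplotypes and running the interaction scan")
    scan, hap, windows = run_scan(
        pools, panel, gmap, width_cm=config.width_cm, step_cm=config.step_cm,
        min_depth=config.min_depth, min_snps=config.min_snps,
        span_cm=config.span_cm, degree=config.degree,
        duplicate_policy=config.duplicate_policy)
    scan.attrs["config_hash"] = chash
    _write_with_hash(scan, out / "scan.tsv", chash)
    hap.to_dataframe(gmap).to_csv(out / "haplotypes.tsv", sep="\t", index=False)

    logger.info("[peaks] calling QTL peaks")
    peaks = call_peaks(scan, gmap, threshold=config.threshold, drop=config.drop,
                       lowrec_cutoff=config.lowrec_cutoff)
    _write_with_hash(peaks_to_dataframe(peaks), out / "peaks.tsv", chash)
    write_peaks_bed(peaks, out / "peaks.bed")

    meta = pool_metadata(pools)
    delta = haplotype_frequency_change(hap, meta)
    ddf = pd.DataFrame(delta, columns=[f"delta_{f}" for f in panel.founders])
    ddf.insert(0, "chrom", [w.chrom for w in windows])
    ddf.insert(1, "center_cM", [w.center_cm for w in windows])
    _write_with_hash(ddf, out / "delta_freq.tsv", chash)

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump({"config_hash": chash, **self_dict(config)}, fh)
    logger.info("[done] outputs in %s (config %s)", out, chash)
    return out


def self_dict(config: RunConfig) -> dict:
    return config.to_dict()


def _write_with_hash(df: pd.DataFrame, path, chash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={chash}\n")
        df.to_csv(fh, sep="\t", index=False)
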