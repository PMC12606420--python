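"""Synthetic X-QTL experiments.

Generates the objects the analysis side consumes: an 8-founder SNP panel, an
outbred recombinant ("mosaic") base population, viability selection at planted
QTL, and pooled sequencing of survivor/control pools — together with truth
tracks (true per-window founder frequencies, planted-QTL metadata) so that
every downstream estimator can be checked against a known answer.

The defaults mirror a replicated developmental-toxin X-QTL design: 12
replicates of paired control and selected pools of a few hundred females,
~7% egg-to-adult survival under selection, ~67x pooled coverage, and a base
population whose founder-haplotype frequencies vary widely around 1/8.

Model summary
-------------
* Each individual is a pair of founder mosaics per chromosome: crossover
  counts are Poisson(generations x length-in-Morgans) per homolog, crossover
  positions uniform in cM, segment founder labels iid from the base-population
  founder weights (no interference, no pedigree).
* Viability selection is per-copy multiplicative genic selection: an
  individual's fitness factor is the product over planted loci and over its
  two homologs of ``1 + s_founder``, clamped at zero, then rescaled so the
  expected survival equals the configured target.  To first order in s the
  founder-frequency change among survivors is p*q*s.
* Sequencing draws per-SNP depth ~ Poisson(mean coverage); each read samples
  a uniformly random member homolog's allele and is flipped with the error
  rate, which collapses to a binomial draw on the pool allele frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genmap import GeneticMap

__all__ = [
    "FounderPanel", "PoolCounts", "MosaicIndividual", "MosaicPopulation",
    "QTLEffectModel", "SimConfig", "SimTruth",
    "simulate_founders", "simulate_base_population", "apply_viability_selection",
    "sequence_pool", "simulate_experiment",
]

MISSING = -1  # founder allele code for a missing call (else 1=REF, 0=ALT)


class ConfigError(ValueError):
    """Invalid simulation or analysis configuration."""


# ---------------------------------------------------------------------------
# panel


@dataclass
class FounderPanel:
    """Biallelic SNP x founder allele matrix defining the known haplotypes.

    ``alleles`` holds 1 where the founder carries REF, 0 for ALT and -1 for a
    missing call. SNPs are sorted by (chromosome, position); positions are
    1-based bp.
    """

    snps: pd.DataFrame            # columns: chrom, pos, ref, alt
    alleles: np.ndarray           # (S, F) int8 in {1, 0, -1}
    founders: list[str]

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape != (len(self.snps), len(self.founders)):
            raise ValueError("alleles shape does not match snps x founders")
        if not set(np.unique(self.alleles)) <= {-1, 0, 1}:
            raise ValueError("allele codes must be in {1 (REF), 0 (ALT), -1 (missing)}")
        for chrom, sub in self.snps.groupby("chrom", sort=False):
            if np.any(np.diff(sub["pos"].to_numpy()) <= 0):
                raise ValueError(f"SNP positions not strictly increasing on {chrom!r}")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_founders(self) -> int:
        return len(self.founders)

    def informative_mask(self) -> np.ndarray:
        """SNPs where at least two founders carry different non-missing alleles."""
        a = self.alleles
        has_ref = (a == 1).any(axis=1)
        has_alt = (a == 0).any(axis=1)
        return has_ref & has_alt

    def fully_called_mask(self) -> np.ndarray:
        return (self.alleles != MISSING).all(axis=1)

    def ref_indicator(self) -> np.ndarray:
        """(S, F) float matrix: 1.0 REF carrier, 0.0 ALT, NaN missing."""
        out = self.alleles.astype(float)
        out[self.alleles == MISSING] = np.nan
        return out

    def chrom_slices(self) -> dict[str, slice]:
        out = {}
        chroms = self.snps["chrom"].to_numpy()
        start = 0
        for chrom in pd.unique(chroms):
            n = int((chroms == chrom).sum())
            out[str(chrom)] = slice(start, start + n)
            start += n
        return out


@dataclass
class PoolCounts:
    """REF/ALT read counts for one sequenced pool, with design metadata."""

    pool_id: str
    replicate: int
    treatment: str                # "control" or "selected" (or "A"/"B" contrasts)
    duplicate_label: str | None   # "A", "B" or None
    chrom: np.ndarray             # (S,) per-SNP chromosome
    pos: np.ndarray               # (S,) 1-based bp
    ref_count: np.ndarray         # (S,) int
    alt_count: np.ndarray         # (S,) int
    n_members: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ref_count = np.asarray(self.ref_count)
        self.alt_count = np.asarray(self.alt_count)
        if np.any(self.ref_count < 0) or np.any(self.alt_count < 0):
            raise ValueError(f"negative read count in pool {self.pool_id!r}")

    @property
    def depth(self) -> np.ndarray:
        return self.ref_count + self.alt_count


def pool_metadata(pools: list[PoolCounts]) -> pd.DataFrame:
    return pd.DataFrame({
        "pool_id": [p.pool_id for p in pools],
        "replicate": [p.replicate for p in pools],
        "treatment": [p.treatment for p in pools],
        "duplicate_label": [p.duplicate_label if p.duplicate_label else "NA"
                            for p in pools],
    })


# ---------------------------------------------------------------------------
# mosaic individuals / populations


@dataclass
class MosaicIndividual:
    """Founder-of-origin mosaic: per chromosome, two homologs, each an ordered
    list of ``(start_cM, end_cM, founder)`` segments tiling [0, length]."""

    segments: dict[str, tuple[list[tuple[float, float, int]],
                              list[tuple[float, float, int]]]]

    def founder_at(self, chrom: str, pos_cm: float) -> tuple[int, int]:
        out = []
        for homolog in self.segments[chrom]:
            for start, end, f in homolog:
                if start <= pos_cm <= end:
                    out.append(f)
                    break
        return tuple(out)


class MosaicPopulation:
    """A batch of mosaic individuals stored as flat arrays for speed.

    Per chromosome the interior crossover positions of all ``2n`` homologs are
    concatenated (``breaks``, indexed by ``offsets``) and the founder label of
    every segment is concatenated in homolog order (homolog ``i`` owns
    ``k_i + 1`` labels where ``k_i`` is its crossover count). Individual ``j``
    owns homologs ``2j`` and ``2j+1``. Iterating yields
    :class:`MosaicIndividual` views.
    """

    def __init__(self, chrom_lengths_cm: dict[str, float], n: int,
                 data: dict[str, dict[str, np.ndarray]]):
        self.chrom_lengths_cm = dict(chrom_lengths_cm)
        self._n = n
        self._data = data  # per chrom: breaks, offsets (len 2n+1), founders

    def __len__(self) -> int:
        return self._n

    def __iter__(self):
        for i in range(self._n):
            yield self[i]

    def __getitem__(self, i: int) -> MosaicIndividual:
        if not 0 <= i < self._n:
            raise IndexError(i)
        segs: dict[str, tuple] = {}
        for chrom, d in self._data.items():
            length = self.chrom_lengths_cm[chrom]
            homologs = []
            for h in (2 * i, 2 * i + 1):
                lo, hi = d["offsets"][h], d["offsets"][h + 1]
                breaks = d["breaks"][lo:hi]
                founders = d["founders"][lo + h: hi + h + 1]
                bounds = np.concatenate(([0.0], breaks, [length]))
                homologs.append([(float(bounds[k]), float(bounds[k + 1]), int(founders[k]))
                                 for k in range(founders.size)])
            segs[chrom] = tuple(homologs)
        return MosaicIndividual(segs)

    # -- vectorized queries --------------------------------------------
    def founder_of_origin(self, chrom: str, query_cm: np.ndarray) -> np.ndarray:
        """(2n, Q) founder index of every homolog at the query positions."""
        d = self._data[chrom]
        n_h = 2 * self._n
        q = np.asarray(query_cm, dtype=float)
        counts = np.diff(d["offsets"])
        total = int(d["breaks"].size)
        if q.size > 1 and np.any(np.diff(q) < 0):
            order = np.argsort(q)
            out = np.empty((n_h, q.size), dtype=np.int8)
            out[:, order] = self.founder_of_origin(chrom, q[order])
            return out
        # place every crossover into the sorted query grid, then spread the
        # segment founder labels across the runs of queries they cover
        cuts = np.searchsorted(q, d["breaks"], side="left")
        starts = d["offsets"] + 2 * np.arange(n_h + 1)  # block starts in `bounds`
        bounds = np.empty(total + 2 * n_h, dtype=np.int64)
        bounds[starts[:-1]] = 0
        bounds[starts[1:] - 1] = q.size
        if total:
            homolog_of = np.repeat(np.arange(n_h), counts)
            bounds[np.arange(total) + 2 * homolog_of + 1] = cuts
        lengths = np.diff(bounds)
        if n_h > 1:  # drop the junk diffs straddling homolog blocks
            keep = np.ones(lengths.size, dtype=bool)
            keep[starts[1:-1] - 1] = False
            lengths = lengths[keep]
        return np.repeat(d["founders"], lengths).reshape(n_h, q.size)

    def founder_counts(self, chrom: str, query_cm: np.ndarray,
                       n_founders: int) -> np.ndarray:
        """(Q, F) counts of homologs tracing to each founder at each query."""
        fo = self.founder_of_origin(chrom, query_cm)
        Q = np.size(query_cm)
        flat = (np.arange(Q, dtype=np.int64) * n_founders)[None, :] + fo
        return np.bincount(flat.ravel(), minlength=Q * n_founders).reshape(Q, n_founders)

    def subset(self, keep: np.ndarray) -> "MosaicPopulation":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        data = {}
        for chrom, d in self._data.items():
            h = np.ravel(np.column_stack((2 * keep, 2 * keep + 1)))
            off = d["offsets"]
            counts = (off[1:] - off[:-1])[h]
            new_breaks = np.concatenate(
                [d["breaks"][off[i]:off[i + 1]] for i in h]) if h.size else np.empty(0)
            new_founders = np.concatenate(
                [d["founders"][off[i] + i: off[i + 1] + i + 1] for i in h]
            ) if h.size else np.empty(0, dtype=np.int8)
            data[chrom] = {
                "breaks": new_breaks,
                "offsets": np.concatenate(([0], np.cumsum(counts))),
                "founders": new_founders,
            }
        return MosaicPopulation(self.chrom_lengths_cm, keep.size, data)

    def founder_frequencies(self, chrom: str, query_cm: np.ndarray,
                            n_founders: int) -> np.ndarray:
        """(Q, F) founder-of-origin frequencies over the 2n homologs."""
        return self.founder_counts(chrom, query_cm, n_founders) / (2 * self._n)


# ---------------------------------------------------------------------------
# QTL model / config / truth


@dataclass
class QTLEffectModel:
    """Planted viability QTL: loci are (chrom, position cM, per-founder s)."""

    loci: list[tuple[str, float, np.ndarray]] = field(default_factory=list)
    baseline_survival: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.baseline_survival <= 1:
            raise ConfigError("baseline_survival must be in (0, 1]")
        self.loci = [(c, float(p), np.asarray(s, dtype=float)) for c, p, s in self.loci]
        for _, _, s in self.loci:
            if np.any(s < -1):
                raise ConfigError("per-founder effects below -1 are not meaningful")


@dataclass
class SimConfig:
    """Study-design parameters of one synthetic X-QTL experiment."""

    n_replicates: int = 12
    pool_size_range: tuple[int, int] = (190, 476)
    mean_coverage: float = 67.0
    survival_target: float = 0.07
    duplicate_control_replicates: tuple[int, ...] = (5, 6, 8, 11, 12)
    seed: int = 0
    n_founders: int = 8
    chrom_lengths_cm: dict[str, float] = field(default_factory=lambda: {"chr1": 50.0})
    recomb_rate_cm_per_mb: float = 2.0
    snps_per_cm: float = 40.0
    informative_fraction: float = 1.0
    founder_missing_rate: float = 0.0
    n_generations: int = 33
    dirichlet_alpha: float | None = 1.0   # None => uniform 1/F weights
    founder_weights: dict[str, np.ndarray] | None = None  # overrides Dirichlet
    error_rate: float = 0.001
    window_width_cm: float = 1.5
    window_step_cm: float = 0.5

    def __post_init__(self) -> None:
        if self.n_replicates < 1 or self.n_founders < 2:
            raise ConfigError("need >= 1 replicate and >= 2 founders")
        if not 0 < self.survival_target <= 1:
            raise ConfigError("survival_target must be in (0, 1]")
        lo, hi = self.pool_size_range
        if lo < 1 or hi < lo:
            raise ConfigError("pool_size_range must be positive and ordered")
        if self.mean_coverage < 0 or self.error_rate < 0:
            raise ConfigError("coverage and error rate must be non-negative")
        if not self.chrom_lengths_cm:
            raise ConfigError("empty genome")
        if not 0 <= self.informative_fraction <= 1:
            raise ConfigError("informative_fraction must be in [0, 1]")

    def genetic_map(self) -> GeneticMap:
        return GeneticMap.linear(self.chrom_lengths_cm, self.recomb_rate_cm_per_mb)


@dataclass
class SimTruth:
    """Truth tracks: planted QTL and true pool founder frequencies at the
    window-center grid."""

    qtl: list[tuple[str, float, np.ndarray]]
    founder_weights: dict[str, np.ndarray]
    centers_cm: dict[str, np.ndarray]                 # per chrom window centers
    pool_freqs: dict[str, dict[str, np.ndarray]]      # pool_id -> chrom -> (Q, F)
    seed: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for pool_id, by_chrom in self.pool_freqs.items():
            for chrom, freqs in by_chrom.items():
                centers = self.centers_cm[chrom]
                for w, (c, vec) in enumerate(zip(centers, freqs)):
                    rows.append({"chrom": chrom, "window_id": w, "center_cM": c,
                                 "pool_id": pool_id,
                                 **{f"h{f+1}": v for f, v in enumerate(vec)}})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# operations


def _rng_streams(seed: int, names: tuple[str, ...]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def simulate_founders(config: SimConfig, rng: np.random.Generator | None = None) -> FounderPanel:
    """Draw a founder SNP panel with a configurable informative fraction.

    Informative SNPs get iid Bernoulli(1/2) founder alleles, resampled (by
    flipping one founder) when monomorphic; the remaining SNPs are made
    monomorphic across founders on purpose.
    """
    rng = rng or _rng_streams(config.seed, ("founders",))["founders"]
    frames, allele_blocks = [], []
    gmap = config.genetic_map()
    F = config.n_founders
    for chrom, length_cm in config.chrom_lengths_cm.items():
        n_snps = max(int(round(length_cm * config.snps_per_cm)), 1)
        # jittered-regular cM grid keeps windows evenly populated
        grid = (np.arange(n_snps) + rng.uniform(0.05, 0.95, n_snps)) / n_snps * length_cm
        pos_bp = np.maximum(np.round(gmap.bp(chrom, grid)).astype(np.int64), 1)
        pos_bp = np.maximum.accumulate(pos_bp)  # non-decreasing
        pos_bp += np.concatenate(([0], np.cumsum(np.diff(pos_bp) == 0)))  # strictify ties
        alleles = rng.integers(0, 2, size=(n_snps, F)).astype(np.int8)
        mono = (alleles.min(axis=1) == alleles.max(axis=1))
        flip_col = rng.integers(0, F, size=int(mono.sum()))
        alleles[np.flatnonzero(mono), flip_col] ^= 1
        noninf = rng.random(n_snps) >= config.informative_fraction
        alleles[noninf] = rng.integers(0, 2, size=(int(noninf.sum()), 1)).astype(np.int8)
        if config.founder_missing_rate > 0:
            miss = rng.random(alleles.shape) < config.founder_missing_rate
            alleles[miss] = MISSING
        refs = rng.choice(list("ACGT"), size=n_snps)
        alts = np.array([rng.choice([b for b in "ACGT" if b != r]) for r in refs])
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos_bp,
                                    "ref": refs, "alt": alts}))
        allele_blocks.append(alleles)
    snps = pd.concat(frames, ignore_index=True)
    return FounderPanel(snps, np.vstack(allele_blocks),
                        [f"F{i+1}" for i in range(F)])


def simulate_base_population(gmap: GeneticMap, n_individuals: int, n_generations: int,
                             founder_weights: dict[str, np.ndarray] | np.ndarray,
                             rng: np.random.Generator) -> MosaicPopulation:
    """Generate founder mosaics from an outbred base population.

    Crossovers per homolog ~ Poisson(n_generations x Morgans), positions
    uniform in cM, founder labels iid from ``founder_weights`` (per chromosome
    if a dict is given). Locus-wise founder-of-origin frequencies therefore
    equal the weights in expectation.
    """
    if n_generations < 1:
        raise ConfigError("n_generations must be >= 1")
    if n_individuals < 1:
        raise ConfigError("n_individuals must be >= 1")
    n_h = 2 * n_individuals
    data = {}
    lengths = {c: gmap.length_cm(c) for c in gmap.chroms}
    for chrom, length in lengths.items():
        w = founder_weights[chrom] if isinstance(founder_weights, dict) else founder_weights
        w = np.asarray(w, dtype=float)
        if abs(w.sum() - 1.0) > 1e-6 or np.any(w < 0):
            raise ConfigError("founder_weights must lie on the simplex")
        w = w / w.sum()
        lam = n_generations * length / 100.0
        k = rng.poisson(lam, size=n_h)
        total = int(k.sum())
        shift = np.arange(n_h, dtype=float) * (length + 1.0)
        pos = rng.uniform(0.0, length, total) + np.repeat(shift, k)
        pos = np.sort(pos) - np.repeat(shift, k)
        founders = rng.choice(w.size, size=total + n_h, p=w).astype(np.int8)
        data[chrom] = {"breaks": pos,
                       "offsets": np.concatenate(([0], np.cumsum(k))),
                       "founders": founders}
    return MosaicPopulation(lengths, n_individuals, data)


def apply_viability_selection(population: MosaicPopulation, qtl_model: QTLEffectModel,
                              target_survival: float, rng: np.random.Generator
                              ) -> tuple[MosaicPopulation, float]:
    """Bernoulli-thin a population by per-copy multiplicative genic selection.

    Each individual's fitness factor is the product over planted loci and over
    its two homologs of ``1 + s_founder`` (clamped at 0); survival
    probabilities are rescaled so the population-mean survival equals
    ``target_survival`` (then clamped to [0, 1]).
    """
    if not 0 < target_survival <= 1:
        raise ConfigError("target_survival must be in (0, 1]")
    n = len(population)
    if n == 0:
        raise ValueError("population is empty")
    w = np.full(n, qtl_model.baseline_survival)
    by_chrom: dict[str, list[tuple[float, np.ndarray]]] = {}
    for chrom, pos_cm, s in qtl_model.loci:
        by_chrom.setdefault(chrom, []).append((pos_cm, s))
    for chrom, loci in by_chrom.items():
        positions = np.array([p for p, _ in loci])
        fo = population.founder_of_origin(chrom, positions)  # (2n, L)
        for j, (_, s) in enumerate(loci):
            fit = 1.0 + s[fo[:, j]]
            w *= np.maximum(fit[0::2] * fit[1::2], 0.0)
    p = np.clip(target_survival * w / w.mean(), 0.0, 1.0) if w.mean() > 0 else np.zeros(n)
    survive = rng.random(n) < p
    return population.subset(survive), float(survive.mean())


def sequence_pool(members: MosaicPopulation, panel: FounderPanel, gmap: GeneticMap,
                  mean_coverage: float, error_rate: float, rng: np.random.Generator,
                  pool_id: str = "pool", replicate: int = 0, treatment: str = "control",
                  duplicate_label: str | None = None) -> PoolCounts:
    """Pool-seq read counts: depth ~ Poisson(mean), reads sample member
    homolog alleles uniformly and flip with ``error_rate``."""
    if len(members) == 0:
        raise ValueError("cannot sequence an empty pool")
    if mean_coverage < 0 or not 0 <= error_rate <= 1:
        raise ConfigError("invalid coverage or error rate")
    S = panel.n_snps
    p_true = np.empty(S)
    is_ref = (panel.alleles == 1)
    called = (panel.alleles != MISSING)
    for chrom, sl in panel.chrom_slices().items():
        snp_cm = gmap.cm(chrom, panel.snps["pos"].to_numpy()[sl])
        counts = members.founder_counts(chrom, snp_cm, panel.n_founders)  # (S_c, F)
        ref = (counts * is_ref[sl]).sum(axis=1)
        tot = (counts * called[sl]).sum(axis=1)  # homologs from uncalled founders drop out
        with np.errstate(invalid="ignore"):
            p_true[sl] = np.where(tot > 0, ref / np.maximum(tot, 1), 0.5)
    depth = rng.poisson(mean_coverage, size=S)
    p_eff = p_true * (1 - error_rate) + (1 - p_true) * error_rate
    ref = rng.binomial(depth, p_eff)
    return PoolCounts(pool_id=pool_id, replicate=replicate, treatment=treatment,
                      duplicate_label=duplicate_label,
                      chrom=panel.snps["chrom"].to_numpy(),
                      pos=panel.snps["pos"].to_numpy(),
                      ref_count=ref, alt_count=depth - ref, n_members=len(members))


def _window_centers(length_cm: float, width: float, step: float) -> np.ndarray:
    first = width / 2.0
    last = length_cm - width / 2.0
    if last < first:
        return np.empty(0)
    n = int(np.floor((last - first) / step + 1e-9)) + 1
    return first + np.arange(n) * step


def simulate_experiment(config: SimConfig, qtl_model: QTLEffectModel | None = None,
                        panel: FounderPanel | None = None
                        ) -> tuple[list[PoolCounts], SimTruth, FounderPanel]:
    """Run one full synthetic X-QTL experiment.

    Per replicate: an egg cohort sized so that the expected number of
    selection survivors lands in the configured pool-size range is simulated
    and selected; all survivors form the "selected" pool, and a fresh cohort
    of matched size forms the "control" pool (two independent control pools
    for duplicate-control replicates). Returns the pools, truth tracks and
    the founder panel used.
    """
    qtl_model = qtl_model or QTLEffectModel()
    rngs = _rng_streams(config.seed, ("founders", "population", "selection",
                                      "sequencing", "design"))
    if panel is None:
        panel = simulate_founders(config, rngs["founders"])
    gmap = config.genetic_map()
    F = config.n_founders
    if config.founder_weights is not None:
        weights = {c: np.asarray(config.founder_weights[c], dtype=float)
                   for c in config.chrom_lengths_cm}
    elif config.dirichlet_alpha is None:
        weights = {c: np.full(F, 1.0 / F) for c in config.chrom_lengths_cm}
    else:
        weights = {c: rngs["design"].dirichlet(np.full(F, config.dirichlet_alpha))
                   for c in config.chrom_lengths_cm}

    centers = {c: _window_centers(L, config.window_width_cm, config.window_step_cm)
               for c, L in config.chrom_lengths_cm.items()}
    pools: list[PoolCounts] = []
    pool_freqs: dict[str, dict[str, np.ndarray]] = {}

    def emit(members: MosaicPopulation, pool_id: str, replicate: int,
             treatment: str, dup: str | None) -> None:
        pools.append(sequence_pool(members, panel, gmap, config.mean_coverage,
                                   config.error_rate, rngs["sequencing"],
                                   pool_id=pool_id, replicate=replicate,
                                   treatment=treatment, duplicate_label=dup))
        pool_freqs[pool_id] = {c: members.founder_frequencies(c, centers[c], F)
                               for c in config.chrom_lengths_cm}

    for r in range(1, config.n_replicates + 1):
        lo, hi = config.pool_size_range
        target_pool = int(rngs["design"].integers(lo, hi + 1))
        n_eggs = max(int(round(target_pool / config.survival_target)), 1)
        cohort = simulate_base_population(gmap, n_eggs, config.n_generations,
                                          weights, rngs["population"])
        survivors, _ = apply_viability_selection(cohort, qtl_model,
                                                 config.survival_target,
                                                 rngs["selection"])
        m = len(survivors)
        if m == 0:
            warnings.warn(f"replicate {r}: no selection survivors; skipped")
            continue
        emit(survivors, f"R{r}Z", r, "selected", None)
        is_dup = r in config.duplicate_control_replicates
        for label in (("A", "B") if is_dup else (None,)):
            ctrl = simulate_base_population(gmap, m, config.n_generations,
                                            weights, rngs["population"])
            suffix = label or ""
            emit(ctrl, f"R{r}C{suffix}", r, "control", label)

    truth = SimTruth(qtl=list(qtl_model.loci), founder_weights=weights,
                     centers_cm=centers, pool_freqs=pool_freqs, seed=config.seed)
    return pools, truth, panel
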