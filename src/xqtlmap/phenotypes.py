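"""Phenotype statistics for developmental toxin-resistance assays.

Covers the measurements taken alongside the mapping experiment: per-vial
egg-to-adult emergence (vials seeded with a fixed egg count, adults counted
for 30 days), per-fly egg-to-adult development time in days, two-way
genotype/population x treatment factorial ANOVAs with interaction, and the
conservative multi-control RNAi hit rule: a knockdown construct is a "hit"
for a phenotype when its genotype-by-treatment interaction is strictly
significant (Bonferroni-style alpha) against at least one control genotype,
at least nominally significant (p < 0.05) against every other control, and
the interaction direction agrees across all controls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

__all__ = [
    "VialRecord", "FlyRecord", "RNAiResult", "HitCall",
    "emergence_fraction", "treatment_delta", "factorial_anova",
    "adjusted_alpha", "call_rnai_hits",
]

MAX_DEV_DAYS = 30  # assay censoring horizon: flies not emerged by then count as not emerged


@dataclass
class VialRecord:
    """One test vial: eggs in, adults out, by sex."""

    vial_id: str
    genotype: str
    treatment: str               # e.g. "water", "zinc", "copper", "cadmium"
    eggs_in: int = 50
    emerged_female: int = 0
    emerged_male: int = 0

    def __post_init__(self) -> None:
        if self.eggs_in <= 0:
            raise ValueError(f"vial {self.vial_id!r}: eggs_in must be positive")
        if self.emerged_female + self.emerged_male > self.eggs_in:
            raise ValueError(f"vial {self.vial_id!r}: more adults than eggs")


@dataclass
class FlyRecord:
    """One emerged adult: vial of origin, sex, egg-to-adult days."""

    vial_id: str
    sex: str
    dev_days: int

    def __post_init__(self) -> None:
        if not 1 <= self.dev_days <= MAX_DEV_DAYS:
            raise ValueError(
                f"dev_days must be in [1, {MAX_DEV_DAYS}] (got {self.dev_days})")


@dataclass
class RNAiResult:
    """Interaction tests of one construct against each control genotype."""

    gene: str
    construct: str
    phenotype: str                       # "emergence" or "dev_time"
    p_values: dict[str, float]           # control genotype -> interaction p
    directions: dict[str, int]           # control genotype -> sign(+1/-1/0)
    delta_emergence: float = np.nan      # zinc - water, knockdown genotype
    delta_dev_days: float = np.nan


@dataclass
class HitCall:
    gene: str
    construct: str
    phenotype: str
    is_hit: bool
    p_values: dict[str, float] = field(default_factory=dict)
    reason: str = ""


# ---------------------------------------------------------------------------


def emergence_fraction(vial: VialRecord) -> float:
    """Fraction of the vial's eggs that developed into adults."""
    return (vial.emerged_female + vial.emerged_male) / vial.eggs_in


def treatment_delta(vials: list[VialRecord] | None = None,
                    flies: pd.DataFrame | None = None,
                    treatment_a: str = "zinc",
                    treatment_b: str = "water") -> tuple[float, float]:
    """(emergence delta, development-time delta): treatment_a minus treatment_b.

    Emergence is averaged over vials per treatment; development time over
    flies (``flies`` needs columns ``treatment`` and ``dev_days``). A missing
    treatment yields NaN for that phenotype with a warning.
    """
    d_emerge = d_dev = np.nan
    if vials:
        by = {}
        for v in vials:
            by.setdefault(v.treatment, []).append(emergence_fraction(v))
        if treatment_a in by and treatment_b in by:
            d_emerge = float(np.mean(by[treatment_a]) - np.mean(by[treatment_b]))
        else:
            warnings.warn(f"missing treatment for emergence delta "
                          f"({sorted(by)} present)")
    if flies is not None and len(flies):
        by_t = flies.groupby("treatment")["dev_days"].mean()
        if treatment_a in by_t.index and treatment_b in by_t.index:
            d_dev = float(by_t[treatment_a] - by_t[treatment_b])
        else:
            warnings.warn("missing treatment for development-time delta")
    return d_emerge, d_dev


def factorial_anova(data: pd.DataFrame, response: str, factor_a: str,
                    factor_b: str) -> tuple[float, float, int]:
    """Two-way fixed-effects ANOVA with interaction.

    Returns ``(interaction F, interaction p, direction)``. For two-level
    factors the direction is the sign of the interaction contrast
    ``(a2: b2-b1) - (a1: b2-b1)`` with levels in sorted order; 0 for factors
    with more than two levels.
    """
    for fac in (factor_a, factor_b):
        if data[fac].nunique() < 2:
            raise ValueError(f"factor {fac!r} needs >= 2 levels")
    counts = data.groupby([factor_a, factor_b]).size()
    full = data[factor_a].nunique() * data[factor_b].nunique()
    if len(counts) < full:
        have = set(counts.index)
        cells = [(a, b) for a in data[factor_a].unique()
                 for b in data[factor_b].unique() if (a, b) not in have]
        raise ValueError(f"empty design cells: {cells}")
    model = ols(f"Q('{response}') ~ C(Q('{factor_a}')) * C(Q('{factor_b}'))",
                data=data).fit()
    aov = anova_lm(model, typ=2)
    inter = [i for i in aov.index if ":" in i][0]
    F = float(aov.loc[inter, "F"])
    p = float(aov.loc[inter, "PR(>F)"])
    direction = 0
    if data[factor_a].nunique() == 2 and data[factor_b].nunique() == 2:
        a1, a2 = sorted(data[factor_a].unique())
        b1, b2 = sorted(data[factor_b].unique())
        cm = data.groupby([factor_a, factor_b])[response].mean()
        contrast = (cm[(a2, b2)] - cm[(a2, b1)]) - (cm[(a1, b2)] - cm[(a1, b1)])
        direction = int(np.sign(contrast))
    return F, p, direction


def adjusted_alpha(n_constructs: int, n_controls: int, n_phenotypes: int) -> float:
    """Bonferroni-style strict significance level 0.05 / (constructs x controls x phenotypes)."""
    if min(n_constructs, n_controls, n_phenotypes) < 1:
        raise ValueError("all counts must be >= 1")
    return 0.05 / (n_constructs * n_controls * n_phenotypes)


def call_rnai_hits(result: RNAiResult, alpha_strict: float,
                   alpha_nominal: float = 0.05,
                   n_controls: int = 4) -> HitCall:
    """Apply the multi-control hit rule to one construct x phenotype.

    Hit iff: min p < ``alpha_strict``, every p < ``alpha_nominal``, and all
    interaction directions agree (and are nonzero).
    """
    ps = result.p_values
    if len(ps) != n_controls:
        return HitCall(result.gene, result.construct, result.phenotype,
                       is_hit=False, p_values=dict(ps),
                       reason=f"not callable: {len(ps)}/{n_controls} contrasts present")
    pv = np.array(list(ps.values()))
    dirs = np.array([result.directions[c] for c in ps])
    strict = bool(pv.min() < alpha_strict)
    nominal = bool((pv < alpha_nominal).all())
    consistent = bool((dirs != 0).all() and len(set(dirs)) == 1)
    is_hit = strict and nominal and consistent
    reason = "hit" if is_hit else "; ".join(
        m for ok, m in [(strict, "no contrast below strict alpha"),
                        (nominal, "a contrast not nominally significant"),
                        (consistent, "inconsistent effect direction")] if not ok)
    return HitCall(result.gene, result.construct, result.phenotype,
                   is_hit=is_hit, p_values=dict(ps), reason=reason)
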