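"""Marker-trait association for tetraploid dosage genotypes.

Each marker x trait combination is tested with a one-way fixed-effects
analysis of variance across the observed genotype classes.  Treating
genotype as a categorical factor (rather than a linear dosage
regression) lets the test pick up non-additive patterns — e.g. an
effect confined to one homozygous class, or directions that reverse
between genotypic groups — which a single slope cannot express.  The
effect size is the percent variance explained, eta^2 = SS_between /
SS_total x 100.  The direction of the minor-frequency-allele (MFA)
effect is a separate derived quantity from the dosage-ordered class
means.

Significance tiers follow the reporting convention:
ns (p > 0.05), * (0.05 > p >= 0.01), ** (0.01 > p >= 0.001),
*** (p < 0.001); a marker is "reportable" when p < 0.01 for at least
one trait.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotyping import PLOIDY, DosageMatrix, apply_mfa_filter, mfa_dosage, presence_absence_frequency

logger = logging.getLogger(__name__)

__all__ = [
    "TraitSpecMeta",
    "TraitTable",
    "AnovaResult",
    "AssociationResult",
    "oneway_dosage_anova",
    "direction_of_effect",
    "associate_all",
    "validation_transform",
    "significance_tier",
    "DIRECTION_GLYPHS",
]

DIRECTION_GLYPHS = {"up": "↑", "down": "↓", "inconsistent": "↑↓", "none": ""}

#: Default MFA carrier-count filters: discovery (n=208, MFA >= 1%) and
#: validation (n=40, MFA >= 2%) modes.
MIN_CARRIERS = {"discovery": 8, "validation": 3}


@dataclass(frozen=True)
class TraitSpecMeta:
    """Per-column trait metadata: measurement scale, units, transform."""

    scale: str = "continuous"  # continuous | ordinal_1_9
    units: str = ""
    transform: str = "none"  # none | log10


class TraitTable:
    """Individuals x named phenotypes, continuous or ordinal 1-9."""

    def __init__(self, values: pd.DataFrame, metadata: Mapping[str, TraitSpecMeta] | None = None) -> None:
        if values.index.has_duplicates:
            raise ValueError("duplicate individual ids")
        self._values = values.astype(float)
        self.metadata = dict(metadata or {})
        for col in values.columns:
            self.metadata.setdefault(col, TraitSpecMeta())
        for col, meta in self.metadata.items():
            if meta.scale == "ordinal_1_9":
                v = self._values[col].dropna()
                if ((v != v.round()) | (v < 1) | (v > 9)).any():
                    raise ValueError(f"ordinal column {col!r} must contain integers 1-9")
            if meta.transform == "log10":
                v = self._values[col].dropna()
                if (v <= 0).any():
                    raise ValueError(f"log10 column {col!r} must be strictly positive")

    @property
    def values(self) -> pd.DataFrame:
        return self._values

    @property
    def individuals(self) -> pd.Index:
        return self._values.index

    @property
    def trait_names(self) -> list[str]:
        return list(self._values.columns)


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p_value: float
    eta2: float
    df_between: int
    df_within: int
    n: int
    testable: bool = True
    merged_classes: tuple = ()


@dataclass(frozen=True)
class AssociationResult:
    """One marker x trait test, Table-2-style."""

    marker_id: str
    trait: str
    n_used: int
    p_value: float
    percent_variance: float
    mfa_allele: str
    mfa_frequency_percent: float
    direction: str  # up | down | inconsistent | none
    tier: str  # ns | * | ** | ***
    testable: bool = True
    reportable: bool = False


def significance_tier(p: float) -> str:
    if math.isnan(p):
        return "ns"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _merge_singletons(codes: np.ndarray) -> tuple[np.ndarray, tuple]:
    """Merge single-observation dosage classes into the nearest class.

    Classes with one observation contribute a zero-df cell to the
    ANOVA; each is relabelled to the observed class nearest in dosage
    (ties toward the lower dosage).  Returns the recoded vector and a
    log of (from, to) merges.
    """
    codes = codes.copy()
    merges = []
    while True:
        vals, counts = np.unique(codes, return_counts=True)
        single = vals[counts == 1]
        if len(single) == 0 or len(vals) <= 2:
            break
        s = single[0]
        others = vals[(vals != s)]
        target = others[np.argmin(np.abs(others - s))]
        codes[codes == s] = target
        merges.append((float(s), float(target)))
    return codes, tuple(merges)


def oneway_dosage_anova(
    values: Sequence[float],
    classes: Sequence[float],
    merge_singletons: bool = True,
    rank_based: bool = False,
) -> AnovaResult:
    """One-way fixed-effects ANOVA across genotype classes.

    Parameters
    ----------
    values : trait observations.
    classes : genotype class codes (dosages 0-4, or triallelic class
        indices); pairwise-incomplete observations must be dropped by
        the caller.
    merge_singletons : merge single-observation classes into the
        adjacent dosage class before testing.
    rank_based : use the Kruskal-Wallis test instead of the parametric
        F test (eta^2 is still the sums-of-squares ratio of the raw
        values).

    Returns ``AnovaResult`` with eta2 = SS_between / SS_total and the
    p-value from the F distribution with (k-1, n-k) degrees of
    freedom.  A single observed class is not testable (distinct from a
    non-significant result); zero total variance gives eta2=0, p=1.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(classes, dtype=float)
    if y.shape != g.shape:
        raise ValueError("values and classes must have equal length")
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 observations")
    merges: tuple = ()
    if merge_singletons:
        g, merges = _merge_singletons(g)
        if merges:
            logger.debug("merged singleton classes: %s", merges)
    levels = np.unique(g)
    k = len(levels)
    if k < 2:
        return AnovaResult(np.nan, np.nan, np.nan, 0, n - k, n, testable=False, merged_classes=merges)
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    if ss_total == 0.0:
        return AnovaResult(0.0, 1.0, 0.0, k - 1, n - k, n, merged_classes=merges)
    ss_between = 0.0
    for lv in levels:
        grp = y[g == lv]
        ss_between += len(grp) * (grp.mean() - grand) ** 2
    ss_within = ss_total - ss_between
    df_b, df_w = k - 1, n - k
    eta2 = ss_between / ss_total
    if rank_based:
        groups = [y[g == lv] for lv in levels]
        stat, p = stats.kruskal(*groups)
        return AnovaResult(float(stat), float(p), eta2, df_b, df_w, n, merged_classes=merges)
    if ss_within == 0.0:
        return AnovaResult(np.inf, 0.0, eta2, df_b, df_w, n, merged_classes=merges)
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(float(F), p, eta2, df_b, df_w, n, merged_classes=merges)


def direction_of_effect(
    values: Sequence[float],
    mfa_dosages: Sequence[float],
    tau_factor: float = 0.25,
) -> str:
    """Direction of the MFA effect: ``up``, ``down`` or ``inconsistent``.

    Class means are ordered by MFA dosage.  When two successive
    class-mean differences have strictly opposite signs and each
    exceeds a tolerance tau = ``tau_factor`` x pooled within-class SD,
    the direction is inconsistent between genotypic groups.  Otherwise
    the direction is the sign of the count-weighted least-squares
    slope of class mean against dosage.
    """
    y = np.asarray(values, dtype=float)
    d = np.asarray(mfa_dosages, dtype=float)
    levels = np.unique(d)
    if len(levels) < 2:
        raise ValueError("need at least 2 dosage groups")
    means = np.array([y[d == lv].mean() for lv in levels])
    counts = np.array([(d == lv).sum() for lv in levels])
    # pooled within-class SD for the inconsistency tolerance
    ss_w = sum(((y[d == lv] - y[d == lv].mean()) ** 2).sum() for lv in levels)
    df_w = len(y) - len(levels)
    pooled_sd = math.sqrt(ss_w / df_w) if df_w > 0 else 0.0
    tau = tau_factor * pooled_sd
    diffs = np.diff(means)
    for a, b in zip(diffs, diffs[1:]):
        if a * b < 0 and abs(a) > tau and abs(b) > tau:
            return "inconsistent"
    # count-weighted least-squares slope of class mean vs dosage
    w = counts / counts.sum()
    xbar = (w * levels).sum()
    ybar = (w * means).sum()
    slope = (w * (levels - xbar) * (means - ybar)).sum()
    return "up" if slope >= 0 else "down"


def validation_transform(values: Sequence[float]) -> np.ndarray:
    """log10-transform sugar measurements to approximate normality."""
    v = np.asarray(values, dtype=float)
    if np.nanmin(v) <= 0:
        raise ValueError("log10 transform requires strictly positive values")
    return np.log10(v)


def associate_all(
    matrix: DosageMatrix,
    traits: TraitTable,
    mode: str = "discovery",
    alpha_report: float = 0.01,
    min_carriers: int | None = None,
    rank_based: bool = False,
    tau_factor: float = 0.25,
) -> list[AssociationResult]:
    """Test every retained marker against every trait.

    ``mode`` selects the MFA carrier filter (8 in discovery, 3 in
    validation) and, in validation mode, applies each trait column's
    declared log10 transform before testing.  Missing genotype or
    phenotype values are dropped pairwise per test.  Markers are
    flagged reportable when p < ``alpha_report`` for at least one
    trait.
    """
    if mode not in MIN_CARRIERS:
        raise ValueError(f"mode must be one of {sorted(MIN_CARRIERS)}")
    shared = matrix.individuals.intersection(traits.individuals)
    if shared.empty:
        raise ValueError("genotype and trait tables share no individual ids")
    if len(shared) < len(matrix.individuals) or len(shared) < len(traits.individuals):
        logger.warning(
            "id join: %d shared of %d genotyped / %d phenotyped individuals",
            len(shared), len(matrix.individuals), len(traits.individuals),
        )

    threshold = MIN_CARRIERS[mode] if min_carriers is None else min_carriers
    retained = apply_mfa_filter(matrix, threshold)
    logger.info(
        "MFA filter (>=%d carriers, %s mode): retained %d of %d markers",
        threshold, mode, len(retained), len(matrix.marker_ids),
    )

    trait_values: dict[str, pd.Series] = {}
    for name in traits.trait_names:
        col = traits.values[name].loc[shared]
        meta = traits.metadata[name]
        if mode == "validation" and meta.transform == "log10":
            col = pd.Series(validation_transform(col.dropna()), index=col.dropna().index).reindex(shared)
        trait_values[name] = col

    results: list[AssociationResult] = []
    for mid in retained:
        geno = matrix.column(mid).loc[shared]
        mode_m = matrix.scoring_mode(mid)
        if mode_m == "dosage":
            marker = matrix.markers.get(mid)
            allele, freq, mfa_d = mfa_dosage(geno, marker)
            classes = geno
            freq_pct = freq * 100.0
        else:
            carrier_frac, _ = presence_absence_frequency(geno)
            allele, freq_pct = "present", carrier_frac * 100.0
            mfa_d = geno if carrier_frac <= 0.5 else 1 - geno
            classes = geno
        marker_rows: list[AssociationResult] = []
        any_reportable = False
        for name in traits.trait_names:
            joined = pd.concat([trait_values[name].rename("y"), classes.rename("g"), mfa_d.rename("m")], axis=1).dropna()
            if len(joined) < 3 or joined["g"].nunique() < 2:
                marker_rows.append(AssociationResult(
                    mid, name, len(joined), float("nan"), float("nan"),
                    allele, freq_pct, "none", "ns", testable=False,
                ))
                continue
            res = oneway_dosage_anova(joined["y"], joined["g"], rank_based=rank_based)
            if not res.testable:
                marker_rows.append(AssociationResult(
                    mid, name, res.n, float("nan"), float("nan"),
                    allele, freq_pct, "none", "ns", testable=False,
                ))
                continue
            tier = significance_tier(res.p_value)
            if tier == "ns":
                direction = "none"
            else:
                direction = direction_of_effect(joined["y"], joined["m"], tau_factor=tau_factor)
            if res.p_value < alpha_report:
                any_reportable = True
            marker_rows.append(AssociationResult(
                mid, name, res.n, res.p_value, res.eta2 * 100.0,
                allele, freq_pct, direction, tier,
            ))
        if any_reportable:
            marker_rows = [
                AssociationResult(**{**r.__dict__, "reportable": True}) for r in marker_rows
            ]
        results.extend(marker_rows)
    return results


def results_to_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Long-format DataFrame of association results."""
    return pd.DataFrame([r.__dict__ for r in results])
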