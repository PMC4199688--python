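"""Linkage disequilibrium between dosage-scored markers.

For unphased tetraploid data the gametic phase is unobservable, so LD
is tested phase-free: a chi-square test of independence on the
observed genotype-class contingency table (rows = dosage classes of
one marker, columns of the other).  Sparse dosage classes (expected
count < 1) are pooled with the adjacent class before testing, since
tetraploid class tables at n ~ 200 are thin in the extreme classes.
The composite dosage correlation r is reported alongside as an effect
size.  P-values over a family of pairs are corrected to q-values by
Benjamini-Hochberg step-up (default) or Storey's pi0-adjusted method,
and same-locus markers are grouped into LD blocks by single linkage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genotyping import DosageMatrix, SnpMarker

logger = logging.getLogger(__name__)

__all__ = [
    "LdResult",
    "ld_chi2",
    "correct_pvalues",
    "pairwise_ld",
    "ld_blocks",
]

#: Default within-locus LD block span (bp): strong blocks in candidate-gene
#: amplicons extend up to about 700 bp.
DEFAULT_MAX_SPAN_BP = 700


@dataclass(frozen=True)
class LdResult:
    marker_i: str
    marker_j: str
    chi2: float
    df: int
    p_value: float
    q_value: float | None = None
    n: int = 0
    r: float = float("nan")  # composite dosage correlation
    same_locus: bool = False
    distance_bp: int | None = None
    testable: bool = True


def _merge_sparsest_row(t: np.ndarray) -> np.ndarray:
    """Merge the row with the smallest total into its adjacent dosage
    class (the neighbor with the smaller total; ties toward lower
    dosage)."""
    sums = t.sum(axis=1)
    i = int(np.argmin(sums))
    if i == 0:
        j = 1
    elif i == t.shape[0] - 1:
        j = i - 1
    else:
        j = i - 1 if sums[i - 1] <= sums[i + 1] else i + 1
    t[j] += t[i]
    return np.delete(t, i, axis=0)


def _pool_sparse(table: np.ndarray, min_expected: float) -> np.ndarray:
    """Pool adjacent dosage classes until no cell is expected below
    ``min_expected`` (or both dimensions are down to two classes).

    Each step merges the sparsest class on whichever axis has the
    smaller minimal marginal (both on a tie), so the procedure is
    symmetric under transposition and ``ld_chi2`` is symmetric in its
    two markers.
    """
    t = table.astype(float)
    while True:
        expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
        if expected.min() >= min_expected:
            break
        row_min = t.sum(axis=1).min()
        col_min = t.sum(axis=0).min()
        can_row = t.shape[0] > 2
        can_col = t.shape[1] > 2
        do_row = can_row and (row_min <= col_min or not can_col)
        do_col = can_col and (col_min <= row_min or not can_row)
        if not (do_row or do_col):
            break
        if do_row:
            t = _merge_sparsest_row(t)
        if do_col:
            t = _merge_sparsest_row(t.T).T
    return t


def ld_chi2(
    dosages_i: Sequence[float],
    dosages_j: Sequence[float],
    min_n: int = 10,
    min_expected: float = 1.0,
) -> LdResult:
    """Chi-square independence test on the genotype-class table.

    Classes with expected counts below ``min_expected`` (default 1)
    are pooled with the adjacent dosage class; a warning is emitted
    when expected counts below 5 remain.  A monomorphic marker yields
    a not-testable result, distinct from p = 1.  The test is symmetric
    in its two arguments.
    """
    a = pd.Series(np.asarray(dosages_i, dtype=float))
    b = pd.Series(np.asarray(dosages_j, dtype=float))
    ok = a.notna() & b.notna()
    a, b = a[ok], b[ok]
    n = len(a)
    if n < min_n:
        raise ValueError(f"need at least {min_n} pairwise-complete individuals, got {n}")
    if a.nunique() < 2 or b.nunique() < 2:
        return LdResult("", "", float("nan"), 0, float("nan"), n=n, testable=False)
    r = float(np.corrcoef(a, b)[0, 1])
    table = pd.crosstab(a, b).to_numpy()
    table = _pool_sparse(table, min_expected)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected < 5).any():
        warnings.warn(
            "expected counts < 5 after pooling; chi-square approximation is rough",
            stacklevel=2,
        )
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return LdResult("", "", float(chi2), int(df), float(p), n=n, r=r)


def correct_pvalues(
    p_values: Sequence[float],
    method: str = "bh",
    storey_lambda: float = 0.5,
) -> np.ndarray:
    """False-discovery-rate q-values for a family of tests.

    ``bh`` is the Benjamini-Hochberg monotone step-up procedure;
    ``storey`` rescales it by the estimated null proportion
    pi0 = #{p > lambda} / ((1 - lambda) m), clipped to (0, 1], using a
    fixed lambda (default 0.5).  Both are order-preserving; Storey
    q-values can drop below the raw p when pi0 < 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method == "storey":
        m = p.size
        pi0 = np.sum(p > storey_lambda) / ((1.0 - storey_lambda) * m)
        pi0 = min(max(pi0, 1.0 / m), 1.0)
        order = np.argsort(p, kind="stable")
        q = np.empty(m)
        prev = 1.0
        for rank in range(m, 0, -1):
            idx = order[rank - 1]
            val = min(prev, pi0 * m * p[idx] / rank)
            q[idx] = val
            prev = val
        return q
    raise ValueError(f"unknown correction method {method!r}")


def _marker_meta(matrix: DosageMatrix, mid: str) -> SnpMarker | None:
    marker = matrix.markers.get(mid)
    if marker is not None:
        return marker
    try:
        return SnpMarker.from_id(mid)
    except ValueError:
        return None


def pairwise_ld(
    matrix: DosageMatrix,
    pairs: Iterable[tuple[str, str]] | None = None,
    method: str = "bh",
    min_n: int = 10,
) -> list[LdResult]:
    """LD test for every requested marker pair, with q-values.

    When ``pairs`` is omitted, all dosage-marker pairs are tested.
    Same-locus flags and base-pair distances are derived from parsed
    marker ids sharing a locus and coordinate system.
    """
    dosage_ids = [m for m in matrix.marker_ids if matrix.scoring_mode(m) == "dosage"]
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(dosage_ids) for b in dosage_ids[i + 1 :]]
    results: list[LdResult] = []
    for mid_i, mid_j in pairs:
        base = ld_chi2(matrix.column(mid_i), matrix.column(mid_j), min_n=min_n)
        ma, mb = _marker_meta(matrix, mid_i), _marker_meta(matrix, mid_j)
        same_locus = False
        distance = None
        if ma is not None and mb is not None and ma.locus == mb.locus:
            same_locus = True
            if ma.coordinate_system == mb.coordinate_system:
                distance = abs(ma.position - mb.position)
        results.append(LdResult(
            mid_i, mid_j, base.chi2, base.df, base.p_value,
            n=base.n, r=base.r, same_locus=same_locus,
            distance_bp=distance, testable=base.testable,
        ))
    testable_idx = [i for i, r in enumerate(results) if r.testable]
    if testable_idx:
        q = correct_pvalues([results[i].p_value for i in testable_idx], method=method)
        for i, qi in zip(testable_idx, q):
            r = results[i]
            results[i] = LdResult(
                r.marker_i, r.marker_j, r.chi2, r.df, r.p_value, float(qi),
                r.n, r.r, r.same_locus, r.distance_bp, r.testable,
            )
    logger.info("tested %d marker pairs (%d testable), correction=%s",
                len(results), len(testable_idx), method)
    return results


def ld_blocks(
    results: Sequence[LdResult],
    q_threshold: float = 0.05,
    max_span_bp: int = DEFAULT_MAX_SPAN_BP,
) -> list[tuple[str, list[str]]]:
    """Group same-locus markers into LD blocks by single linkage.

    Markers are connected when their pair is significant
    (q <= ``q_threshold``) and within ``max_span_bp``; connected
    components form blocks.  Each block nominates the marker with the
    lowest position (ties by id) as its reporting representative, so
    tables can show one SNP per block.  Returns
    ``(representative, sorted member ids)`` per block.
    """
    g = nx.Graph()
    for r in results:
        if not (r.same_locus and r.testable and r.distance_bp is not None):
            continue
        g.add_node(r.marker_i)
        g.add_node(r.marker_j)
        if r.q_value is not None and r.q_value <= q_threshold and r.distance_bp <= max_span_bp:
            g.add_edge(r.marker_i, r.marker_j)

    def sort_key(mid: str):
        try:
            return (SnpMarker.from_id(mid).position, mid)
        except ValueError:
            return (np.inf, mid)

    blocks = []
    for comp in nx.connected_components(g):
        members = sorted(comp, key=sort_key)
        blocks.append((members[0], members))
    blocks.sort(key=lambda b: sort_key(b[0]))
    return blocks
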