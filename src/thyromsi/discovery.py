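"""Per-feature differential analysis between annotated tissue regions.

Each aligned m/z feature is scored for one ordered region comparison
(positive, reference) with the rank-based ROC AUC — the probability, with
half credit for ties, that a random positive-region pixel is more intense
than a random reference-region pixel — together with the two-sided Wilcoxon
rank-sum p-value.  A feature is called significant under the published rule:
AUC at least ``auc_min`` (or, symmetrically, at most ``1 - auc_min`` for
under-expression) and p at most ``p_max``; the defaults are the published
thresholds AUC 0.75 and p 0.001.  No multiple-testing correction enters the
call; a Benjamini–Hochberg column is emitted for information only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .errors import DataError, ParameterError
from .msi_data import ROIMap
from .preprocess import FeatureMatrix

__all__ = ["DiscoveryResult", "roc_auc", "wilcoxon_p", "discover", "results_frame"]

OVER = "OVER"
UNDER = "UNDER"

DEFAULT_AUC_MIN = 0.75
DEFAULT_P_MAX = 0.001


@dataclass
class DiscoveryResult:
    feature_mz: float
    comparison: tuple[str, str]      # (positive, reference)
    auc: float
    p_value: float
    direction: str                   # OVER iff auc > 0.5
    significant: bool
    q_value: float = float("nan")    # BH-adjusted p, informational only


def roc_auc(a: np.ndarray, b: np.ndarray) -> float:
    """Rank-based ROC AUC of positive sample ``a`` against reference ``b``.

    Equals ``(#{a_i > b_j} + 0.5 #{a_i = b_j}) / (|a| |b|)``; ties get half
    credit.  Computed from midranks in O((n+m) log(n+m)).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("both samples must be non-empty")
    ranks = _stats.rankdata(np.concatenate([a, b]))
    r_a = ranks[: a.size].sum()
    u = r_a - a.size * (a.size + 1) / 2.0
    return float(u / (a.size * b.size))


def wilcoxon_p(a: np.ndarray, b: np.ndarray, method: str = "auto") -> float:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) p-value.

    ``method="auto"`` enumerates the exact null distribution when the pooled
    size is at most 20 and the data are tie-free, and otherwise uses the
    normal approximation with tie correction and continuity correction.
    ``"exact"`` and ``"normal"`` force the respective route.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if method == "auto":
        method = "exact" if (pooled.size <= 20 and not has_ties) else "normal"
    if method == "exact":
        if has_ties:
            raise ParameterError("exact enumeration is only defined without ties")
        res = _stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    elif method == "normal":
        res = _stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    else:
        raise ParameterError(f"unknown method {method!r}")
    return float(min(res.pvalue, 1.0))


def discover(
    fm: FeatureMatrix,
    roi: ROIMap,
    comparison: tuple[str, str],
    auc_min: float = DEFAULT_AUC_MIN,
    p_max: float = DEFAULT_P_MAX,
    per_nodule: bool = False,
) -> list[DiscoveryResult]:
    """Score every feature for one (positive, reference) region comparison.

    Pixels are pooled across nodules within each region label, matching the
    spectrum-level analysis of imaging software; ``per_nodule=True``
    aggregates to one mean observation per nodule first, trading power for
    protection against pseudo-replication.  Results are sorted by
    descending ``|auc - 0.5|``.
    """
    if not 0.5 < auc_min <= 1.0:
        raise ParameterError(f"auc_min must be in (0.5, 1], got {auc_min}")
    if not 0.0 < p_max <= 1.0:
        raise ParameterError(f"p_max must be in (0, 1], got {p_max}")
    pos_label, ref_label = comparison
    labels = np.array(
        [str(roi.label_grid[y, x]) for x, y in fm.pixel_index], dtype=object
    )
    nodules = np.array([int(roi.nodule_grid[y, x]) for x, y in fm.pixel_index])
    pos_rows = np.flatnonzero(labels == pos_label)
    ref_rows = np.flatnonzero(labels == ref_label)
    for label, rows in ((pos_label, pos_rows), (ref_label, ref_rows)):
        if rows.size < 2:
            raise DataError(f"region {label!r} has fewer than 2 pixels")

    def observations(rows: np.ndarray, j: int) -> np.ndarray:
        values = fm.values[rows, j]
        if not per_nodule:
            return values
        ids = nodules[rows]
        groups = [values[ids == nid] for nid in np.unique(ids)]
        return np.array([g.mean() for g in groups])

    results: list[DiscoveryResult] = []
    p_values = np.empty(fm.n_features)
    for j in range(fm.n_features):
        a = observations(pos_rows, j)
        b = observations(ref_rows, j)
        auc = roc_auc(a, b)
        p = wilcoxon_p(a, b)
        p_values[j] = p
        significant = (auc >= auc_min or auc <= 1 - auc_min) and p <= p_max
        results.append(
            DiscoveryResult(
                feature_mz=float(fm.feature_mz[j]),
                comparison=(pos_label, ref_label),
                auc=auc,
                p_value=p,
                direction=OVER if auc > 0.5 else UNDER,
                significant=bool(significant),
            )
        )
    if results:
        q = _stats.false_discovery_control(p_values, method="bh")
        for res, qv in zip(results, q):
            res.q_value = float(qv)
    results.sort(key=lambda r: (-abs(r.auc - 0.5), r.feature_mz))
    return results


def results_frame(results: list[DiscoveryResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature_mz": r.feature_mz,
                "positive": r.comparison[0],
                "reference": r.comparison[1],
                "auc": r.auc,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "direction": r.direction,
                "significant": r.significant,
            }
            for r in results
        ]
    )
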