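"""Benchmarking decomposition components against reference tract maps.

Components carry an arbitrary permutation and scale, so they are matched
to references by maximal Pearson correlation, never by index. The module
also provides the box-plot notch statistic (95% CI of the median,
``median +/- 1.57 * IQR / sqrt(n)``) used to summarize correlation
distributions across component counts.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidSpecError, UndefinedStatisticError


class NotchInterval(NamedTuple):
    low: float
    median: float
    high: float


def map_correlation(map_a: np.ndarray, map_b: np.ndarray) -> float:
    """Pearson product-moment correlation between two spatial maps."""
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidSpecError("maps must be 1-D vectors of equal length")
    if a.size < 2:
        raise InvalidSpecError("correlation requires at least 2 samples")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedStatisticError(
            "correlation undefined for a constant map")
    return float(stats.pearsonr(a, b).statistic)


def best_match_table(components: Sequence[np.ndarray] | np.ndarray,
                     references: Sequence[np.ndarray] | np.ndarray,
                     K: int | None = None,
                     component_ids: Sequence | None = None,
                     reference_ids: Sequence | None = None) -> pd.DataFrame:
    """Best-correlated component per reference map.

    Rows with no defined correlation (constant reference, or all
    components constant) are flagged ``missing`` with NaN ``best_r``
    rather than silently reported as zero. Ties break toward the lowest
    component index.
    """
    comps = [np.asarray(c, dtype=float) for c in components]
    refs = [np.asarray(r, dtype=float) for r in references]
    if not comps or not refs:
        raise InvalidSpecError("need at least one component and one reference")
    comp_ids = list(component_ids) if component_ids is not None \
        else list(range(len(comps)))
    ref_ids = list(reference_ids) if reference_ids is not None \
        else list(range(len(refs)))
    rows = []
    for rid, ref in zip(ref_ids, refs):
        best_r, best_c = -np.inf, None
        for cid, comp in zip(comp_ids, comps):
            try:
                r = map_correlation(comp, ref)
            except UndefinedStatisticError:
                continue
            if r > best_r:
                best_r, best_c = r, cid
        missing = best_c is None
        rows.append({"reference_id": rid,
                     "best_component_id": best_c,
                     "best_r": np.nan if missing else best_r,
                     "missing": missing,
                     "K": len(comps) if K is None else K})
    return pd.DataFrame(rows)


def notch_interval(values: Sequence[float]) -> NotchInterval:
    """Box-plot notch: 95% CI of the median.

    Quartiles use linear interpolation between order statistics and the
    median uses the midpoint convention; the half-width is
    ``1.57 * IQR / sqrt(n)``.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InvalidSpecError("notch interval requires at least one value")
    med = float(np.median(v))
    q1, q3 = np.percentile(v, [25, 75])
    half = 1.57 * float(q3 - q1) / np.sqrt(v.size)
    return NotchInterval(med - half, med, med + half)
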