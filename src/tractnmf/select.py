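"""Screening and anatomical selection of decomposition components.

Mirrors a tract-identification workflow: components are scored by the
product of their mean gray-matter signal in two regions of interest
(e.g. anterior temporal pole x prefrontal cortex for an anterior
temporal-frontal connection), contralateral signal is zeroed, candidates
must pass quantitative anatomical filters (endpoint mass, minimal
parietal/occipital involvement, tract-core orientation), and components
that split one connection across several factors are summed back into a
single reconstruction.

The visual-inspection step of the original workflow is replaced by
declared numeric surrogates (thresholds in :class:`FilterThresholds` and
the median + 2*MAD / top-5 screening rule), all exposed in configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, InvalidMaskError, InvalidSpecError
from .synthetic import HEMISPHERES, CohortGeometry

#: Anterior-posterior axis of the white-matter box (axis 0).
_AP_AXIS = np.array([1.0, 0.0, 0.0])


@dataclass
class ScreenResult:
    component_id: int
    mean_roiA: float
    mean_roiB: float
    product_score: float
    selected: bool


@dataclass
class FilterThresholds:
    """Numeric surrogates for the anatomical selection criteria."""

    parietal_max: float = 0.10   # max parietal share of gray mass
    occipital_max: float = 0.10  # max occipital share (ATF only)
    endpoint_min: float = 0.15   # min gray-mass share at each endpoint
    axis_cone_deg: float = 30.0  # OTF tract core vs anterior-posterior axis


@dataclass
class ConnectionReconstruction:
    """One or more merged components identified as a named connection."""

    connection_class: str  # ATF | OTF
    member_component_ids: list[int]
    gray_map: np.ndarray   # per-vertex, contralateral side zeroed
    white_map: np.ndarray  # per-voxel
    hemisphere: str


def roi_mean(gray_map: np.ndarray, roi_mask: np.ndarray) -> float:
    """Arithmetic mean of a gray map over a region of interest.

    ``roi_mask`` is a vertex index array or boolean mask; it must select
    at least one vertex.
    """
    gray_map = np.asarray(gray_map, dtype=float)
    roi = np.asarray(roi_mask)
    values = gray_map[roi]
    if values.size == 0:
        raise InvalidMaskError("ROI mask selects no vertices")
    return float(values.mean())


def screening_scores(H: np.ndarray, roiA: np.ndarray, roiB: np.ndarray,
                     top_n: int = 5, mad_factor: float = 2.0
                     ) -> list[ScreenResult]:
    """Score every component by mean(ROI A) x mean(ROI B) and mark the
    selected set.

    Selection takes the smaller nonempty of (a) scores strictly above
    median + ``mad_factor`` x MAD and (b) the ``top_n`` highest scores;
    zero-score components are never selected while any positive score
    exists.
    """
    H = np.atleast_2d(np.asarray(H, dtype=float))
    mean_a = np.array([roi_mean(row, roiA) for row in H])
    mean_b = np.array([roi_mean(row, roiB) for row in H])
    scores = mean_a * mean_b

    positive = np.flatnonzero(scores > 0)
    selected: set[int] = set()
    if positive.size:
        med = float(np.median(scores))
        mad = float(np.median(np.abs(scores - med)))
        above = set(np.flatnonzero(scores > med + mad_factor * mad)) & set(positive)
        # top_n among positive scores, ties broken by lower index
        order = sorted(positive, key=lambda i: (-scores[i], i))
        top = set(order[:top_n])
        if not above:
            selected = top
        else:
            selected = above if len(above) <= len(top) else top
    return [ScreenResult(i, float(mean_a[i]), float(mean_b[i]),
                         float(scores[i]), i in selected)
            for i in range(len(scores))]


def zero_contralateral(gray_map: np.ndarray, hemisphere_of: np.ndarray,
                       keep: str) -> np.ndarray:
    """Zero the gray map outside the kept hemisphere (idempotent)."""
    if keep not in HEMISPHERES:
        raise DomainError(f"unknown hemisphere {keep!r}")
    hemisphere_of = np.asarray(hemisphere_of)
    unknown = set(np.unique(hemisphere_of)) - set(HEMISPHERES)
    if unknown:
        raise DomainError(f"unknown hemisphere labels {sorted(unknown)}")
    out = np.array(gray_map, dtype=float, copy=True)
    out[hemisphere_of != keep] = 0.0
    return out


def principal_axis_angle(white_map: np.ndarray,
                         voxel_position: np.ndarray) -> float:
    """Angle (degrees) between the dominant eigenvector of the
    intensity-weighted voxel-coordinate covariance and the
    anterior-posterior axis."""
    w = np.asarray(white_map, dtype=float)
    total = w.sum()
    if total <= 0:
        raise DomainError("principal axis undefined for a zero white map")
    mu = (w[:, None] * voxel_position).sum(axis=0) / total
    centered = voxel_position - mu
    cov = (w[:, None, None] * (centered[:, :, None] * centered[:, None, :])
           ).sum(axis=0) / total
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, np.argmax(evals)]
    cosang = abs(float(v @ _AP_AXIS)) / np.linalg.norm(v)
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def anatomical_filter(gray_map: np.ndarray, white_map: np.ndarray,
                      geometry: CohortGeometry, connection_class: str,
                      thresholds: FilterThresholds | None = None
                      ) -> tuple[bool, dict]:
    """Apply the quantitative anatomical criteria for a connection class.

    ATF passes iff parietal and occipital gray-mass fractions are below
    their ceilings and both the anterior temporal pole and prefrontal
    cortex hold at least the endpoint minimum. OTF passes iff the
    parietal fraction is below its ceiling, occipital and prefrontal
    endpoints hold the minimum, and the white tract core runs within the
    axis cone of the anterior-posterior axis.

    Returns ``(passed, diagnostics)``; a zero-mass candidate fails with a
    ``ZERO_MASS`` diagnostic.
    """
    if connection_class not in ("ATF", "OTF"):
        raise InvalidSpecError(f"unknown connection class {connection_class!r}")
    th = thresholds or FilterThresholds()
    gray = np.asarray(gray_map, dtype=float)
    if gray.shape != (geometry.n_vertices,):
        raise InvalidSpecError("gray map does not conform to the geometry")
    total = gray.sum()
    diag: dict = {"connection_class": connection_class, "total_gray_mass": float(total)}
    if total <= 0:
        diag["reason"] = "ZERO_MASS"
        return False, diag

    def frac(parcels) -> float:
        return float(gray[geometry.vertices_of(parcels)].sum() / total)

    diag["parietal_fraction"] = frac("PARIETAL")
    diag["occipital_fraction"] = frac("OCCIPITAL")
    diag["temporal_pole_fraction"] = frac("TEMPORAL_POLE")
    diag["prefrontal_fraction"] = frac(("OFC", "PFC_OTHER"))

    if connection_class == "ATF":
        passed = (diag["parietal_fraction"] < th.parietal_max
                  and diag["occipital_fraction"] < th.occipital_max
                  and diag["temporal_pole_fraction"] >= th.endpoint_min
                  and diag["prefrontal_fraction"] >= th.endpoint_min)
    else:
        w = np.asarray(white_map, dtype=float)
        if w.sum() <= 0:
            diag["reason"] = "ZERO_MASS"
            return False, diag
        diag["axis_angle_deg"] = principal_axis_angle(w, geometry.voxel_position)
        passed = (diag["parietal_fraction"] < th.parietal_max
                  and diag["occipital_fraction"] >= th.endpoint_min
                  and diag["prefrontal_fraction"] >= th.endpoint_min
                  and diag["axis_angle_deg"] <= th.axis_cone_deg)
    return bool(passed), diag


def merge_components(members: list[tuple[np.ndarray, np.ndarray]],
                     connection_class: str, hemisphere: str,
                     hemisphere_of: np.ndarray,
                     component_ids: list[int] | None = None
                     ) -> ConnectionReconstruction:
    """Sum split components into a single connection reconstruction.

    ``members`` is a list of ``(gray_map, white_map)`` pairs from the
    same decomposition. Gray maps are contralaterally zeroed before
    summation; the result is order-independent.
    """
    if not members:
        raise InvalidSpecError("merge requires at least one component")
    gray = np.zeros_like(np.asarray(members[0][0], dtype=float))
    white = np.zeros_like(np.asarray(members[0][1], dtype=float))
    for g, w in members:
        gray += zero_contralateral(g, hemisphere_of, hemisphere)
        white += np.asarray(w, dtype=float)
    ids = list(component_ids) if component_ids is not None \
        else list(range(len(members)))
    return ConnectionReconstruction(connection_class, ids, gray, white,
                                    hemisphere)
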