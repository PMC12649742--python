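"""The orbitofrontal bias index (OBI).

OBI quantifies how strongly a connection's prefrontal termination is
confined to the orbitofrontal cortex (OFC), a subregion of prefrontal
cortex (PFC):

    OBI = (sum of gray signal over OFC / sum over PFC)
          / (|OFC| / |PFC|)

i.e. the OFC share of prefrontal termination intensity normalized by the
OFC share of prefrontal size (vertex counts stand in for surface area).
A uniform termination gives OBI = 1; values above 1 indicate an
orbitofrontal bias, up to |PFC|/|OFC| when all prefrontal mass is
orbitofrontal. The sum-ratio form equals the ratio of ROI means, an
identity used as an internal consistency check.

An alternative denominator convention normalizes OFC against the *rest*
of PFC (``denominator="rest"``); both conventions give 1 on uniform
maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidMaskError, InvalidSpecError, UndefinedStatisticError
from .select import ConnectionReconstruction


@dataclass
class ObiRecord:
    species: str
    subject_id: str
    hemisphere: str
    K: int
    connection_class: str  # ATF | OTF
    obi: float
    mask_set_id: str


@dataclass(frozen=True)
class MaskSet:
    """A named OFC/PFC vertex-mask pair, optionally species-specific."""

    mask_set_id: str
    ofc_mask: np.ndarray  # vertex indices
    pfc_mask: np.ndarray  # vertex indices, superset of ofc_mask
    species: str | None = None  # None = applies to every species


def _index_set(mask: np.ndarray, n: int | None = None) -> np.ndarray:
    m = np.asarray(mask)
    if m.dtype == bool:
        return np.flatnonzero(m)
    return m.astype(int)


def compute_obi(gray_map: np.ndarray, ofc_mask: np.ndarray,
                pfc_mask: np.ndarray, denominator: str = "pfc") -> float:
    """OBI of a gray termination map for an OFC/PFC mask pair.

    ``denominator="pfc"`` (default) normalizes the OFC intensity share by
    |OFC|/|PFC|; ``"rest"`` compares OFC against PFC \\ OFC instead.
    Raises if OFC is not contained in PFC, either mask is empty, or the
    map carries no prefrontal mass.
    """
    gray = np.asarray(gray_map, dtype=float)
    ofc = _index_set(ofc_mask)
    pfc = _index_set(pfc_mask)
    if ofc.size == 0 or pfc.size == 0:
        raise InvalidMaskError("OFC and PFC masks must be nonempty")
    if not np.isin(ofc, pfc).all():
        raise InvalidMaskError("OFC mask must be a subset of the PFC mask")
    if denominator not in ("pfc", "rest"):
        raise InvalidSpecError(f"unknown denominator {denominator!r}")
    sum_pfc = gray[pfc].sum()
    if sum_pfc <= 0:
        raise UndefinedStatisticError(
            "OBI undefined: no prefrontal termination mass")
    sum_ofc = gray[ofc].sum()
    if denominator == "pfc":
        return float((sum_ofc / sum_pfc) / (ofc.size / pfc.size))
    rest = np.setdiff1d(pfc, ofc)
    if rest.size == 0:
        raise InvalidMaskError(
            "denominator='rest' requires PFC vertices outside OFC")
    sum_rest = gray[rest].sum()
    if sum_rest <= 0:
        raise UndefinedStatisticError(
            "OBI (rest convention) undefined: no mass outside OFC")
    return float((sum_ofc / sum_rest) / (ofc.size / rest.size))


def obi_table(connections: Sequence[tuple[ConnectionReconstruction, Mapping]],
              mask_sets: Sequence[MaskSet],
              denominator: str = "pfc") -> pd.DataFrame:
    """One OBI record per connection x applicable mask set.

    ``connections`` pairs each reconstruction with a metadata mapping
    carrying ``species``, ``subject_id``, ``hemisphere`` and ``K`` for
    the downstream nested-ANOVA hierarchy. A mask set applies to a
    connection when its ``species`` is None or matches the connection's.
    """
    rows = []
    for conn, meta in connections:
        applicable = [m for m in mask_sets
                      if m.species is None or m.species == meta["species"]]
        if not applicable:
            raise InvalidSpecError(
                f"no mask set for species {meta['species']!r}")
        for mset in applicable:
            try:
                value = compute_obi(conn.gray_map, mset.ofc_mask,
                                    mset.pfc_mask, denominator=denominator)
            except (UndefinedStatisticError, InvalidMaskError) as exc:
                raise type(exc)(
                    f"{exc} (connection {conn.connection_class} "
                    f"{meta.get('subject_id')}/{meta.get('hemisphere')}"
                    f"/K={meta.get('K')})") from exc
            rows.append({"species": meta["species"],
                         "subject_id": meta["subject_id"],
                         "hemisphere": meta["hemisphere"],
                         "K": meta["K"],
                         "connection_class": conn.connection_class,
                         "mask_set_id": mset.mask_set_id,
                         "obi": value})
    return pd.DataFrame(rows)
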