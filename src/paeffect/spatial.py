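"""Protection assignment and within-study land-use matching.

A site is "protected" when its coordinates fall inside any protected-area
polygon (boundary points count as inside). The containing area's IUCN
category maps onto a four-level management-group factor, and its age and
reported area onto a size/age class. The matched-sites dataset keeps, within
each study, only sites whose land use occurs on both sides of the
protected-area boundary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon, shape

from paeffect.constants import (
    DEFAULT_REFERENCE_YEAR,
    IUCN_TO_GROUP,
    MAX_TYPICAL_AGE_YEARS,
    MAX_TYPICAL_AREA_KM2,
    SMALL_AREA_KM2,
    YOUNG_AGE_YEARS,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ProtectedArea",
    "point_in_polygon",
    "assign_protection",
    "match_sites_by_land_use",
    "read_protected_areas",
]

# Most restrictive first: used to resolve sites inside overlapping areas.
_RESTRICTIVENESS = {"I-II": 0, "III-VI": 1, "unknown": 2}


@dataclass(frozen=True)
class ProtectedArea:
    """One protected-area polygon with its register attributes."""

    pa_id: str
    geometry: Polygon
    iucn_category: str | None  # Ia, Ib, II..VI, or None when unreported
    year_established: float | None
    area_km2: float | None

    @property
    def management_group(self) -> str:
        if self.iucn_category in IUCN_TO_GROUP:
            return IUCN_TO_GROUP[self.iucn_category]
        return "unknown"


def _check_ring(ring) -> Polygon:
    ring = [(float(x), float(y)) for x, y in ring]
    if len(ring) < 4 or ring[0] != ring[-1]:
        raise ValueError("polygon ring must be closed (first vertex == last)")
    lons = [x for x, _ in ring]
    if max(lons) - min(lons) > 180.0:
        raise ValueError(
            "polygon spans more than 180 degrees of longitude; "
            "antimeridian-crossing polygons are not supported"
        )
    return Polygon(ring)


def point_in_polygon(point, polygon) -> bool:
    """Boundary-inclusive containment of a lon/lat point in a single ring.

    Containment is evaluated on the plane of raw coordinates (topological,
    no projection); points exactly on an edge or vertex count as inside.
    """
    x, y = float(point[0]), float(point[1])
    if not (np.isfinite(x) and np.isfinite(y)):
        raise ValueError("point coordinates must be finite")
    poly = _check_ring(polygon)
    return bool(poly.covers(Point(x, y)))


def read_protected_areas(source) -> list[ProtectedArea]:
    """Load protected areas from GeoJSON (path, dict, or file object).

    Expects Polygon/MultiPolygon features with properties ``pa_id``,
    ``iucn_category``, ``year_established``, ``area_km2``.
    """
    if isinstance(source, dict):
        gj = source
    elif hasattr(source, "read"):
        gj = json.load(source)
    else:
        with open(source) as fh:
            gj = json.load(fh)
    pas = []
    for k, feat in enumerate(gj.get("features", [])):
        props = feat.get("properties", {}) or {}
        geom = shape(feat["geometry"])
        minx, _, maxx, _ = geom.bounds
        if maxx - minx > 180.0:
            raise ValueError("protected-area polygon spans the antimeridian")
        cat = props.get("iucn_category")
        if cat in ("", None):
            cat = None
        year = props.get("year_established")
        area = props.get("area_km2")
        if area is not None and not area > 0:
            raise ValueError(f"protected area {props.get('pa_id', k)}: area_km2 must be > 0")
        pas.append(
            ProtectedArea(
                pa_id=str(props.get("pa_id", f"pa_{k}")),
                geometry=geom,
                iucn_category=cat,
                year_established=None if year is None else float(year),
                area_km2=None if area is None else float(area),
            )
        )
    return pas


def _size_age_class(pa: ProtectedArea, reference_year: float) -> str | None:
    if pa.year_established is None or pa.area_km2 is None:
        return None
    age = reference_year - pa.year_established
    if age < 0:
        logger.warning("PA %s established after reference year; age clamped to 0", pa.pa_id)
        age = 0.0
    if age > MAX_TYPICAL_AGE_YEARS:
        logger.warning("PA %s age %.0f y exceeds the typical sampled range", pa.pa_id, age)
    if pa.area_km2 > MAX_TYPICAL_AREA_KM2:
        logger.warning(
            "PA %s area %.0f km^2 exceeds the typical sampled range", pa.pa_id, pa.area_km2
        )
    young = age < YOUNG_AGE_YEARS
    small = pa.area_km2 < SMALL_AREA_KM2
    return ("young" if young else "old") + "-" + ("small" if small else "large")


def assign_protection(
    sites: pd.DataFrame,
    protected_areas: list[ProtectedArea],
    reference_year: float = DEFAULT_REFERENCE_YEAR,
) -> pd.DataFrame:
    """Attach protection attributes to every site.

    Parameters
    ----------
    sites
        Must carry ``site_id, longitude, latitude``.
    protected_areas
        Polygons with IUCN category / year / area attributes.
    reference_year
        Year against which protected-area ages are computed (the
        protected-area database snapshot year).

    Returns
    -------
    Copy of ``sites`` with columns ``protected`` (bool), ``pa_id``,
    ``management_group``, ``size_age_class`` added. A site inside several
    overlapping areas is attributed to the most restrictively managed one
    (I-II over III-VI over unknown; ties broken by pa_id) and logged.
    """
    out = sites.copy()
    pts = shapely.points(
        np.asarray(out["longitude"], dtype=float),
        np.asarray(out["latitude"], dtype=float),
    )
    hits: list[list[ProtectedArea]] = [[] for _ in range(len(out))]
    for pa in protected_areas:
        inside = shapely.covers(pa.geometry, pts)
        for i in np.flatnonzero(inside):
            hits[i].append(pa)

    prot, pa_ids, groups, classes = [], [], [], []
    n_overlap = 0
    for h in hits:
        if not h:
            prot.append(False)
            pa_ids.append(None)
            groups.append("unprotected")
            classes.append("unprotected")
            continue
        if len(h) > 1:
            n_overlap += 1
            h = sorted(h, key=lambda p: (_RESTRICTIVENESS[p.management_group], p.pa_id))
        pa = h[0]
        prot.append(True)
        pa_ids.append(pa.pa_id)
        groups.append(pa.management_group)
        classes.append(_size_age_class(pa, reference_year))
    if n_overlap:
        logger.warning(
            "%d sites fell inside overlapping protected areas; "
            "attributed to the most restrictive one",
            n_overlap,
        )
    out["protected"] = prot
    out["pa_id"] = pa_ids
    out["management_group"] = groups
    out["size_age_class"] = classes
    return out


def match_sites_by_land_use(
    sites: pd.DataFrame, *, on_intensity: bool = False
) -> pd.DataFrame:
    """Within-study subset of sites whose land use straddles the boundary.

    A site is retained iff its land-use class (optionally the land-use x
    use-intensity combination, with ``on_intensity=True``) occurs among its
    study's sites both inside and outside protected areas. Studies with no
    such land use drop out entirely. The operation is idempotent.
    """
    req = {"study_id", "land_use", "protected"}
    if not req.issubset(sites.columns):
        raise ValueError(f"matching needs columns {sorted(req)}")
    keycols = ["land_use", "use_intensity"] if on_intensity else ["land_use"]
    keep = pd.Series(False, index=sites.index)
    for _, g in sites.groupby("study_id", sort=False):
        inside = g[g["protected"].astype(bool)]
        outside = g[~g["protected"].astype(bool)]
        common = set(map(tuple, inside[keycols].itertuples(index=False))) & set(
            map(tuple, outside[keycols].itertuples(index=False))
        )
        if not common:
            continue
        mask = g[keycols].apply(tuple, axis=1).isin(common)
        keep.loc[g.index[mask]] = True
    return sites.loc[keep].copy()
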