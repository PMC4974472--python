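"""Site-level biodiversity measures.

Four responses are computed per sampled site from a long-format community
table and a species range table:

* within-sample species richness ``S`` — number of taxa recorded present;
* total abundance ``N`` — summed abundance (undefined for occurrence data);
* rarefied richness ``E[S_n]`` — analytic (hypergeometric) expected richness
  in a subsample of ``n`` individuals, where ``n`` is the smallest site
  total within the study;
* endemicity — reciprocal of the community-weighted mean (CWM) log10
  geographic range size; higher values mean narrow-ranged assemblages.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)

__all__ = [
    "site_richness_abundance",
    "rarefied_richness",
    "study_rarefaction",
    "endemicity",
    "compute_site_measures",
]


def site_richness_abundance(measurements) -> tuple[int, float]:
    """Richness ``S`` and total abundance ``N`` from one site's measurements.

    Parameters
    ----------
    measurements
        Per-taxon abundances (counts or densities) or 0/1 occurrences for a
        single site.

    Returns
    -------
    (S, N)
        ``S`` counts taxa with a measurement strictly greater than zero;
        ``N`` is the plain sum. For occurrence-coded data ``N`` is the
        number of present taxa and should be discarded by the caller.
    """
    a = np.asarray(measurements, dtype=float)
    if a.size and np.any(a < 0):
        raise ValueError("negative abundance")
    if a.size and not np.all(np.isfinite(a)):
        raise ValueError("non-finite abundance")
    return int(np.count_nonzero(a > 0)), float(a.sum())


def rarefied_richness(counts, n: int) -> float:
    """Analytic expected richness in a random subsample of ``n`` individuals.

    Uses the hypergeometric expectation
    ``E[S_n] = sum_i (1 - C(N - N_i, n) / C(N, n))`` over taxa with count
    ``N_i > 0``, evaluated with log-gamma functions so that large counts do
    not overflow.
    """
    c = np.asarray(counts)
    cf = c.astype(float)
    if cf.size and np.any(cf < 0):
        raise ValueError("counts must be nonnegative")
    if cf.size and not np.all(np.isfinite(cf)):
        raise ValueError("counts must be finite")
    if not np.all(cf == np.floor(cf)):
        raise ValueError("rarefaction is defined on integer counts of individuals")
    c = cf.astype(np.int64)
    total = int(c.sum())
    if not float(n) == int(n):
        raise ValueError("subsample size n must be an integer")
    n = int(n)
    if n < 0 or n > total:
        raise ValueError(f"need 0 <= n <= total count ({total}), got {n}")
    if n == 0:
        return 0.0
    pos = c[c > 0]
    # log C(N - Ni, n) - log C(N, n); C(m, n) = 0 when m < n.
    rest = total - pos
    with np.errstate(invalid="ignore"):
        log_keep = (
            gammaln(rest + 1)
            - gammaln(n + 1)
            - gammaln(rest - n + 1)
            - (gammaln(total + 1) - gammaln(n + 1) - gammaln(total - n + 1))
        )
    p_absent = np.where(rest >= n, np.exp(log_keep), 0.0)
    return float(np.sum(1.0 - p_absent))


def study_rarefaction(site_counts: dict[str, np.ndarray]) -> tuple[dict[str, float], int]:
    """Rarefy every site of one study to the study's minimum site total.

    Parameters
    ----------
    site_counts
        Mapping of site id to that site's per-taxon integer counts.

    Returns
    -------
    (values, n_min)
        ``values[site] = E[S_{n_min}]``; all values are NaN when any site
        total is zero (``n_min = 0`` leaves the whole study undefined).
    """
    totals = {s: float(np.asarray(c, dtype=float).sum()) for s, c in site_counts.items()}
    if not totals:
        return {}, 0
    n_min = int(min(totals.values()))
    if n_min < 1:
        return {s: float("nan") for s in site_counts}, 0
    return {s: rarefied_richness(c, n_min) for s, c in site_counts.items()}, n_min


def endemicity(
    measurements,
    range_km2,
    *,
    occurrence: bool = False,
) -> tuple[float, float]:
    """Community-weighted mean log10 range size and its reciprocal.

    ``CWM = sum_i a_i log10(R_i) / sum_i a_i`` over taxa recorded present,
    with abundances as weights (equal weights for occurrence data);
    endemicity is ``1 / CWM``. Taxa without a range entry must be removed
    by the caller before this point.

    Returns
    -------
    (cwm_log10_range, endemicity)
    """
    a = np.asarray(measurements, dtype=float)
    r = np.asarray(range_km2, dtype=float)
    if a.shape != r.shape:
        raise ValueError("measurements and ranges must align")
    if a.size and np.any(a < 0):
        raise ValueError("negative abundance")
    if np.any(r[a > 0] <= 0):
        raise ValueError("range sizes must be positive")
    keep = a > 0
    if not np.any(keep):
        return float("nan"), float("nan")
    w = np.ones(keep.sum()) if occurrence else a[keep]
    cwm = float(np.sum(w * np.log10(r[keep])) / np.sum(w))
    if cwm <= 0:
        raise ValueError(
            "community-weighted mean log10 range size is not positive; "
            "range sizes below 1 km^2 need rescaling before use"
        )
    return cwm, 1.0 / cwm


def _is_integer_valued(x: np.ndarray) -> bool:
    x = np.asarray(x, dtype=float)
    return bool(np.all(np.isfinite(x)) and np.all(x == np.floor(x)))


def compute_site_measures(
    community: pd.DataFrame,
    sites: pd.DataFrame,
    ranges: pd.DataFrame,
) -> pd.DataFrame:
    """Compute all four measures for every site.

    Parameters
    ----------
    community
        Columns ``site_id, taxon_id, measurement, measurement_type`` with
        measurement_type in {"abundance", "occurrence"}; one type per study.
    sites
        Site table with at least ``site_id`` and ``study_id``.
    ranges
        Columns ``taxon_id, range_km2``.

    Returns
    -------
    DataFrame with one row per site: ``site_id, richness, abundance,
    rarefied_richness, n_min, cwm_log10_range, endemicity`` (NaN marks an
    undefined measure).

    Notes
    -----
    Rarefaction is restricted to studies whose abundances are integer
    counts; density-valued studies get NaN rather than rounded counts.
    Abundance ``N`` is NaN for occurrence-coded studies. Taxa lacking a
    range entry are dropped from the endemicity sums with a logged warning.
    """
    req = {"site_id", "taxon_id", "measurement", "measurement_type"}
    if not req.issubset(community.columns):
        raise ValueError(f"community table must have columns {sorted(req)}")
    bad_type = set(community["measurement_type"].unique()) - {"abundance", "occurrence"}
    if bad_type:
        raise ValueError(f"unknown measurement_type values: {sorted(bad_type)}")
    if (community["measurement"] < 0).any():
        raise ValueError("negative measurement in community table")

    site_study = sites.set_index("site_id")["study_id"]
    unknown = set(community["site_id"]) - set(site_study.index)
    if unknown:
        raise ValueError(f"community rows reference unknown sites: {sorted(unknown)[:5]}")

    range_map = ranges.set_index("taxon_id")["range_km2"]
    missing_ranges = set(community["taxon_id"]) - set(range_map.index)
    if missing_ranges:
        logger.warning(
            "%d taxa lack range entries and are dropped from endemicity",
            len(missing_ranges),
        )

    comm = community.merge(
        site_study.rename("study_id"), left_on="site_id", right_index=True, how="left"
    )

    rows: list[dict] = []
    # Group once by study so rarefaction sees every site of the study,
    # including sites that recorded no taxa (they appear in `sites`).
    for study_id, sdf in sites.groupby("study_id", sort=True):
        sub = comm[comm["study_id"] == study_id]
        types = set(sub["measurement_type"].unique())
        if len(types) > 1:
            raise ValueError(f"study {study_id} mixes abundance and occurrence rows")
        occ = types == {"occurrence"}
        by_site = {sid: g for sid, g in sub.groupby("site_id")}

        base: dict[str, dict] = {}
        for sid in sdf["site_id"]:
            g = by_site.get(sid)
            meas = g["measurement"].to_numpy() if g is not None else np.empty(0)
            s, n = site_richness_abundance(meas)
            base[sid] = {
                "site_id": sid,
                "richness": s,
                "abundance": float("nan") if occ else n,
            }

        # Rarefaction: count-based studies only, common n_min across sites.
        if not occ and all(
            _is_integer_valued(g["measurement"].to_numpy()) for g in by_site.values()
        ):
            counts = {
                sid: (
                    by_site[sid]["measurement"].to_numpy()
                    if sid in by_site
                    else np.empty(0)
                )
                for sid in sdf["site_id"]
            }
            esn, n_min = study_rarefaction(counts)
        else:
            esn = {sid: float("nan") for sid in sdf["site_id"]}
            n_min = 0
        for sid in sdf["site_id"]:
            base[sid]["rarefied_richness"] = esn.get(sid, float("nan"))
            base[sid]["n_min"] = n_min

        for sid in sdf["site_id"]:
            g = by_site.get(sid)
            cwm = end = float("nan")
            if g is not None:
                have = g[g["taxon_id"].isin(range_map.index)]
                if len(have) < len(g):
                    logger.warning(
                        "site %s: %d taxa without range entries dropped from CWM",
                        sid,
                        len(g) - len(have),
                    )
                if len(have) and (have["measurement"] > 0).any():
                    cwm, end = endemicity(
                        have["measurement"].to_numpy(),
                        range_map.loc[have["taxon_id"]].to_numpy(),
                        occurrence=occ,
                    )
            base[sid]["cwm_log10_range"] = cwm
            base[sid]["endemicity"] = end
        rows.extend(base.values())

    out = pd.DataFrame(rows)
    return out[
        [
            "site_id",
            "richness",
            "abundance",
            "rarefied_richness",
            "n_min",
            "cwm_log10_range",
            "endemicity",
        ]
    ]
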