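"""Reading and writing the delimited-text input bundle.

A bundle directory holds ``sites.csv``, ``community.csv``, ``ranges.csv``,
``protected_areas.geojson`` (RFC 7946) and, for synthetic worlds,
``truth.json``. All tables are UTF-8, comma-delimited, with header rows;
coordinates are decimal degrees (WGS84).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

SITE_COLUMNS = [
    "site_id",
    "study_id",
    "block_id",
    "longitude",
    "latitude",
    "land_use",
    "use_intensity",
    "elevation",
    "slope",
    "ag_suitability",
    "taxonomic_group",
]
COMMUNITY_COLUMNS = ["site_id", "taxon_id", "measurement", "measurement_type"]
RANGE_COLUMNS = ["taxon_id", "range_km2"]


def write_bundle(world, outdir) -> Path:
    """Write a SyntheticWorld (or equivalent) as the standard bundle."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    world.sites.to_csv(out / "sites.csv", index=False)
    world.community.to_csv(out / "community.csv", index=False)
    world.ranges.to_csv(out / "ranges.csv", index=False)
    with open(out / "protected_areas.geojson", "w") as fh:
        json.dump(world.protected_areas, fh)
    if getattr(world, "truth", None) is not None:
        with open(out / "truth.json", "w") as fh:
            json.dump(world.truth, fh, indent=0)
    return out


def read_bundle(indir):
    """Read a bundle directory back into a SyntheticWorld container."""
    from paeffect.synthetic import SyntheticWorld

    ind = Path(indir)
    sites = pd.read_csv(ind / "sites.csv")
    community = pd.read_csv(ind / "community.csv")
    ranges = pd.read_csv(ind / "ranges.csv")
    with open(ind / "protected_areas.geojson") as fh:
        pas = json.load(fh)
    truth = None
    if (ind / "truth.json").exists():
        with open(ind / "truth.json") as fh:
            truth = json.load(fh)
    return SyntheticWorld(
        sites=sites, community=community, ranges=ranges, protected_areas=pas, truth=truth
    )
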