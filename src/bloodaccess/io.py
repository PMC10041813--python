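"""GeoJSON and tabular I/O for the pipeline's vector artifacts."""

from __future__ import annotations

import json
from pathlib import Path

import shapely
from shapely.geometry import mapping, shape

__all__ = ["write_geojson", "read_geojson"]


def write_geojson(features, path, class_key: str = "class") -> None:
    """Write [{"geometry": shapely geom, "class": label, ...}] as GeoJSON."""
    out = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(f["geometry"]),
                "properties": {k: v for k, v in f.items() if k != "geometry"},
            }
            for f in features
        ],
    }
    Path(path).write_text(json.dumps(out))


def read_geojson(path) -> list[dict]:
    """Read a FeatureCollection back into [{"geometry": ..., props}]."""
    doc = json.loads(Path(path).read_text())
    feats = []
    for f in doc["features"]:
        rec = dict(f.get("properties") or {})
        rec["geometry"] = shape(f["geometry"])
        feats.append(rec)
    return feats
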