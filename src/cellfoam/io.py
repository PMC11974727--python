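"""Readers and writers for annotations and result tables.

Annotations travel as CSV with columns ``frame,label,x,y`` or as JSON;
result tables are UTF-8 CSV with a header row and unit-suffixed column
names.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .geometry import VertexAnnotation

ANNOTATION_COLUMNS = ("frame", "label", "x", "y")


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read point annotations from CSV (frame,label,x,y) or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            records = json.load(fh)
        df = pd.DataFrame(records)
    else:
        df = pd.read_csv(path)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation file {path} lacks columns: {sorted(missing)}")
    return df[list(ANNOTATION_COLUMNS)].astype(
        {"frame": int, "label": str, "x": float, "y": float})


def vertex_annotations(df: pd.DataFrame) -> list[VertexAnnotation]:
    """Group rows into tri-furrow annotations.

    Labels follow ``vertex:<id>`` for the node and ``ray:<id>`` for its
    three ray endpoints.
    """
    out = []
    ids = sorted({lab.split(":", 1)[1] for lab in df["label"]
                  if ":" in lab and lab.startswith(("vertex", "ray"))})
    for vid in ids:
        vrow = df[df["label"] == f"vertex:{vid}"]
        rrows = df[df["label"] == f"ray:{vid}"]
        if len(vrow) != 1 or len(rrows) != 3:
            raise ValueError(f"annotation group {vid!r} needs 1 vertex and 3 rays")
        out.append(VertexAnnotation(
            vertex=(float(vrow["x"].iloc[0]), float(vrow["y"].iloc[0])),
            rays=tuple((float(r.x), float(r.y)) for r in rrows.itertuples())))
    return out


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
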