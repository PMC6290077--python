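"""Report surfaces: per-transcript tables, map-ready points, network tables.

These mirror the three outputs an analyst works from: the expression of a
transcript across datasets (raw fold change in tables, log2 in plots), a
geographic scatter of the datasets where it is significant, and the tabular
view of its correlation network.
"""

from __future__ import annotations

import difflib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import DatasetMeta, Filter, IntegratedTable, subset_datasets
from .corrnet import CorrelationNetwork
from .errors import ValidationError

UP_HIGH_FC = 5.0  # "fold changes of 1-5" are orange; > 5 red; < 1 green


@dataclass
class MapPoint:
    dataset_id: str
    latitude: float
    longitude: float
    category: str  # down | up_low | up_high
    fold_change: float
    q_value: float


@dataclass
class TranscriptReport:
    transcript_id: str
    table: pd.DataFrame  # dataset_id, fold_change, log2_fc, q_value, significant + metadata
    n_significant: int
    alpha: float


def classify_fold_change(fc: float) -> str:
    """Map a significant fold change to its map category.

    Down-regulation (FC < 1) is green, 1 < FC <= 5 orange (up_low), FC > 5
    red (up_high).  FC exactly 1 has no category (callers warn and skip).
    """
    if fc < 1.0:
        return "down"
    if fc == 1.0:
        raise ValidationError("fold change exactly 1 has no direction")
    return "up_low" if fc <= UP_HIGH_FC else "up_high"


def transcript_report(
    table: IntegratedTable,
    meta: Sequence[DatasetMeta],
    transcript_id: str,
    filter: Filter = None,
    alpha: float = 0.05,
) -> TranscriptReport:
    """Fold change and significance of one transcript across selected datasets."""
    if transcript_id not in table.fc.index:
        near = difflib.get_close_matches(transcript_id, [str(t) for t in table.fc.index], n=5)
        raise ValidationError(f"unknown transcript {transcript_id!r}; near matches: {near}")
    selected = [d for d in subset_datasets(meta, filter) if d in table.datasets]
    if not selected:
        warnings.warn("filter excludes every dataset; empty report", stacklevel=2)
    by_id = {m.dataset_id: m for m in meta}
    rows = []
    n_sig = 0
    for ds in selected:
        fc = table.fc.loc[transcript_id, ds]
        q = table.q.loc[transcript_id, ds]
        sig = bool(pd.notna(q) and q <= alpha)
        n_sig += sig
        m = by_id[ds]
        rows.append(
            {
                "dataset_id": ds,
                "fold_change": fc,
                "log2_fc": np.log2(fc) if pd.notna(fc) else np.nan,
                "q_value": q,
                "significant": sig,
                "discordant": bool(table.discordant.loc[transcript_id, ds]),
                "country": m.country,
                "species": m.species,
                "resistance_class": m.resistance_class,
                "exposure": m.exposure,
                "year": m.year,
            }
        )
    cols = [
        "dataset_id", "fold_change", "log2_fc", "q_value", "significant", "discordant",
        "country", "species", "resistance_class", "exposure", "year",
    ]
    return TranscriptReport(
        transcript_id=transcript_id,
        table=pd.DataFrame(rows, columns=cols),
        n_significant=n_sig,
        alpha=alpha,
    )


def map_points(
    table: IntegratedTable,
    meta: Sequence[DatasetMeta],
    transcript_id: str,
    alpha: float = 0.05,
    filter: Filter = None,
) -> list[MapPoint]:
    """One point per dataset where the transcript is significant (q <= alpha)."""
    rep = transcript_report(table, meta, transcript_id, filter=filter, alpha=alpha)
    by_id = {m.dataset_id: m for m in meta}
    points = []
    for _, row in rep.table.iterrows():
        if not row["significant"]:
            continue
        fc = float(row["fold_change"])
        if fc == 1.0:
            warnings.warn(
                f"{transcript_id} in {row['dataset_id']}: significant with FC exactly 1; "
                "skipped from the map",
                stacklevel=2,
            )
            continue
        m = by_id[row["dataset_id"]]
        if m.latitude is None or m.longitude is None:
            warnings.warn(f"{row['dataset_id']}: no coordinates; skipped", stacklevel=2)
            continue
        points.append(
            MapPoint(
                dataset_id=row["dataset_id"],
                latitude=m.latitude,
                longitude=m.longitude,
                category=classify_fold_change(fc),
                fold_change=fc,
                q_value=float(row["q_value"]),
            )
        )
    return points


def map_points_to_geojson(points: Sequence[MapPoint]) -> dict:
    """GeoJSON FeatureCollection of map points (category as a property)."""
    return {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [p.longitude, p.latitude]},
                "properties": {
                    "dataset_id": p.dataset_id,
                    "category": p.category,
                    "fold_change": p.fold_change,
                    "q_value": p.q_value,
                },
            }
            for p in points
        ],
    }


def write_geojson(points: Sequence[MapPoint], path: str | Path) -> None:
    Path(path).write_text(json.dumps(map_points_to_geojson(points), indent=2), encoding="utf-8")


def map_points_to_frame(points: Sequence[MapPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "dataset_id": [p.dataset_id for p in points],
            "latitude": [p.latitude for p in points],
            "longitude": [p.longitude for p in points],
            "category": [p.category for p in points],
            "fold_change": [p.fold_change for p in points],
            "q_value": [p.q_value for p in points],
        }
    )


def network_report(
    network: CorrelationNetwork,
    table: IntegratedTable,
    meta: Sequence[DatasetMeta] | None = None,
) -> pd.DataFrame:
    """Tabular network view: one row per partner, sorted by |r|, with the
    partner's log2 fold change in every dataset of the table."""
    log2 = table.log2_fc()
    rows = []
    for e in network.edges:
        row = {"partner": e.partner, "r": e.r, "n_overlap": e.n_overlap}
        for ds in table.datasets:
            row[f"{ds}_log2FC"] = log2.loc[e.partner, ds] if e.partner in log2.index else np.nan
        rows.append(row)
    cols = ["partner", "r", "n_overlap"] + [f"{ds}_log2FC" for ds in table.datasets]
    return pd.DataFrame(rows, columns=cols)


def plot_transcript(report: TranscriptReport, path: str | Path) -> None:
    """Bar chart of log2 fold change per dataset (static image)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = report.table
    fig, ax = plt.subplots(figsize=(max(4, 0.4 * len(t)), 3.5))
    colors = ["#c0392b" if sig else "#95a5a6" for sig in t["significant"]]
    ax.bar(t["dataset_id"], t["log2_fc"], color=colors)
    ax.axhline(0, color="black", lw=0.8)
    ax.set_ylabel("log2 fold change (R/S)")
    ax.set_title(f"{report.transcript_id} (significant in {report.n_significant})")
    ax.tick_params(axis="x", rotation=90, labelsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_network(
    network: CorrelationNetwork, table: IntegratedTable, path: str | Path
) -> None:
    """Log2 fold-change traces across datasets for every network partner."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    log2 = table.log2_fc()
    fig, ax = plt.subplots(figsize=(max(4, 0.35 * len(table.datasets)), 3.5))
    x = np.arange(len(table.datasets))
    if network.focal in log2.index:
        ax.plot(x, log2.loc[network.focal], color="black", lw=2, label=network.focal)
    for e in network.edges:
        ax.plot(x, log2.loc[e.partner], lw=0.8, alpha=0.6)
    ax.set_xticks(x)
    ax.set_xticklabels(table.datasets, rotation=90, fontsize=7)
    ax.set_ylabel("log2 fold change (R/S)")
    ax.set_title(f"{network.focal}: {len(network.edges)} partners at |r| >= {network.cutoff}")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
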