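"""Co-expression correlation networks across datasets.

For a focal transcript, partners are all other transcript rows of the
integrated table whose cross-dataset log2 fold-change profile correlates with
the focal profile at |r| above a cutoff (Pearson, pairwise-complete).  Such
networks are used to hypothesise shared pathways or co-regulation — e.g. the
cuticular-hydrocarbon synthesis genes clustering around CYP4G16.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import IntegratedTable
from .errors import ValidationError

DEFAULT_CUTOFF = 0.75  # the loose default; 0.85 is the strict published choice
DEFAULT_MIN_OVERLAP = 10
_MIN_PAIRS = 3


@dataclass
class CorrelationEdge:
    focal: str
    partner: str
    r: float
    n_overlap: int


@dataclass
class CorrelationNetwork:
    focal: str
    cutoff: float
    edges: list[CorrelationEdge]

    @property
    def partners(self) -> list[str]:
        return [e.partner for e in self.edges]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "focal": [e.focal for e in self.edges],
                "partner": [e.partner for e in self.edges],
                "r": [e.r for e in self.edges],
                "n_overlap": [e.n_overlap for e in self.edges],
            }
        )


def pearson_r(
    x: Sequence[float], y: Sequence[float], min_overlap: int = _MIN_PAIRS
) -> tuple[float, int] | None:
    """Pearson correlation over pairwise-complete positions.

    Returns (r, n_overlap), or None when fewer than ``min_overlap`` complete
    pairs remain (never below 3) or either vector is constant over them.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("vectors must be paired")
    mask = ~(np.isnan(x) | np.isnan(y))
    n = int(mask.sum())
    if n < max(min_overlap, _MIN_PAIRS):
        return None
    xm = x[mask] - x[mask].mean()
    ym = y[mask] - y[mask].mean()
    sx = np.sqrt(np.sum(xm * xm))
    sy = np.sqrt(np.sum(ym * ym))
    if sx == 0.0 or sy == 0.0:
        return None
    r = float(np.sum(xm * ym) / (sx * sy))
    return max(-1.0, min(1.0, r)), n


def correlation_network(
    table: IntegratedTable,
    focal: str,
    cutoff: float = DEFAULT_CUTOFF,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    use_log2: bool = True,
    strict: bool = False,
) -> CorrelationNetwork:
    """Edges from the focal transcript to every partner with |r| >= cutoff.

    Correlations are computed on log2 fold changes by default (``use_log2``
    False switches to raw ratios).  ``strict`` makes the cutoff comparison
    strict (>).  Splice variants of the focal gene are ordinary partners;
    only the exact self-edge is excluded.
    """
    if focal not in table.fc.index:
        near = difflib.get_close_matches(focal, [str(t) for t in table.fc.index], n=5)
        raise ValidationError(f"focal transcript {focal!r} not in table; near matches: {near}")
    values = table.log2_fc() if use_log2 else table.fc
    fx = values.loc[focal].to_numpy(dtype=float)
    edges: list[CorrelationEdge] = []
    mat = values.to_numpy(dtype=float)
    index = list(values.index)
    for i, partner in enumerate(index):
        if partner == focal:
            continue
        res = pearson_r(fx, mat[i], min_overlap=min_overlap)
        if res is None:
            continue
        r, n = res
        keep = abs(r) > cutoff if strict else abs(r) >= cutoff
        if keep:
            edges.append(CorrelationEdge(focal=focal, partner=partner, r=r, n_overlap=n))
    edges.sort(key=lambda e: (-abs(e.r), e.partner))
    return CorrelationNetwork(focal=focal, cutoff=cutoff, edges=edges)


def write_edge_list(network: CorrelationNetwork, path) -> None:
    """Edge-list TSV loadable by standard network tools."""
    network.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")
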