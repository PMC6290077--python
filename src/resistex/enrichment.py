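"""Hypergeometric over-representation tests for gene sets.

The parameterisation mirrors R's ``phyper``: for a query list of size k drawn
from a universe of m + n transcripts of which m belong to the set, the
p-value is the upper tail P(X >= q) where q is the observed overlap.
Benjamini–Hochberg adjustment is applied across the sets tested in one call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats

from .core import GeneSet
from .dea import bh_adjust
from .errors import ValidationError


@dataclass
class EnrichmentResult:
    set_name: str
    q: int  # set members in the query
    m: int  # set members in the universe
    n: int  # universe size minus m
    k: int  # query size
    p_value: float
    q_value: float


def hypergeom_upper(q: int, m: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= q).

    X counts set members among k draws without replacement from a population
    of m + n items containing m set members.  Computed via the survival
    function (log-space internally), so tiny tails are stable.
    """
    q, m, n, k = int(q), int(m), int(n), int(k)
    if min(q, m, n, k) < 0:
        raise ValidationError("counts must be non-negative")
    if q > k or q > m or k > m + n:
        raise ValidationError(f"inconsistent counts q={q}, m={m}, n={n}, k={k}")
    if q == 0:
        return 1.0
    return float(stats.hypergeom.sf(q - 1, m + n, m, k))


def enrich(
    query: Sequence[str],
    sets: Sequence[GeneSet],
    universe: Sequence[str],
) -> list[EnrichmentResult]:
    """Test each gene set for over-representation in the query list.

    Duplicates are dropped; sets are intersected with the universe before
    counting; the query must be a subset of the universe.  q values are BH
    across the sets tested here.
    """
    uni = set(universe)
    if not uni:
        raise ValidationError("universe is empty")
    qset = set(query)
    stray = qset - uni
    if stray:
        raise ValidationError(f"query members outside the universe: {sorted(stray)[:5]}...")
    k = len(qset)
    results = []
    for gs in sets:
        members = gs.members & uni
        m = len(members)
        n = len(uni) - m
        overlap = len(members & qset)
        p = hypergeom_upper(overlap, m, n, k) if m else 1.0
        results.append((gs.name, overlap, m, n, k, p))
    qvals = bh_adjust([r[5] for r in results]) if results else []
    return [
        EnrichmentResult(
            set_name=name, q=q_, m=m, n=n, k=k, p_value=p, q_value=float(qv)
        )
        for (name, q_, m, n, k, p), qv in zip(results, qvals)
    ]


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set_name": [r.set_name for r in results],
            "q": [r.q for r in results],
            "m": [r.m for r in results],
            "n": [r.n for r in results],
            "k": [r.k for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
        }
    )
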