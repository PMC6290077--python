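"""Variance explained by metadata factors: the unbiased omega-squared estimator.

For a one-way decomposition of a response over a factor with a levels,

    omega^2 = (SS_treatment - (a - 1) * MS_within) / (SS_total + MS_within)

Unlike eta^2 = SS_treatment / SS_total, this estimator is unbiased under the
null and can therefore be slightly negative for factors that explain
nothing; negative values are reported as-is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import DatasetMeta, IntegratedTable
from .errors import ValidationError


@dataclass
class AnovaDecomposition:
    factor_name: str
    alpha_levels: int
    ss_treatment: float
    ss_total: float
    ms_within: float
    omega_sq: float

    @property
    def ss_within(self) -> float:
        return self.ss_total - self.ss_treatment


def omega_squared(
    response: Sequence[float],
    groups: Sequence[str],
    factor_name: str = "factor",
) -> AnovaDecomposition:
    """One-way decomposition with the unbiased variance-explained estimate.

    Requires at least two groups, each with at least two observations (the
    within-group mean square is otherwise undefined).
    """
    y = np.asarray(response, dtype=float)
    g = np.asarray(groups)
    if y.shape != g.shape:
        raise ValidationError("response and groups must be paired")
    levels, inverse = np.unique(g, return_inverse=True)
    a = len(levels)
    if a < 2:
        raise ValidationError(f"{factor_name}: needs >= 2 groups, got {a}")
    counts = np.bincount(inverse)
    if np.any(counts < 2):
        small = [str(levels[i]) for i in np.flatnonzero(counts < 2)]
        raise ValidationError(f"{factor_name}: groups with < 2 observations: {small}")

    grand = y.mean()
    group_means = np.bincount(inverse, weights=y) / counts
    ss_treatment = float(np.sum(counts * (group_means - grand) ** 2))
    ss_total = float(np.sum((y - grand) ** 2))
    df_within = len(y) - a
    ms_within = (ss_total - ss_treatment) / df_within
    omega = (ss_treatment - (a - 1) * ms_within) / (ss_total + ms_within)
    return AnovaDecomposition(
        factor_name=factor_name,
        alpha_levels=a,
        ss_treatment=ss_treatment,
        ss_total=ss_total,
        ms_within=float(ms_within),
        omega_sq=float(omega),
    )


def _pc1_scores(log2_fc: pd.DataFrame) -> pd.Series:
    """Dataset scores on the first principal axis of the log2 FC matrix.

    Transcript rows are centred; absent cells are filled with the transcript
    mean (which is zero after centring, i.e. absences carry no signal).
    """
    mat = log2_fc.to_numpy(dtype=float)
    row_means = np.nanmean(mat, axis=1, keepdims=True)
    centred = mat - row_means
    centred = np.where(np.isnan(centred), 0.0, centred)
    # first right singular vector gives per-dataset scores
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    scores = s[0] * vt[0]
    return pd.Series(scores, index=log2_fc.columns)


def variance_screen(
    table: IntegratedTable,
    meta: Sequence[DatasetMeta],
    factors: Sequence[str],
    response: str = "pc1",
) -> list[AnovaDecomposition]:
    """omega^2 of each metadata factor against a per-dataset expression summary.

    ``response`` chooses the summary: "pc1" (default) scores each dataset on
    the first principal axis of the log2 fold-change matrix; "mean_omega"
    runs the decomposition per transcript (complete rows only) and reports
    the mean omega^2.  Factors with fewer than two observed levels, or with
    any level observed once, are skipped with a warning.  Results are sorted
    by omega^2 descending.
    """
    by_id = {m.dataset_id: m for m in meta}
    missing = [d for d in table.datasets if d not in by_id]
    if missing:
        raise ValidationError(f"datasets missing from metadata: {missing}")
    if response not in {"pc1", "mean_omega"}:
        raise ValidationError(f"unknown response choice {response!r}")

    log2 = table.log2_fc()
    scores = _pc1_scores(log2) if response == "pc1" else None

    out: list[AnovaDecomposition] = []
    for factor in factors:
        if factor not in DatasetMeta.field_names():
            raise ValidationError(f"unknown metadata field {factor!r}")
        labels = {d: getattr(by_id[d], factor) for d in table.datasets}
        kept = [d for d in table.datasets if labels[d] is not None]
        groups = [str(labels[d]) for d in kept]
        level_counts = pd.Series(groups).value_counts()
        if len(level_counts) < 2 or (level_counts < 2).any():
            warnings.warn(f"factor {factor!r}: insufficient level replication; skipped",
                          stacklevel=2)
            continue
        if response == "pc1":
            dec = omega_squared(scores[kept].to_numpy(), groups, factor_name=factor)
        else:
            complete = log2[kept].dropna(axis=0)
            per_t = [
                omega_squared(complete.loc[t].to_numpy(), groups, factor_name=factor).omega_sq
                for t in complete.index
            ]
            mean_omega = float(np.mean(per_t)) if per_t else float("nan")
            dec = AnovaDecomposition(
                factor_name=factor,
                alpha_levels=len(level_counts),
                ss_treatment=float("nan"),
                ss_total=float("nan"),
                ms_within=float("nan"),
                omega_sq=mean_omega,
            )
        out.append(dec)
    out.sort(key=lambda d: -d.omega_sq)
    return out


def decompositions_to_frame(decs: Sequence[AnovaDecomposition]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "factor": [d.factor_name for d in decs],
            "levels": [d.alpha_levels for d in decs],
            "ss_treatment": [d.ss_treatment for d in decs],
            "ss_total": [d.ss_total for d in decs],
            "ms_within": [d.ms_within for d in decs],
            "omega_sq": [d.omega_sq for d in decs],
        }
    )
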