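"""Two-colour differential-expression pipeline.

Implements the standard analysis chain for direct resistant-vs-susceptible
two-colour hybridisations: MA transformation with dye-swap correction,
within-array loess normalisation of M on A, between-array Aquantile
normalisation of the A values, empirical-Bayes moderated t-statistics, and
Benjamini–Hochberg adjustment.

The moderated t shrinks each probe's sample variance s_g^2 toward a common
prior s_0^2 with prior degrees of freedom d_0, both estimated by matching the
first two moments of log s_g^2 against the scaled-F model; the posterior
variance is (d_0 s_0^2 + d_g s_g^2) / (d_0 + d_g) and the statistic is
referred to a t distribution on d_0 + d_g degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .errors import ValidationError

DEFAULT_LOESS_SPAN = 0.4
DEFAULT_LOESS_ITERATIONS = 4
_MIN_PROBES_FOR_LOESS = 50
_VAR_FLOOR = 1e-8


@dataclass
class TwoColorArray:
    """Raw signal for one hybridisation.

    ``dye_swapped`` is true when the resistant sample was labelled in the
    green channel, so the raw log-ratio must be negated to keep "positive M =
    higher in resistant".
    """

    array_id: str
    probe_ids: np.ndarray
    red: np.ndarray
    green: np.ndarray
    dye_swapped: bool = False

    def __post_init__(self) -> None:
        self.probe_ids = np.asarray(self.probe_ids)
        self.red = np.asarray(self.red, dtype=float)
        self.green = np.asarray(self.green, dtype=float)
        if not (len(self.probe_ids) == len(self.red) == len(self.green)):
            raise ValidationError(f"array {self.array_id}: channel lengths differ")
        if np.any(self.red <= 0) or np.any(self.green <= 0):
            raise ValidationError(f"array {self.array_id}: intensities must be positive")

    def swapped_copy(self) -> "TwoColorArray":
        """Physically exchange the channels (the orientation flag is kept)."""
        return TwoColorArray(
            array_id=self.array_id,
            probe_ids=self.probe_ids,
            red=self.green.copy(),
            green=self.red.copy(),
            dye_swapped=self.dye_swapped,
        )


@dataclass
class MAValues:
    """M (log2 ratio, resistant over susceptible) and A (mean log2 intensity).

    Both are probe × array matrices sharing ``probe_ids`` row order and
    ``array_ids`` column order.
    """

    probe_ids: np.ndarray
    array_ids: list[str]
    M: np.ndarray
    A: np.ndarray

    def copy(self) -> "MAValues":
        return MAValues(self.probe_ids.copy(), list(self.array_ids), self.M.copy(), self.A.copy())


@dataclass
class DEAResult:
    probe_id: str
    mean_M: float
    t_mod: float
    df_total: float
    p_value: float
    q_value: float

    @property
    def fold_change(self) -> float:
        return float(2.0 ** self.mean_M)


def to_ma(arrays: Sequence[TwoColorArray]) -> MAValues:
    """Convert raw two-channel intensities to MA values, correcting dye swaps.

    A is computed from the physical channels and is unaffected by orientation;
    M is negated on dye-swapped arrays so its sign always means
    resistant-over-susceptible.
    """
    if not arrays:
        raise ValidationError("no arrays supplied")
    ref = arrays[0].probe_ids
    for a in arrays[1:]:
        if len(a.probe_ids) != len(ref) or not np.array_equal(a.probe_ids, ref):
            raise ValidationError(
                f"array {a.array_id}: probe list differs from {arrays[0].array_id}"
            )
    M = np.empty((len(ref), len(arrays)))
    A = np.empty_like(M)
    for j, a in enumerate(arrays):
        lr, lg = np.log2(a.red), np.log2(a.green)
        m = lr - lg
        if a.dye_swapped:
            m = -m
        M[:, j] = m
        A[:, j] = 0.5 * (lr + lg)
    return MAValues(probe_ids=ref.copy(), array_ids=[a.array_id for a in arrays], M=M, A=A)


def loess_normalise(
    ma: MAValues,
    span: float = DEFAULT_LOESS_SPAN,
    iterations: int = DEFAULT_LOESS_ITERATIONS,
) -> MAValues:
    """Remove the intensity-dependent dye trend within each array.

    Per array, M is replaced by the residual of a robust locally-weighted
    regression of M on A (tricube weights, ``iterations`` robustifying
    passes); A is unchanged.  Arrays with fewer than 50 probes fall back to
    median-centering with a warning.
    """
    if not 0.0 < span <= 1.0:
        raise ValidationError(f"loess span must be in (0, 1], got {span}")
    out = ma.copy()
    n = out.M.shape[0]
    if n < _MIN_PROBES_FOR_LOESS:
        warnings.warn(
            f"only {n} probes: falling back to median-centering instead of loess",
            stacklevel=2,
        )
        out.M = out.M - np.median(out.M, axis=0, keepdims=True)
        return out
    for j in range(out.M.shape[1]):
        fit = _sm_lowess(
            out.M[:, j], out.A[:, j], frac=span, it=iterations, return_sorted=False
        )
        out.M[:, j] = out.M[:, j] - fit
    return out


def aquantile_normalise(ma: MAValues) -> MAValues:
    """Equalise the A-value distribution across arrays (Aquantile).

    Each array's A vector is mapped rank-wise onto the mean of the sorted A
    vectors; M values are untouched.  A single array is returned unchanged
    with a warning.
    """
    out = ma.copy()
    n_arrays = out.A.shape[1]
    if n_arrays < 2:
        warnings.warn("Aquantile normalisation needs >= 2 arrays; returning input", stacklevel=2)
        return out
    order = np.argsort(out.A, axis=0, kind="mergesort")
    sorted_a = np.take_along_axis(out.A, order, axis=0)
    target = sorted_a.mean(axis=1)
    ranks = np.empty_like(order)
    rows = np.arange(out.A.shape[0])
    for j in range(n_arrays):
        ranks[order[:, j], j] = rows
    out.A = target[ranks]
    return out


# ---------------------------------------------------------------------------
# Moderated t
# ---------------------------------------------------------------------------


def _trigamma_inverse(y: np.ndarray) -> np.ndarray:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    y = np.asarray(y, dtype=float)
    x = 0.5 + 1.0 / y  # good start: trigamma(x) ~ 1/x + 1/(2x^2)
    for _ in range(60):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif / x) < 1e-12):
            break
    return x


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate (prior_df d0, prior_variance s0^2) from probe-level variances.

    Under the scaled-F model, log s^2 has mean log s0^2 + digamma(df/2) -
    log(df/2) plus a prior term, and excess variance trigamma(d0/2); matching
    the observed moments of log s^2 yields d0 and s0^2.  When the observed
    spread does not exceed the chi-square expectation, d0 is infinite and
    every probe shares s0^2.
    """
    s2 = np.maximum(np.asarray(s2, dtype=float), _VAR_FLOOR)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    n = len(e)
    if n < 2:
        return float("inf"), float(np.exp(e_mean))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        return float("inf"), float(np.exp(e_mean))
    d0 = float(2.0 * _trigamma_inverse(np.array([e_var]))[0])
    s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def moderated_t(
    M_matrix: np.ndarray,
    probe_ids: Sequence[str] | None = None,
    prior_df: float | None = None,
    prior_s2: float | None = None,
) -> list[DEAResult]:
    """Empirical-Bayes moderated one-sample t-test on a probe × array matrix.

    ``prior_df``/``prior_s2`` override the estimated hyperparameters (0 gives
    the ordinary t; infinity pools every probe to the prior variance).
    P-values are two-sided; q values are BH-adjusted.
    """
    M = np.asarray(M_matrix, dtype=float)
    if M.ndim != 2 or M.shape[1] < 2:
        raise ValidationError("moderated_t needs a probe x array matrix with >= 2 arrays")
    n = M.shape[1]
    df = n - 1
    mean = M.mean(axis=1)
    s2 = np.maximum(M.var(axis=1, ddof=1), _VAR_FLOOR)

    if prior_df is None:
        d0, s0_2 = estimate_variance_prior(s2, df)
        if prior_s2 is not None:
            s0_2 = prior_s2
    else:
        d0 = float(prior_df)
        if prior_s2 is not None:
            s0_2 = float(prior_s2)
        elif d0 == 0:
            s0_2 = float(np.median(s2))  # unused when d0 == 0
        else:
            _, s0_2 = estimate_variance_prior(s2, df)

    if np.isinf(d0):
        post_var = np.full_like(s2, s0_2)
        df_total = float("inf")
    else:
        post_var = (d0 * s0_2 + df * s2) / (d0 + df)
        df_total = d0 + df
    t = mean / np.sqrt(post_var / n)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    q = bh_adjust(p)

    if probe_ids is None:
        probe_ids = [f"probe_{i}" for i in range(M.shape[0])]
    return [
        DEAResult(
            probe_id=str(pid),
            mean_M=float(mean[i]),
            t_mod=float(t[i]),
            df_total=float(df_total),
            p_value=float(p[i]),
            q_value=float(q[i]),
        )
        for i, pid in enumerate(probe_ids)
    ]


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment.

    q_i = min over j with p_j >= p_i of m * p_j / rank_j, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def run_dea(
    arrays: Sequence[TwoColorArray],
    span: float = DEFAULT_LOESS_SPAN,
    iterations: int = DEFAULT_LOESS_ITERATIONS,
) -> list[DEAResult]:
    """Full pipeline: MA → loess → Aquantile → moderated t → BH."""
    ma = to_ma(arrays)
    ma = loess_normalise(ma, span=span, iterations=iterations)
    ma = aquantile_normalise(ma)
    return moderated_t(ma.M, probe_ids=list(ma.probe_ids))


def read_raw_signals(path) -> list[TwoColorArray]:
    """Read raw signal TSV (array_id, probe_id, red, green, dye_swapped)."""
    from .core import _read_with_schema  # local import to avoid a cycle
    from .errors import SchemaError

    df = _read_with_schema(path, "raw-signals")
    needed = ["array_id", "probe_id", "red", "green", "dye_swapped"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: raw-signal columns missing: {missing}")
    arrays = []
    for aid, grp in df.groupby("array_id", sort=False):
        swapped = set(grp["dye_swapped"].astype(int))
        if len(swapped) != 1:
            raise ValidationError(f"array {aid}: inconsistent dye_swapped flags")
        arrays.append(
            TwoColorArray(
                array_id=str(aid),
                probe_ids=grp["probe_id"].astype(str).to_numpy(),
                red=grp["red"].to_numpy(dtype=float),
                green=grp["green"].to_numpy(dtype=float),
                dye_swapped=bool(swapped.pop()),
            )
        )
    return arrays


def write_raw_signals(arrays: Sequence[TwoColorArray], path) -> None:
    from .core import _write_with_schema

    frames = []
    for a in arrays:
        frames.append(
            pd.DataFrame(
                {
                    "array_id": a.array_id,
                    "probe_id": a.probe_ids,
                    "red": a.red,
                    "green": a.green,
                    "dye_swapped": int(a.dye_swapped),
                }
            )
        )
    _write_with_schema(pd.concat(frames, ignore_index=True), path, "raw-signals")


def dea_results_to_frame(results: Sequence[DEAResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "probe_id": [r.probe_id for r in results],
            "mean_M": [r.mean_M for r in results],
            "fold_change": [r.fold_change for r in results],
            "t_mod": [r.t_mod for r in results],
            "df_total": [r.df_total for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
        }
    )
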