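"""Probe → transcript aggregation and assembly of the integrated table.

A transcript measured by several probes in one dataset gets a single value
only when the probes agree: strictly more than 75% must share fold-change
direction (concordant), or — failing that — every probe must be
non-significant (all_nonsignificant).  Otherwise the transcript is flagged
discordant in that dataset and carries no value.

Averaging is geometric on fold changes (arithmetic on log2), so inverting the
strain orientation of every probe inverts the transcript fold change exactly;
q values are averaged arithmetically.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import DatasetMeta, IntegratedTable, ProbeAnnotation, ProbeResult
from .errors import ValidationError

CONSENSUS_FRACTION = 0.75


@dataclass
class TranscriptResult:
    dataset_id: str
    transcript_id: str
    fold_change: float | None
    q_value: float | None
    status: str  # concordant | all_nonsignificant | discordant
    cross_hyb: bool = False

    def __post_init__(self) -> None:
        if self.status not in {"concordant", "all_nonsignificant", "discordant"}:
            raise ValidationError(f"unknown status {self.status!r}")
        absent = self.fold_change is None and self.q_value is None
        if (self.status == "discordant") != absent:
            raise ValidationError(
                f"{self.dataset_id}/{self.transcript_id}: discordant status must pair "
                "with absent values"
            )


def aggregate_probes(
    probes: Sequence[ProbeResult],
    transcript_id: str,
    alpha: float = 0.05,
    cross_hyb: bool = False,
) -> TranscriptResult:
    """Collapse one transcript's probes (one dataset) under the consensus rule.

    Branch (a): strictly more than 75% of probes share direction (FC>1 vs
    FC<1) → concordant, with geometric-mean FC and arithmetic-mean q.
    Branch (b), evaluated only if (a) fails: every probe has q > alpha →
    all_nonsignificant, same averaging.  Otherwise discordant, no values.
    """
    if not probes:
        raise ValidationError(f"{transcript_id}: no probes to aggregate")
    ds_ids = {p.dataset_id for p in probes}
    if len(ds_ids) > 1:
        raise ValidationError(f"{transcript_id}: probes span datasets {sorted(ds_ids)}")
    dataset_id = probes[0].dataset_id

    fcs = np.array([p.fold_change for p in probes], dtype=float)
    qs = np.array([p.q_value for p in probes], dtype=float)
    n = len(probes)
    n_up = int(np.sum(fcs > 1.0))
    n_down = int(np.sum(fcs < 1.0))  # FC exactly 1 counts toward neither direction

    concordant = max(n_up, n_down) > CONSENSUS_FRACTION * n
    if concordant or bool(np.all(qs > alpha)):
        fc = float(np.exp(np.mean(np.log(fcs))))
        q = float(np.mean(qs))
        status = "concordant" if concordant else "all_nonsignificant"
        return TranscriptResult(dataset_id, transcript_id, fc, q, status, cross_hyb)
    return TranscriptResult(dataset_id, transcript_id, None, None, "discordant", cross_hyb)


def aggregate_dataset(
    probes: Sequence[ProbeResult],
    annotation: Sequence[ProbeAnnotation],
    alpha: float = 0.05,
) -> list[TranscriptResult]:
    """Aggregate every transcript of one dataset using the probe annotation.

    Cross-hybridising probes participate in aggregation but taint their
    transcripts with a warning flag carried through to the integrated table.
    """
    ann_by_probe = {a.probe_id: a for a in annotation}
    per_transcript: dict[str, list[ProbeResult]] = {}
    tainted: dict[str, bool] = {}
    for p in probes:
        ann = ann_by_probe.get(p.probe_id)
        if ann is None:
            raise ValidationError(f"probe {p.probe_id} missing from annotation")
        for t in ann.transcript_ids:
            per_transcript.setdefault(t, []).append(p)
            tainted[t] = tainted.get(t, False) or ann.cross_hyb
    return [
        aggregate_probes(plist, t, alpha=alpha, cross_hyb=tainted[t])
        for t, plist in per_transcript.items()
    ]


def build_integrated_table(
    per_dataset: Mapping[str, Sequence[TranscriptResult]] | Sequence[TranscriptResult],
    meta: Sequence[DatasetMeta],
) -> IntegratedTable:
    """Assemble transcript-level results from several datasets into one table.

    Columns follow metadata order; the transcript set is the union across
    datasets, with absences where a transcript is missing and discordant
    flags where consensus failed.
    """
    if not isinstance(per_dataset, Mapping):
        grouped: dict[str, list[TranscriptResult]] = {}
        for r in per_dataset:
            grouped.setdefault(r.dataset_id, []).append(r)
        per_dataset = grouped

    meta_ids = [m.dataset_id for m in meta]
    unknown = set(per_dataset) - set(meta_ids)
    if unknown:
        raise ValidationError(f"datasets missing from metadata: {sorted(unknown)}")

    seen: Counter[tuple[str, str]] = Counter()
    transcripts: list[str] = []
    seen_t: set[str] = set()
    for ds in meta_ids:
        for r in per_dataset.get(ds, []):
            if r.dataset_id != ds:
                raise ValidationError(f"result for {r.dataset_id} grouped under {ds}")
            seen[(ds, r.transcript_id)] += 1
            if r.transcript_id not in seen_t:
                seen_t.add(r.transcript_id)
                transcripts.append(r.transcript_id)
    dupes = [pair for pair, c in seen.items() if c > 1]
    if dupes:
        raise ValidationError(f"duplicate (dataset, transcript) pairs: {sorted(dupes)}")

    datasets = [ds for ds in meta_ids if ds in per_dataset]
    fc = pd.DataFrame(np.nan, index=pd.Index(transcripts, name="transcript"), columns=datasets)
    q = fc.copy()
    disc = pd.DataFrame(False, index=fc.index, columns=datasets)
    cross = pd.Series(False, index=fc.index)
    for ds in datasets:
        for r in per_dataset[ds]:
            if r.status == "discordant":
                disc.loc[r.transcript_id, ds] = True
            else:
                fc.loc[r.transcript_id, ds] = r.fold_change
                q.loc[r.transcript_id, ds] = r.q_value
            if r.cross_hyb:
                cross.loc[r.transcript_id] = True
    return IntegratedTable(fc=fc, q=q, discordant=disc, cross_hyb=cross)
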