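"""Cross-dataset consensus signatures and candidate-frequency screens.

A transcript joins the meta-signature of a dataset selection when it is
present (non-absent, non-discordant) in every selected dataset and its fold
change lies on the same side of 1 throughout — optionally also requiring
q <= alpha in every dataset.  Fold change exactly 1 belongs to neither
direction and excludes the transcript.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GeneSet, IntegratedTable, gene_stem
from .errors import ValidationError


@dataclass
class MetaSignature:
    selection: list[str]
    up: list[str]
    down: list[str]
    mean_fc: pd.Series  # geometric mean over the selection, all signature transcripts
    fc: pd.DataFrame  # signature transcripts x selection
    q: pd.DataFrame
    alpha: float = 0.05
    require_significance: bool = True

    @property
    def transcripts(self) -> list[str]:
        return self.up + self.down

    @property
    def gene_count_up(self) -> int:
        return len(collapse_to_genes(self.up))

    @property
    def gene_count_down(self) -> int:
        return len(collapse_to_genes(self.down))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.transcripts:
            rows.append(
                {
                    "transcript": t,
                    "direction": "up" if t in set(self.up) else "down",
                    "mean_fc": self.mean_fc[t],
                    **{f"{ds}_FC": self.fc.loc[t, ds] for ds in self.selection},
                    **{f"{ds}_Q": self.q.loc[t, ds] for ds in self.selection},
                }
            )
        return pd.DataFrame(rows)


def consensus_signature(
    table: IntegratedTable,
    selection: Sequence[str],
    alpha: float = 0.05,
    require_significance: bool = True,
) -> MetaSignature:
    """Transcripts differentially expressed in the same direction in every
    selected dataset.

    "Up" means FC > 1 everywhere in the selection (and q <= alpha everywhere
    when ``require_significance``); "down" symmetrically with FC < 1.
    Transcripts absent or discordant anywhere in the selection are excluded.
    """
    selection = list(selection)
    if not selection:
        raise ValidationError("dataset selection is empty")
    missing = [d for d in selection if d not in table.datasets]
    if missing:
        raise ValidationError(f"selection not in table: {missing}")

    fc = table.fc[selection]
    q = table.q[selection]
    present = fc.notna().all(axis=1)
    sig_ok = (q <= alpha).all(axis=1) if require_significance else pd.Series(True, index=fc.index)
    up_mask = present & (fc > 1).all(axis=1) & sig_ok
    down_mask = present & (fc < 1).all(axis=1) & sig_ok
    up = list(fc.index[up_mask])
    down = list(fc.index[down_mask])
    keep = up + down
    mean_fc = np.exp(np.log(fc.loc[keep]).mean(axis=1)) if keep else pd.Series(dtype=float)
    return MetaSignature(
        selection=selection,
        up=up,
        down=down,
        mean_fc=mean_fc,
        fc=fc.loc[keep],
        q=q.loc[keep],
        alpha=alpha,
        require_significance=require_significance,
    )


def collapse_to_genes(transcripts: Sequence[str]) -> list[str]:
    """Collapse splice variants to unique gene stems, keeping first-occurrence order.

    ``AGAP001076-RA`` and ``AGAP001076-RB`` collapse to ``AGAP001076``;
    identifiers without a recognised suffix pass through verbatim.
    """
    out: list[str] = []
    seen: set[str] = set()
    for t in transcripts:
        g = gene_stem(t)
        if g not in seen:
            seen.add(g)
            out.append(g)
    return out


def frequency_threshold(n_datasets: int, min_fraction: float) -> int:
    """Smallest dataset count strictly exceeding min_fraction of n_datasets.

    With 31 datasets and min_fraction 0.5 ("differentially expressed in over
    50% of the arrays"), the threshold is 16.
    """
    if not 0.0 < min_fraction <= 1.0:
        raise ValidationError(f"min_fraction must be in (0, 1], got {min_fraction}")
    return math.floor(min_fraction * n_datasets) + 1


@dataclass
class FrequencyScreenResult:
    counts: pd.DataFrame  # candidate, n_significant, n_present, passes
    threshold: int
    skipped: list[str] = field(default_factory=list)

    @property
    def passing(self) -> list[str]:
        return list(self.counts.loc[self.counts["passes"], "candidate"])


def frequency_screen(
    table: IntegratedTable,
    candidates: GeneSet,
    min_fraction: float = 0.5,
    alpha: float = 0.05,
    same_direction: bool = False,
) -> FrequencyScreenResult:
    """Screen a candidate list (e.g. transcription factors) by how many
    datasets call each candidate significant.

    A candidate passes when it is significant (q <= alpha, either direction
    by default) in strictly more than ``min_fraction`` of the table's
    datasets.  With ``same_direction`` the count is the larger of the
    significant-up and significant-down dataset counts, so mixed-direction
    candidates need a one-sided majority.  Candidates absent from the table
    are reported as skipped, not errors.
    """
    n = len(table.datasets)
    threshold = frequency_threshold(n, min_fraction)
    rows = []
    skipped = []
    for cand in sorted(candidates.members):
        if cand not in table.fc.index:
            skipped.append(cand)
            continue
        q_row = table.q.loc[cand]
        fc_row = table.fc.loc[cand]
        sig = (q_row <= alpha) & q_row.notna()
        if same_direction:
            count = int(max((sig & (fc_row > 1)).sum(), (sig & (fc_row < 1)).sum()))
        else:
            count = int(sig.sum())
        rows.append(
            {
                "candidate": cand,
                "n_significant": count,
                "n_present": int(fc_row.notna().sum()),
                "passes": count >= threshold,
            }
        )
    counts = pd.DataFrame(rows, columns=["candidate", "n_significant", "n_present", "passes"])
    return FrequencyScreenResult(counts=counts, threshold=threshold, skipped=skipped)
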