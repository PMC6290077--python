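"""Domain types and delimited-text I/O for the resistance-transcriptomics pipeline.

Everything downstream consumes the :class:`IntegratedTable`: a transcript ×
dataset matrix of linear fold changes (resistant / susceptible) paired with
Benjamini–Hochberg adjusted p-values ("Q values").  Fold changes are stored on
the linear ratio scale; log2 is applied only inside computations and displays.

All tables travel as tab-separated UTF-8 text with ``NA`` for absent values and
a one-line ``# resistex <kind> v1`` schema comment at the top, so that a
write/read cycle is the identity on valid data.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FilterError, SchemaError, ValidationError

SPECIES = frozenset({"gambiae", "coluzzii", "arabiensis"})
RESISTANCE_CLASSES = frozenset({"high", "moderate", "low", "susceptible"})
EXPOSURES = frozenset({"DDT", "pyrethroid", "bendiocarb", "none", "unknown"})

_SCHEMA_PREFIX = "# resistex"
_SCHEMA_VERSION = "v1"

_GENE_STEM_RE = re.compile(r"^(?P<gene>.+?)-R[A-Z]$")


def derive_resistance_class(mortality_pct: float) -> str:
    """Classify a population by its WHO discriminating-dose mortality.

    Bins are half-open: [0, 33) high, [33, 66) moderate, [66, 100) low;
    only exactly 100% mortality is susceptible (populations that consistently
    die at the discriminating dose).
    """
    m = float(mortality_pct)
    if not (0.0 <= m <= 100.0) or math.isnan(m):
        raise ValidationError(f"mortality_pct must be in [0, 100], got {mortality_pct!r}")
    if m == 100.0:
        return "susceptible"
    if m < 33.0:
        return "high"
    if m < 66.0:
        return "moderate"
    return "low"


@dataclass
class DatasetMeta:
    """Per-dataset annotations driving subsetting and map output.

    ``comparator`` names the susceptible reference strain the resistant
    population was hybridised against; ``kdr_frequency`` is the frequency of
    the pyrethroid target-site knockdown-resistance allele.
    """

    dataset_id: str
    country: str
    species: str
    latitude: float
    longitude: float
    resistance_class: str
    exposure: str
    year: int
    comparator: str
    mortality_pct: float | None = None
    kdr_frequency: float | None = None

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValidationError(f"{self.dataset_id}: unknown species {self.species!r}")
        if self.resistance_class not in RESISTANCE_CLASSES:
            raise ValidationError(
                f"{self.dataset_id}: unknown resistance_class {self.resistance_class!r}"
            )
        if self.exposure not in EXPOSURES:
            raise ValidationError(f"{self.dataset_id}: unknown exposure {self.exposure!r}")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValidationError(f"{self.dataset_id}: latitude {self.latitude} out of range")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValidationError(f"{self.dataset_id}: longitude {self.longitude} out of range")
        if self.kdr_frequency is not None and not 0.0 <= self.kdr_frequency <= 1.0:
            raise ValidationError(
                f"{self.dataset_id}: kdr_frequency {self.kdr_frequency} not a proportion"
            )
        if self.mortality_pct is not None:
            derived = derive_resistance_class(self.mortality_pct)
            if derived != self.resistance_class:
                raise ValidationError(
                    f"{self.dataset_id}: resistance_class {self.resistance_class!r} "
                    f"inconsistent with mortality {self.mortality_pct}% (expected {derived!r})"
                )

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dc_fields(cls))


@dataclass
class ProbeResult:
    """One probe's differential-expression call in one dataset."""

    dataset_id: str
    probe_id: str
    fold_change: float
    q_value: float

    def __post_init__(self) -> None:
        if not self.fold_change > 0:
            raise ValidationError(
                f"{self.dataset_id}/{self.probe_id}: fold_change must be > 0, "
                f"got {self.fold_change}"
            )
        if not 0.0 <= self.q_value <= 1.0:
            raise ValidationError(
                f"{self.dataset_id}/{self.probe_id}: q_value {self.q_value} not in [0, 1]"
            )


@dataclass
class ProbeAnnotation:
    """Probe → transcript mapping with a cross-hybridisation flag.

    ``cross_hyb`` is true whenever the probe sequence matches transcripts of
    more than one gene (the flag is supplied by upstream sequence analysis and
    treated as input here).
    """

    probe_id: str
    transcript_ids: tuple[str, ...]
    cross_hyb: bool = False

    def __post_init__(self) -> None:
        self.transcript_ids = tuple(self.transcript_ids)
        if not self.transcript_ids:
            raise ValidationError(f"probe {self.probe_id}: maps to no transcript")
        genes = {gene_stem(t) for t in self.transcript_ids}
        if len(genes) > 1 and not self.cross_hyb:
            raise ValidationError(
                f"probe {self.probe_id}: spans genes {sorted(genes)} but cross_hyb is false"
            )


@dataclass
class GeneSet:
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} is empty")


def gene_stem(transcript_id: str) -> str:
    """Strip a VectorBase splice-variant suffix (``-RA``, ``-RB``...) if present."""
    m = _GENE_STEM_RE.match(transcript_id)
    return m.group("gene") if m else transcript_id


@dataclass
class IntegratedTable:
    """Transcript × dataset matrix of fold changes and adjusted p-values.

    ``fc`` and ``q`` are pandas DataFrames sharing index (transcripts),
    columns (dataset ids) and missingness pattern.  ``discordant`` marks
    (transcript, dataset) cells where the probe-consensus rule failed; those
    cells carry absent fc/q.  ``cross_hyb`` flags transcripts measured by at
    least one multi-gene probe.
    """

    fc: pd.DataFrame
    q: pd.DataFrame
    discordant: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    cross_hyb: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.discordant is None:
            self.discordant = pd.DataFrame(
                False, index=self.fc.index, columns=self.fc.columns
            )
        if self.cross_hyb is None:
            self.cross_hyb = pd.Series(False, index=self.fc.index)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        fc, q, disc = self.fc, self.q, self.discordant
        if fc.shape != q.shape or not fc.index.equals(q.index) or not fc.columns.equals(q.columns):
            raise ValidationError("fc and q must share index, columns and shape")
        if disc.shape != fc.shape:
            raise ValidationError("discordant flags must match fc shape")
        if not fc.index.is_unique:
            dupes = fc.index[fc.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate transcript rows: {dupes}")
        if (fc.isna() != q.isna()).any().any():
            raise ValidationError("fc and q must share their missingness pattern")
        bad_fc = (fc <= 0).any(axis=1)
        if bad_fc.any():
            raise ValidationError(
                f"non-positive fold changes for transcripts {list(fc.index[bad_fc])}"
            )
        bad_q = ((q < 0) | (q > 1)).any(axis=1)
        if bad_q.any():
            raise ValidationError(f"q values outside [0,1] for transcripts {list(q.index[bad_q])}")
        if fc.size and (disc.to_numpy(dtype=bool) & fc.notna().to_numpy(dtype=bool)).any():
            raise ValidationError("discordant cells must have absent fc/q")

    # -- convenience ------------------------------------------------------
    @property
    def transcripts(self) -> list[str]:
        return list(self.fc.index)

    @property
    def datasets(self) -> list[str]:
        return list(self.fc.columns)

    def log2_fc(self) -> pd.DataFrame:
        return np.log2(self.fc)

    def subset(self, datasets: Sequence[str]) -> "IntegratedTable":
        missing = [d for d in datasets if d not in self.fc.columns]
        if missing:
            raise KeyError(f"unknown dataset ids: {missing}")
        return IntegratedTable(
            fc=self.fc[list(datasets)].copy(),
            q=self.q[list(datasets)].copy(),
            discordant=self.discordant[list(datasets)].copy(),
            cross_hyb=self.cross_hyb.copy(),
        )

    def equals(self, other: "IntegratedTable") -> bool:
        return (
            self.fc.equals(other.fc)
            and self.q.equals(other.q)
            and self.discordant.equals(other.discordant)
            and self.cross_hyb.equals(other.cross_hyb)
        )


# ---------------------------------------------------------------------------
# Metadata filtering
# ---------------------------------------------------------------------------

Filter = Mapping[str, object] | Callable[[DatasetMeta], bool] | None


def parse_filter(expr: str) -> dict[str, object]:
    """Parse ``"species=coluzzii,exposure=pyrethroid"`` into a filter mapping.

    Values are matched by equality; numeric fields are coerced.
    """
    out: dict[str, object] = {}
    if not expr.strip():
        return out
    for clause in expr.split(","):
        if "=" not in clause:
            raise FilterError(f"malformed filter clause {clause!r} (expected field=value)")
        key, value = (s.strip() for s in clause.split("=", 1))
        out[key] = value
    return out


def subset_datasets(meta: Sequence[DatasetMeta], filter: Filter = None) -> list[str]:
    """Return the dataset_ids matching a filter, in input order.

    ``filter`` may be a mapping field → required value (equality, with numeric
    coercion), a predicate over :class:`DatasetMeta`, or None/empty for all.
    """
    if filter is None:
        return [m.dataset_id for m in meta]
    if callable(filter):
        return [m.dataset_id for m in meta if filter(m)]
    known = set(DatasetMeta.field_names())
    unknown = set(filter) - known
    if unknown:
        raise FilterError(f"unknown metadata fields in filter: {sorted(unknown)}")

    def matches(m: DatasetMeta) -> bool:
        for key, wanted in filter.items():
            have = getattr(m, key)
            if have is None:
                return False
            if isinstance(have, (int, float)) and not isinstance(wanted, (int, float)):
                try:
                    wanted = type(have)(wanted)  # type: ignore[arg-type]
                except (TypeError, ValueError):
                    return False
            if have != wanted:
                return False
        return True

    return [m.dataset_id for m in meta if matches(m)]


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------


def _read_with_schema(path: str | Path, kind: str) -> pd.DataFrame:
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline()
        if not first.startswith("#"):
            # Tolerate files without the schema comment, but a missing header
            # row is a schema error caught below.
            fh.seek(0)
        elif kind not in first:
            raise SchemaError(f"{path}: expected a '{_SCHEMA_PREFIX} {kind}' header, got {first!r}")
        body = fh.read()
    if not body.strip():
        raise SchemaError(f"{path}: empty table body")
    df = pd.read_csv(
        io.StringIO(body), sep="\t", na_values=["NA"], keep_default_na=False, dtype={0: str}
    )
    return df


def _write_with_schema(df: pd.DataFrame, path: str | Path, kind: str) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"{_SCHEMA_PREFIX} {kind} {_SCHEMA_VERSION}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_integrated_table(
    path: str | Path, annotation: Sequence[ProbeAnnotation] | None = None
) -> IntegratedTable:
    """Read a transcript × dataset FC/Q table from TSV.

    The header names dataset columns in ``<id>_FC`` / ``<id>_Q`` pairs after a
    leading ``transcript`` column.  Rows violating invariants are rejected with
    file row numbers (header = row 1).  When probe annotation is supplied, the
    per-transcript cross-hybridisation flags are derived from it.
    """
    df = _read_with_schema(path, "integrated-table")
    if df.columns[0] != "transcript":
        raise SchemaError(f"{path}: first column must be 'transcript', got {df.columns[0]!r}")
    fc_cols = [c for c in df.columns if c.endswith("_FC")]
    q_cols = [c for c in df.columns if c.endswith("_Q")]
    disc_cols = [c for c in df.columns if c.endswith("_DISCORDANT")]
    datasets = [c[: -len("_FC")] for c in fc_cols]
    if [f"{d}_Q" for d in datasets] != q_cols:
        raise SchemaError(f"{path}: FC/Q column pairs do not match: {fc_cols} vs {q_cols}")
    if not datasets:
        raise SchemaError(f"{path}: no dataset FC/Q column pairs found")

    fc = df[fc_cols].astype(float)
    q = df[q_cols].astype(float)
    # row numbers in the file: +3 (schema line, header line, 1-based)
    offsets = df.index + 3
    bad_rows: list[int] = []
    bad_rows += list(offsets[(fc <= 0).any(axis=1)])
    bad_rows += list(offsets[((q < 0) | (q > 1)).any(axis=1)])
    bad_rows += list(offsets[(fc.isna().to_numpy() != q.isna().to_numpy()).any(axis=1)])
    if bad_rows:
        raise ValidationError(
            f"{path}: invalid FC/Q values on file rows {sorted(set(bad_rows))}"
        )

    transcripts = df["transcript"].astype(str)
    fc.index = q.index = pd.Index(transcripts, name="transcript")
    fc.columns = q.columns = pd.Index(datasets)
    if disc_cols:
        disc = df[disc_cols].fillna(0).astype(bool)
        disc.index = fc.index
        disc.columns = pd.Index([c[: -len("_DISCORDANT")] for c in disc_cols])
        disc = disc.reindex(columns=fc.columns, fill_value=False)
    else:
        disc = None

    cross = None
    if annotation is not None:
        flagged: set[str] = set()
        for ann in annotation:
            if ann.cross_hyb:
                flagged.update(ann.transcript_ids)
        cross = pd.Series([t in flagged for t in fc.index], index=fc.index)
    return IntegratedTable(fc=fc, q=q, discordant=disc, cross_hyb=cross)


def write_integrated_table(table: IntegratedTable, path: str | Path) -> None:
    table.validate()
    df = pd.DataFrame({"transcript": table.fc.index})
    for ds in table.datasets:
        df[f"{ds}_FC"] = table.fc[ds].to_numpy()
        df[f"{ds}_Q"] = table.q[ds].to_numpy()
    if table.discordant.any().any():
        for ds in table.datasets:
            df[f"{ds}_DISCORDANT"] = table.discordant[ds].astype(int).to_numpy()
    _write_with_schema(df, path, "integrated-table")


_META_COLUMNS = [
    "dataset_id",
    "country",
    "species",
    "latitude",
    "longitude",
    "resistance_class",
    "mortality_pct",
    "exposure",
    "kdr_frequency",
    "year",
    "comparator",
]


def read_metadata(path: str | Path) -> list[DatasetMeta]:
    df = _read_with_schema(path, "metadata")
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: metadata columns missing: {missing}")
    out = []
    for _, row in df.iterrows():
        out.append(
            DatasetMeta(
                dataset_id=str(row["dataset_id"]),
                country=str(row["country"]),
                species=str(row["species"]),
                latitude=float(row["latitude"]),
                longitude=float(row["longitude"]),
                resistance_class=str(row["resistance_class"]),
                mortality_pct=None if pd.isna(row["mortality_pct"]) else float(row["mortality_pct"]),
                exposure=str(row["exposure"]),
                kdr_frequency=None if pd.isna(row["kdr_frequency"]) else float(row["kdr_frequency"]),
                year=int(row["year"]),
                comparator=str(row["comparator"]),
            )
        )
    ids = [m.dataset_id for m in out]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate dataset_ids")
    return out


def write_metadata(meta: Sequence[DatasetMeta], path: str | Path) -> None:
    rows = []
    for m in meta:
        rows.append({c: getattr(m, c) for c in _META_COLUMNS})
    _write_with_schema(pd.DataFrame(rows, columns=_META_COLUMNS), path, "metadata")


def read_annotation(path: str | Path) -> list[ProbeAnnotation]:
    df = _read_with_schema(path, "probe-annotation")
    for col in ("probe_id", "transcript_ids", "cross_hyb"):
        if col not in df.columns:
            raise SchemaError(f"{path}: annotation column {col!r} missing")
    return [
        ProbeAnnotation(
            probe_id=str(r["probe_id"]),
            transcript_ids=tuple(str(r["transcript_ids"]).split(",")),
            cross_hyb=bool(int(r["cross_hyb"])),
        )
        for _, r in df.iterrows()
    ]


def write_annotation(annotation: Sequence[ProbeAnnotation], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "probe_id": [a.probe_id for a in annotation],
            "transcript_ids": [",".join(a.transcript_ids) for a in annotation],
            "cross_hyb": [int(a.cross_hyb) for a in annotation],
        }
    )
    _write_with_schema(df, path, "probe-annotation")


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read gene sets from long-format TSV (columns: name, member)."""
    df = _read_with_schema(path, "gene-sets")
    if list(df.columns[:2]) != ["name", "member"]:
        raise SchemaError(f"{path}: expected columns (name, member), got {list(df.columns)}")
    out = []
    for name, grp in df.groupby("name", sort=False):
        out.append(GeneSet(name=str(name), members=frozenset(grp["member"].astype(str))))
    return out


def write_gene_sets(sets: Sequence[GeneSet], path: str | Path) -> None:
    rows = [
        {"name": s.name, "member": member} for s in sets for member in sorted(s.members)
    ]
    _write_with_schema(pd.DataFrame(rows, columns=["name", "member"]), path, "gene-sets")


def read_probe_results(path: str | Path) -> list[ProbeResult]:
    """Read probe-level DE results (dataset_id, probe_id, fold_change, q_value)."""
    df = _read_with_schema(path, "probe-results")
    needed = ["dataset_id", "probe_id", "fold_change", "q_value"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: probe-result columns missing: {missing}")
    return [
        ProbeResult(
            dataset_id=str(r["dataset_id"]),
            probe_id=str(r["probe_id"]),
            fold_change=float(r["fold_change"]),
            q_value=float(r["q_value"]),
        )
        for _, r in df.iterrows()
    ]


def write_probe_results(results: Sequence[ProbeResult], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "dataset_id": [r.dataset_id for r in results],
            "probe_id": [r.probe_id for r in results],
            "fold_change": [r.fold_change for r in results],
            "q_value": [r.q_value for r in results],
        }
    )
    _write_with_schema(df, path, "probe-results")
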