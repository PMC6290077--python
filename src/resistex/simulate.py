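"""Synthetic data with known ground truth for every pipeline input.

Two generators are provided.  ``simulate_integrated`` emulates the published
study design directly at the table level: 31 resistant-vs-susceptible
comparisons on a shared probe set, with planted consistently up/down
transcripts, latent-factor co-expression modules, multi-probe transcripts
(including cross-hybridising probes), and per-dataset q values derived from
simulated replicate variability (ordinary t on the replicates, BH within the
dataset).  ``simulate_raw_signals`` goes one level deeper and emits raw
two-colour intensities with an intensity-dependent dye bias and dye-swapped
arrays, to exercise the normalisation pipeline end to end.

The co-expression model is a latent factor per module:
log2FC[g, d] = mu_g + loading_g * f_d + eps, f_d ~ N(0, 1), so the expected
within-module correlation is loading^2 / (loading^2 + sigma_total^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    DatasetMeta,
    GeneSet,
    IntegratedTable,
    ProbeAnnotation,
    ProbeResult,
    derive_resistance_class,
    write_annotation,
    write_gene_sets,
    write_integrated_table,
    write_metadata,
)
from .dea import TwoColorArray, bh_adjust, estimate_variance_prior
from .errors import ValidationError
from .integration import aggregate_dataset, build_integrated_table

# African collection sites with plausible coordinate boxes
_SITES = [
    ("Burkina Faso", (10.5, 14.0), (-5.5, 2.0)),
    ("Cote d'Ivoire", (4.5, 10.5), (-8.5, -2.5)),
    ("Cameroon", (2.0, 12.5), (9.0, 16.0)),
    ("Kenya", (-4.5, 4.5), (34.0, 41.5)),
    ("Tanzania", (-11.5, -1.0), (30.0, 40.0)),
    ("Uganda", (-1.5, 4.0), (29.5, 35.0)),
    ("Sudan", (9.0, 22.0), (22.0, 38.0)),
    ("Zambia", (-18.0, -8.0), (22.0, 33.5)),
]
_COMPARATORS = ["N'Gousso", "Kisumu", "Mali-NIH", "Dongola"]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults mirror the published study design: 31 datasets on one platform,
    six replicate arrays per comparison with replicate noise SD 0.5 on the
    log2 scale, 56 transcripts planted consistently up and 30 down (strong
    candidates, planted log2 FC 2, i.e. fourfold), one six-transcript
    co-expression module with unit loading and residual SD 0.1, a 0.05
    significance level, and half of the raw arrays dye-swapped.
    """

    seed: int
    n_datasets: int = 31
    n_transcripts: int = 1000
    multi_probe_fraction: float = 0.3  # transcripts measured by 2-3 probes
    cross_hyb_fraction: float = 0.02
    splice_variant_fraction: float = 0.15  # genes contributing a second transcript
    n_planted_up: int = 56
    n_planted_down: int = 30
    planted_log2fc: float = 2.0
    module_specs: list[tuple[int, float, float]] = field(
        default_factory=lambda: [(6, 1.0, 0.1)]
    )
    noise_sd: float = 0.5
    arrays_per_dataset: int = 6
    dye_swap_fraction: float = 0.5
    dye_bias_amplitude: float = 0.4
    alpha: float = 0.05

    def validate(self) -> None:
        if self.seed is None:
            raise ValidationError("a seed is mandatory")
        for name in ("n_datasets", "n_transcripts", "arrays_per_dataset"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        n_planted = self.n_planted_up + self.n_planted_down
        n_module = sum(size for size, _, _ in self.module_specs)
        if n_planted + n_module > self.n_transcripts:
            raise ValidationError(
                f"planted ({n_planted}) + module ({n_module}) transcripts exceed "
                f"n_transcripts ({self.n_transcripts})"
            )


@dataclass
class GroundTruth:
    planted_up: frozenset[str]
    planted_down: frozenset[str]
    module_membership: dict[str, int]
    true_log2fc: pd.DataFrame  # transcript x dataset


def _transcript_ids(config: SimulationConfig, rng: np.random.Generator) -> list[str]:
    """Synthetic VectorBase-style identifiers; a fraction of genes carry a
    second splice variant so gene-collapsing has something to do."""
    ids: list[str] = []
    gene = 0
    while len(ids) < config.n_transcripts:
        gene += 1
        stem = f"AGSYN{gene:06d}"
        ids.append(f"{stem}-RA")
        if (
            len(ids) < config.n_transcripts
            and rng.random() < config.splice_variant_fraction
        ):
            ids.append(f"{stem}-RB")
    return ids[: config.n_transcripts]


def simulate_metadata(config: SimulationConfig, rng: np.random.Generator) -> list[DatasetMeta]:
    meta = []
    species_pool = ["coluzzii", "gambiae", "arabiensis"]
    exposure_pool = ["pyrethroid", "pyrethroid", "DDT", "bendiocarb", "none", "unknown"]
    for i in range(config.n_datasets):
        country, lat_box, lon_box = _SITES[rng.integers(len(_SITES))]
        mortality = float(np.round(rng.uniform(0, 90), 1))
        meta.append(
            DatasetMeta(
                dataset_id=f"DS{i + 1:02d}",
                country=country,
                species=species_pool[rng.integers(3)],
                latitude=float(np.round(rng.uniform(*lat_box), 3)),
                longitude=float(np.round(rng.uniform(*lon_box), 3)),
                resistance_class=derive_resistance_class(mortality),
                mortality_pct=mortality,
                exposure=exposure_pool[rng.integers(len(exposure_pool))],
                kdr_frequency=float(np.round(rng.uniform(0, 1), 2)),
                year=int(rng.integers(2009, 2016)),
                comparator=_COMPARATORS[rng.integers(len(_COMPARATORS))],
            )
        )
    return meta


def _true_log2fc(
    config: SimulationConfig, transcripts: list[str], rng: np.random.Generator
) -> tuple[pd.DataFrame, GroundTruth]:
    n_t, n_d = config.n_transcripts, config.n_datasets
    true = np.zeros((n_t, n_d))
    order = rng.permutation(n_t)
    up_idx = order[: config.n_planted_up]
    down_idx = order[config.n_planted_up : config.n_planted_up + config.n_planted_down]
    true[up_idx, :] = config.planted_log2fc
    true[down_idx, :] = -config.planted_log2fc

    module_membership: dict[str, int] = {}
    cursor = config.n_planted_up + config.n_planted_down
    for mod_id, (size, loading, mod_sd) in enumerate(config.module_specs):
        members = order[cursor : cursor + size]
        cursor += size
        f = rng.standard_normal(n_d)
        true[members, :] += loading * f[None, :] + rng.normal(0.0, mod_sd, (size, n_d))
        for m in members:
            module_membership[transcripts[m]] = mod_id

    df = pd.DataFrame(true, index=pd.Index(transcripts, name="transcript"),
                      columns=[f"DS{i + 1:02d}" for i in range(n_d)])
    truth = GroundTruth(
        planted_up=frozenset(transcripts[i] for i in up_idx),
        planted_down=frozenset(transcripts[i] for i in down_idx),
        module_membership=module_membership,
        true_log2fc=df,
    )
    return df, truth


def simulate_annotation(
    config: SimulationConfig,
    transcripts: list[str],
    rng: np.random.Generator,
    protected: frozenset[str] = frozenset(),
) -> list[ProbeAnnotation]:
    """Probe layout: most transcripts have one probe; a fraction have 2-3;
    a small fraction of probes cross-hybridise to a second gene.

    ``protected`` transcripts (planted signature and module members) never
    take part in cross-hybridisation, so their measured profiles stay
    identifiable against the planted ground truth; contaminated probes are
    confined to background transcripts.
    """
    annotation: list[ProbeAnnotation] = []
    background = [t for t in transcripts if t not in protected]
    probe_no = 0
    for i, t in enumerate(transcripts):
        n_probes = 1
        if rng.random() < config.multi_probe_fraction:
            n_probes = int(rng.integers(2, 4))
        for _ in range(n_probes):
            probe_no += 1
            pid = f"P{probe_no:07d}"
            targets = [t]
            if (
                t not in protected
                and len(background) > 1
                and rng.random() < config.cross_hyb_fraction
            ):
                other = background[int(rng.integers(len(background)))]
                if other != t:
                    targets.append(other)
            annotation.append(
                ProbeAnnotation(probe_id=pid, transcript_ids=tuple(targets),
                                cross_hyb=len(targets) > 1)
            )
    return annotation


def _simulate_core(
    config: SimulationConfig,
) -> tuple[IntegratedTable, list[DatasetMeta], GroundTruth, list[ProbeAnnotation]]:
    config.validate()
    rng = np.random.default_rng(config.seed)
    transcripts = _transcript_ids(config, rng)
    meta = simulate_metadata(config, rng)
    true, truth = _true_log2fc(config, transcripts, rng)
    protected = frozenset(
        truth.planted_up | truth.planted_down | set(truth.module_membership)
    )
    annotation = simulate_annotation(config, transcripts, rng, protected=protected)

    t_index = {t: i for i, t in enumerate(transcripts)}
    n_arr = config.arrays_per_dataset
    per_dataset: dict[str, list] = {}
    for d, m in enumerate(meta):
        # per-probe true effect: mean over the transcripts the probe reports
        probe_true = np.array(
            [
                np.mean([true.iloc[t_index[t], d] for t in a.transcript_ids])
                for a in annotation
            ]
        )
        reps = probe_true[:, None] + rng.normal(0.0, config.noise_sd, (len(annotation), n_arr))
        mean = reps.mean(axis=1)
        s2 = np.maximum(reps.var(axis=1, ddof=1), 1e-8)
        # moderated test on the replicates, mirroring the upstream pipeline
        d0, s0_2 = estimate_variance_prior(s2, n_arr - 1)
        if np.isinf(d0):
            post_var, df_total = np.full_like(s2, s0_2), np.inf
        else:
            post_var = (d0 * s0_2 + (n_arr - 1) * s2) / (d0 + n_arr - 1)
            df_total = d0 + n_arr - 1
        tstat = mean / np.sqrt(post_var / n_arr)
        p = 2.0 * stats.t.sf(np.abs(tstat), df_total)
        q = bh_adjust(p)
        probes = [
            ProbeResult(
                dataset_id=m.dataset_id,
                probe_id=a.probe_id,
                fold_change=float(2.0 ** mean[i]),
                q_value=float(q[i]),
            )
            for i, a in enumerate(annotation)
        ]
        per_dataset[m.dataset_id] = aggregate_dataset(probes, annotation, alpha=config.alpha)

    results = [r for rs in per_dataset.values() for r in rs]
    table = build_integrated_table(results, meta)
    # keep declared transcript order for reproducible downstream indexing
    order = [t for t in transcripts if t in table.fc.index]
    table = IntegratedTable(
        fc=table.fc.loc[order],
        q=table.q.loc[order],
        discordant=table.discordant.loc[order],
        cross_hyb=table.cross_hyb.loc[order],
    )
    return table, meta, truth, annotation


def simulate_integrated(
    config: SimulationConfig,
) -> tuple[IntegratedTable, list[DatasetMeta], GroundTruth]:
    """Generate a full integrated table plus metadata and ground truth.

    Probe-level measurements are simulated around the true transcript log2
    fold change, replicate noise is summarised by an ordinary per-probe
    t-test with BH within each dataset, and the probe → transcript consensus
    aggregation is performed by the real integration code — so every
    generated table has passed the same path real data would.
    """
    table, meta, truth, _ = _simulate_core(config)
    return table, meta, truth


def simulate_raw_signals(
    config: SimulationConfig, n_probes: int | None = None
) -> tuple[list[TwoColorArray], GroundTruth]:
    """Raw two-colour intensities for one resistant-vs-susceptible comparison.

    Probe A values are uniform on [6, 14] log2 units; the raw log ratio of
    each array carries the biological M (sign flipped on dye-swapped arrays),
    replicate noise, and a smooth intensity-dependent dye bias that loess
    normalisation is expected to remove.
    """
    config.validate()
    if config.arrays_per_dataset < 2:
        raise ValidationError("arrays_per_dataset must be >= 2")
    rng = np.random.default_rng(config.seed)
    n = n_probes if n_probes is not None else config.n_transcripts
    probe_ids = np.array([f"P{i + 1:07d}" for i in range(n)])

    true_m = np.zeros(n)
    order = rng.permutation(n)
    up = order[: config.n_planted_up]
    down = order[config.n_planted_up : config.n_planted_up + config.n_planted_down]
    true_m[up] = config.planted_log2fc
    true_m[down] = -config.planted_log2fc

    base_a = rng.uniform(6.0, 14.0, n)
    n_swapped = int(round(config.dye_swap_fraction * config.arrays_per_dataset))
    arrays = []
    for j in range(config.arrays_per_dataset):
        swapped = j < n_swapped
        a_vals = base_a + rng.normal(0.0, 0.1, n)
        bias = config.dye_bias_amplitude * np.sin(2.0 * np.pi * (a_vals - 6.0) / 8.0)
        sign = -1.0 if swapped else 1.0
        log_ratio = sign * (true_m + rng.normal(0.0, config.noise_sd, n)) + bias
        red = 2.0 ** (a_vals + log_ratio / 2.0)
        green = 2.0 ** (a_vals - log_ratio / 2.0)
        arrays.append(
            TwoColorArray(
                array_id=f"array_{j + 1}",
                probe_ids=probe_ids,
                red=red,
                green=green,
                dye_swapped=swapped,
            )
        )
    truth = GroundTruth(
        planted_up=frozenset(probe_ids[up]),
        planted_down=frozenset(probe_ids[down]),
        module_membership={},
        true_log2fc=pd.DataFrame({"true_M": true_m}, index=pd.Index(probe_ids, name="probe_id")),
    )
    return arrays, truth


def truth_gene_sets(truth: GroundTruth) -> list[GeneSet]:
    """Gene sets derived from the planted structure (for enrichment demos)."""
    sets = []
    if truth.planted_up:
        sets.append(GeneSet("planted_up", frozenset(truth.planted_up)))
    if truth.planted_down:
        sets.append(GeneSet("planted_down", frozenset(truth.planted_down)))
    modules: dict[int, set[str]] = {}
    for t, mod in truth.module_membership.items():
        modules.setdefault(mod, set()).add(t)
    for mod, members in sorted(modules.items()):
        sets.append(GeneSet(f"module_{mod}", frozenset(members)))
    return sets


def write_simulation(
    config: SimulationConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Run ``simulate_integrated`` and write every standard TSV to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, meta, truth, annotation = _simulate_core(config)

    paths = {
        "integrated": out / "integrated.tsv",
        "metadata": out / "metadata.tsv",
        "annotation": out / "annotation.tsv",
        "gene_sets": out / "gene_sets.tsv",
        "ground_truth": out / "ground_truth.tsv",
    }
    write_integrated_table(table, paths["integrated"])
    write_metadata(meta, paths["metadata"])
    write_annotation(annotation, paths["annotation"])
    write_gene_sets(truth_gene_sets(truth), paths["gene_sets"])
    gt = truth.true_log2fc.copy()
    gt.insert(0, "planted", [
        "up" if t in truth.planted_up
        else "down" if t in truth.planted_down
        else f"module_{truth.module_membership[t]}" if t in truth.module_membership
        else "none"
        for t in gt.index
    ])
    gt.reset_index().to_csv(paths["ground_truth"], sep="\t", index=False, na_rep="NA")
    return paths
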