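"""Synthetic multi-platform, multi-experiment expression collections.

The generator emulates the structure of a pooled injury-vs-control microarray
compendium: several independent experiments, run on platform designs from
different "species" whose gene symbols differ in capitalisation (mouse
``Gene0001`` vs human ``GENE0001``), measuring a shared gene universe through
platform-specific probe sets with multi-probe genes and a fraction of
unannotated probes.  A minority of planted genes carries a direction-
consistent group-mean shift on the log2 scale; every other gene is pure
noise.  The planted set and directions come back as an explicit truth set,
so every downstream stage is testable with known ground truth.

Values are generated — and recorded in metadata — on the log2 scale, with
independent Gaussian within-group noise per probe.

Seeding: one master seed; each experiment, each platform and the truth draw
use fixed-offset substreams, so adding an experiment never perturbs the data
of earlier ones.
"""

from __future__ import annotations

import os
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .linking import ANNOTATION_COLUMNS
from .sam import CASE, CONTROL, ExperimentMatrix

__all__ = [
    "PlatformSpec",
    "SimulationConfig",
    "TruthSet",
    "generate_collection",
    "write_fixture",
]

_SPECIES_CYCLE = ("mouse", "human", "rat")
# fixed substream offsets off the master seed
_TRUTH_STREAM = 1_000_003
_PLATFORM_STREAM = 2_000_003
_EXPERIMENT_STREAM = 3_000_003


@dataclass
class PlatformSpec:
    """One array design: probe count and annotation quirks."""

    n_probes: int
    fraction_multiprobe_genes: float = 0.1
    fraction_unannotated_probes: float = 0.05
    species: str | None = None

    def validate(self, name: str) -> None:
        if self.n_probes < 1:
            raise ValueError(f"{name}.n_probes must be >= 1")
        for fld in ("fraction_multiprobe_genes", "fraction_unannotated_probes"):
            v = getattr(self, fld)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}.{fld} must lie in [0, 1]")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic collection.

    effect_log2fc is the mean absolute group-mean shift of planted genes;
    direction_consistency is the probability that a planted gene keeps its
    global direction in any given experiment; sigma_within is the
    within-group standard deviation on the log2 scale.
    """

    n_experiments: int = 10
    platforms: list[PlatformSpec] = field(
        default_factory=lambda: [PlatformSpec(n_probes=6000), PlatformSpec(n_probes=6000)]
    )
    n_genes: int = 5000
    n_planted: int = 50
    effect_log2fc: float = 1.0
    direction_consistency: float = 1.0
    sigma_within: float = 0.5
    n_per_group: int = 3
    baseline_mean: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_experiments < 1:
            raise ValueError("n_experiments must be >= 1")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0 <= self.n_planted < self.n_genes:
            raise ValueError("n_planted must satisfy 0 <= n_planted < n_genes")
        if self.effect_log2fc < 0:
            raise ValueError("effect_log2fc must be non-negative")
        if not 0.0 <= self.direction_consistency <= 1.0:
            raise ValueError("direction_consistency must lie in [0, 1]")
        if self.sigma_within <= 0:
            raise ValueError("sigma_within must be positive")
        if self.n_per_group < 3:
            raise ValueError("n_per_group must be >= 3 (minimum biological replication)")
        if not self.platforms:
            raise ValueError("platforms must not be empty")
        for i, p in enumerate(self.platforms):
            p.validate(f"platforms[{i}]")


@dataclass
class TruthSet:
    """Planted differentially expressed genes, by unified gene key."""

    planted_genes: set[str]
    planted_direction: dict[str, int]  # gene -> +1 (up in injury) or -1

    def __post_init__(self) -> None:
        if set(self.planted_direction) != self.planted_genes:
            raise ValueError("planted_direction keys must equal planted_genes")


def _symbol_for_species(key: str, species: str) -> str:
    # human arrays print full-uppercase symbols, rodent arrays capitalise
    return key if species == "human" else key.capitalize()


def _platform_annotation(
    spec: PlatformSpec, platform_idx: int, gene_keys: list[str], seed: int
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Probe table for one platform and the probe ids backing each gene."""
    rng = np.random.default_rng([seed, _PLATFORM_STREAM + platform_idx])
    species = spec.species or _SPECIES_CYCLE[platform_idx % len(_SPECIES_CYCLE)]
    platform_id = f"P{platform_idx + 1}"
    n_unann = int(round(spec.fraction_unannotated_probes * spec.n_probes))
    n_annotated = spec.n_probes - n_unann

    n_genes = len(gene_keys)
    if n_annotated >= n_genes:
        measured = list(gene_keys)
        spare = n_annotated - n_genes
    else:
        idx = np.sort(rng.choice(n_genes, size=n_annotated, replace=False))
        measured = [gene_keys[i] for i in idx]
        spare = 0
    # designated multi-probe genes soak up the spare probes round-robin
    n_multi = int(round(spec.fraction_multiprobe_genes * len(measured)))
    multi_idx = np.sort(rng.choice(len(measured), size=n_multi, replace=False)) if n_multi else np.array([], dtype=int)
    extra_per_gene = np.zeros(len(measured), dtype=int)
    if n_multi and spare:
        base, rem = divmod(spare, n_multi)
        extra_per_gene[multi_idx] = base
        extra_per_gene[multi_idx[:rem]] += 1
    probes_per_gene = 1 + extra_per_gene

    rows = []
    gene_probes: dict[str, list[str]] = {}
    counter = 0
    for g_i, key in enumerate(measured):
        chrom, pos = _gene_coordinates(key)
        for _ in range(probes_per_gene[g_i]):
            counter += 1
            probe_id = f"{platform_id}_{counter:06d}"
            rows.append(
                (platform_id, probe_id, _symbol_for_species(key, species), species, chrom, pos)
            )
            gene_probes.setdefault(key, []).append(probe_id)
    for _ in range(n_unann):
        counter += 1
        rows.append((platform_id, f"{platform_id}_{counter:06d}", "", species, None, None))
    table = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    return table, gene_probes


def _gene_coordinates(key: str) -> tuple[str, int]:
    """Deterministic chromosome/position layout over 20 chromosomes."""
    idx = (
        int(key[4:]) - 1
        if key.startswith("GENE") and key[4:].isdigit()
        else zlib.crc32(key.encode()) % 10**6
    )
    labels = [str(c) for c in range(1, 20)] + ["X"]
    return labels[idx % 20], 100_000 + (idx // 20) * 50_000


def generate_collection(
    config: SimulationConfig,
) -> tuple[list[ExperimentMatrix], list[pd.DataFrame], TruthSet]:
    """Draw one full synthetic collection under the configured conditions.

    Returns (experiments, per-platform annotation tables, truth set).
    Experiments cycle through the platforms in order; each has
    2 * n_per_group samples labelled control/case.  Identical config and
    seed reproduce the collection exactly, element for element.
    """
    gene_keys = [f"GENE{i + 1:05d}" for i in range(config.n_genes)]

    truth_rng = np.random.default_rng([config.seed, _TRUTH_STREAM])
    planted_idx = (
        np.sort(truth_rng.choice(config.n_genes, size=config.n_planted, replace=False))
        if config.n_planted
        else np.array([], dtype=int)
    )
    planted = [gene_keys[i] for i in planted_idx]
    # balanced up/down plant: exercises both call directions equally and keeps
    # the global positive/negative vote totals comparable, to which the
    # all-other-genes background of the vote statistic is sensitive
    directions = {g: (1 if k % 2 == 0 else -1) for k, g in enumerate(planted)}
    truth = TruthSet(planted_genes=set(planted), planted_direction=directions)

    annotations: list[pd.DataFrame] = []
    platform_gene_probes: list[dict[str, list[str]]] = []
    for p_i, spec in enumerate(config.platforms):
        table, gene_probes = _platform_annotation(spec, p_i, gene_keys, config.seed)
        annotations.append(table)
        platform_gene_probes.append(gene_probes)

    experiments: list[ExperimentMatrix] = []
    n = config.n_per_group
    groups = np.array([CONTROL] * n + [CASE] * n, dtype=object)
    for e_i in range(config.n_experiments):
        p_i = e_i % len(config.platforms)
        table = annotations[p_i]
        gene_probes = platform_gene_probes[p_i]
        probe_ids = table["probe"].tolist()
        rng = np.random.default_rng([config.seed, _EXPERIMENT_STREAM + e_i])

        # per-experiment direction flips, drawn once per planted gene
        exp_shift: dict[str, float] = {}
        for g in planted:
            keep = rng.random() < config.direction_consistency
            direction = directions[g] if keep else -directions[g]
            exp_shift[g] = direction * config.effect_log2fc

        shift_by_probe = np.zeros(len(probe_ids))
        probe_pos = {p: i for i, p in enumerate(probe_ids)}
        for g, shift in exp_shift.items():
            for probe in gene_probes.get(g, ()):
                shift_by_probe[probe_pos[probe]] = shift

        baseline = rng.normal(config.baseline_mean, 1.0, size=len(probe_ids))
        noise = rng.normal(0.0, config.sigma_within, size=(len(probe_ids), 2 * n))
        values = baseline[:, None] + noise
        values[:, n:] += shift_by_probe[:, None]
        experiments.append(
            ExperimentMatrix(
                probe_ids=probe_ids,
                values=values,
                groups=groups.copy(),
                experiment_id=f"E{e_i + 1:03d}",
                platform_id=f"P{p_i + 1}",
                sample_ids=[f"E{e_i + 1:03d}_S{j + 1}" for j in range(2 * n)],
            )
        )
    return experiments, annotations, truth


def write_fixture(
    collection: tuple[list[ExperimentMatrix], list[pd.DataFrame], TruthSet],
    directory: str | os.PathLike,
) -> dict[str, list[str]]:
    """Write a collection as plain TSVs that round-trip through the readers.

    Emits one expression TSV plus a two-column sample sheet per experiment,
    one annotation TSV per platform, a truth TSV (gene, direction), and a
    metadata YAML noting the log2 scale.  Returns the file manifest.
    """
    from .io import write_experiment  # deferred: io imports this module's types

    experiments, annotations, truth = collection
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, list[str]] = {"expression": [], "samples": [], "annotation": [], "truth": []}
    for exp in experiments:
        expr_path = directory / f"{exp.experiment_id}.expression.tsv"
        sheet_path = directory / f"{exp.experiment_id}.samples.tsv"
        write_experiment(exp, expr_path, sheet_path)
        manifest["expression"].append(str(expr_path))
        manifest["samples"].append(str(sheet_path))
    seen: set[str] = set()
    for table in annotations:
        platform_id = str(table["platform"].iloc[0]) if len(table) else "P?"
        if platform_id in seen:
            continue
        seen.add(platform_id)
        path = directory / f"{platform_id}.annotation.tsv"
        table.to_csv(path, sep="\t", index=False)
        manifest["annotation"].append(str(path))
    truth_path = directory / "truth.tsv"
    truth_frame = pd.DataFrame(
        {
            "gene": sorted(truth.planted_genes),
            "direction": [truth.planted_direction[g] for g in sorted(truth.planted_genes)],
        }
    )
    truth_frame.to_csv(truth_path, sep="\t", index=False)
    manifest["truth"].append(str(truth_path))
    with open(directory / "metadata.yaml", "w") as fh:
        yaml.safe_dump({"scale": "log2", "generator": "egwas_meta.simulate"}, fh)
    return manifest
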