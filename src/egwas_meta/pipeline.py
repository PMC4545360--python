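"""End-to-end orchestration: filters, SAM, linking, vote statistic, reports.

``run_collection`` is the in-memory engine; ``run_pipeline`` wraps it with
file I/O, dataset inclusion filtering, deterministic TSV serialization and a
run log.  Both are deterministic given the configuration and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as eio
from .linking import (
    AliasTable,
    ProbeGeneMap,
    build_gene_call_matrix,
    collapse_to_gene,
    link_collection,
)
from .literature import classify_table, read_citation_frame, summarize
from .sam import (
    ExperimentMatrix,
    SamConfig,
    choose_s0,
    permutation_null,
    run_sam,
    sam_d_scores,
    sam_qc,
)
from .stats import (
    AnalysisConfig,
    bonferroni_threshold,
    build_vote_table,
    manhattan_data,
    rank_and_flag,
    run_contingency_tests,
)

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "apply_inclusion_filters",
    "run_collection",
    "run_pipeline",
    "RANKED_COLUMNS",
]

logger = logging.getLogger(__name__)

RANKED_COLUMNS = [
    "gene",
    "n_pos",
    "n_neg",
    "n_tested",
    "test_used",
    "p_value",
    "significant",
    "rank",
    "chromosome",
    "position",
]

REASON_PLATFORM = "platform size"
REASON_REPLICATION = "replication"
REASON_QC = "sam_qc"


class PipelineError(RuntimeError):
    """Stage failure carrying the stage name and the offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class ExperimentInput:
    expression: str
    samples: str
    platform: str
    experiment_id: str | None = None


@dataclass
class PipelineConfig:
    """Everything one run needs; round-trips losslessly through YAML."""

    experiments: list[ExperimentInput] = field(default_factory=list)
    annotations: list[str] = field(default_factory=list)
    aliases: str | None = None
    citations: str | None = None
    sam: SamConfig = field(default_factory=SamConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    out_dir: str = "egwas_out"
    log_level: str = "INFO"
    apply_filters: bool = True
    min_probes: int = 5000
    min_per_group: int = 3
    run_qc: bool = True
    collapse_rule: str = "majority"

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw["experiments"] = [ExperimentInput(**e) for e in raw.get("experiments", [])]
        if "sam" in raw:
            raw["sam"] = SamConfig(**raw["sam"])
        if "analysis" in raw:
            raw["analysis"] = AnalysisConfig(**raw["analysis"])
        return cls(**raw)

    def validate_paths(self) -> None:
        for e in self.experiments:
            for p in (e.expression, e.samples):
                if not Path(p).exists():
                    raise PipelineError("config", f"missing input file: {p}")
        for p in list(self.annotations) + [self.aliases, self.citations]:
            if p is not None and not Path(p).exists():
                raise PipelineError("config", f"missing input file: {p}")

    def content_hash(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def apply_inclusion_filters(
    experiments: list[ExperimentMatrix],
    min_probes: int = 5000,
    min_per_group: int = 3,
    sam_config: SamConfig | None = None,
    run_qc: bool = True,
) -> tuple[list[ExperimentMatrix], list[tuple[str, str]]]:
    """Dataset QC filters applied before any analysis.

    In order: platform size (strictly more than ``min_probes`` interrogated
    probes — a genome-wide design, not a focussed custom array), biological
    replication (at least ``min_per_group`` per arm), and the SAM-plot signal
    distribution check.  Each rejected experiment carries the first criterion
    it failed; retained experiments keep their input order.
    """
    sam_config = sam_config or SamConfig()
    retained: list[ExperimentMatrix] = []
    rejected: list[tuple[str, str]] = []
    for exp in experiments:
        if exp.n_probes <= min_probes:
            rejected.append((exp.experiment_id, REASON_PLATFORM))
            continue
        if exp.n_control < min_per_group or exp.n_case < min_per_group:
            rejected.append((exp.experiment_id, REASON_REPLICATION))
            continue
        if run_qc:
            qc_config = dataclasses.replace(
                sam_config, n_permutations=min(sam_config.n_permutations, 100)
            )
            s0 = choose_s0(exp, qc_config.s0_quantile)
            d = sam_d_scores(exp, s0)
            null = permutation_null(exp, qc_config, s0)
            if not sam_qc(exp, d, null).passed:
                rejected.append((exp.experiment_id, REASON_QC))
                continue
        retained.append(exp)
    return retained, rejected


def run_collection(
    experiments: list[ExperimentMatrix],
    annotations: list[pd.DataFrame],
    aliases: AliasTable | None = None,
    sam_config: SamConfig | None = None,
    analysis_config: AnalysisConfig | None = None,
    collapse_rule: str = "majority",
) -> dict:
    """SAM every experiment, link, vote, test, rank — all in memory.

    Returns a dict with the probe map, per-experiment SAM results, the gene
    call matrix, vote table, Bonferroni threshold, the ranked gene records
    and the Manhattan plot data.
    """
    if not experiments:
        raise PipelineError("sam", "no experiments to analyse")
    sam_config = sam_config or SamConfig()
    analysis_config = analysis_config or AnalysisConfig()

    probe_map: ProbeGeneMap = link_collection(annotations, aliases)
    if not probe_map.universe:
        raise PipelineError("linking", "empty gene universe after linking")

    sam_results = {}
    per_experiment = {}
    for exp in experiments:
        result = run_sam(exp, sam_config)
        sam_results[exp.experiment_id] = result
        per_experiment[exp.experiment_id] = collapse_to_gene(
            result, probe_map, exp.platform_id, rule=collapse_rule
        )
    calls = build_gene_call_matrix(per_experiment, probe_map.universe)
    votes = build_vote_table(calls)
    threshold = bonferroni_threshold(len(probe_map.universe), analysis_config.alpha)
    records = run_contingency_tests(votes, analysis_config, probe_map.coordinates)
    ranked = rank_and_flag(records, threshold)
    manhattan = manhattan_data(ranked, threshold=threshold)
    return {
        "probe_map": probe_map,
        "sam_results": sam_results,
        "calls": calls,
        "votes": votes,
        "threshold": threshold,
        "ranked": ranked,
        "manhattan": manhattan,
    }


def _format_ranked(ranked: pd.DataFrame) -> pd.DataFrame:
    out = ranked.reset_index()[
        [c for c in RANKED_COLUMNS if c in ranked.reset_index().columns]
    ].copy()
    out["p_value"] = [f"{p:.5e}" for p in out["p_value"]]
    out["position"] = [
        "" if pd.isna(p) else str(int(p)) for p in out["position"]
    ]
    out["chromosome"] = ["" if c is None or pd.isna(c) else str(c) for c in out["chromosome"]]
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """File-to-file pipeline run; returns the result bundle with paths.

    Outputs under ``config.out_dir``: ranked_genes.tsv, vote_table.tsv,
    manhattan.tsv, classification.tsv (when a citation table is given) and
    run.log recording the config hash and seed.  Reruns with an identical
    config produce byte-identical TSVs.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.validate_paths()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    try:
        experiments = [
            eio.read_experiment(
                e.expression,
                e.samples,
                experiment_id=e.experiment_id,
                platform_id=e.platform,
                strict=False,
            )
            for e in config.experiments
        ]
        annotations = [eio.read_annotation(p) for p in config.annotations]
        aliases = eio.read_alias_table(config.aliases) if config.aliases else None
    except (ValueError, OSError) as err:
        raise PipelineError("read", str(err)) from err

    rejected: list[tuple[str, str]] = []
    if config.apply_filters:
        experiments, rejected = apply_inclusion_filters(
            experiments,
            min_probes=config.min_probes,
            min_per_group=config.min_per_group,
            sam_config=config.sam,
            run_qc=config.run_qc,
        )
        for exp_id, reason in rejected:
            logger.info("excluded %s: %s", exp_id, reason)
    # the under-replicated were filtered; the survivors must satisfy the invariant
    experiments = [
        ExperimentMatrix(
            probe_ids=e.probe_ids,
            values=e.values,
            groups=e.groups,
            experiment_id=e.experiment_id,
            platform_id=e.platform_id,
            sample_ids=e.sample_ids,
        )
        for e in experiments
    ]

    result = run_collection(
        experiments,
        annotations,
        aliases=aliases,
        sam_config=config.sam,
        analysis_config=config.analysis,
        collapse_rule=config.collapse_rule,
    )

    ranked_path = out_dir / "ranked_genes.tsv"
    _format_ranked(result["ranked"]).to_csv(ranked_path, sep="\t", index=False)
    votes_path = out_dir / "vote_table.tsv"
    result["votes"].counts.to_csv(votes_path, sep="\t")
    manhattan_path = out_dir / "manhattan.tsv"
    mtab = result["manhattan"]["table"].copy()
    mtab["neg_log10_p"] = [f"{y:.6g}" for y in mtab["neg_log10_p"]]
    mtab.to_csv(manhattan_path, sep="\t", index=False)

    paths = {
        "ranked": str(ranked_path),
        "votes": str(votes_path),
        "manhattan": str(manhattan_path),
    }
    if config.citations:
        try:
            classified = classify_table(read_citation_frame(config.citations))
        except (ValueError, OSError) as err:
            raise PipelineError("classify", str(err)) from err
        class_path = out_dir / "classification.tsv"
        classified.to_csv(class_path, sep="\t", index=False)
        paths["classification"] = str(class_path)
        result["classification"] = classified
        result["class_summary"] = summarize(classified)

    log_path = out_dir / "run.log"
    with open(log_path, "w") as fh:
        fh.write(f"config_hash\t{config.content_hash()}\n")
        fh.write(f"seed\t{config.sam.seed}\n")
        fh.write(f"n_experiments\t{len(experiments)}\n")
        fh.write(f"n_genes\t{len(result['probe_map'].universe)}\n")
        fh.write(f"bonferroni_threshold\t{result['threshold']:.5e}\n")
        for exp_id, reason in rejected:
            fh.write(f"excluded\t{exp_id}\t{reason}\n")
    paths["log"] = str(log_path)

    result["paths"] = paths
    result["rejected"] = rejected
    return result
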