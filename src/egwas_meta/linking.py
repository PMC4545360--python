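"""Cross-platform, cross-species probe-to-gene linking.

Array platforms name the same gene differently (mouse ``Clec4e`` vs human
``CLEC4E``; retired aliases like ``PAI1`` for ``SERPINE1``).  Probes are
resolved to a unified gene key in two stages: case-folded symbol
normalisation, then an alias table mapping retired or alternate symbols onto
approved ones.  Probe-level differential-expression calls are then collapsed
to one ternary call per gene per experiment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .sam import SamResult

__all__ = [
    "ANNOTATION_COLUMNS",
    "AliasTable",
    "ProbeGeneMap",
    "normalize_symbol",
    "link_collection",
    "collapse_to_gene",
    "build_gene_call_matrix",
    "POSITIVE",
    "NEGATIVE",
    "NULL",
    "NOT_MEASURED",
]

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ["platform", "probe", "symbol", "species", "chromosome", "position"]

POSITIVE = "positive"
NEGATIVE = "negative"
NULL = "null"
NOT_MEASURED = "not_measured"


class AliasTable:
    """Alias -> approved-symbol lookup; approved symbols are fixed points."""

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()):
        self._map: dict[str, str] = {}
        for alias, approved in pairs:
            a = alias.strip().upper()
            b = approved.strip().upper()
            if not a or not b:
                continue
            self._map[a] = b
            self._map.setdefault(b, b)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AliasTable":
        return cls(zip(frame.iloc[:, 0].astype(str), frame.iloc[:, 1].astype(str)))

    def resolve(self, symbol: str) -> str:
        return self._map.get(symbol, symbol)

    def __len__(self) -> int:
        return len(self._map)


def normalize_symbol(raw: str | None, aliases: AliasTable | None = None) -> str | None:
    """Case-fold and alias-resolve one symbol; None for unmappable input.

    Idempotent: the output is always a fixed point of the normalisation.
    """
    if raw is None:
        return None
    sym = str(raw).strip().upper()
    if not sym or sym in {"NA", "NAN", "NONE", "---"}:
        return None
    if aliases is not None:
        sym = aliases.resolve(sym)
    return sym


@dataclass
class ProbeGeneMap:
    """(platform, probe) -> unified gene key, plus the linked gene universe."""

    mapping: dict[tuple[str, str], str]
    universe: list[str]
    coordinates: pd.DataFrame  # index gene, columns chromosome/position
    genes_by_platform: dict[str, set[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.mapping)

    def get(self, platform: str, probe: str) -> str | None:
        return self.mapping.get((platform, probe))


def _validate_annotation(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ANNOTATION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"annotation table lacks columns: {missing}")
    return table


def link_collection(
    annotations: Iterable[pd.DataFrame], aliases: AliasTable | None = None
) -> ProbeGeneMap:
    """Resolve every annotated probe on every platform to one gene key.

    Unannotated probes (empty symbol) are simply absent from the map.  The
    union of mapped keys across platforms is the linked gene universe — the N
    that the Bonferroni correction divides by downstream.  Conflicting
    duplicate (platform, probe) rows are a hard error; conflicting
    chromosome/position annotations only log (the coordinates order a plot,
    nothing more), and the first annotating platform wins.
    """
    mapping: dict[tuple[str, str], str] = {}
    coords: dict[str, tuple[str, int]] = {}
    genes_by_platform: dict[str, set[str]] = {}
    conflicts: list[tuple[str, str]] = []
    for table in annotations:
        table = _validate_annotation(table)
        for row in table.itertuples(index=False):
            key = (str(row.platform), str(row.probe))
            gene = normalize_symbol(row.symbol, aliases)
            if gene is None:
                continue
            if key in mapping and mapping[key] != gene:
                conflicts.append(key)
                continue
            mapping[key] = gene
            genes_by_platform.setdefault(key[0], set()).add(gene)
            if gene not in coords and pd.notna(row.chromosome):
                coords[gene] = (str(row.chromosome), int(row.position))
            elif gene in coords and pd.notna(row.chromosome):
                if coords[gene] != (str(row.chromosome), int(row.position)):
                    logger.debug("coordinate conflict for %s; keeping first", gene)
    if conflicts:
        raise ValueError(
            f"conflicting symbols for duplicated (platform, probe) pairs: {conflicts[:10]}"
        )
    universe = sorted(set(mapping.values()))
    coord_frame = pd.DataFrame(
        {
            "chromosome": [coords.get(g, (None, None))[0] for g in universe],
            "position": [coords.get(g, (None, None))[1] for g in universe],
        },
        index=pd.Index(universe, name="gene"),
    )
    return ProbeGeneMap(
        mapping=mapping,
        universe=universe,
        coordinates=coord_frame,
        genes_by_platform=genes_by_platform,
    )


def collapse_to_gene(
    sam: SamResult,
    probe_map: ProbeGeneMap,
    platform_id: str,
    rule: str = "majority",
) -> pd.Series:
    """Collapse probe calls to one ternary call per gene on this platform.

    majority (default): the call held by a strict majority of the gene's
    non-null probe calls; a positive/negative tie and an all-null probe set
    both yield null.  any_positive: positive if any probe is positive, else
    negative if any is negative, else null.
    """
    if rule not in {"majority", "any_positive"}:
        raise ValueError(f"unknown collapse rule: {rule!r}")
    calls_by_gene: dict[str, list[str]] = {}
    for probe, call in zip(sam.probe_ids, sam.call):
        gene = probe_map.get(platform_id, probe)
        if gene is None:
            continue
        calls_by_gene.setdefault(gene, []).append(call)
    out: dict[str, str] = {}
    for gene, calls in calls_by_gene.items():
        n_pos = calls.count(POSITIVE)
        n_neg = calls.count(NEGATIVE)
        if rule == "any_positive":
            out[gene] = POSITIVE if n_pos else (NEGATIVE if n_neg else NULL)
        elif n_pos > n_neg:
            out[gene] = POSITIVE
        elif n_neg > n_pos:
            out[gene] = NEGATIVE
        else:
            out[gene] = NULL
    return pd.Series(out, dtype=object).sort_index()


def build_gene_call_matrix(
    per_experiment: Mapping[str, pd.Series], universe: Iterable[str]
) -> pd.DataFrame:
    """Assemble experiments x genes ternary calls; unmeasured genes marked.

    A gene is ``not_measured`` in an experiment iff no mapped probe of that
    gene exists on the experiment's platform.
    """
    universe = sorted(universe)
    frame = pd.DataFrame(
        NOT_MEASURED, index=list(per_experiment.keys()), columns=universe, dtype=object
    )
    for exp_id, series in per_experiment.items():
        frame.loc[exp_id, series.index] = series.values
    frame.index.name = "experiment"
    frame.columns.name = "gene"
    return frame
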