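"""Literature-based tiering of candidate genes.

Given per-gene citation counts against three search terms — "lung",
"lung injury", "acute lung injury" — candidates are partitioned into

    known : at least one citation with "acute lung injury";
    novel : none with "acute lung injury" but at least one with "lung injury";
    new   : no "lung injury" citations at all.

The "lung" column is descriptive context only and never affects the class.
A transcription of the published 42-candidate table ships with the package
(``load_bundled_citations``) so the classifier is exercisable offline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "CITATION_COLUMNS",
    "ClassSummary",
    "read_citation_frame",
    "load_bundled_citations",
    "classify_gene",
    "classify_table",
    "summarize",
]

CITATION_COLUMNS = ["gene", "lung", "lung_injury", "acute_lung_injury"]

KNOWN = "known"
NOVEL = "novel"
NEW = "new"


def _validate(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CITATION_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"citation table lacks columns: {missing}")
    counts = frame[CITATION_COLUMNS[1:]]
    if (counts.to_numpy() < 0).any():
        raise ValueError("citation counts must be non-negative")
    if frame["gene"].duplicated().any():
        dupes = frame.loc[frame["gene"].duplicated(), "gene"].tolist()
        raise ValueError(f"duplicated genes in citation table: {dupes}")
    return frame


def read_citation_frame(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    frame.columns = [c.strip().lower().replace(" ", "_") for c in frame.columns]
    return _validate(frame)


def load_bundled_citations() -> pd.DataFrame:
    """The packaged 42-gene citation-count table."""
    ref = resources.files("egwas_meta").joinpath("data/pubmatrix_lung_citations.tsv")
    with resources.as_file(ref) as path:
        return read_citation_frame(path)


def classify_gene(n_lung: int, n_lung_injury: int, n_acute_lung_injury: int) -> str:
    """Apply the citation rule to one gene's counts."""
    if min(n_lung, n_lung_injury, n_acute_lung_injury) < 0:
        raise ValueError("citation counts must be non-negative")
    if n_acute_lung_injury >= 1:
        return KNOWN
    if n_lung_injury >= 1:
        return NOVEL
    return NEW


def classify_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Classify every row; returns the frame with a ``category`` column."""
    frame = _validate(frame.copy())
    frame["category"] = [
        classify_gene(int(r.lung), int(r.lung_injury), int(r.acute_lung_injury))
        for r in frame.itertuples(index=False)
    ]
    return frame


def _truncate1(x: float) -> float:
    return math.floor(x * 10.0) / 10.0


@dataclass
class ClassSummary:
    """Partition sizes and headline fractions.

    Percentages are reported both truncated and rounded to one decimal:
    published gene-partition fractions are frequently truncated (23/42 =
    54.76% printed as 54.7%), so both conventions are kept visible.
    """

    n_known: int
    n_novel: int
    n_new: int
    pct_known_truncated: float
    pct_known_rounded: float
    pct_lung_injury_linked_truncated: float
    pct_lung_injury_linked_rounded: float

    @property
    def n_total(self) -> int:
        return self.n_known + self.n_novel + self.n_new


def summarize(classified: pd.DataFrame) -> ClassSummary:
    """Partition counts and the known / lung-injury-linked percentages."""
    if len(classified) == 0:
        raise ValueError("cannot summarize an empty classification")
    cats = classified["category"]
    n_known = int((cats == KNOWN).sum())
    n_novel = int((cats == NOVEL).sum())
    n_new = int((cats == NEW).sum())
    total = len(classified)
    pct_known = 100.0 * n_known / total
    pct_linked = 100.0 * (n_known + n_novel) / total
    return ClassSummary(
        n_known=n_known,
        n_novel=n_novel,
        n_new=n_new,
        pct_known_truncated=_truncate1(pct_known),
        pct_known_rounded=round(pct_known, 1),
        pct_lung_injury_linked_truncated=_truncate1(pct_linked),
        pct_lung_injury_linked_rounded=round(pct_linked, 1),
    )
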