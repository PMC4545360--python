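"""The eGWAS vote-count statistic.

Across experiments, each gene accumulates votes: the number of experiments
calling it significantly up (positive) or down (negative).  Consistent
differential expression is then tested gene by gene with a 2x2 contingency
table pitting the gene's own (positive, negative) counts against the summed
counts of all other genes:

        [[ n_pos(g),           n_neg(g)          ],
         [ total_pos - n_pos,  total_neg - n_neg ]]

Pearson's chi-square (1 df, no continuity correction) is used when every
expected cell is large enough, otherwise a two-sided Fisher exact test
computed by exact integer enumeration of the hypergeometric distribution.
Genome-wide significance is a Bonferroni threshold, alpha over the number of
genes in the linked universe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

__all__ = [
    "AnalysisConfig",
    "VoteTable",
    "build_vote_table",
    "fisher_exact_two_sided",
    "pearson_chi2_2x2",
    "gene_contingency_test",
    "run_contingency_tests",
    "bonferroni_threshold",
    "rank_and_flag",
    "manhattan_data",
]


@dataclass
class AnalysisConfig:
    """Knobs of the contingency stage.

    alpha : family-wise error rate behind the Bonferroni threshold.
    fisher_switch_expected : minimum expected cell count for the chi-square
        branch; any smaller expected cell routes the gene to Fisher.
    continuity_correction : Yates correction for the chi-square branch
        (off by default).
    seed : reserved; the exact tests consume no randomness.
    """

    alpha: float = 0.05
    fisher_switch_expected: float = 5.0
    continuity_correction: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class VoteTable:
    """Per-gene positive/negative experiment counts plus global totals."""

    counts: pd.DataFrame  # index gene; columns n_pos, n_neg, n_tested
    total_pos: int
    total_neg: int

    def background(self, gene: str) -> tuple[int, int]:
        row = self.counts.loc[gene]
        return self.total_pos - int(row.n_pos), self.total_neg - int(row.n_neg)


def build_vote_table(calls: pd.DataFrame) -> VoteTable:
    """Count positive/negative experiments per gene from the call matrix.

    Experiments, not probes, are what gets counted; ``not_measured`` entries
    contribute neither to the votes nor to ``n_tested``.
    """
    if calls.size == 0:
        raise ValueError("empty gene call matrix")
    arr = calls.to_numpy(dtype=object)
    n_pos = (arr == "positive").sum(axis=0)
    n_neg = (arr == "negative").sum(axis=0)
    n_tested = (arr != "not_measured").sum(axis=0)
    counts = pd.DataFrame(
        {"n_pos": n_pos, "n_neg": n_neg, "n_tested": n_tested},
        index=calls.columns.copy(),
    )
    counts.index.name = "gene"
    return VoteTable(
        counts=counts, total_pos=int(n_pos.sum()), total_neg=int(n_neg.sum())
    )


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for [[a, b], [c, d]] by integer enumeration.

    Sums the hypergeometric probabilities of every table with the observed
    margins whose probability does not exceed that of the observed table.
    All comparisons happen on integer numerators over the common denominator
    C(N, a+c), so tie decisions are exact — no floating-point pmf round-off.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("contingency cells must be non-negative")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    total = 0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        t = math.comb(r1, x) * math.comb(r2, c1 - x)
        if t <= obs:
            total += t
    return min(1.0, total / math.comb(n, c1))


def pearson_chi2_2x2(
    a: int, b: int, c: int, d: int, continuity: bool = False
) -> tuple[float, float]:
    """Pearson chi-square statistic and p (1 df) for a 2x2 table."""
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return 0.0, 1.0
    num = abs(a * d - b * c)
    if continuity:
        num = max(0.0, num - n / 2.0)
    stat = n * num * num / (r1 * r2 * c1 * c2)
    return float(stat), float(chi2_dist.sf(stat, df=1))


def gene_contingency_test(
    gene_votes: tuple[int, int],
    background: tuple[int, int],
    config: AnalysisConfig | None = None,
) -> tuple[float, float | None, str]:
    """Test one gene's votes against the all-other-genes background.

    Returns (p_value, statistic-or-None, test_used).  Chi-square runs when
    every expected cell reaches ``fisher_switch_expected``; otherwise Fisher.
    A gene never called in any experiment is assigned p = 1 by convention.
    """
    config = config or AnalysisConfig()
    a, b = int(gene_votes[0]), int(gene_votes[1])
    c, d = int(background[0]), int(background[1])
    if min(a, b, c, d) < 0:
        raise ValueError("contingency cells must be non-negative")
    if c == 0 and d == 0:
        raise ValueError("background row must not be all zero")
    if a == 0 and b == 0:
        return 1.0, None, "none"
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    min_expected = min(
        r1 * c1, r1 * c2, r2 * c1, r2 * c2
    ) / n
    if min_expected >= config.fisher_switch_expected:
        stat, p = pearson_chi2_2x2(a, b, c, d, continuity=config.continuity_correction)
        return p, stat, "chi2"
    return fisher_exact_two_sided(a, b, c, d), None, "fisher"


def bonferroni_threshold(n_genes: int, alpha: float = 0.05) -> float:
    """Genome-wide significance threshold: alpha / number of tested genes."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / n_genes


def run_contingency_tests(
    votes: VoteTable,
    config: AnalysisConfig | None = None,
    coordinates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Run the contingency test for every gene in the vote table.

    Returns one row per gene: n_pos, n_neg, n_tested, p_value, statistic,
    test_used, and plotting coordinates when supplied.
    """
    config = config or AnalysisConfig()
    counts = votes.counts
    p_values = np.empty(len(counts))
    stats: list[float | None] = []
    tests: list[str] = []
    np_arr = counts["n_pos"].to_numpy()
    nn_arr = counts["n_neg"].to_numpy()
    for i in range(len(counts)):
        a, b = int(np_arr[i]), int(nn_arr[i])
        bg = (votes.total_pos - a, votes.total_neg - b)
        if bg == (0, 0):
            # the gene holds every vote in the collection: a single
            # realisable table under the margins, hence p = 1
            p, stat, used = (1.0, None, "fisher") if (a or b) else (1.0, None, "none")
        else:
            p, stat, used = gene_contingency_test((a, b), bg, config)
        p_values[i] = p
        stats.append(stat)
        tests.append(used)
    out = counts.copy()
    out["p_value"] = p_values
    out["statistic"] = [s if s is not None else np.nan for s in stats]
    out["test_used"] = tests
    if coordinates is not None:
        out = out.join(coordinates, how="left")
    else:
        out["chromosome"] = None
        out["position"] = np.nan
    return out


def rank_and_flag(records: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Order genes by p ascending and flag genome-wide significance.

    Ties break by descending total votes (n_pos + n_neg), then gene key;
    the significance flag uses strict inequality p < threshold.
    """
    df = records.copy()
    if "gene" in df.columns:
        df = df.set_index("gene")
    df.index.name = "gene"
    df["_votes"] = df["n_pos"] + df["n_neg"]
    df = (
        df.reset_index()
        .sort_values(
            by=["p_value", "_votes", "gene"],
            ascending=[True, False, True],
            kind="stable",
        )
        .set_index("gene")
        .drop(columns="_votes")
    )
    df["rank"] = np.arange(1, len(df) + 1)
    df["significant"] = df["p_value"] < threshold
    return df


def _chromosome_sort_key(label) -> tuple[int, float, str]:
    if label is None or (isinstance(label, float) and math.isnan(label)):
        return (3, math.inf, "")
    text = str(label)
    if text.isdigit():
        return (0, int(text), "")
    if text in ("X", "Y"):
        return (1, 0 if text == "X" else 1, "")
    return (2, math.inf, text)


def manhattan_data(records: pd.DataFrame, threshold: float | None = None) -> dict:
    """Per-gene plotting table: cumulative genome x, -log10 p on y.

    Chromosomes order numerically, then X, Y, then other labels
    lexicographically; genes lacking coordinates land in a trailing
    "unplaced" bin.  Gene labels are emitted for significant genes only.
    Returns {"table": DataFrame, "threshold": float, "chromosome_offsets": dict}.
    """
    df = records.copy()
    if "gene" not in df.columns:
        df = df.reset_index()
    df["chromosome"] = df["chromosome"].where(pd.notna(df["chromosome"]), None)
    df["position"] = pd.to_numeric(df["position"], errors="coerce")

    chroms = sorted({c for c in df["chromosome"] if c is not None}, key=_chromosome_sort_key)
    offsets: dict[str, float] = {}
    offset = 0.0
    for ch in chroms:
        offsets[ch] = offset
        sub = df.loc[df["chromosome"] == ch, "position"]
        span = float(sub.max()) if len(sub) and np.isfinite(sub.max()) else 1.0
        offset += max(span, 1.0)
    offsets["unplaced"] = offset

    xs = np.empty(len(df))
    chrom_out = []
    for i, (ch, pos) in enumerate(zip(df["chromosome"], df["position"])):
        if ch is None or not np.isfinite(pos):
            xs[i] = offsets["unplaced"] + i  # stable spread within the bin
            chrom_out.append("unplaced")
        else:
            xs[i] = offsets[ch] + pos
            chrom_out.append(str(ch))
    with np.errstate(divide="ignore"):
        ys = -np.log10(df["p_value"].to_numpy(dtype=float))
    table = pd.DataFrame(
        {
            "gene": df["gene"],
            "chromosome": chrom_out,
            "x": xs,
            "neg_log10_p": ys,
        }
    )
    if "significant" in df.columns:
        table["label"] = np.where(df["significant"].to_numpy(dtype=bool), df["gene"], "")
    else:
        table["label"] = ""
    return {"table": table, "threshold": threshold, "chromosome_offsets": offsets}
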