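"""Significance Analysis of Microarrays (SAM) for two-class unpaired designs.

Each injury-vs-control experiment is scored with the moderated statistic

    d_i = (mean_case_i - mean_control_i) / (s_i + s0)

where ``s_i`` is the pooled standard error of the group-mean difference and
``s0`` ("fudge factor") is a small positive constant that stabilises d for
low-dispersion probes.  Significance is assessed against a permutation null:
group labels are reshuffled, d recomputed, and the sorted observed scores are
compared with the expected order statistics of the null.  A symmetric delta
band around the identity line defines up/down cutoffs; the smallest delta
whose estimated false discovery rate is at or below the target yields the
per-probe calls (positive / negative / null).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "ExperimentMatrix",
    "SamConfig",
    "SamResult",
    "PermutationNull",
    "QcSummary",
    "sam_d_scores",
    "pooled_standard_errors",
    "choose_s0",
    "permutation_null",
    "call_probes",
    "sam_qc",
    "run_sam",
]

CONTROL = "control"
CASE = "case"


@dataclass
class ExperimentMatrix:
    """One two-group expression experiment (probes x samples, log2 scale).

    Missing cells are represented as NaN; a probe is dropped from scoring when
    either group retains fewer than two observed values.
    """

    probe_ids: list[str]
    values: np.ndarray
    groups: np.ndarray  # per-sample label, 'control' or 'case'
    experiment_id: str = "experiment"
    platform_id: str = "platform"
    sample_ids: list[str] | None = None
    # strict=False defers the replication check to the inclusion filters,
    # so under-replicated experiments can be loaded and then rejected
    strict: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.groups = np.asarray(self.groups, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D probes x samples matrix")
        if self.values.shape[0] != len(self.probe_ids):
            raise ValueError("probe_ids length does not match value rows")
        if self.values.shape[1] != len(self.groups):
            raise ValueError("groups length does not match value columns")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            dupes = sorted({p for p in self.probe_ids if self.probe_ids.count(p) > 1})
            raise ValueError(f"duplicated probe ids: {dupes[:5]}")
        bad = set(self.groups) - {CONTROL, CASE}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if self.strict and (self.n_control < 3 or self.n_case < 3):
            raise ValueError(
                "each group needs at least 3 biological replicates "
                f"(got control={self.n_control}, case={self.n_case})"
            )
        if self.sample_ids is None:
            self.sample_ids = [f"S{i + 1}" for i in range(self.values.shape[1])]

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def case_mask(self) -> np.ndarray:
        return np.asarray([g == CASE for g in self.groups], dtype=bool)

    @property
    def control_mask(self) -> np.ndarray:
        return np.asarray([g == CONTROL for g in self.groups], dtype=bool)

    @property
    def n_case(self) -> int:
        return int(np.sum([g == CASE for g in self.groups]))

    @property
    def n_control(self) -> int:
        return int(np.sum([g == CONTROL for g in self.groups]))


@dataclass
class SamConfig:
    """Tunables of the SAM stage.

    n_permutations : upper bound on label permutations; designs whose distinct
        assignments fit within it are enumerated exhaustively instead.
    s0_quantile : a fixed quantile of the per-probe standard errors, or
        "auto" for the coefficient-of-variation minimisation.
    target_fdr : the estimated FDR the delta search must reach.
    """

    n_permutations: int = 1000
    s0_quantile: float | Literal["auto"] = "auto"
    target_fdr: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0.0 < self.target_fdr < 1.0:
            raise ValueError("target_fdr must lie in (0, 1)")
        if self.s0_quantile != "auto" and not 0.0 <= float(self.s0_quantile) <= 1.0:
            raise ValueError("s0_quantile must be 'auto' or a proportion in [0, 1]")


@dataclass
class PermutationNull:
    """Permutation null of the d statistic.

    ``expected_order_stats`` holds the per-rank mean of the sorted permuted
    scores (the x coordinates of a SAM plot); ``sorted_scores`` retains every
    permutation's sorted vector for FDR estimation.
    """

    expected_order_stats: np.ndarray
    sorted_scores: np.ndarray  # (n_permutations, n_defined), rows sorted
    exhaustive: bool
    n_permutations: int


@dataclass
class SamResult:
    """Per-probe SAM output for one experiment."""

    probe_ids: list[str]
    d: np.ndarray
    s: np.ndarray
    fold_change: np.ndarray
    q_value: np.ndarray
    call: np.ndarray  # 'positive' | 'negative' | 'null'
    defined: np.ndarray  # probes with a well-defined score
    metadata: dict = field(default_factory=dict)

    def calls_by_probe(self) -> dict[str, str]:
        return dict(zip(self.probe_ids, self.call))


@dataclass
class QcSummary:
    """SAM-plot QC: observed vs expected order statistics and a pass flag."""

    expected: np.ndarray
    observed: np.ndarray
    central_max_deviation: float
    fraction_defined: float
    passed: bool


def _group_stats(values: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Complete-case per-probe mean, sum of squared deviations, and count."""
    sub = values[:, mask]
    obs = ~np.isnan(sub)
    n = obs.sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, np.nansum(sub, axis=1) / np.maximum(n, 1), np.nan)
        ss = np.nansum((sub - mean[:, None]) ** 2, axis=1)
    return mean, ss, n


def pooled_standard_errors(
    values: np.ndarray, case_mask: np.ndarray, control_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Difference of group means and its pooled standard error, per probe.

    Returns (diff, s, mean_case, mean_control, usable) where ``usable`` marks
    probes with >= 2 observed values in each group.
    """
    mean_case, ss_case, n_case = _group_stats(values, case_mask)
    mean_ctrl, ss_ctrl, n_ctrl = _group_stats(values, control_mask)
    usable = (n_case >= 2) & (n_ctrl >= 2)
    n1 = np.maximum(n_ctrl, 2)
    n2 = np.maximum(n_case, 2)
    a = (1.0 / n1 + 1.0 / n2) / (n1 + n2 - 2)
    s = np.sqrt(a * (ss_case + ss_ctrl))
    diff = mean_case - mean_ctrl
    diff = np.where(usable, diff, np.nan)
    s = np.where(usable, s, np.nan)
    return diff, s, mean_case, mean_ctrl, usable


def sam_d_scores(matrix: ExperimentMatrix, s0: float) -> np.ndarray:
    """The SAM score d = (mean_case - mean_control) / (s + s0), probe order.

    Probes with zero dispersion in both groups and ``s0 == 0`` have no
    defined score and come back NaN; callers treat them as excluded rather
    than propagating NaN into downstream calls.
    """
    if s0 < 0:
        raise ValueError("s0 must be non-negative")
    diff, s, _, _, usable = pooled_standard_errors(
        matrix.values, matrix.case_mask, matrix.control_mask
    )
    denom = s + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = diff / denom
    d = np.where(usable & (denom > 0), d, np.nan)
    return d


def choose_s0(matrix: ExperimentMatrix, mode: float | str = "auto") -> float:
    """Select the exchangeability constant s0.

    A numeric ``mode`` takes that quantile of the per-probe pooled standard
    errors.  ``"auto"`` runs the coefficient-of-variation minimisation: for a
    grid of candidate quantiles, probes are binned by their standard error and
    the spread (MAD) of d within each bin is computed; the candidate whose
    bin-wise MADs have the smallest coefficient of variation wins.  Fully
    deterministic given the input.
    """
    diff, s, _, _, usable = pooled_standard_errors(
        matrix.values, matrix.case_mask, matrix.control_mask
    )
    s_ok = s[usable & np.isfinite(s)]
    if s_ok.size == 0 or np.all(s_ok == 0):
        warnings.warn("all pooled standard errors are zero; using tiny epsilon s0")
        return float(np.finfo(float).tiny)
    if mode != "auto":
        return float(np.quantile(s_ok, float(mode)))

    d_ok = diff[usable & np.isfinite(s)]
    alphas = np.round(np.arange(0.0, 1.0001, 0.05), 2)
    candidates = np.quantile(s_ok, alphas)
    # bins of roughly equal occupancy by standard error
    n_bins = min(100, max(2, s_ok.size // 10))
    edges = np.quantile(s_ok, np.linspace(0, 1, n_bins + 1))
    bin_idx = np.clip(np.searchsorted(edges, s_ok, side="right") - 1, 0, n_bins - 1)
    best_cv, best_s0 = np.inf, float(candidates[0])
    for s0_cand in candidates:
        with np.errstate(divide="ignore", invalid="ignore"):
            d_cand = d_ok / (s_ok + s0_cand)
        mads = []
        for b in range(n_bins):
            db = d_cand[bin_idx == b]
            db = db[np.isfinite(db)]
            if db.size:
                med = np.median(db)
                mads.append(np.median(np.abs(db - med)))
        mads = np.asarray(mads)
        if mads.size == 0 or np.mean(mads) == 0:
            continue
        cv = np.std(mads) / np.mean(mads)
        if cv < best_cv - 1e-15:
            best_cv, best_s0 = cv, float(s0_cand)
    return best_s0


def _label_assignments(n_samples: int, n_case: int, config: SamConfig) -> tuple[np.ndarray, bool]:
    """Case-column index sets for every permutation (exhaustive when small)."""
    total = math.comb(n_samples, n_case)
    if total <= config.n_permutations:
        combos = np.array(
            list(itertools.combinations(range(n_samples), n_case)), dtype=int
        )
        return combos, True
    rng = np.random.default_rng(config.seed)
    combos = np.empty((config.n_permutations, n_case), dtype=int)
    for i in range(config.n_permutations):
        combos[i] = rng.choice(n_samples, size=n_case, replace=False)
    return combos, False


def permutation_null(
    matrix: ExperimentMatrix, config: SamConfig, s0: float
) -> PermutationNull:
    """Null distribution of d under label reshuffling, at the same s0.

    Each permutation's scores are sorted; the expected order statistics are
    the per-rank means across permutations.  Designs with no more distinct
    label assignments than ``n_permutations`` (e.g. 3 vs 3: C(6,3) = 20) are
    enumerated exhaustively, making the null seed-independent there.
    """
    d_obs = sam_d_scores(matrix, s0)
    defined = np.isfinite(d_obs)
    values = matrix.values[defined]
    n_samples = matrix.values.shape[1]
    combos, exhaustive = _label_assignments(n_samples, matrix.n_case, config)
    sorted_scores = np.empty((combos.shape[0], int(defined.sum())))
    for k, case_idx in enumerate(combos):
        case_mask = np.zeros(n_samples, dtype=bool)
        case_mask[case_idx] = True
        diff, s, _, _, usable = pooled_standard_errors(values, case_mask, ~case_mask)
        with np.errstate(divide="ignore", invalid="ignore"):
            d_perm = diff / (s + s0)
        d_perm = np.where(usable & np.isfinite(d_perm), d_perm, 0.0)
        sorted_scores[k] = np.sort(d_perm)
    return PermutationNull(
        expected_order_stats=sorted_scores.mean(axis=0),
        sorted_scores=sorted_scores,
        exhaustive=exhaustive,
        n_permutations=combos.shape[0],
    )


def _cuts_for_delta(
    d_sorted: np.ndarray, dbar: np.ndarray, delta: float
) -> tuple[float, float]:
    """Upper/lower d cutoffs for one delta, scanning outward from the origin."""
    diffs = d_sorted - dbar
    start = int(np.searchsorted(dbar, 0.0, side="left"))
    up = diffs[start:] >= delta
    cut_up = float(d_sorted[start + int(np.argmax(up))]) if up.any() else np.inf
    low = diffs[:start] <= -delta
    if low.any():
        cut_low = float(d_sorted[start - 1 - int(np.argmax(low[::-1]))])
    else:
        cut_low = -np.inf
    return cut_up, cut_low


def _estimate_pi0(d_defined: np.ndarray, all_null: np.ndarray) -> float:
    """Proportion of truly null probes, from the inner 50% of null scores."""
    q25, q75 = np.quantile(all_null, [0.25, 0.75])
    inside = np.sum((d_defined >= q25) & (d_defined <= q75))
    return float(min(1.0, 2.0 * inside / max(1, d_defined.size)))


def call_probes(
    matrix: ExperimentMatrix,
    d: np.ndarray,
    null: PermutationNull,
    config: SamConfig,
    s0: float | None = None,
    n_delta_grid: int = 101,
) -> SamResult:
    """Delta-threshold the observed scores against the permutation null.

    The smallest delta whose estimated FDR (median permutation exceedance
    count, scaled by the pi0 estimate, over the observed call count) reaches
    ``target_fdr`` defines the cuts; probes exactly on a cut are called
    (inclusive threshold).  The per-probe q-value is the smallest estimated
    FDR at which that probe would be called.  If no delta reaches the target,
    every call is null and the metadata records it.
    """
    defined = np.isfinite(d)
    d_def = d[defined]
    order = np.argsort(d_def, kind="stable")
    d_sorted = d_def[order]
    dbar = null.expected_order_stats
    if dbar.size != d_sorted.size:
        raise ValueError("null distribution does not match the defined probe set")

    all_null = null.sorted_scores.ravel()
    pi0 = _estimate_pi0(d_def, all_null) if d_def.size else 1.0

    diffs = np.abs(d_sorted - dbar)
    max_delta = float(diffs.max()) if diffs.size else 0.0
    deltas = np.linspace(0.0, max_delta, n_delta_grid)

    m = d_sorted.size

    def evaluate(delta: float) -> tuple[float, float, int, float]:
        """Cuts, call count and estimated FDR for one delta."""
        cut_up, cut_low = _cuts_for_delta(d_sorted, dbar, delta)
        n_called = int(np.sum(d_sorted >= cut_up) + np.sum(d_sorted <= cut_low))
        if n_called == 0:
            return cut_up, cut_low, 0, 0.0
        # strictly beyond the cuts: the observed scores themselves sit in the
        # null (identity permutation) exactly on the cut values
        counts = np.empty(null.sorted_scores.shape[0])
        for k in range(null.sorted_scores.shape[0]):
            row = null.sorted_scores[k]
            n_up = m - np.searchsorted(row, cut_up, side="right")
            n_low = np.searchsorted(row, cut_low, side="left")
            counts[k] = n_up + n_low
        fdr = min(1.0, pi0 * float(np.median(counts)) / n_called)
        return cut_up, cut_low, n_called, fdr

    fdrs = np.empty_like(deltas)
    cuts = np.empty((deltas.size, 2))
    called_n = np.empty(deltas.size, dtype=int)
    for j, delta in enumerate(deltas):
        cut_up, cut_low, n_called, fdr = evaluate(delta)
        cuts[j] = (cut_up, cut_low)
        called_n[j] = n_called
        fdrs[j] = fdr

    chosen = None
    for j in range(deltas.size):
        if called_n[j] > 0 and fdrs[j] <= config.target_fdr:
            chosen = j
            break

    chosen_delta = None
    chosen_cuts = None
    chosen_fdr = None
    if chosen is not None:
        chosen_delta = float(deltas[chosen])
        chosen_cuts = tuple(cuts[chosen])
        chosen_fdr = float(fdrs[chosen])
        if chosen > 0:
            # bisect for the smallest passing delta between the grid points
            lo, hi = float(deltas[chosen - 1]), float(deltas[chosen])
            for _ in range(30):
                mid = 0.5 * (lo + hi)
                cut_up, cut_low, n_called, fdr = evaluate(mid)
                if n_called > 0 and fdr <= config.target_fdr:
                    hi = mid
                    chosen_delta, chosen_cuts, chosen_fdr = mid, (cut_up, cut_low), fdr
                else:
                    lo = mid

    call = np.full(len(d), "null", dtype=object)
    q_value = np.ones(len(d))
    # q-value: smallest FDR over the delta grid at which the probe is called
    q_def = np.ones(m)
    for j in range(deltas.size):
        called_here = (d_sorted >= cuts[j, 0]) | (d_sorted <= cuts[j, 1])
        q_def[called_here] = np.minimum(q_def[called_here], fdrs[j])
    q_back = np.empty(m)
    q_back[order] = q_def
    q_value[defined] = q_back

    metadata: dict = {"s0": s0, "pi0": pi0, "n_permutations": null.n_permutations}
    if chosen is None:
        metadata.update({"delta": None, "no_delta_found": True, "fdr": None})
    else:
        cut_up, cut_low = chosen_cuts
        pos_sorted = d_sorted >= cut_up
        neg_sorted = d_sorted <= cut_low
        call_def = np.full(m, "null", dtype=object)
        call_def[pos_sorted] = "positive"
        call_def[neg_sorted] = "negative"
        call_back = np.empty(m, dtype=object)
        call_back[order] = call_def
        call[defined] = call_back
        # the refined cuts define one more (delta, FDR) point for q-values
        q_here = np.ones(m)
        q_here[pos_sorted | neg_sorted] = chosen_fdr
        q_def = np.minimum(q_def, q_here)
        q_back = np.empty(m)
        q_back[order] = q_def
        q_value[defined] = q_back
        metadata.update(
            {
                "delta": float(chosen_delta),
                "cut_up": float(cut_up),
                "cut_low": float(cut_low),
                "fdr": float(chosen_fdr),
                "no_delta_found": False,
            }
        )

    diff_s = pooled_standard_errors(
        matrix.values, matrix.case_mask, matrix.control_mask
    )
    _, _, mean_case, mean_ctrl, usable = diff_s
    with np.errstate(over="ignore", invalid="ignore"):
        fold = np.where(usable, np.exp2(mean_case - mean_ctrl), np.nan)
    return SamResult(
        probe_ids=list(matrix.probe_ids),
        d=d,
        s=diff_s[1],
        fold_change=fold,
        q_value=q_value,
        call=call,
        defined=defined,
        metadata=metadata,
    )


def sam_qc(
    matrix: ExperimentMatrix,
    d: np.ndarray,
    null: PermutationNull,
    central_tolerance: float = 0.5,
) -> QcSummary:
    """The SAM-plot QC used as a dataset inclusion criterion.

    Emits the (expected, observed) order-statistic pairs.  QC fails when
    degenerate probes (zero dispersion in both groups) dominate, or when the
    central 50% of points stray from the identity line by more than
    ``central_tolerance`` in d units — the signature of an improper signal
    distribution.
    """
    diff, s, _, _, usable = pooled_standard_errors(
        matrix.values, matrix.case_mask, matrix.control_mask
    )
    degenerate = usable & (s == 0) & (diff == 0)
    fraction_defined = float(np.isfinite(d).sum()) / max(1, len(d))
    nondegenerate_frac = 1.0 - float(degenerate.sum()) / max(1, len(d))

    d_sorted = np.sort(d[np.isfinite(d)])
    dbar = null.expected_order_stats
    m = d_sorted.size
    if m and dbar.size == m:
        lo, hi = int(math.floor(0.25 * m)), int(math.ceil(0.75 * m))
        central = np.abs(d_sorted[lo:hi] - dbar[lo:hi])
        central_max = float(central.max()) if central.size else 0.0
    else:
        central_max = float("inf")
    passed = (
        fraction_defined >= 0.5
        and nondegenerate_frac >= 0.5
        and central_max <= central_tolerance
    )
    return QcSummary(
        expected=dbar,
        observed=d_sorted,
        central_max_deviation=central_max,
        fraction_defined=fraction_defined,
        passed=passed,
    )


def run_sam(matrix: ExperimentMatrix, config: SamConfig | None = None) -> SamResult:
    """Convenience wrapper: choose s0, build the null, and call probes."""
    config = config or SamConfig()
    s0 = choose_s0(matrix, config.s0_quantile)
    d = sam_d_scores(matrix, s0)
    null = permutation_null(matrix, config, s0)
    return call_probes(matrix, d, null, config, s0=s0)
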