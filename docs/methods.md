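# Methods

## The model

The pipeline treats a phenotype (here: acute lung injury) as a *vote
aggregation* problem over many independent two-group expression
experiments. Three statistical layers are stacked:

1. **Per-experiment calling (SAM).** Each experiment is a probes × samples
   matrix on the log2 scale with a control arm and a case (injury) arm of at
   least three biological replicates each. The moderated statistic
   `d = Δx̄ / (s + s0)` divides the group-mean difference by the pooled
   standard error plus an exchangeability constant. The null is obtained by
   relabelling samples: every distinct assignment of case labels is
   enumerated when their count does not exceed the permutation budget
   (3 vs 3 gives exactly C(6,3) = 20, making small designs seed-free);
   otherwise assignments are sampled from the seeded generator. Observed
   sorted scores are compared with the expected order statistics of the
   null; the calling threshold is the smallest delta whose estimated FDR —
   π0 times the median count of permuted scores strictly beyond the cuts,
   over the observed call count — reaches the target (default 0.05). A probe
   exactly on a cut is called. π0 is estimated from the fraction of observed
   scores inside the inner 50 % of the null. The result is a ternary call
   per probe: positive, negative, null.

2. **Linking.** Probe identifiers from heterogeneous platforms resolve to a
   unified gene key by case-folded symbol matching plus an alias table
   (retired or alternate symbols map to approved ones; approved symbols are
   fixed points, making normalisation idempotent). Orthology across species
   is approximated by symbol identity after case folding — no sequence-based
   orthology. Multi-probe genes collapse by majority vote of their non-null
   probe calls; a positive/negative tie is conservatively null (an
   any-positive rule is available behind a switch). A gene absent from a
   platform is `not_measured` there and contributes nothing downstream.

3. **The vote statistic.** Gene g's (n_pos, n_neg) experiment counts are
   tested against the summed counts of all other genes in a 2×2 table.
   Pearson chi-square (1 df, no continuity correction) runs when every
   expected cell is at least 5 (configurable); otherwise a two-sided Fisher
   exact test. The Fisher branch is computed by exact integer enumeration:
   table probabilities are compared as integer numerators over the common
   denominator C(N, c1), so tie decisions are exact rather than subject to
   floating-point pmf round-off. Genes never called anywhere have p = 1 by
   convention, as does the degenerate case where one gene holds every vote
   in the collection (a single realisable table). Ranking is by ascending p,
   ties broken by descending total votes then gene key; the genome-wide flag
   is strict p < α/N with N the size of the linked gene universe.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `SamConfig.target_fdr` | 0.05 | estimated FDR the delta search must reach |
| `SamConfig.n_permutations` | 1000 | permutation budget; small designs enumerate exhaustively |
| `SamConfig.s0_quantile` | `"auto"` | s0 as a quantile of the per-probe standard errors, or CV-minimisation |
| `AnalysisConfig.alpha` | 0.05 | family-wise rate behind the Bonferroni threshold |
| `AnalysisConfig.fisher_switch_expected` | 5 | minimum expected cell for the chi-square branch |
| `min_probes` (filters) | 5000 | strictly-greater platform-size inclusion criterion |
| `min_per_group` (filters) | 3 | minimum biological replication per arm |

The automatic s0 follows the coefficient-of-variation minimisation: for
candidate quantiles 0, 0.05, …, 1 of the standard-error distribution,
probes are binned into up to 100 equal-occupancy bins by standard error,
the median absolute deviation of d is computed per bin, and the candidate
minimising the across-bin coefficient of variation wins. On homoscedastic
synthetic data this lands near the top quantile (d is then roughly
proportional to the raw group difference), which is also empirically the
most sensitive choice there.

## Dataset inclusion filters

Experiments pass three checks, in order, before analysis: platform size
(strictly more than `min_probes` interrogated probes — a genome-wide array,
not a focussed custom design; exactly 5000 does not pass), replication
(≥ 3 per arm), and the SAM-plot QC: the observed vs expected order
statistics of d must keep their central 50 % within 0.5 d-units of the
identity line, and probes with zero dispersion in both groups must not
dominate. Each rejected experiment reports the first criterion it failed.

## The synthetic generator

`simulate.generate_collection` emulates the structure of a pooled
injury-vs-control compendium: several experiments cycling over platform
designs from different "species" whose symbols differ only in
capitalisation (exercising the normalisation path); a shared gene universe
measured through platform-specific probe sets with a configurable fraction
of multi-probe genes (all probes of a gene share its true shift plus
independent noise — the ambiguity the collapse rule must resolve) and of
unannotated probes; a minority of planted genes carrying a group-mean shift
of ±`effect_log2fc`; and independent Gaussian within-group noise per probe
(σ default 0.5 on the log2 scale, around a per-probe baseline near 8).
Values are emitted — and recorded in the fixture metadata — on the log2
scale.

Planted directions are assigned deterministically balanced (alternating
up/down) rather than i.i.d. random. This is intentional: the 2×2 statistic
tests each gene against the *global* vote background, and when planted
genes dominate the call totals an unbalanced up/down split skews the
background columns and dilutes the minority direction. A balanced plant
exercises both call directions symmetrically. Per experiment, a planted
gene keeps its global direction with probability `direction_consistency`,
else flips — `direction_consistency = 1` models a conserved response,
0.5 a direction-random artefact.

Seeding: one master seed; the truth draw, each platform annotation and
each experiment use fixed-offset substreams, so appending an experiment
never perturbs earlier data, and identical configurations reproduce
byte-identical fixtures.

What the generator does *not* emulate: array-specific artefacts (dye bias,
spatial effects), heavy-tailed or probe-correlated noise, partial platform
overlap of the gene universe, or citation counts. Passing tests on this
generator therefore demonstrate the pipeline's statistical machinery, not
robustness to real microarray pathology.

## Numerical and design choices

- Fold changes are anti-logged ratios of group means (2^Δx̄), reported
  descriptively and never used for calling.
- Missing cells are handled probe-wise complete-case within each group; a
  probe with fewer than two observed values in either group is dropped.
- A probe with zero dispersion in both groups and s0 = 0 has no defined
  score; it is excluded from calling rather than propagating NaN.
- The delta search evaluates a 101-point grid over the observed-vs-expected
  deviations and then bisects between the last failing and first passing
  grid points for the smallest passing delta.
- The 2×2 orientation is gene-row vs all-other-genes-row with
  positive/negative columns; the alternative (votes vs experiments-tested)
  was considered and rejected as it answers a different question (fraction
  of experiments responding, rather than consistency relative to the
  transcriptome-wide background).
- Bonferroni N is the linked-universe size, not per-platform probe counts.
- Ranked TSVs serialise p-values in 6-significant-digit scientific
  notation, so reruns with identical configuration are byte-identical.
- Chromosome ordering in Manhattan output is numeric ascending, then X, Y,
  then other labels lexicographically; genes without coordinates fall into
  a trailing "unplaced" bin. Coordinates come from the first platform that
  annotates a gene; conflicts are logged, not fatal, as they affect plot
  ordering only.
- Published candidate-fraction percentages are reproduced under truncation
  to one decimal (23/42 → 54.7), and the summary reports both truncated and
  rounded values.

## Problem sizes used by the test and acceptance runs

Desk-scale analogues of a full compendium: null calibration uses 100
collections of 10 experiments × 2000 genes with nothing planted (the
expected outcome, observed in all 100, is zero genome-wide-significant
genes); recovery uses 20 experiments × 2000 genes with 20 genes planted at
four within-group standard deviations. The Fisher branch is verified
against an independent exact enumeration on all 635 376 tables with grand
total ≤ 60.

## Known limitations

- At n = 3 per arm, the exhaustive permutation null has only 20 points, so
  per-experiment SAM sensitivity saturates around 0.85–0.90 for a 4σ
  effect at target FDR 0.05: the permutation null is contaminated by the
  planted probes themselves (the identity relabelling reproduces the
  observed scores), which makes the estimated FDR conservative relative to
  the realised one. Consequently, at Bonferroni stringency a gene typically
  needs votes in ≳ 85 % of experiments to be flagged, and gene-level
  recovery of strongly planted signal varies between roughly 60 % and 90 %
  across collections even though planted genes essentially always occupy
  the top ranks. Deeper replication or more experiments move recovery
  toward 1.
- The vote background is the whole collection, so when a handful of genes
  dominate the calls the test partly measures "consistency relative to
  other responders" — visible in small synthetic universes, negligible in
  transcriptome-scale ones.
- Species weighting is out of scope; every experiment contributes one vote
  regardless of species representation.
- Live retrieval (expression repositories, literature queries) is out of
  scope; the pipeline consumes local tables only.
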