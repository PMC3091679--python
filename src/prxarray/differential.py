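"""Differential-expression classification and developmental partitioning.

A gene is called **up** in a comparison when its linear fold ratio is at
least the up threshold (default 1.3) with a significant two-sided pooled
Student t-test on the replicate ratios (default p < 0.05), **down** when
the fold is at most the down threshold (default 0.7) with significance,
and **stable** otherwise.  Calls over several comparisons sharing one gene
universe partition the genes into Venn cells; stage-preference labels
("Highest in F2-S1", "Stable F1-S2") summarize each gene's profile along
the developmental trajectory; a 4-fold organ filter extracts genes
enriched in one organ group over another.

No multiple-testing correction is applied (the procedure is a per-gene
screen); reports carry the expected false-positive count at the chosen
alpha instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix, FoldTable, fold_ratios

UP, DOWN, STABLE, NOT_EVALUABLE = "up", "down", "stable", "not_evaluable"
CALLS = (UP, DOWN, STABLE, NOT_EVALUABLE)


@dataclass(frozen=True)
class DifferentialConfig:
    """Thresholds of the classification rule.

    ``up_threshold``/``down_threshold`` are linear fold ratios (inclusive
    bounds); ``alpha`` is the t-test significance level;
    ``organ_enrichment_fold`` is the mean-ratio cutoff of the organ filter.
    """

    up_threshold: float = 1.3
    down_threshold: float = 0.7
    alpha: float = 0.05
    organ_enrichment_fold: float = 4.0

    def __post_init__(self) -> None:
        if not (0 < self.down_threshold < 1 < self.up_threshold):
            raise ValueError(
                "thresholds must satisfy 0 < down < 1 < up, got "
                f"down={self.down_threshold}, up={self.up_threshold}"
            )
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.organ_enrichment_fold <= 1:
            raise ValueError(
                f"organ_enrichment_fold must exceed 1, got {self.organ_enrichment_fold}"
            )


def classify(fold: float, p_value: float, cfg: DifferentialConfig | None = None) -> str:
    """Classify one (fold, p) pair as up / down / stable.

    Thresholds are inclusive: fold ≥ up_threshold (or ≤ down_threshold)
    with p < alpha.  Folds must be positive and p in [0, 1].
    """
    cfg = cfg or DifferentialConfig()
    if not np.isfinite(fold) or fold <= 0:
        raise ValueError(f"fold must be positive and finite, got {fold}")
    if not 0 <= p_value <= 1:
        raise ValueError(f"p-value outside [0, 1]: {p_value}")
    if p_value < cfg.alpha:
        if fold >= cfg.up_threshold:
            return UP
        if fold <= cfg.down_threshold:
            return DOWN
    return STABLE


def ttest_gene(replicates_a: Sequence[float], replicates_b: Sequence[float]) -> float:
    """Two-sided pooled-variance Student t-test on replicate ratios.

    Returns a p-value in (0, 1].  Degenerate inputs are handled outside
    scipy: two constant, equal groups carry no signal and return 1; two
    constant, unequal groups are maximally significant and return the
    smallest positive normal float (scipy would return 0, outside the
    stated interval).
    """
    a = np.asarray(replicates_a, dtype=float)
    b = np.asarray(replicates_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(
            "t-test needs at least 2 replicates per group "
            f"(got {a.size} and {b.size}); flag the gene not_evaluable"
        )
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return 1.0
        return float(np.finfo(float).tiny)
    with warnings.catch_warnings():
        # rounding-level replicate jitter (e.g. noise-free simulations) makes
        # scipy warn about near-identical data; the test itself is well defined
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


def differential_calls(
    expr: ExpressionMatrix,
    reference_sample: str,
    samples: Sequence[str] | None = None,
    cfg: DifferentialConfig | None = None,
) -> pd.DataFrame:
    """Call every gene in every sample against a reference sample.

    Returns one row per (gene, comparison) with columns gene_id,
    comparison, fold, p_value, call.  Comparisons are labelled
    ``"<sample>_vs_<reference>"``.  Genes undetected in the reference are
    not evaluable; control probes are excluded from the universe.
    """
    cfg = cfg or DifferentialConfig()
    table: FoldTable = fold_ratios(expr, reference_sample)
    if samples is None:
        samples = [s for s in expr.sample_ids if s != reference_sample]
    rows = []
    for gene in expr.gene_ids:
        ref_reps = expr.replicates(gene, reference_sample)
        for sample in samples:
            comparison = f"{sample}_vs_{reference_sample}"
            fold = float(table.folds.at[gene, sample])
            if not table.evaluable.at[gene, sample]:
                rows.append((gene, comparison, np.nan, np.nan, NOT_EVALUABLE))
                continue
            p = ttest_gene(expr.replicates(gene, sample), ref_reps)
            rows.append((gene, comparison, fold, p, classify(fold, p, cfg)))
    return pd.DataFrame(
        rows, columns=["gene_id", "comparison", "fold", "p_value", "call"]
    )


@dataclass
class VennPartition:
    """Disjoint, exhaustive partition of a gene universe by call signature.

    ``cells`` maps a per-comparison signature tuple over
    {up, down, neither} to the genes carrying it; not-evaluable and stable
    calls both read as "neither".
    """

    comparisons: list[str]
    cells: dict[tuple[str, ...], frozenset[str]]
    universe: frozenset[str]

    def counts(self, comparison: str) -> dict[str, int]:
        """Up/down/neither totals of one comparison (marginal of the cells)."""
        i = self.comparisons.index(comparison)
        out = {"up": 0, "down": 0, "neither": 0}
        for sig, genes in self.cells.items():
            out[sig[i]] += len(genes)
        return out


def _signature_symbol(call: str) -> str:
    return call if call in (UP, DOWN) else "neither"


def venn_partition(calls: pd.DataFrame) -> VennPartition:
    """Partition genes by their per-comparison up/down/neither signature.

    ``calls`` must contain exactly one row per (gene, comparison) over at
    least two comparisons; missing or duplicated pairs are reported.
    """
    comparisons = list(dict.fromkeys(calls["comparison"]))
    if len(comparisons) < 2:
        raise ValueError("Venn partition needs at least 2 comparisons")
    universe = frozenset(calls["gene_id"])
    dup = calls.duplicated(subset=["gene_id", "comparison"])
    if dup.any():
        offenders = calls.loc[dup, ["gene_id", "comparison"]].values.tolist()
        raise ValueError(f"duplicate calls for {offenders}")
    pivot = calls.pivot(index="gene_id", columns="comparison", values="call")
    if pivot.isna().any().any():
        missing = [
            (g, c)
            for g in pivot.index
            for c in comparisons
            if pd.isna(pivot.at[g, c])
        ]
        raise ValueError(f"missing calls for {missing}")
    cells: dict[tuple[str, ...], set[str]] = {}
    for gene in pivot.index:
        sig = tuple(_signature_symbol(pivot.at[gene, c]) for c in comparisons)
        cells.setdefault(sig, set()).add(gene)
    return VennPartition(
        comparisons=comparisons,
        cells={sig: frozenset(genes) for sig, genes in cells.items()},
        universe=universe,
    )


def stage_category(
    expr: ExpressionMatrix,
    stage_order: Sequence[str],
    cfg: DifferentialConfig | None = None,
) -> pd.Series:
    """Label each gene with its preferred contiguous stage block.

    The "highest block" is the maximal contiguous run of stages containing
    the argmax stage whose values stay within ``[down_threshold × max, max]``.
    A gene whose every stage sits in that band is "Stable <first>-<last>";
    ties at the maximum break toward the earlier stage.  Genes undetected
    in all stages are labelled not_evaluable.
    """
    cfg = cfg or DifferentialConfig()
    missing = [s for s in stage_order if s not in expr.values.columns]
    if missing:
        raise ValueError(f"stages {missing} absent from the expression matrix")
    labels = {}
    for gene in expr.gene_ids:
        values = expr.values.loc[gene, list(stage_order)].to_numpy(dtype=float)
        if not expr.detected.loc[gene, list(stage_order)].any():
            labels[gene] = NOT_EVALUABLE
            continue
        peak = float(values.max())
        in_band = values >= cfg.down_threshold * peak
        if in_band.all():
            labels[gene] = f"Stable {stage_order[0]}-{stage_order[-1]}"
            continue
        argmax = int(np.argmax(values))  # ties break toward the earlier stage
        lo = argmax
        while lo > 0 and in_band[lo - 1]:
            lo -= 1
        hi = argmax
        while hi < len(values) - 1 and in_band[hi + 1]:
            hi += 1
        if lo == hi:
            labels[gene] = f"Highest in {stage_order[lo]}"
        else:
            labels[gene] = f"Highest in {stage_order[lo]}-{stage_order[hi]}"
    return pd.Series(labels, name="stage_category").rename_axis("gene_id")


def organ_enrichment(
    expr: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    cfg: DifferentialConfig | None = None,
) -> pd.DataFrame:
    """Classify genes as enriched in one organ group over another.

    A gene is ``a-enriched`` when its mean expression over ``group_a``
    samples is at least ``organ_enrichment_fold`` times the mean over
    ``group_b`` and the pooled t-test over all replicate ratios of the two
    groups is significant; symmetrically for ``b-enriched``; otherwise
    ``neither``.  Genes detected in no sample of either group are
    ``neither`` and flagged undetected.
    """
    cfg = cfg or DifferentialConfig()
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both organ groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError(f"organ groups overlap: {sorted(set(group_a) & set(group_b))}")
    for s in group_a + group_b:
        if s not in expr.values.columns:
            raise ValueError(f"sample {s!r} absent from the expression matrix")
    rows = []
    for gene in expr.gene_ids:
        mean_a = float(expr.values.loc[gene, group_a].mean())
        mean_b = float(expr.values.loc[gene, group_b].mean())
        detected = bool(expr.detected.loc[gene, group_a + group_b].any())
        reps_a = np.concatenate([expr.replicates(gene, s) for s in group_a])
        reps_b = np.concatenate([expr.replicates(gene, s) for s in group_b])
        p = ttest_gene(reps_a, reps_b)
        label = "neither"
        if detected and p < cfg.alpha:
            if mean_a >= cfg.organ_enrichment_fold * mean_b:
                label = "a-enriched"
            elif mean_b >= cfg.organ_enrichment_fold * mean_a:
                label = "b-enriched"
        rows.append((gene, mean_a, mean_b, p, detected, label))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "mean_a", "mean_b", "p_value", "detected", "label"],
    ).set_index("gene_id")


def expected_false_positives(n_tests: int, cfg: DifferentialConfig | None = None) -> float:
    """Expected count of spurious significant calls at the configured alpha."""
    cfg = cfg or DifferentialConfig()
    return n_tests * cfg.alpha
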