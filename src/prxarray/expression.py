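"""Normalization of membrane spot intensities to control-ratio expression.

Each nylon membrane (one sample × one replicate) carries all probes plus a
constitutively expressed positive control (histone H4 in the original
design) and a non-expressed negative control defining the background floor.
Expression is quantified per membrane as the ratio of a gene's spot
intensity to the control-gene intensity on the same membrane, which cancels
global membrane-to-membrane scale differences; the per-sample value is the
mean of the replicate ratios.  Genes whose mean ratio does not exceed the
negative-control ratio are flagged undetected and floored at that ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RECORD_COLUMNS = ["gene_id", "sample_id", "replicate", "intensity"]


@dataclass
class ArrayExperiment:
    """Raw spot intensities of one macroarray experiment.

    ``records`` holds one row per spot: gene_id, sample_id, replicate
    (1-based membrane index within the sample), intensity (non-negative
    signal units).  ``control_gene`` and ``negative_control`` name the
    normalization and background probes, which appear in ``records`` like
    any other gene.
    """

    records: pd.DataFrame
    control_gene: str
    negative_control: str

    def __post_init__(self) -> None:
        missing = [c for c in RECORD_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"intensity records missing columns {missing}")
        self.records = self.records.reset_index(drop=True)

    @property
    def gene_ids(self) -> list[str]:
        """Assayed genes, excluding the two control probes, sorted."""
        genes = set(self.records["gene_id"]) - {self.control_gene, self.negative_control}
        return sorted(genes)

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.records["sample_id"]))

    def validate(self) -> None:
        """Check the membrane-completeness invariants; raise on violation."""
        rec = self.records
        if (rec["intensity"] < 0).any():
            bad = rec.loc[rec["intensity"] < 0].iloc[0]
            raise ValueError(
                f"negative intensity for gene {bad['gene_id']!r} on membrane "
                f"({bad['sample_id']}, replicate {bad['replicate']})"
            )
        dup = rec.duplicated(subset=["gene_id", "sample_id", "replicate"])
        if dup.any():
            bad = rec.loc[dup].iloc[0]
            raise ValueError(
                f"duplicate spot for gene {bad['gene_id']!r} on membrane "
                f"({bad['sample_id']}, replicate {bad['replicate']})"
            )
        membranes = rec.groupby("sample_id")["replicate"].unique()
        for sample, reps in membranes.items():
            expect = set(range(1, len(reps) + 1))
            if set(reps) != expect:
                raise ValueError(
                    f"sample {sample!r}: replicate indices {sorted(reps)} "
                    f"do not form 1..n"
                )
        ctrl = rec[rec["gene_id"] == self.control_gene]
        for sample in self.sample_ids:
            reps = set(rec.loc[rec["sample_id"] == sample, "replicate"])
            ctrl_reps = ctrl[ctrl["sample_id"] == sample]
            if set(ctrl_reps["replicate"]) != reps:
                raise ValueError(
                    f"control gene {self.control_gene!r} missing from a membrane "
                    f"of sample {sample!r}"
                )
            if (ctrl_reps["intensity"] <= 0).any():
                bad = ctrl_reps.loc[ctrl_reps["intensity"] <= 0].iloc[0]
                raise ValueError(
                    f"control gene intensity is not positive on membrane "
                    f"({sample}, replicate {bad['replicate']})"
                )


@dataclass
class ExpressionMatrix:
    """Control-normalized expression per (gene, sample).

    ``values`` is a genes × samples frame of mean replicate ratios
    (dimensionless, relative to the control gene, which maps to exactly 1);
    ``replicate_ratios`` keeps the per-membrane ratios in long form for
    replicate-level statistics; ``detected`` marks values that exceed the
    negative-control ratio of their sample (undetected values are floored
    at that ratio).
    """

    values: pd.DataFrame
    replicate_ratios: pd.DataFrame  # long: gene_id, sample_id, replicate, ratio
    detected: pd.DataFrame
    control_gene: str
    negative_control: str

    @property
    def gene_ids(self) -> list[str]:
        genes = set(self.values.index) - {self.control_gene, self.negative_control}
        return sorted(genes)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def replicates(self, gene: str, sample: str) -> np.ndarray:
        """Per-membrane normalized ratios for one gene in one sample."""
        rr = self.replicate_ratios
        sel = rr[(rr["gene_id"] == gene) & (rr["sample_id"] == sample)]
        return sel.sort_values("replicate")["ratio"].to_numpy()


@dataclass
class FoldTable:
    """Linear fold ratios of every sample against a reference sample.

    ``folds`` is genes × samples with fold(g, ref) = 1 exactly;
    ``evaluable`` is False where the gene is undetected in the reference
    (the fold is then meaningless and excluded from classification);
    ``log2_display`` is the log-scale rendering used for reporting only —
    all thresholding operates on the linear ratios.
    """

    folds: pd.DataFrame
    evaluable: pd.DataFrame
    reference_sample: str

    @property
    def log2_display(self) -> pd.DataFrame:
        with np.errstate(divide="ignore"):
            return np.log2(self.folds)


def normalize(raw: ArrayExperiment) -> ExpressionMatrix:
    """Normalize spot intensities to the control gene, membrane by membrane.

    Per membrane, ratio(g) = intensity(g) / intensity(control); per
    (gene, sample) the value is the mean of the replicate ratios.  A gene
    whose mean ratio does not exceed the negative-control mean ratio in
    that sample is flagged undetected and its value floored at that
    background ratio (flooring applies to the summary value only; the raw
    replicate ratios are kept for the t-test).
    """
    raw.validate()
    rec = raw.records.copy()
    ctrl = (
        rec[rec["gene_id"] == raw.control_gene]
        .set_index(["sample_id", "replicate"])["intensity"]
        .rename("control_intensity")
    )
    rec = rec.join(ctrl, on=["sample_id", "replicate"])
    rec["ratio"] = rec["intensity"] / rec["control_intensity"]
    # exact self-ratio for the control gene, immune to float division quirks
    rec.loc[rec["gene_id"] == raw.control_gene, "ratio"] = 1.0

    values = (
        rec.pivot_table(index="gene_id", columns="sample_id", values="ratio",
                        aggfunc="mean", sort=True)
        .loc[:, raw.sample_ids]
    )
    values.columns.name = None
    values.index.name = "gene_id"

    floor = values.loc[raw.negative_control]
    detected = values.gt(floor, axis=1)
    detected.loc[raw.control_gene] = True
    values = values.where(detected, other=floor, axis=1)
    values.loc[raw.control_gene] = 1.0

    replicate_ratios = rec[["gene_id", "sample_id", "replicate", "ratio"]].copy()
    return ExpressionMatrix(
        values=values,
        replicate_ratios=replicate_ratios,
        detected=detected,
        control_gene=raw.control_gene,
        negative_control=raw.negative_control,
    )


def fold_ratios(expr: ExpressionMatrix, reference_sample: str) -> FoldTable:
    """Fold change of every sample relative to ``reference_sample``.

    fold(g, s) = value(g, s) / value(g, reference); the reference column is
    exactly 1.  Genes undetected in the reference sample are flagged not
    evaluable rather than producing unbounded ratios.
    """
    if reference_sample not in expr.values.columns:
        raise ValueError(f"reference sample {reference_sample!r} not in matrix")
    ref = expr.values[reference_sample]
    folds = expr.values.div(ref, axis=0)
    folds[reference_sample] = 1.0
    ref_ok = expr.detected[reference_sample] & (ref > 0)
    evaluable = pd.DataFrame(
        np.broadcast_to(ref_ok.to_numpy()[:, None], folds.shape),
        index=folds.index,
        columns=folds.columns,
    )
    return FoldTable(folds=folds, evaluable=evaluable, reference_sample=reference_sample)
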