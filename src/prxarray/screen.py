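"""Candidate nomination across transcription-factor mutant lines.

The screen intersects two filters: a gene must be significantly altered in
the *same direction* in every mutant line relative to wild type (the
concordance requirement), and it must be enriched in the organ group of
interest (flowers/siliques over leaves, via the 4-fold organ filter).  In
the original shatterproof screen this two-way intersection over the
*shp1*, *shp2* and *shp1 shp2* lines nominated three peroxidase genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .differential import DOWN, UP


@dataclass
class ScreenConfig:
    """Lines and filters of the mutant screen.

    ``mutant_lines`` are the comparison ids of each line vs wild type;
    ``enriched_label`` is the organ-enrichment label a candidate must
    carry (the group holding flowers/siliques).
    """

    mutant_lines: Sequence[str] = field(
        default_factory=lambda: ["shp1", "shp2", "shp1_shp2"]
    )
    wild_type: str = "WT"
    enriched_label: str = "a-enriched"

    def __post_init__(self) -> None:
        if not self.mutant_lines:
            raise ValueError("at least one mutant line is required")
        if self.wild_type in self.mutant_lines:
            raise ValueError(
                f"wild type {self.wild_type!r} must be distinct from the mutant lines"
            )


def screen_candidates(
    mutant_calls: pd.DataFrame,
    enrichment: pd.DataFrame,
    cfg: ScreenConfig | None = None,
) -> pd.DataFrame:
    """Nominate genes concordantly altered in all lines and organ-enriched.

    ``mutant_calls`` holds one differential call per (gene, line) with
    columns gene_id, line (or comparison), fold, p_value, call;
    ``enrichment`` is the per-gene organ-enrichment table (indexed by
    gene_id with a ``label`` column).  Returns one row per gene, sorted by
    gene id, with per-line folds/p-values, the concordant direction (if
    any), both filter outcomes, and the final candidate flag
    (candidate ⇔ concordant ∧ enriched).
    """
    cfg = cfg or ScreenConfig()
    calls = mutant_calls.copy()
    if "line" not in calls.columns:
        calls = calls.rename(columns={"comparison": "line"})
    needed = {"gene_id", "line", "fold", "p_value", "call"}
    if not needed <= set(calls.columns):
        raise ValueError(f"mutant calls missing columns {sorted(needed - set(calls.columns))}")

    lines = list(cfg.mutant_lines)
    pivot_call = calls.pivot(index="gene_id", columns="line", values="call")
    missing = [
        (g, ln)
        for g in pivot_call.index
        for ln in lines
        if ln not in pivot_call.columns or pd.isna(pivot_call.at[g, ln])
    ]
    if missing:
        raise ValueError(f"missing per-line calls for {missing}")
    pivot_fold = calls.pivot(index="gene_id", columns="line", values="fold")
    pivot_p = calls.pivot(index="gene_id", columns="line", values="p_value")

    genes = sorted(pivot_call.index)
    no_enrichment = [g for g in genes if g not in enrichment.index]
    if no_enrichment:
        raise ValueError(f"genes without an enrichment label: {no_enrichment}")

    rows = []
    for gene in genes:
        per_line = [pivot_call.at[gene, ln] for ln in lines]
        if all(c == UP for c in per_line):
            direction, concordant = UP, True
        elif all(c == DOWN for c in per_line):
            direction, concordant = DOWN, True
        else:
            direction, concordant = "none", False
        enriched = enrichment.at[gene, "label"] == cfg.enriched_label
        row = {"gene_id": gene}
        for ln in lines:
            row[f"fold_{ln}"] = pivot_fold.at[gene, ln]
            row[f"p_{ln}"] = pivot_p.at[gene, ln]
        row.update(
            direction=direction,
            passes_concordance=concordant,
            passes_enrichment=bool(enriched),
            candidate=bool(concordant and enriched),
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")


def candidate_genes(report: pd.DataFrame) -> list[str]:
    """Gene ids flagged as candidates, in deterministic (sorted) order."""
    return sorted(report.index[report["candidate"]])
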