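"""File formats, pipeline configuration and orchestration.

All tables are tab-separated with headers; floats are rendered with six
significant digits and gene ordering is lexicographic, so reruns with the
same inputs and seed produce byte-identical outputs.  Promoter sets are
standard multi-FASTA; ground truth and the run manifest are JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .assays import AssayRecord, Calibration
from .differential import (
    DifferentialConfig,
    differential_calls,
    organ_enrichment,
    stage_category,
    venn_partition,
)
from .expression import RECORD_COLUMNS, ArrayExperiment, normalize
from .motifs import (
    SEQUENCE_ALPHABET,
    MotifHit,
    frequency,
    hits_to_frame,
    load_motif_table,
    scan,
)
from .screen import ScreenConfig, screen_candidates
from .simulate import GroundTruth

logger = logging.getLogger("prxarray")

FLOAT_FORMAT = "%.6g"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


# ---------------------------------------------------------------------------
# intensity tables


def write_intensity_table(experiment: ArrayExperiment, path: str | Path) -> None:
    """Write spot intensities as TSV (gene_id, sample_id, replicate, intensity)."""
    rec = experiment.records.sort_values(
        ["sample_id", "replicate", "gene_id"], kind="stable"
    )
    rec.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_intensity_table(
    path: str | Path,
    control_gene: str,
    negative_control: str,
) -> ArrayExperiment:
    """Read and validate a spot-intensity TSV.

    Rejects malformed rows (naming the 1-based line number, header being
    line 1), duplicate (gene, sample, replicate) spots, non-numeric
    intensities, and membranes missing the control gene.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in RECORD_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    rows = []
    seen: dict[tuple[str, str, int], int] = {}
    for idx, row in raw.iterrows():
        line_no = idx + 2  # header is line 1
        gene, sample = row["gene_id"], row["sample_id"]
        if not gene or not sample:
            raise ValueError(f"{path}:{line_no}: empty gene or sample id")
        try:
            replicate = int(row["replicate"])
        except ValueError:
            raise ValueError(
                f"{path}:{line_no}: replicate {row['replicate']!r} is not an integer"
            ) from None
        try:
            intensity = float(row["intensity"])
        except ValueError:
            raise ValueError(
                f"{path}:{line_no}: intensity {row['intensity']!r} is not numeric"
            ) from None
        if not intensity == intensity:  # NaN
            raise ValueError(f"{path}:{line_no}: intensity is NaN")
        key = (gene, sample, replicate)
        if key in seen:
            raise ValueError(
                f"{path}:{line_no}: duplicate spot for {key} "
                f"(first at line {seen[key]})"
            )
        seen[key] = line_no
        rows.append((gene, sample, replicate, intensity))
    experiment = ArrayExperiment(
        records=pd.DataFrame(rows, columns=RECORD_COLUMNS),
        control_gene=control_gene,
        negative_control=negative_control,
    )
    experiment.validate()
    return experiment


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a multi-FASTA promoter set into an ordered id → sequence map.

    Sequences are upper-cased and line wrapping is transparent.  Duplicate
    ids, empty records and characters outside {A, C, G, T, N} are rejected
    with the offending record named.
    """
    promoters: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in promoters:
            raise ValueError(f"{path}: duplicate FASTA id {record.id!r}")
        seq = str(record.seq).upper()
        if not seq:
            raise ValueError(f"{path}: empty sequence for record {record.id!r}")
        bad = set(seq) - SEQUENCE_ALPHABET
        if bad:
            raise ValueError(
                f"{path}: record {record.id!r} contains illegal characters {sorted(bad)}"
            )
        promoters[record.id] = seq
    if not promoters:
        raise ValueError(f"{path}: no FASTA records found")
    return promoters


def write_fasta(promoters: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in promoters.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# ground truth and generic tables


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "true_fold": [
            {"gene_id": g, "comparison": c, "fold": f}
            for (g, c), f in sorted(truth.true_fold.items())
        ],
        "true_class": [
            {"gene_id": g, "comparison": c, "class": k}
            for (g, c), k in sorted(truth.true_class.items())
        ],
        "planted_hits": [
            {"promoter_id": h.promoter_id, "motif": h.motif,
             "start": h.start, "strand": h.strand}
            for h in truth.planted_hits
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    truth = GroundTruth()
    for row in payload.get("true_fold", []):
        truth.true_fold[(row["gene_id"], row["comparison"])] = row["fold"]
    for row in payload.get("true_class", []):
        truth.true_class[(row["gene_id"], row["comparison"])] = row["class"]
    truth.planted_hits = [
        MotifHit(r["promoter_id"], r["start"], r["strand"], r["motif"])
        for r in payload.get("planted_hits", [])
    ]
    return truth


def write_table(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """Inputs, thresholds and outputs of a full pipeline run.

    The developmental experiment (``intensity_table``) drives
    normalization, classification, the Venn partition, stage categories
    and the organ filter; an optional mutant experiment
    (``mutant_intensity_table``) drives the candidate screen; an optional
    promoter FASTA drives the motif scan.
    """

    intensity_table: str
    out_dir: str
    control_gene: str
    negative_control: str
    reference_sample: str
    stage_order: Sequence[str] = ()
    organ_group_a: Sequence[str] = ()
    organ_group_b: Sequence[str] = ()
    mutant_intensity_table: str | None = None
    mutant_wild_type: str | None = None
    mutant_lines: Sequence[str] = ()
    promoter_fasta: str | None = None
    motif_file: str | None = None
    differential: DifferentialConfig = field(default_factory=DifferentialConfig)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        diff = DifferentialConfig(**raw.pop("differential", {}))
        return cls(differential=diff, **raw)

    def validate(self) -> None:
        for label, p in [
            ("intensity_table", self.intensity_table),
            ("mutant_intensity_table", self.mutant_intensity_table),
            ("promoter_fasta", self.promoter_fasta),
            ("motif_file", self.motif_file),
        ]:
            if p is not None and not Path(p).exists():
                raise PipelineError(f"config: {label} path {p!r} does not exist")
        if self.mutant_intensity_table is not None:
            if not self.mutant_wild_type or not self.mutant_lines:
                raise PipelineError(
                    "config: mutant screen needs mutant_wild_type and mutant_lines"
                )


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage named."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name}: {exc}") from exc
            logger.info("stage %s: done", name)
            return False

    return _Ctx()


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run normalize → classify → Venn/stage → organ filter → screen → scan.

    Writes every result table plus a machine-readable manifest to
    ``cfg.out_dir`` and returns the paths keyed by artifact name.
    Rerunning with the same config reproduces identical bytes.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def save(name: str, frame: pd.DataFrame, index: bool = False) -> None:
        path = out / f"{name}.tsv"
        write_table(frame, path, index=index)
        artifacts[name] = path

    with _stage("normalize"):
        experiment = read_intensity_table(
            cfg.intensity_table, cfg.control_gene, cfg.negative_control
        )
        expr = normalize(experiment)
        save("expression_matrix", expr.values.sort_index(), index=True)

    with _stage("classify"):
        calls = differential_calls(expr, cfg.reference_sample, cfg=cfg.differential)
        calls = calls.sort_values(["gene_id", "comparison"], kind="stable")
        save("differential_calls", calls)

    with _stage("venn"):
        comparisons = sorted(set(calls["comparison"]))
        if len(comparisons) >= 2:
            venn = venn_partition(calls)
            rows = [
                {
                    "signature": "/".join(sig),
                    "n_genes": len(genes),
                    "genes": ",".join(sorted(genes)),
                }
                for sig, genes in sorted(venn.cells.items())
            ]
            save("venn_partition", pd.DataFrame(rows))

    with _stage("stage_categories"):
        if cfg.stage_order:
            cats = stage_category(expr, list(cfg.stage_order), cfg.differential)
            save("stage_categories", cats.sort_index().to_frame(), index=True)

    enrichment = None
    with _stage("organ_enrichment"):
        if cfg.organ_group_a and cfg.organ_group_b:
            enrichment = organ_enrichment(
                expr, list(cfg.organ_group_a), list(cfg.organ_group_b), cfg.differential
            )
            save("organ_enrichment", enrichment.sort_index(), index=True)

    with _stage("screen"):
        if cfg.mutant_intensity_table is not None:
            if enrichment is None:
                raise PipelineError(
                    "stage screen: the candidate screen needs organ_group_a/b "
                    "for its enrichment filter"
                )
            mut_exp = read_intensity_table(
                cfg.mutant_intensity_table, cfg.control_gene, cfg.negative_control
            )
            mut_expr = normalize(mut_exp)
            mut_calls = differential_calls(
                mut_expr,
                cfg.mutant_wild_type,
                samples=list(cfg.mutant_lines),
                cfg=cfg.differential,
            )
            mut_calls["line"] = mut_calls["comparison"].str.replace(
                f"_vs_{cfg.mutant_wild_type}", "", regex=False
            )
            screen_cfg = ScreenConfig(
                mutant_lines=list(cfg.mutant_lines), wild_type=cfg.mutant_wild_type
            )
            report = screen_candidates(mut_calls, enrichment, screen_cfg)
            save("candidate_report", report.sort_index(), index=True)

    with _stage("scan"):
        if cfg.promoter_fasta is not None:
            promoters = read_fasta(cfg.promoter_fasta)
            motifs = load_motif_table(cfg.motif_file)
            hits = scan(promoters, motifs, strands="both")
            save("motif_hits", hits_to_frame(hits))
            freq = frequency(hits, promoters.keys(), motifs)
            save("motif_frequency", freq.counts)

    with _stage("manifest"):
        manifest = {
            "version": __version__,
            "seed": cfg.seed,
            "inputs": {
                "intensity_table": cfg.intensity_table,
                "mutant_intensity_table": cfg.mutant_intensity_table,
                "promoter_fasta": cfg.promoter_fasta,
                "motif_file": cfg.motif_file,
            },
            "thresholds": asdict(cfg.differential),
            "reference_sample": cfg.reference_sample,
            "outputs": {k: str(v) for k, v in sorted(artifacts.items())},
        }
        path = out / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        artifacts["manifest"] = path

    return artifacts
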