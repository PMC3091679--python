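"""Synthetic macroarray experiments and promoter sets with known ground truth.

The generator emulates the dedicated membrane design it is meant to test:
73 peroxidase probes plus a constitutively expressed positive control
(histone H4 role) and a non-expressed negative control (pseudogene role),
hybridized in triplicate per sample.  Each spot intensity is

    membrane_scale × baseline_signal(gene) × fold(gene, sample) × noise

with a per-membrane global scale factor (uniform over
``membrane_scale_range``) that forces the normalization step to matter,
per-gene baseline signals log-uniform over three orders of magnitude
(mirroring the dynamic range of a real membrane), and multiplicative
mean-1 log-normal spot noise of configurable coefficient of variation.
The planted folds and their implied up/down/stable classes are returned as
ground truth so recovery can be scored exactly.

Promoter sets are uniform-random 1000-bp windows with concrete
realizations of degenerate motifs planted at known positions; in
collision-free mode the background is redrawn until the planted sites are
the only matches, so the truth set equals the full hit set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .differential import DifferentialConfig, DOWN, STABLE, UP
from .expression import ArrayExperiment
from .motifs import (
    IUPAC_CODES,
    MotifHit,
    MotifPattern,
    compile_motif,
    reverse_complement,
    scan,
)

DEFAULT_GENE_IDS = [f"AtPrx{i:02d}" for i in range(1, 74)]
DEFAULT_CONTROL = "HistoneH4"          # histone H4 role (At2g28740 in the real design)
DEFAULT_NEGATIVE = "pseudogene_I"      # background floor probe

#: Reference signal of the control-gene spot, in arbitrary intensity units.
CONTROL_SIGNAL = 1000.0


class SampleSpec(NamedTuple):
    """One hybridized sample: identifier, stage/organ label, genotype."""

    sample_id: str
    stage: str
    genotype: str = "WT"


@dataclass
class SimulationDesign:
    """Layout and noise model of a simulated macroarray experiment.

    ``noise_cv`` is the coefficient of variation of the multiplicative
    spot noise (dimensionless); ``membrane_scale_range`` bounds the
    uniform per-membrane global intensity multiplier;
    ``baseline_range`` bounds the log-uniform per-gene baseline signal as
    a fraction of the control-gene signal; ``background_fraction`` sets
    the negative-control signal as a fraction of the control signal.
    """

    gene_ids: Sequence[str] = field(default_factory=lambda: list(DEFAULT_GENE_IDS))
    control_gene: str = DEFAULT_CONTROL
    negative_control: str = DEFAULT_NEGATIVE
    samples: Sequence[SampleSpec] = field(
        default_factory=lambda: [
            SampleSpec("F1", "flower bud"),
            SampleSpec("F2", "mature flower"),
            SampleSpec("F3", "senescing flower"),
            SampleSpec("S1", "mature silique"),
            SampleSpec("S2", "senescing silique"),
        ]
    )
    n_replicates: int = 3
    noise_cv: float = 0.1
    membrane_scale_range: tuple[float, float] = (0.5, 2.0)
    baseline_range: tuple[float, float] = (0.01, 10.0)
    background_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        self.samples = [SampleSpec(*s) for s in self.samples]
        if self.n_replicates < 2:
            raise ValueError(f"n_replicates must be ≥ 2, got {self.n_replicates}")
        if self.noise_cv < 0:
            raise ValueError(f"noise_cv must be ≥ 0, got {self.noise_cv}")
        if self.control_gene in self.gene_ids or self.negative_control in self.gene_ids:
            raise ValueError("control probes must not appear in gene_ids")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate sample ids in design: {ids}")
        lo, hi = self.membrane_scale_range
        if not 0 < lo <= hi:
            raise ValueError(f"bad membrane_scale_range {self.membrane_scale_range}")
        lo, hi = self.baseline_range
        if not 0 < lo <= hi:
            raise ValueError(f"bad baseline_range {self.baseline_range}")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]


@dataclass
class GroundTruth:
    """Planted truth of a simulation, for recovery scoring.

    ``true_fold`` maps (gene, comparison) to the planted linear fold;
    ``true_class`` maps the same keys to the class implied by the
    classification thresholds; ``planted_hits`` lists motif sites planted
    in a simulated promoter set.
    """

    true_fold: dict[tuple[str, str], float] = field(default_factory=dict)
    true_class: dict[tuple[str, str], str] = field(default_factory=dict)
    planted_hits: list[MotifHit] = field(default_factory=list)


def _truth_class(fold: float, cfg: DifferentialConfig) -> str:
    if fold >= cfg.up_threshold:
        return UP
    if fold <= cfg.down_threshold:
        return DOWN
    return STABLE


def _noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-1 multiplicative log-normal noise with the requested CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


def simulate_experiment(
    design: SimulationDesign,
    effects: Mapping[tuple[str, str], float] | None = None,
    baseline_sample: str | None = None,
    cfg: DifferentialConfig | None = None,
) -> tuple[ArrayExperiment, GroundTruth]:
    """Simulate triplicate membrane hybridizations with planted fold changes.

    ``effects`` maps (gene, sample) to a linear fold relative to
    ``baseline_sample`` (default: the design's first sample); unlisted
    pairs have fold 1.  The control gene always has fold 1 and the
    negative control emits only the background signal.  Identical
    (design, effects, seed) reproduce identical output bit for bit.
    """
    cfg = cfg or DifferentialConfig()
    effects = dict(effects or {})
    sample_ids = design.sample_ids
    if baseline_sample is None:
        baseline_sample = sample_ids[0]
    if baseline_sample not in sample_ids:
        raise ValueError(f"baseline sample {baseline_sample!r} not in design")
    gene_set = set(design.gene_ids)
    for (gene, sample), fold in effects.items():
        if gene not in gene_set:
            raise ValueError(f"effect targets unknown or control gene {gene!r}")
        if sample not in sample_ids:
            raise ValueError(f"effect for gene {gene!r} names unknown sample {sample!r}")
        if sample == baseline_sample:
            raise ValueError(
                f"effect for gene {gene!r} targets the baseline sample {sample!r}"
            )
        if not fold > 0:
            raise ValueError(
                f"non-positive fold {fold} for gene {gene!r} in sample {sample!r}"
            )

    ss = np.random.SeedSequence(design.seed)
    n_membranes = len(sample_ids) * design.n_replicates
    streams = ss.spawn(1 + n_membranes)
    rng0 = np.random.default_rng(streams[0])

    lo, hi = design.baseline_range
    baselines = CONTROL_SIGNAL * np.exp(
        rng0.uniform(np.log(lo), np.log(hi), size=len(design.gene_ids))
    )
    baseline_of = dict(zip(design.gene_ids, baselines))

    all_genes = list(design.gene_ids) + [design.control_gene, design.negative_control]
    signal = np.empty(len(all_genes))
    records = []
    membrane_index = 0
    for sample in sample_ids:
        for gene_i, gene in enumerate(design.gene_ids):
            fold = effects.get((gene, sample), 1.0) if sample != baseline_sample else 1.0
            signal[gene_i] = baseline_of[gene] * fold
        signal[-2] = CONTROL_SIGNAL
        signal[-1] = design.background_fraction * CONTROL_SIGNAL
        for replicate in range(1, design.n_replicates + 1):
            rng = np.random.default_rng(streams[1 + membrane_index])
            membrane_index += 1
            scale = rng.uniform(*design.membrane_scale_range)
            noise = _noise(rng, design.noise_cv, len(all_genes))
            intensities = scale * signal * noise
            records.extend(
                (gene, sample, replicate, intensity)
                for gene, intensity in zip(all_genes, intensities)
            )

    experiment = ArrayExperiment(
        records=pd.DataFrame(records, columns=["gene_id", "sample_id", "replicate", "intensity"]),
        control_gene=design.control_gene,
        negative_control=design.negative_control,
    )
    truth = GroundTruth()
    for gene in design.gene_ids:
        for sample in sample_ids:
            if sample == baseline_sample:
                continue
            comparison = f"{sample}_vs_{baseline_sample}"
            fold = effects.get((gene, sample), 1.0)
            truth.true_fold[(gene, comparison)] = fold
            truth.true_class[(gene, comparison)] = _truth_class(fold, cfg)
    return experiment, truth


class Planting(NamedTuple):
    """A motif site to embed: pattern, 0-based promoter index, 1-based start."""

    pattern: MotifPattern | str
    promoter_index: int
    start: int
    strand: str = "+"


def _as_pattern(pattern: MotifPattern | str) -> MotifPattern:
    if isinstance(pattern, MotifPattern):
        return pattern
    return compile_motif(pattern, pattern)


def simulate_promoters(
    n: int,
    length: int = 1000,
    plantings: Sequence[Planting | tuple] = (),
    seed: int = 0,
    collision_free: bool = True,
    max_attempts: int = 1000,
) -> tuple[dict[str, str], GroundTruth]:
    """Generate uniform-random promoters with motif sites planted at known spots.

    Each planted site is a concrete realization of its degenerate pattern
    (reverse-complemented on the minus strand).  In collision-free mode
    (default) every promoter's background is redrawn until the planted
    motifs match nowhere outside the planted windows on either strand, so
    the ground-truth hit list equals the scanner's full output.  A
    self-reverse-complementary pattern (e.g. the CArG box ``CC[W]6GG``)
    unavoidably matches its own planted window on both strands; such
    mirror twins are included in the ground truth.
    """
    plantings = [Planting(*p) for p in plantings]
    compiled = [_as_pattern(p.pattern) for p in plantings]
    for p, motif in zip(plantings, compiled):
        if not 0 <= p.promoter_index < n:
            raise ValueError(f"planting promoter index {p.promoter_index} outside 0..{n - 1}")
        if p.strand not in "+-":
            raise ValueError(f"planting strand must be '+' or '-', got {p.strand!r}")
        if p.start < 1 or p.start + motif.length - 1 > length:
            raise ValueError(
                f"planting of {motif.name!r} at start {p.start} does not fit in "
                f"a {length}-bp promoter"
            )

    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(max(n, 1))
    bases = np.array(list("ACGT"))
    promoters: dict[str, str] = {}
    truth = GroundTruth()
    width = max(3, len(str(n)))
    # every planted motif is screened in every promoter, so a chance
    # background match anywhere in the set would break truth == hit set
    check_motifs = list({(m.name, m.expanded): m for m in compiled}.values())
    for i in range(n):
        pid = f"promoter_{i + 1:0{width}d}"
        rng = np.random.default_rng(streams[i])
        mine = [(p, m) for p, m in zip(plantings, compiled) if p.promoter_index == i]
        expected = {MotifHit(pid, p.start, p.strand, m.name) for p, m in mine}
        allowed = {(p.start, m.name) for p, m in mine}
        for _attempt in range(max_attempts):
            seq = rng.choice(bases, size=length)
            for p, motif in mine:
                realization = "".join(
                    rng.choice(list(IUPAC_CODES[c])) for c in motif.expanded
                )
                site = realization if p.strand == "+" else reverse_complement(realization)
                seq[p.start - 1 : p.start - 1 + motif.length] = list(site)
            candidate = "".join(seq)
            if not collision_free or not check_motifs:
                found = expected
                break
            found = set(scan({pid: candidate}, check_motifs, strands="both"))
            # accept when the only hits are the planted sites themselves,
            # possibly mirrored onto the other strand by a palindromic pattern
            if expected <= found and all(
                (h.start, h.motif) in allowed for h in found
            ):
                break
        else:
            raise RuntimeError(
                f"{pid}: could not draw a collision-free background in "
                f"{max_attempts} attempts (motifs too permissive for {length} bp)"
            )
        promoters[pid] = candidate
        truth.planted_hits.extend(sorted(found))
    truth.planted_hits.sort()
    return promoters, truth

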