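import pandas as pd
import pytest

from prxarray import (
    ArrayExperiment,
    SampleSpec,
    SimulationDesign,
    normalize,
    simulate_experiment,
)


@pytest.fixture
def flower_design():
    """Standard developmental design: 73 genes, 5 stages, triplicates."""
    return SimulationDesign(seed=11)


@pytest.fixture
def noiseless_design():
    """Zero-noise triplicate design with varying membrane scales.

    The baseline range stays clear of the detection floor so every gene
    is evaluable and planted folds are recoverable.
    """
    return SimulationDesign(
        noise_cv=0.0, baseline_range=(0.1, 10.0), seed=7
    )


@pytest.fixture
def tiny_experiment():
    """Hand-written 2-gene, 2-sample, duplicate-membrane experiment."""
    rows = []
    intensities = {
        # sample, replicate -> (geneA, geneB, control, negctrl)
        ("s1", 1): (2370.0, 500.0, 1000.0, 10.0),
        ("s1", 2): (2370.0, 500.0, 1000.0, 10.0),
        ("s2", 1): (4740.0, 500.0, 1000.0, 10.0),
        ("s2", 2): (4740.0, 500.0, 1000.0, 10.0),
    }
    for (sample, rep), (a, b, c, n) in intensities.items():
        rows += [
            ("geneA", sample, rep, a),
            ("geneB", sample, rep, b),
            ("ctrl", sample, rep, c),
            ("neg", sample, rep, n),
        ]
    return ArrayExperiment(
        records=pd.DataFrame(
            rows, columns=["gene_id", "sample_id", "replicate", "intensity"]
        ),
        control_gene="ctrl",
        negative_control="neg",
    )


@pytest.fixture
def mutant_design():
    """Wild type plus three loss-of-function lines, flower-bud stage."""
    return SimulationDesign(
        samples=[
            SampleSpec("WT", "F1", "WT"),
            SampleSpec("shp1", "F1", "shp1"),
            SampleSpec("shp2", "F1", "shp2"),
            SampleSpec("shp1_shp2", "F1", "shp1-shp2"),
        ],
        noise_cv=0.0,
        baseline_range=(0.1, 10.0),
        seed=23,
    )


@pytest.fixture
def organ_design():
    """Flower-bud versus three leaf stages, zero noise."""
    return SimulationDesign(
        samples=[
            SampleSpec("F1", "flower bud"),
            SampleSpec("yL", "young leaf"),
            SampleSpec("mL", "mature leaf"),
            SampleSpec("sL", "senescing leaf"),
        ],
        noise_cv=0.0,
        baseline_range=(0.1, 10.0),
        seed=29,
    )
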