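import numpy as np
import pandas as pd
import pytest

import pitmeth as pm


@pytest.fixture(scope="session")
def genome():
    return pm.mini_genome()


@pytest.fixture(scope="session")
def manifest(genome):
    return pm.generate_manifest(genome, 5000, seed=11)


@pytest.fixture(scope="session")
def cohort(genome, manifest):
    """Default desk-scale cohort: 30 aggressive/metastatic vs 12 benign,
    100 planted DMPs, one planted gain and one planted whole-chromosome loss."""
    design = pm.CohortDesign(
        seed=11,
        arm_events=(
            pm.ArmEvent("APT", "chr1p", "gain", 0.6),
            pm.ArmEvent("PC", "chr2", "loss", 0.6),
        ),
    )
    beta, intensity, sheet, truth = pm.generate_cohort(design, manifest, genome)
    return {"beta": beta, "intensity": intensity, "sheet": sheet,
            "truth": truth, "design": design}


def make_sheet(samples, groups, slides=None, **overrides):
    """Minimal valid sample sheet for hand-built matrices."""
    n = len(samples)
    base = {
        "sample": list(samples),
        "group": list(groups),
        "first_surgery": [True] * n,
        "lineage": ["PIT1"] * n,
        "functional": ["F"] * n,
        "slide": list(slides) if slides is not None else ["S1"] * n,
        "array": ["R1C1"] * n,
        "sex": ["F"] * n,
        "age": [50.0] * n,
    }
    base.update(overrides)
    return pd.DataFrame(base)


def make_beta(values, probes=None, samples=None, detection=None):
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    frame = pd.DataFrame(values, index=probes, columns=samples)
    det = None
    if detection is not None:
        det = pd.DataFrame(detection, index=probes, columns=samples)
    return pm.BetaMatrix(frame, det)
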