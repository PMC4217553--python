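"""Shared fixtures: synthetic bundles and hand-built small inputs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pepnet import coexpr, io_model, wgcna
from pepnet.synthetic import SyntheticSpec, generate, recovery_benchmark_spec


@pytest.fixture(scope="session")
def benchmark_bundle():
    """Compact planted-module bundle: 4 modules × 10 proteins × 3 peptides,
    20 samples, seed 7."""
    spec = recovery_benchmark_spec(seed=7)
    table, design, ppi, ann, truth = generate(spec)
    return {"spec": spec, "table": table, "design": design, "ppi": ppi,
            "ann": ann, "truth": truth}


@pytest.fixture(scope="session")
def benchmark_ratios(benchmark_bundle):
    return io_model.to_log_ratios(benchmark_bundle["table"],
                                  benchmark_bundle["design"])


@pytest.fixture(scope="session")
def benchmark_tom(benchmark_ratios):
    corr = coexpr.pearson_matrix(benchmark_ratios)
    return wgcna.topological_overlap(wgcna.soft_adjacency(corr, power=6))


@pytest.fixture(scope="session")
def default_bundle():
    """Study-scale bundle (~1,100 peptides, 20 samples)."""
    spec = SyntheticSpec(seed=11)
    table, design, ppi, ann, truth = generate(spec)
    return {"spec": spec, "table": table, "design": design, "ppi": ppi,
            "ann": ann, "truth": truth}


@pytest.fixture()
def tiny_design():
    """Two treated + two control samples, one trait."""
    frame = pd.DataFrame(
        {
            "condition": ["ethanol", "ethanol", "salt", "salt"],
            "time_point": ["24h", "24h", "24h", "24h"],
            "replicate_id": ["r1", "c1", "r1", "c1"],
            "replicate_kind": ["technical", "control", "technical", "control"],
            "control_sample_id": ["e_ctrl", np.nan, "s_ctrl", np.nan],
        },
        index=pd.Index(["e_t", "e_ctrl", "s_t", "s_ctrl"], name="sample_id"),
    )
    traits = pd.DataFrame({"biofuel": [1.0, 1.0, 0.0, 0.0]}, index=frame.index)
    return io_model.StudyDesign(frame=frame, traits=traits, ratio_input=False)


def make_ratio_matrix(values: np.ndarray, proteins: list[str] | None = None,
                      peptides: list[str] | None = None,
                      samples: list[str] | None = None) -> io_model.RatioMatrix:
    values = np.asarray(values, dtype=float)
    n, s = values.shape
    peptides = peptides or [f"pep{i}" for i in range(n)]
    samples = samples or [f"s{j}" for j in range(s)]
    proteins = proteins or [f"prot{i}" for i in range(n)]
    return io_model.RatioMatrix(
        values=pd.DataFrame(values, index=peptides, columns=samples),
        protein_of=pd.Series(proteins, index=peptides, name="protein"),
    )
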