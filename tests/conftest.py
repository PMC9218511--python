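"""Shared fixtures: synthetic study data and end-to-end pipeline artifacts.

The expensive artifacts (full factorial design, counts, estimated networks)
are session-scoped so the pipeline-level and acceptance-level tests share
one computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from toxgnet import classify, feature_net, pipeline, simulate
from toxgnet.io import CATEGORIES, load_label_table

# problem sizes for the desk-scale runs: one timepoint, 300 genes, a
# 60-point penalty path and the reduced kernel grid
SIM_GENES = 300
NLAMBDA = 60
GLASSO_OPTS = dict(nlambda=NLAMBDA, tol=1e-3, max_iter=50)
GRID = "reduced"


@pytest.fixture(scope="session")
def labels() -> pd.DataFrame:
    return load_label_table()


@pytest.fixture(scope="session")
def sim_study(labels):
    """One-timepoint synthetic study at the default (planted-signal) truth."""
    truth = simulate.make_truth(seed=7)
    sheet = simulate.gen_design(timepoints=(24,))
    counts = simulate.gen_counts(sheet, truth, n_genes=SIM_GENES, seed=8)
    return truth, sheet, counts


@pytest.fixture(scope="session")
def sim_lfc(sim_study):
    truth, sheet, counts = sim_study
    return pipeline.counts_to_lfc(counts, sheet, timepoint=24)


def run_categories(edges: pd.DataFrame, labels: pd.DataFrame) -> dict[str, classify.PredictionRun]:
    runs = {}
    for cat in CATEGORIES:
        y = (labels.loc[list(edges.index), cat] == "P").to_numpy().astype(int)
        runs[cat] = classify.loocv_sweep(edges, y, kernels=GRID, category=cat)
    return runs


@pytest.fixture(scope="session")
def end_to_end_runs(labels):
    """Two full gen->preprocess->select->networks->classify replicates."""
    per_seed = []
    for seed in (7, 11):
        truth = simulate.make_truth(seed=seed)
        sheet = simulate.gen_design(timepoints=(24,))
        counts = simulate.gen_counts(sheet, truth, n_genes=SIM_GENES, seed=seed + 1)
        lfc = pipeline.counts_to_lfc(counts, sheet, timepoint=24)
        panel = feature_net.pca_select_genes(lfc)
        _, edges = pipeline.lfc_to_edge_features(lfc, panel=panel, **GLASSO_OPTS)
        per_seed.append(run_categories(edges, labels))
    return per_seed


@pytest.fixture(scope="session")
def null_runs(labels):
    """End-to-end replicate with the effects switched off: the data carry
    no label information (all-negative truth labels), while evaluation
    still uses the real category labels."""
    all_negative = labels.copy()
    all_negative.loc[:, :] = "N"
    truth = simulate.make_truth(seed=5, labels=all_negative, n_deg=0)
    sheet = simulate.gen_design(timepoints=(24,))
    counts = simulate.gen_counts(sheet, truth, n_genes=SIM_GENES, seed=6)
    lfc = pipeline.counts_to_lfc(counts, sheet, timepoint=24)
    panel = feature_net.pca_select_genes(lfc)
    _, edges = pipeline.lfc_to_edge_features(lfc, panel=panel, **GLASSO_OPTS)
    return run_categories(edges, labels)


@pytest.fixture(scope="session")
def null_band():
    """Random-feature baseline band matching the null_runs sweep setup."""
    y = (np.arange(24) < 13).astype(int)
    return classify.random_baseline(y, n_features=190, n_rep=10, seed=3, kernels=GRID)
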