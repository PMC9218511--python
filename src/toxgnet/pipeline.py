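"""End-to-end glue: counts to edge features to category predictions."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import classify, feature_net, preprocess
from .feature_net import FeaturePanel
from .io import Config, logger


def counts_to_lfc(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    timepoint: int | None = None,
    min_count: int = 30,
    min_total: int = 0,
) -> pd.DataFrame:
    """Filter, normalize, batch-correct and reduce to per-condition LFCs."""
    if timepoint is not None:
        sheet = sheet[sheet["timepoint"] == timepoint]
        counts = counts.loc[:, list(sheet["sample_id"])]
    groups = preprocess.condition_groups(sheet)
    filtered = preprocess.filter_low_counts(
        counts, groups, min_count=min_count, min_total=min_total
    )
    logger.info("low-count filter kept %d/%d genes", len(filtered), len(counts))
    x = preprocess.logcpm(filtered)
    batch = pd.Series(sheet["batch"].to_numpy(), index=sheet["sample_id"].to_numpy())
    x = preprocess.remove_batch_effect(x, batch, groups)
    return preprocess.compute_lfc(x, sheet)


def lfc_to_edge_features(
    lfc: pd.DataFrame,
    panel: FeaturePanel | list[str] | None = None,
    n_pcs: int = 5,
    nlambda: int = 1000,
    lambda_min_ratio: float = 0.01,
    gamma: float = 0.0,
    use_correlation: bool = True,
    max_iter: int = 100,
    tol: float = 1e-4,
) -> tuple[FeaturePanel | list[str], pd.DataFrame]:
    """Select the feature panel (unless given) and fit all chemical networks."""
    if panel is None:
        panel = feature_net.pca_select_genes(lfc, n_pcs=n_pcs)
    edges = feature_net.edge_feature_matrix(
        lfc,
        panel,
        nlambda=nlambda,
        lambda_min_ratio=lambda_min_ratio,
        gamma=gamma,
        use_correlation=use_correlation,
        max_iter=max_iter,
        tol=tol,
    )
    return panel, edges


def run_category_predictions(
    edges: pd.DataFrame,
    labels: pd.DataFrame,
    config: Config | None = None,
    categories=None,
    n_baseline: int = 10,
) -> pd.DataFrame:
    """Category sweep plus random baselines and significance flags.

    Returns a per-category report frame mirroring the summary-table layout:
    baseline mean/SD accuracy and AUC, actual accuracy/AUC, best kernel and
    k, and the one-sided p-value against the baseline.
    """
    from .io import CATEGORIES

    config = config or Config()
    categories = list(categories or CATEGORIES)
    k_grid = np.arange(config.k_min, (config.k_max or edges.shape[1]) + 1)
    rows = []
    for ci, cat in enumerate(categories):
        y = (labels.loc[list(edges.index), cat] == "P").to_numpy().astype(int)
        run = classify.loocv_sweep(
            edges, y, kernels=config.kernel_grid, k_grid=k_grid, category=cat
        )
        base = classify.random_baseline(
            y,
            n_features=edges.shape[1],
            n_rep=n_baseline,
            seed=config.seed * 1009 + ci,
            kernels=config.kernel_grid,
            k_grid=k_grid,
        )
        sig = classify.significance_test(run.max_accuracy, base.max_accuracies)
        rows.append(
            {
                "category": cat,
                "random_mean_accuracy": base.mean_accuracy,
                "random_sd_accuracy": base.sd_accuracy,
                "random_mean_auc": base.mean_auc,
                "random_sd_auc": base.sd_auc,
                "accuracy": run.max_accuracy,
                "auc": run.auc_at_max,
                "best_kernel": run.best_kernel,
                "best_k": run.best_k,
                "p_one_sided": sig.p_one_sided,
                "significant_05": sig.significant_05,
                "significant_01": sig.significant_01,
                "kernel_grid": config.kernel_grid,
            }
        )
    return pd.DataFrame(rows).set_index("category")
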