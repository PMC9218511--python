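"""Feature-gene selection and per-chemical partial-correlation networks.

A PCA of the condition x gene LFC panel picks, for each of the top PCs, the
genes with the extreme positive and negative loadings (20 genes for 5 PCs).
For every chemical, the covariance of its dose-level LFC vectors over those
genes feeds an L1-penalized Gaussian graphical model: the graphical lasso is
run along a log-spaced penalty path and the precision matrix minimizing the
extended BIC (gamma = 0, i.e. plain BIC) is selected.  The classifier
features are the p(p-1)/2 partial correlations

    rho_ij = -Theta_ij / sqrt(Theta_ii * Theta_jj)

serialized in the canonical edge order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

try:  # warm-startable solver; falls back to the public one-shot call
    from sklearn.covariance._graph_lasso import _graphical_lasso

    def _glasso_solve(S, alpha, cov_init, max_iter, tol):
        cov, prec = _graphical_lasso(
            S,
            alpha=alpha,
            cov_init=cov_init,
            mode="cd",
            tol=tol,
            enet_tol=tol,
            max_iter=max_iter,
            verbose=False,
            eps=np.finfo(np.float64).eps,
        )[:2]
        return cov, prec

except Exception:  # pragma: no cover - depends on sklearn internals
    from sklearn.covariance import graphical_lasso

    def _glasso_solve(S, alpha, cov_init, max_iter, tol):
        return graphical_lasso(S, alpha=alpha, max_iter=max_iter, tol=tol)

from .io import EdgeIndex, DataError, enumerate_edges, logger

__all__ = [
    "FeaturePanel",
    "CovarianceInput",
    "GgmFit",
    "pca_select_genes",
    "chemical_covariance",
    "glasso_path",
    "select_by_ebic",
    "precision_to_partial",
    "fit_chemical_network",
    "edge_feature_matrix",
]


@dataclass
class FeaturePanel:
    """Ordered feature genes with (PC, sign) provenance per gene."""

    genes: list[str]
    provenance: list[tuple[int, str]]  # (1-based PC index, '+' or '-')


@dataclass
class CovarianceInput:
    chemical: str
    S: np.ndarray
    n_obs: int
    genes: tuple[str, ...]
    standardized: bool = False


@dataclass
class GgmFit:
    chemical: str
    index: EdgeIndex
    lambdas: np.ndarray
    thetas: list[np.ndarray | None]  # None where the solver failed
    n_obs: int
    S: np.ndarray  # matrix the solver saw (correlation by default)
    criterion: np.ndarray | None = None
    chosen: int | None = None
    theta: np.ndarray | None = None
    partial_corr: np.ndarray | None = None
    n_failed: int = 0
    jittered: bool = False


def pca_select_genes(
    panel_lfc: pd.DataFrame,
    n_pcs: int = 5,
    genes_per_sign: int = 2,
    scale: bool = False,
) -> FeaturePanel:
    """Extreme-loading gene selection from a PCA of the LFC panel.

    For PCs 1..n_pcs, the ``genes_per_sign`` genes with the largest positive
    loadings and the same number with the most negative loadings are taken
    (defaults give the 20-gene panel: 2 genes per sign x 2 signs x 5 PCs).
    Eigenvector sign is fixed deterministically so that each PC's
    largest-|loading| gene has a positive loading.  If a gene is extreme on
    more than one PC/sign the next-ranked gene is substituted, keeping the
    panel size at 2 * genes_per_sign * n_pcs.
    """
    x = panel_lfc.to_numpy(dtype=float)
    genes = list(panel_lfc.columns)
    if x.shape[0] <= n_pcs or x.shape[1] < 2 * genes_per_sign * n_pcs:
        raise DataError(
            f"panel too small for {n_pcs} PCs: {x.shape[0]} conditions x "
            f"{x.shape[1]} genes"
        )
    if scale:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = x / sd
    pca = PCA(n_components=n_pcs)
    pca.fit(x)
    loadings = pca.components_  # n_pcs x genes

    chosen: list[str] = []
    provenance: list[tuple[int, str]] = []
    for pc in range(n_pcs):
        load = loadings[pc].copy()
        if load[np.argmax(np.abs(load))] < 0:
            load = -load  # deterministic sign convention
        for sign, order in (("+", np.argsort(-load)), ("-", np.argsort(load))):
            taken = 0
            for idx in order:
                if genes[idx] not in chosen:
                    chosen.append(genes[idx])
                    provenance.append((pc + 1, sign))
                    taken += 1
                    if taken == genes_per_sign:
                        break
            if taken < genes_per_sign:
                raise DataError("fewer distinct genes than requested")
    return FeaturePanel(genes=chosen, provenance=provenance)


def chemical_covariance(
    lfc: pd.DataFrame, chemical: str, panel: FeaturePanel | list[str]
) -> CovarianceInput:
    """Sample covariance (denominator n-1) of one chemical's dose vectors."""
    genes = panel.genes if isinstance(panel, FeaturePanel) else list(panel)
    sub = lfc.loc[chemical, genes] if chemical in lfc.index.get_level_values(0) else None
    if sub is None or len(sub) < 2:
        raise DataError(f"chemical {chemical!r} needs >= 2 dose-level LFC vectors")
    x = sub.to_numpy(dtype=float)
    S = np.cov(x, rowvar=False, ddof=1)
    return CovarianceInput(
        chemical=chemical, S=S, n_obs=x.shape[0], genes=tuple(genes)
    )


def _to_correlation(S: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(S))
    d = np.where(d > 0, d, 1.0)
    R = S / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return R


def glasso_path(
    cov: CovarianceInput,
    nlambda: int = 1000,
    lambda_min_ratio: float = 0.01,
    use_correlation: bool = True,
    max_iter: int = 100,
    tol: float = 1e-4,
) -> GgmFit:
    """Graphical lasso along a log-spaced penalty path.

    The path runs from lambda_max (the largest off-diagonal |correlation|,
    where the estimated graph is empty) down to lambda_max * lambda_min_ratio,
    warm-starting each point from its predecessor.  Non-positive-definite
    inputs are accepted: rank-deficient covariances from few dose levels are
    the normal case.  A solver failure at a given penalty (typical for the
    small-penalty end of the path on singular input) is recorded and
    skipped; if the whole path fails, a small diagonal jitter (1e-8 I) is
    added and the path is retried once.
    """
    S = np.asarray(cov.S, dtype=float)
    if S.shape[0] != S.shape[1] or not np.allclose(S, S.T, atol=1e-10):
        raise DataError("covariance must be square symmetric")
    work = _to_correlation(S) if use_correlation else S.copy()

    off = np.abs(work[~np.eye(work.shape[0], dtype=bool)])
    lam_max = float(off.max()) if off.size else 1.0
    if lam_max <= 0:
        lam_max = 1.0
    lambdas = np.logspace(
        np.log10(lam_max), np.log10(lam_max * lambda_min_ratio), nlambda
    )

    def run(mat: np.ndarray) -> tuple[list[np.ndarray | None], int]:
        thetas: list[np.ndarray | None] = []
        failed = 0
        cov_init = None
        for lam in lambdas:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est_cov, prec = _glasso_solve(
                        mat, float(lam), cov_init, max_iter, tol
                    )
                thetas.append(prec)
                cov_init = est_cov
            except (FloatingPointError, np.linalg.LinAlgError, ValueError):
                thetas.append(None)
                failed += 1
                cov_init = None
        return thetas, failed

    thetas, failed = run(work)
    jittered = False
    if failed == len(lambdas):
        logger.warning(
            "%s: graphical lasso failed on the whole path; retrying with "
            "1e-8 diagonal jitter",
            cov.chemical,
        )
        jittered = True
        thetas, failed = run(work + 1e-8 * np.eye(work.shape[0]))

    return GgmFit(
        chemical=cov.chemical,
        index=enumerate_edges(cov.genes),
        lambdas=lambdas,
        thetas=thetas,
        n_obs=cov.n_obs,
        S=work,
        n_failed=failed,
        jittered=jittered,
    )


def _edge_count(theta: np.ndarray, tol: float = 1e-8) -> int:
    upper = theta[np.triu_indices_from(theta, k=1)]
    return int((np.abs(upper) > tol).sum())


def _gaussian_loglik(theta: np.ndarray, S: np.ndarray, n: int) -> float:
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return -np.inf
    return 0.5 * n * (logdet - float(np.sum(S * theta)))


def select_by_ebic(fit: GgmFit, gamma: float = 0.0) -> GgmFit:
    """Pick the path point minimizing EBIC; gamma = 0 is plain BIC.

    criterion = -2 loglik(Theta; S, n) + E log(n) + 4 gamma E log(p), with
    E the number of nonzero upper-triangle edges.  Ties go to the sparser
    model.
    """
    p = fit.S.shape[0]
    crit = np.full(len(fit.lambdas), np.inf)
    edges = np.zeros(len(fit.lambdas), dtype=int)
    for i, theta in enumerate(fit.thetas):
        if theta is None:
            continue
        e = _edge_count(theta)
        ll = _gaussian_loglik(theta, fit.S, fit.n_obs)
        if not np.isfinite(ll):
            continue
        crit[i] = -2.0 * ll + e * np.log(fit.n_obs) + 4.0 * gamma * e * np.log(p)
        edges[i] = e
    if not np.isfinite(crit).any():
        raise DataError(f"{fit.chemical}: every path point failed")
    best = np.min(crit)
    ties = np.flatnonzero(np.isclose(crit, best, rtol=0.0, atol=1e-9))
    chosen = int(ties[np.argmin(edges[ties])])
    fit.criterion = crit
    fit.chosen = chosen
    fit.theta = fit.thetas[chosen]
    fit.partial_corr = precision_to_partial(fit.theta, fit.index)
    return fit


def precision_to_partial(theta: np.ndarray, index: EdgeIndex) -> np.ndarray:
    """Partial correlations -Theta_ij / sqrt(Theta_ii Theta_jj) in edge order."""
    theta = np.asarray(theta, dtype=float)
    if not np.allclose(theta, theta.T, atol=1e-8):
        raise DataError("precision matrix must be symmetric")
    diag = np.diag(theta)
    if (diag <= 0).any():
        raise DataError("precision matrix needs a positive diagonal")
    denom = np.sqrt(np.outer(diag, diag))
    rho = -theta / denom
    return np.array([rho[i, j] for i, j in index.pairs])


def fit_chemical_network(
    lfc: pd.DataFrame,
    chemical: str,
    panel: FeaturePanel | list[str],
    nlambda: int = 1000,
    lambda_min_ratio: float = 0.01,
    gamma: float = 0.0,
    use_correlation: bool = True,
    max_iter: int = 100,
    tol: float = 1e-4,
) -> GgmFit:
    """Covariance -> penalty path -> BIC selection for one chemical."""
    cov = chemical_covariance(lfc, chemical, panel)
    fit = glasso_path(
        cov,
        nlambda=nlambda,
        lambda_min_ratio=lambda_min_ratio,
        use_correlation=use_correlation,
        max_iter=max_iter,
        tol=tol,
    )
    return select_by_ebic(fit, gamma=gamma)


def edge_feature_matrix(
    lfc: pd.DataFrame,
    panel: FeaturePanel | list[str],
    chemicals: list[str] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Chemicals x edges partial-correlation feature table."""
    if chemicals is None:
        chemicals = list(pd.unique(lfc.index.get_level_values(0)))
    genes = panel.genes if isinstance(panel, FeaturePanel) else list(panel)
    index = enumerate_edges(genes)
    rows = []
    for chem in chemicals:
        fit = fit_chemical_network(lfc, chem, genes, **kwargs)
        rows.append(fit.partial_corr)
    return pd.DataFrame(rows, index=chemicals, columns=index.names)
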