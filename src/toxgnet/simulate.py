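"""Synthetic data with known ground truth for every pipeline input.

The generator emulates the study design: 24 chemicals x 6 doses (including
vehicle) x 2 replicates x 2 timepoints = 576 RNA-seq samples over a
transcription-factor gene panel, plus ATP-assay luminescence tables and
qPCR CT tables for a second cell line.  The planted signal is
category-structured: each toxicity category carries a positive-definite
precision matrix over the 20 feature genes (a private, tightly
co-regulated 3-gene module per category), and a chemical's dose-level LFC
vectors are drawn from the sum of the Gaussians of its positive categories
with a dose-ranked mean shift.  Classifying chemicals
from estimated network edges therefore has a known attainable signal, and
setting the effects to zero yields a calibrated null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CATEGORIES, DOSE_LEVELS, DataError, load_label_table
from .dose_response import AtpAssay, log_logistic

__all__ = [
    "SimTruth",
    "make_truth",
    "chain_precision",
    "gen_design",
    "gen_counts",
    "gen_ct_table",
    "gen_atp",
]

_EXPOSED = DOSE_LEVELS[1:]  # 1/16 ... 1/1


@dataclass
class SimTruth:
    """Ground truth shared by every generator.

    ``panel_lfc`` maps timepoint -> (chemical, dose_level) x panel-gene LFC
    frame: these are the condition effects injected into counts and CT
    tables, so recovery can be checked exactly.
    """

    labels: pd.DataFrame
    panel_genes: list[str]
    precisions: dict[str, np.ndarray]
    mu: float
    noise_sd: float
    panel_lfc: dict[int, pd.DataFrame]
    deg_genes: dict[str, float] = field(default_factory=dict)
    deg_chemicals: list[str] = field(default_factory=list)
    batch_sd: float = 0.3
    dispersion: float = 0.05
    dose_response: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    seed: int = 0


def chain_precision(p: int, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Signed chain (tridiagonal) precision over a random gene permutation.

    Unit diagonal, off-diagonal magnitude ``rho`` with random signs;
    positive definite for rho < 0.5.  Used as a known sparse truth for
    support-recovery checks of the penalized estimator.
    """
    if not 0 < rho < 0.5:
        raise DataError("chain coupling must be in (0, 0.5) for positive definiteness")
    perm = rng.permutation(p)
    theta = np.eye(p)
    for a, b in zip(perm[:-1], perm[1:]):
        w = rho * rng.choice([-1.0, 1.0])
        theta[a, b] = theta[b, a] = w
    eigmin = np.linalg.eigvalsh(theta).min()
    if eigmin <= 0:
        raise DataError("constructed precision is not positive definite")
    return theta


_MODULE_SIZE = 3


def _category_precisions(p: int, rho: float) -> dict[str, np.ndarray]:
    """Deterministic co-regulated module precision per category.

    Category i owns the disjoint 3-gene module {3i, 3i+1, 3i+2}; inside it
    every pair is coupled with partial correlation +rho (off-diagonal
    precision -rho), emulating a tightly co-regulated transcription-factor
    module whose three edges are unique to the category.  Each Theta_c is
    positive definite for rho < 1/(module size - 1) = 0.5, with marginal
    within-module correlations around 0.8 at the default strength, and is
    the identity elsewhere.
    """
    if not 0 < rho < 1.0 / (_MODULE_SIZE - 1):
        raise DataError(
            f"edge strength must be in (0, {1.0 / (_MODULE_SIZE - 1)}) for "
            "positive definiteness"
        )
    if p < _MODULE_SIZE * len(CATEGORIES):
        raise DataError(f"panel of {p} genes too small for the planted design")
    out: dict[str, np.ndarray] = {}
    for i, cat in enumerate(CATEGORIES):
        theta = np.eye(p)
        idx = np.arange(_MODULE_SIZE * i, _MODULE_SIZE * (i + 1))
        for a in idx:
            for b in idx:
                if a != b:
                    theta[a, b] = -rho  # partial correlation = +rho
        out[cat] = theta
    return out


def make_truth(
    labels: pd.DataFrame | None = None,
    panel_size: int = 20,
    mu: float = 1.0,
    edge_strength: float = 0.475,
    noise_sd: float = 0.2,
    n_deg: int = 10,
    deg_lfc: float = 3.0,
    batch_sd: float = 0.3,
    dispersion: float = 0.02,
    timepoints: tuple[int, ...] = (24, 48),
    seed: int = 0,
) -> SimTruth:
    """Draw the ground truth: category networks, labels, and condition LFCs.

    ``mu`` is the dose-ranked mean LFC shift (log2 units at the top dose)
    applied per positive category; ``edge_strength`` the magnitude of the
    planted partial correlations; ``noise_sd`` the per-condition LFC noise
    shared by all chemicals (so completely negative chemicals still have
    estimable covariance).  Setting ``mu=0`` and ``edge_strength`` small
    gives a null generator.
    """
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = load_label_table()
    panel_genes = [f"PG{i:02d}" for i in range(1, panel_size + 1)]
    precisions = _category_precisions(panel_size, edge_strength)

    # A category's effect lives only on its own module genes: the draw is
    # a Gaussian on those genes (covariance = the inverse of the module
    # precision block) plus a dose-ranked mean shift, so multi-label
    # chemicals overlap only at the chemical level and the planted module
    # correlations are not diluted by unrelated labels.
    cat_idx: dict[str, np.ndarray] = {}
    cat_cov: dict[str, np.ndarray] = {}
    for c, theta in precisions.items():
        idx = np.flatnonzero(
            (np.abs(theta - np.eye(panel_size)) > 0).any(axis=1)
        )
        cat_idx[c] = idx
        cat_cov[c] = np.linalg.inv(theta[np.ix_(idx, idx)])

    panel_lfc: dict[int, pd.DataFrame] = {}
    for tp in timepoints:
        rows, keys = [], []
        for chem in labels.index:
            pos = [c for c in CATEGORIES if labels.loc[chem, c] == "P"]
            for rank, dose in enumerate(_EXPOSED, start=1):
                vec = rng.normal(0.0, noise_sd, panel_size)
                for c in pos:
                    idx = cat_idx[c]
                    vec[idx] += rng.multivariate_normal(
                        np.full(len(idx), mu * rank / len(_EXPOSED)), cat_cov[c]
                    )
                rows.append(vec)
                keys.append((chem, dose))
        panel_lfc[tp] = pd.DataFrame(
            rows,
            index=pd.MultiIndex.from_tuples(keys, names=["chemical", "dose_level"]),
            columns=panel_genes,
        )

    deg_chemicals = list(labels.index[:2])
    deg_genes = {f"DG{i:02d}": deg_lfc for i in range(1, n_deg + 1)}
    dose_response = {
        chem: (
            float(rng.uniform(0.8, 2.5)),
            float(rng.uniform(2e4, 8e4)),
            float(10.0 ** rng.uniform(-1, 2)),
        )
        for chem in labels.index
    }
    return SimTruth(
        labels=labels,
        panel_genes=panel_genes,
        precisions=precisions,
        mu=mu,
        noise_sd=noise_sd,
        panel_lfc=panel_lfc,
        deg_genes=deg_genes,
        deg_chemicals=deg_chemicals,
        batch_sd=batch_sd,
        dispersion=dispersion,
        dose_response=dose_response,
        seed=seed,
    )


def gen_design(
    chemicals: list[str] | int = 24,
    n_doses: int = 6,
    reps: int = 2,
    timepoints: tuple[int, ...] = (24, 48),
    labels: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Full factorial sample sheet (default 24 x 6 x 2 x 2 = 576 rows).

    Batch is the replicate run; solvent alternates over chemicals (both
    solvent universes are exercised).
    """
    if isinstance(chemicals, int):
        if labels is None:
            labels = load_label_table()
        chemicals = list(labels.index[:chemicals])
    if n_doses < 1 or reps < 1 or not timepoints:
        raise DataError("design factors must be positive")
    doses = DOSE_LEVELS[:n_doses]
    rows = []
    for ci, chem in enumerate(chemicals):
        solvent = "DMSO" if ci % 2 == 0 else "water"
        for tp in timepoints:
            for rep in range(1, reps + 1):
                for dose in doses:
                    tag = dose.replace("/", "_")
                    rows.append(
                        (
                            f"{chem}|{tp}h|{tag}|r{rep}",
                            chem,
                            dose,
                            tp,
                            rep,
                            f"b{rep}",
                            solvent,
                        )
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "chemical",
            "dose_level",
            "timepoint",
            "replicate",
            "batch",
            "solvent",
        ],
    )


def gen_counts(
    sheet: pd.DataFrame,
    truth: SimTruth,
    n_genes: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Negative-binomial counts with the planted panel and DEG signal.

    Per-gene baseline means are lognormal; panel genes are kept well
    expressed so they survive the low-count filter.  Exposed samples
    receive the truth's condition LFCs on the panel genes, dose-ranked
    shifts on the DEG genes of the designated distinct chemicals, and
    additive per-batch shifts on the log2 scale.
    """
    rng = np.random.default_rng(seed)
    panel = truth.panel_genes
    deg = list(truth.deg_genes)
    n_filler = n_genes - len(panel) - len(deg)
    if n_filler < 0:
        raise DataError(f"n_genes={n_genes} smaller than planted gene sets")
    genes = panel + deg + [f"G{i:04d}" for i in range(1, n_filler + 1)]

    base = rng.lognormal(mean=np.log(120.0), sigma=1.0, size=n_genes)
    base[: len(panel)] = rng.lognormal(np.log(400.0), 0.4, len(panel))
    base[len(panel) : len(panel) + len(deg)] = rng.lognormal(np.log(300.0), 0.4, len(deg))

    batches = sorted(sheet["batch"].unique())
    shift = {b: np.zeros(n_genes) for b in batches}
    for b in batches[1:]:
        shift[b] = rng.normal(0.0, truth.batch_sd, n_genes)

    log2_mean = np.tile(np.log2(base), (len(sheet), 1))  # samples x genes
    gene_pos = {g: i for i, g in enumerate(genes)}
    for si, row in enumerate(sheet.itertuples(index=False)):
        log2_mean[si] += shift[row.batch]
        if row.dose_level == "vehicle":
            continue
        tp_lfc = truth.panel_lfc.get(row.timepoint)
        if tp_lfc is None:
            raise DataError(f"truth lacks timepoint {row.timepoint}")
        if row.chemical not in tp_lfc.index.get_level_values(0):
            raise DataError(f"truth lacks chemical {row.chemical!r}")
        vec = tp_lfc.loc[(row.chemical, row.dose_level)].to_numpy()
        log2_mean[si, : len(panel)] += vec
        if row.chemical in truth.deg_chemicals:
            rank = _EXPOSED.index(row.dose_level) + 1
            for g, lfc in truth.deg_genes.items():
                log2_mean[si, gene_pos[g]] += lfc * rank / len(_EXPOSED)

    mean = 2.0**log2_mean
    if truth.dispersion > 0:
        r = 1.0 / truth.dispersion
        counts = rng.negative_binomial(r, r / (r + mean))
    else:
        counts = rng.poisson(mean)
    return pd.DataFrame(counts.T, index=genes, columns=list(sheet["sample_id"]))


def gen_ct_table(
    lfc_truth: pd.DataFrame,
    noise_sd: float = 0.1,
    sign_convention: int = 1,
    timepoint: int = 24,
    reps: int = 2,
    reference_gene: str = "GAPDH",
    reference_ct: float = 20.0,
    seed: int = 0,
) -> pd.DataFrame:
    """CT table whose ddCT round-trips to ``lfc_truth``.

    Gene CTs are baseline + sign * LFC around the reference; at
    ``noise_sd=0`` the qPCR branch (with the matching ``lfc_sign``)
    recovers the truth exactly after replicate averaging.
    """
    if sign_convention not in (1, -1):
        raise DataError("sign_convention must be +1 or -1")
    rng = np.random.default_rng(seed)
    genes = list(lfc_truth.columns)
    baseline = {g: 25.0 + 0.2 * i for i, g in enumerate(genes)}
    chemicals = list(pd.unique(lfc_truth.index.get_level_values(0)))

    rows = []
    def emit(chem, dose, lfc_row):
        for rep in range(1, reps + 1):
            rows.append(
                (chem, dose, timepoint, rep, reference_gene,
                 reference_ct + rng.normal(0, noise_sd))
            )
            for g in genes:
                ct = (
                    baseline[g]
                    + reference_ct
                    + sign_convention * (0.0 if lfc_row is None else lfc_row[g])
                    + rng.normal(0, noise_sd)
                )
                rows.append((chem, dose, timepoint, rep, g, ct))

    for chem in chemicals:
        emit(chem, "vehicle", None)
        for dose in lfc_truth.loc[chem].index:
            emit(chem, dose, lfc_truth.loc[(chem, dose)])
    return pd.DataFrame(
        rows, columns=["chemical", "dose_level", "timepoint", "replicate", "gene", "ct"]
    )


def gen_atp(
    fitparams: tuple[float, float, float],
    concentrations: np.ndarray | None = None,
    cv: float = 0.05,
    reps: int = 4,
    chemical: str = "chem",
    blank_level: float = 100.0,
    seed: int = 0,
) -> AtpAssay:
    """ATP-assay luminescence from a known log-logistic curve.

    Default concentrations are 10 serial three-fold dilutions bracketing
    the inflection; noise is multiplicative lognormal with coefficient of
    variation ``cv`` over ``reps`` replicates, plus a constant blank.
    """
    b, d, e = fitparams
    rng = np.random.default_rng(seed)
    if concentrations is None:
        concentrations = e * 27.0 / 3.0 ** np.arange(10)
    concentrations = np.asarray(concentrations, dtype=float)
    clean = log_logistic(concentrations, b, d, e)
    if cv > 0:
        sigma = np.sqrt(np.log(1.0 + cv**2))
        noise = rng.lognormal(-0.5 * sigma**2, sigma, (len(concentrations), reps))
    else:
        noise = np.ones((len(concentrations), reps))
    lum = clean[:, None] * noise + blank_level
    blank = np.full(reps, blank_level)
    return AtpAssay(
        chemical=chemical, concentrations=concentrations, luminescence=lum, blank=blank
    )
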