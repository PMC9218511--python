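"""Counts to log-expression, per-condition log-fold-changes and DEG calls.

The expression substrate is a genes x samples count matrix over a
transcription-factor gene panel.  Genes are filtered by a counts-per-million
rule, normalized to log2 CPM, corrected for batch with a per-gene linear
model, and summarized per exposure condition as the log2 fold change (LFC)
of the condition mean against the matched same-solvent vehicle mean.
Differential expression uses moderated t-statistics: per-gene residual
variances from a group-means linear model are shrunk toward an
empirical-Bayes prior (d0, s0^2) estimated by a method of moments on the
log sample variances, and p-values are Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special
from statsmodels.stats.multitest import multipletests

from .io import DOSE_RANK, DataError, logger

__all__ = [
    "condition_groups",
    "filter_low_counts",
    "logcpm",
    "remove_batch_effect",
    "compute_lfc",
    "moderated_t_deg",
    "estimate_variance_prior",
]


def _single_timepoint(sheet: pd.DataFrame, timepoint: int | None) -> pd.DataFrame:
    if timepoint is not None:
        sheet = sheet[sheet["timepoint"] == timepoint]
        if sheet.empty:
            raise DataError(f"no samples at timepoint {timepoint}")
    elif sheet["timepoint"].nunique() > 1:
        raise DataError(
            "sheet mixes timepoints; pass timepoint= to select one "
            f"(found {sorted(sheet['timepoint'].unique())})"
        )
    return sheet


def condition_groups(sheet: pd.DataFrame) -> pd.Series:
    """Condition label per sample: (chemical, dose) for exposures, one pooled
    group per solvent for vehicles (the paper's 120 + 2 = 122 grouping)."""
    labels = np.where(
        sheet["dose_level"] == "vehicle",
        "vehicle:" + sheet["solvent"].astype(str),
        sheet["chemical"].astype(str) + ":" + sheet["dose_level"].astype(str),
    )
    return pd.Series(labels, index=sheet["sample_id"].to_numpy(), name="group")


def filter_low_counts(
    counts: pd.DataFrame,
    groups: pd.Series,
    min_count: int = 30,
    min_total: int = 0,
) -> pd.DataFrame:
    """Drop weakly expressed genes.

    A gene is kept when its CPM exceeds the cutoff implied by ``min_count``
    at the median library size in at least k samples, k being the smallest
    group size, and its total count is at least ``min_total``.
    """
    missing = set(counts.columns) - set(groups.index)
    if missing:
        raise DataError(f"groups missing for samples: {sorted(missing)[:5]}")
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    cutoff_cpm = min_count / np.median(lib) * 1e6
    cpm = counts.to_numpy(dtype=float) / lib * 1e6
    k = int(groups.loc[counts.columns].value_counts().min())
    keep = ((cpm >= cutoff_cpm).sum(axis=1) >= k) & (
        counts.sum(axis=1).to_numpy() >= min_total
    )
    if not keep.any():
        logger.warning("low-count filter removed every gene")
    return counts.loc[keep]


def logcpm(counts: pd.DataFrame) -> pd.DataFrame:
    """log2 counts per million: log2((count + 0.5) / (lib + 1) * 1e6)."""
    lib = counts.sum(axis=0)
    zero = lib.index[lib == 0]
    if len(zero):
        raise DataError(f"zero library size for sample {zero[0]!r}")
    x = np.log2((counts.to_numpy(dtype=float) + 0.5) / (lib.to_numpy() + 1.0) * 1e6)
    return pd.DataFrame(x, index=counts.index, columns=counts.columns)


def _sum_zero_contrasts(factor: np.ndarray) -> np.ndarray:
    """Sum-to-zero indicator columns (levels 2..L) so removing the batch
    term does not shift the overall mean."""
    levels = pd.unique(factor)
    n = len(factor)
    cols = []
    for lev in levels[1:]:
        col = np.where(factor == lev, 1.0, 0.0)
        col[factor == levels[0]] = -1.0
        cols.append(col)
    return np.column_stack(cols) if cols else np.empty((n, 0))


def remove_batch_effect(
    x: pd.DataFrame, batch: pd.Series, design: pd.Series
) -> pd.DataFrame:
    """Subtract per-gene batch coefficients estimated jointly with design.

    Fits, for every gene, ``y ~ design-group means + batch`` (batch coded
    with sum-to-zero contrasts) and removes the batch contribution only, so
    condition effects are preserved.  A single batch is an identity
    transform.
    """
    b = batch.loc[x.columns].to_numpy()
    g = design.loc[x.columns].to_numpy()
    bmat = _sum_zero_contrasts(b)
    if bmat.shape[1] == 0:
        return x.copy()
    dmat = pd.get_dummies(pd.Series(g)).to_numpy(dtype=float)
    full = np.hstack([dmat, bmat])
    if np.linalg.matrix_rank(full) < np.linalg.matrix_rank(dmat) + bmat.shape[1]:
        logger.warning("batch is partially confounded with the design")
    beta = np.linalg.pinv(full) @ x.to_numpy().T  # (p_design + p_batch) x genes
    batch_part = bmat @ beta[dmat.shape[1]:, :]
    return pd.DataFrame(
        x.to_numpy() - batch_part.T, index=x.index, columns=x.columns
    )


def compute_lfc(
    x: pd.DataFrame, sheet: pd.DataFrame, timepoint: int | None = None
) -> pd.DataFrame:
    """Per-condition LFC: exposed mean minus matched-vehicle mean, per gene.

    Vehicles are matched by solvent at the same timepoint and averaged over
    all their replicates.  Returns a (chemical, dose_level) x genes frame,
    dose levels in ascending order.
    """
    sheet = _single_timepoint(sheet, timepoint)
    x = x.loc[:, list(sheet["sample_id"])]
    vehicles = sheet[sheet["dose_level"] == "vehicle"]
    veh_means: dict[str, np.ndarray] = {}
    for solvent, grp in vehicles.groupby("solvent"):
        veh_means[solvent] = x.loc[:, list(grp["sample_id"])].mean(axis=1).to_numpy()

    rows, keys = [], []
    exposed = sheet[sheet["dose_level"] != "vehicle"]
    for chem in pd.unique(exposed["chemical"]):
        sub = exposed[exposed["chemical"] == chem]
        for dose in sorted(pd.unique(sub["dose_level"]), key=DOSE_RANK.get):
            cond = sub[sub["dose_level"] == dose]
            solvent = cond["solvent"].iloc[0]
            if solvent not in veh_means:
                raise DataError(
                    f"no matched vehicle (solvent={solvent}) for "
                    f"condition ({chem}, {dose})"
                )
            mean_exposed = x.loc[:, list(cond["sample_id"])].mean(axis=1).to_numpy()
            rows.append(mean_exposed - veh_means[solvent])
            keys.append((chem, dose))
    return pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(keys, names=["chemical", "dose_level"]),
        columns=x.index,
    )


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments (d0, s0^2) for the scaled inverse-chi-square prior.

    Matches mean and variance of log sample variances against the
    log-F distribution they follow under the hierarchical model.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        raise DataError("need >= 2 positive sample variances to fit the prior")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
    return d0, s0_sq


def moderated_t_deg(
    x: pd.DataFrame,
    sheet: pd.DataFrame,
    fdr_cut: float = 0.01,
    lfc_cut: float = 1.0,
    timepoint: int | None = None,
    d0: float | None = None,
    s0_sq: float | None = None,
) -> pd.DataFrame:
    """Moderated-t differential expression of every condition vs vehicle.

    A group-means linear model over the condition grouping gives per-gene
    pooled residual variances on n - G degrees of freedom; these are shrunk
    as s2_tilde = (d0 s0^2 + d s2) / (d0 + d) with an empirically estimated
    prior (overridable for the no/full-shrinkage limits).  Per condition the
    contrast against the matched solvent vehicle is tested on d0 + d df and
    BH-adjusted across genes.  Returns a tidy frame with a ``deg`` flag at
    (fdr < fdr_cut) & (|lfc| > lfc_cut); the fitted prior is exposed in
    ``.attrs['d0']`` and ``.attrs['s0_sq']``.
    """
    sheet = _single_timepoint(sheet, timepoint)
    x = x.loc[:, list(sheet["sample_id"])]
    groups = condition_groups(sheet)
    glabels = groups.loc[x.columns].to_numpy()
    levels, inverse = np.unique(glabels, return_inverse=True)
    n, n_groups = x.shape[1], len(levels)
    resid_df = n - n_groups
    if resid_df <= 0:
        raise DataError(
            f"zero residual degrees of freedom ({n} samples, {n_groups} groups)"
        )

    y = x.to_numpy()  # genes x samples
    counts = np.bincount(inverse, minlength=n_groups).astype(float)
    sums = np.zeros((y.shape[0], n_groups))
    for j in range(n_groups):
        sums[:, j] = y[:, inverse == j].sum(axis=1)
    means = sums / counts
    resid = y - means[:, inverse]
    s2 = (resid**2).sum(axis=1) / resid_df

    if d0 is None or s0_sq is None:
        d0_est, s0_est = estimate_variance_prior(s2, resid_df)
        d0 = d0_est if d0 is None else d0
        s0_sq = s0_est if s0_sq is None else s0_sq
    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0_sq)
        total_df = np.inf
    else:
        s2_tilde = (d0 * s0_sq + resid_df * s2) / (d0 + resid_df)
        total_df = d0 + resid_df

    from scipy import stats as sps

    group_of = {lev: j for j, lev in enumerate(levels)}
    records = []
    exposed_levels = [lev for lev in levels if not lev.startswith("vehicle:")]
    solvent_of = dict(zip(condition_groups(sheet), sheet["solvent"]))
    for lev in exposed_levels:
        chem, dose = lev.rsplit(":", 1)
        veh = f"vehicle:{solvent_of[lev]}"
        if veh not in group_of:
            raise DataError(f"no vehicle group for condition {lev!r}")
        j, jv = group_of[lev], group_of[veh]
        lfc = means[:, j] - means[:, jv]
        se = np.sqrt(s2_tilde * (1.0 / counts[j] + 1.0 / counts[jv]))
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = lfc / se
        if np.isinf(total_df):
            p = 2.0 * sps.norm.sf(np.abs(tstat))
        else:
            p = 2.0 * sps.t.sf(np.abs(tstat), total_df)
        p = np.where(np.isnan(p), 1.0, p)
        fdr = multipletests(p, method="fdr_bh")[1]
        for g, gene in enumerate(x.index):
            records.append((chem, dose, gene, lfc[g], tstat[g], p[g], fdr[g]))

    out = pd.DataFrame(
        records,
        columns=["chemical", "dose_level", "gene", "lfc", "moderated_t", "p_value", "fdr"],
    )
    out["deg"] = (out["fdr"] < fdr_cut) & (out["lfc"].abs() > lfc_cut)
    out.attrs["d0"] = float(d0)
    out.attrs["s0_sq"] = float(s0_sq)
    out.attrs["residual_df"] = float(resid_df)
    return out
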