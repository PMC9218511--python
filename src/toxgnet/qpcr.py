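"""qPCR cycle-threshold processing into LFC dose profiles.

CT values for the feature-gene panel are normalized against an internal
reference gene (default GAPDH) to give dCT = CT_gene - CT_reference per
sample, replicates are averaged per concentration, and the difference
against the pooled vehicle mean gives ddCT.  The result is stored as LFC in
the same (chemical, dose_level) x genes layout the RNA-seq branch produces,
so network estimation consumes either source.

Sign convention: by default LFC := ddCT.  The conventional expression fold
change is -ddCT (a lower CT means more transcript); ``lfc_sign=-1`` selects
it.  The classifier is insensitive to a global sign flip applied
consistently to both domains.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import DOSE_RANK, DataError

__all__ = ["delta_ct", "ddct_lfc", "ct_table_to_lfc"]

CT_COLUMNS = ("chemical", "dose_level", "timepoint", "replicate", "gene", "ct")
SAMPLE_KEY = ["chemical", "dose_level", "timepoint", "replicate"]


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"CT table missing columns: {missing}")
    if not np.isfinite(table["ct"].to_numpy(dtype=float)).all():
        raise DataError("CT values must be finite")


def delta_ct(table: pd.DataFrame, reference_gene: str = "GAPDH") -> pd.DataFrame:
    """dCT = CT_gene - CT_reference per sample; reference rows are consumed."""
    _check_table(table)
    ref = table[table["gene"] == reference_gene]
    if ref.empty:
        raise DataError(f"reference gene {reference_gene!r} absent from table")
    ref_ct = ref.set_index(SAMPLE_KEY)["ct"]
    if ref_ct.index.duplicated().any():
        ref_ct = ref_ct.groupby(level=SAMPLE_KEY).mean()
    genes = table[table["gene"] != reference_gene].copy()
    key = pd.MultiIndex.from_frame(genes[SAMPLE_KEY])
    missing = key[~key.isin(ref_ct.index)]
    if len(missing):
        raise DataError(f"no reference CT for sample {tuple(missing[0])}")
    genes["dct"] = genes["ct"].to_numpy() - ref_ct.loc[key].to_numpy()
    return genes


def ddct_lfc(
    dct: pd.DataFrame,
    lfc_sign: int = 1,
    timepoint: int | None = None,
) -> pd.DataFrame:
    """ddCT against the pooled vehicle, reported as an LFC panel.

    Per (chemical, concentration, gene) the dCT of the replicates is
    averaged; the vehicle dCT per gene is averaged over all vehicle samples
    (per solvent when a ``solvent`` column is present, pooled otherwise).
    LFC = lfc_sign * (dCT_concentration - dCT_vehicle).
    """
    if lfc_sign not in (1, -1):
        raise DataError("lfc_sign must be +1 or -1")
    if timepoint is not None:
        dct = dct[dct["timepoint"] == timepoint]
    elif dct["timepoint"].nunique() > 1:
        raise DataError("CT table mixes timepoints; pass timepoint=")

    veh = dct[dct["dose_level"] == "vehicle"]
    if veh.empty:
        raise DataError("no vehicle samples in CT table")
    has_solvent = "solvent" in dct.columns
    if has_solvent:
        veh_mean = veh.groupby(["solvent", "gene"])["dct"].mean()
    else:
        veh_mean = veh.groupby("gene")["dct"].mean()

    exposed = dct[dct["dose_level"] != "vehicle"]
    cond_mean = exposed.groupby(["chemical", "dose_level", "gene"], sort=False)[
        "dct"
    ].mean()
    wide = cond_mean.unstack("gene")

    if has_solvent:
        chem_solvent = exposed.drop_duplicates("chemical").set_index("chemical")[
            "solvent"
        ]
        base = pd.DataFrame(
            {
                g: veh_mean.xs(g, level="gene").loc[
                    chem_solvent.loc[wide.index.get_level_values(0)]
                ].to_numpy()
                for g in wide.columns
            },
            index=wide.index,
        )
        lfc = lfc_sign * (wide - base)
    else:
        lfc = lfc_sign * (wide - veh_mean.reindex(wide.columns))

    chem_order = {c: i for i, c in enumerate(pd.unique(exposed["chemical"]))}
    order = sorted(
        lfc.index, key=lambda t: (chem_order[t[0]], DOSE_RANK.get(t[1], 99))
    )
    lfc = lfc.loc[order]
    lfc.index.names = ["chemical", "dose_level"]
    return lfc


def ct_table_to_lfc(
    table: pd.DataFrame,
    reference_gene: str = "GAPDH",
    lfc_sign: int = 1,
    timepoint: int | None = None,
) -> pd.DataFrame:
    """CT table straight to an LFC panel (delta_ct then ddct_lfc)."""
    return ddct_lfc(delta_ct(table, reference_gene), lfc_sign, timepoint)
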