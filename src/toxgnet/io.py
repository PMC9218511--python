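"""Data model and file I/O for the network-toxicology pipeline.

The pipeline works with a small set of tabular artifacts: a sample sheet
describing the exposure design (chemical, dose level, timepoint, replicate,
batch, solvent), a genes x samples count matrix, a chemical x category label
table, a gene panel, and edge-vector feature tables keyed by a canonical
enumeration of unordered gene pairs.  Everything here is plain pandas plus a
couple of frozen dataclasses, so that every downstream module can stay purely
computational.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("toxgnet")

#: The six toxicity categories, in report order: neurotoxin, hepatotoxin,
#: cardiotoxin, glomerular nephrotoxin, tubular nephrotoxin, non-genotoxic
#: carcinogen.
CATEGORIES = ("NT", "HT", "CT", "GT", "TT", "NGC")

#: Dose levels from solvent-only control up to the maximum exposure dose.
DOSE_LEVELS = ("vehicle", "1/16", "1/8", "1/4", "1/2", "1/1")
DOSE_RANK = {level: rank for rank, level in enumerate(DOSE_LEVELS)}
SOLVENTS = ("DMSO", "water")

SHEET_COLUMNS = (
    "sample_id",
    "chemical",
    "dose_level",
    "timepoint",
    "replicate",
    "batch",
    "solvent",
)


class DataError(ValueError):
    """Raised when an input file or table violates the pipeline's contract."""


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Check a sample sheet against the design contract and return it.

    Requires unique sample ids, known dose levels and solvents, and — for
    every exposed (chemical, dose) row — at least one vehicle row with the
    same solvent and timepoint to normalize against.
    """
    missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise DataError(f"sample sheet missing columns: {missing}")
    if sheet["sample_id"].duplicated().any():
        dups = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise DataError(f"duplicate sample_ids: {dups}")
    bad_dose = set(sheet["dose_level"]) - set(DOSE_LEVELS)
    if bad_dose:
        raise DataError(f"unknown dose levels: {sorted(bad_dose)}")
    bad_solv = set(sheet["solvent"]) - set(SOLVENTS)
    if bad_solv:
        raise DataError(f"unknown solvents: {sorted(bad_solv)}")
    exposed = sheet[sheet["dose_level"] != "vehicle"]
    vehicles = sheet[sheet["dose_level"] == "vehicle"]
    have = set(zip(vehicles["solvent"], vehicles["timepoint"]))
    for (solvent, tp), grp in exposed.groupby(["solvent", "timepoint"]):
        if (solvent, tp) not in have:
            chems = sorted(grp["chemical"].unique())
            raise DataError(
                f"no vehicle samples for solvent={solvent}, timepoint={tp} "
                f"(needed by {chems})"
            )
    return sheet


def load_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, dtype={"batch": str})
    return validate_sample_sheet(sheet)


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------

def load_count_matrix(path: str | Path, sheet: pd.DataFrame) -> pd.DataFrame:
    """Load a genes x samples count TSV aligned to the sample sheet order.

    The file header carries sample ids and the first column gene identifiers.
    Counts must be non-negative integers; the file's sample set must equal
    the sheet's sample set.
    """
    counts = pd.read_csv(path, sep="\t", index_col=0)
    file_samples = set(counts.columns)
    sheet_samples = set(sheet["sample_id"])
    if file_samples != sheet_samples:
        only_file = sorted(file_samples - sheet_samples)
        only_sheet = sorted(sheet_samples - file_samples)
        raise DataError(
            f"sample mismatch between counts and sheet: "
            f"only in file {only_file[:5]}, only in sheet {only_sheet[:5]}"
        )
    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()][0]
        raise DataError(f"duplicate gene identifier: {dup!r}")
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = np.argwhere(~np.vectorize(np.isreal)(values))
        raise DataError(f"non-numeric count at {counts.index[bad[0][0]]!r}")
    if (values < 0).any():
        g, s = np.argwhere(values < 0)[0]
        raise DataError(
            f"negative count at gene {counts.index[g]!r}, sample {counts.columns[s]!r}"
        )
    if not np.allclose(values, np.round(values)):
        g, s = np.argwhere(values != np.round(values))[0]
        raise DataError(
            f"non-integer count at gene {counts.index[g]!r}, sample {counts.columns[s]!r}"
        )
    counts = counts.astype(np.int64)
    return counts.loc[:, list(sheet["sample_id"])]


def write_count_matrix(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# labels
# ---------------------------------------------------------------------------

def load_label_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load a chemical x category P/N label table.

    With no path, returns the packaged 24-chemical reference table whose
    positive counts per category are (NT, HT, CT, GT, TT, NGC) =
    (13, 15, 13, 6, 7, 9).
    """
    if path is None:
        ref = importlib.resources.files("toxgnet.data").joinpath("labels.csv")
        with importlib.resources.as_file(ref) as p:
            table = pd.read_csv(p, index_col=0)
    else:
        table = pd.read_csv(path, index_col=0)
    if table.empty:
        raise DataError("label table is empty")
    missing = [c for c in CATEGORIES if c not in table.columns]
    if missing:
        raise DataError(f"label table missing categories: {missing}")
    table = table.loc[:, list(CATEGORIES)]
    if table.index.duplicated().any():
        dup = table.index[table.index.duplicated()][0]
        raise DataError(f"duplicate chemical in label table: {dup!r}")
    bad = set(np.unique(table.to_numpy())) - {"P", "N"}
    if bad:
        raise DataError(f"label values must be P or N, found {sorted(bad)}")
    return table


def positive_mask(labels: pd.DataFrame, category: str) -> pd.Series:
    """Boolean positives for one category, indexed by chemical."""
    if category not in CATEGORIES:
        raise DataError(f"unknown category {category!r}")
    return labels[category] == "P"


# ---------------------------------------------------------------------------
# gene panel and edge index
# ---------------------------------------------------------------------------

def load_gene_panel(path: str | Path) -> list[str]:
    """Read a gene panel file: one identifier per line, blanks ignored."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    genes = [ln for ln in lines if ln]
    if not genes:
        raise DataError(f"empty gene panel: {path}")
    return genes


def write_gene_panel(genes: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


@dataclass(frozen=True)
class EdgeIndex:
    """Canonical enumeration of the unordered gene pairs of a panel.

    Pairs are ordered lexicographically by (i, j) panel position with i < j,
    giving p(p-1)/2 edges; the order is stable across the whole pipeline so
    edge vectors from different chemicals and cell lines are comparable
    column by column.
    """

    genes: tuple[str, ...]
    pairs: tuple[tuple[int, int], ...] = field(init=False)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g in seen:
                raise DataError(f"duplicate gene in panel: {g!r}")
            seen.add(g)
        if len(self.genes) < 2:
            raise DataError("panel needs at least two genes")
        p = len(self.genes)
        pairs = tuple((i, j) for i in range(p) for j in range(i + 1, p))
        object.__setattr__(self, "pairs", pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def names(self) -> list[str]:
        """Edge column names in canonical order, 'geneA|geneB'."""
        return [f"{self.genes[i]}|{self.genes[j]}" for i, j in self.pairs]

    def position(self, gene_a: str, gene_b: str) -> int:
        """Index of the unordered pair (gene_a, gene_b); order-insensitive."""
        ia = self.genes.index(gene_a)
        ib = self.genes.index(gene_b)
        if ia == ib:
            raise DataError(f"self-pair {gene_a!r}")
        i, j = min(ia, ib), max(ia, ib)
        return self.pairs.index((i, j))


def enumerate_edges(gene_panel: Sequence[str]) -> EdgeIndex:
    """Build the canonical edge index for a gene panel."""
    return EdgeIndex(genes=tuple(gene_panel))


# ---------------------------------------------------------------------------
# edge vectors and network export
# ---------------------------------------------------------------------------

def write_edge_vectors(edge_df: pd.DataFrame, path: str | Path) -> None:
    """Write a chemicals x edges feature table (columns 'geneA|geneB')."""
    edge_df.to_csv(path, sep="\t", index_label="chemical")


def read_edge_vectors(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def network_to_edge_list(
    partial_corr: np.ndarray, index: EdgeIndex, keep_zero: bool = False
) -> pd.DataFrame:
    """Tidy (gene_i, gene_j, partial_correlation) rows in canonical order."""
    rows = []
    for (i, j), rho in zip(index.pairs, partial_corr):
        if keep_zero or rho != 0.0:
            rows.append((index.genes[i], index.genes[j], float(rho)))
    return pd.DataFrame(rows, columns=["gene_i", "gene_j", "partial_correlation"])


def network_to_graphml(
    partial_corr: np.ndarray, index: EdgeIndex, path: str | Path
) -> None:
    """Export a network as GraphML; edge sign is kept as an attribute so
    positive and negative conditional dependencies stay distinguishable."""
    graph = nx.Graph()
    graph.add_nodes_from(index.genes)
    for (i, j), rho in zip(index.pairs, partial_corr):
        if rho != 0.0:
            graph.add_edge(
                index.genes[i],
                index.genes[j],
                partial_correlation=float(rho),
                sign="positive" if rho > 0 else "negative",
            )
    nx.write_graphml(graph, path)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class Config:
    """Serializable run configuration echoed into every report."""

    seed: int = 0
    kernel_grid: str = "default"
    k_min: int = 1
    k_max: int | None = None  # None -> number of features
    transfer_mode: str = "stacked"
    nlambda: int = 1000
    lambda_min_ratio: float = 0.01
    ebic_gamma: float = 0.0
    use_correlation: bool = True
    n_pcs: int = 5
    fdr_cut: float = 0.01
    lfc_cut: float = 1.0
    min_count: int = 30
    min_total: int = 0
    p_max: float = 50.0
    lfc_sign: int = 1

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    @classmethod
    def from_file(cls, path: str | Path) -> "Config":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls().__dict__)
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def setup_logging(level: str = "INFO") -> None:
    """Route pipeline logs to standard error."""
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
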