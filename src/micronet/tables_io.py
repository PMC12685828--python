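"""Reading, validating and writing the four tabular inputs and networks.

All tables are TSV, UTF-8, QIIME-style orientation: taxa as rows, samples
as columns, first header cell ``#ASV_ID``.  Counts are nonnegative
integers; relative abundances are always derived downstream, never
stored.  Networks are written as GraphML or edge-list CSV and round-trip
exactly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import TableParseError, ValidationError

TREATMENTS = ("W", "S", "SW")
LOCATIONS = ("bulk", "rhizosphere")
#: Six-level group labels in the fixed display order used everywhere
#: (bulk soil first, then rhizosphere, within each W/SW/S).
GROUP_ORDER = ("W", "SW", "S", "RW", "RSW", "RS")
#: Taxonomic ranks consumed by rank aggregation, coarsest first.
RANKS = ("phylum", "class", "order", "family", "genus")
UNCLASSIFIED = "unclassified"

FEATURE_HEADER = "#ASV_ID"


def group_label(treatment: str, location: str) -> str:
    """Map a (treatment, location) pair to its six-level group label.

    Bulk-soil samples carry the bare treatment name; rhizosphere samples
    are prefixed with ``R`` (``RW``, ``RSW``, ``RS``).
    """
    if treatment not in TREATMENTS:
        raise ValidationError(
            f"unknown treatment {treatment!r}; allowed: {set(TREATMENTS)}"
        )
    if location not in LOCATIONS:
        raise ValidationError(
            f"unknown location {location!r}; allowed: {set(LOCATIONS)}"
        )
    return treatment if location == "bulk" else "R" + treatment


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what} identifier {x!r}")
        seen.add(x)


@dataclass
class FeatureTable:
    """Nonnegative integer count matrix, taxa x samples."""

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # int array, shape (n_taxa, n_samples)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.round(self.counts)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        _check_unique(self.taxon_ids, "taxon")
        _check_unique(self.sample_ids, "sample")
        # >= 2 taxa is enforced at read time; aggregated tables (e.g. a
        # rank with every taxon unclassified) may collapse to one row
        if len(self.taxon_ids) < 1 or len(self.sample_ids) < 2:
            raise ValidationError("need at least 1 taxon and 2 samples")
        if np.any(self.counts < 0):
            t, s = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at taxon {self.taxon_ids[t]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        totals = self.counts.sum(axis=0)
        if np.any(totals == 0):
            bad = self.sample_ids[int(np.argmin(totals))]
            raise ValidationError(f"sample {bad!r} has zero total count")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.taxon_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureTable":
        return cls(
            taxon_ids=[str(i) for i in df.index],
            sample_ids=[str(c) for c in df.columns],
            counts=df.to_numpy(),
        )

    def relative_abundance(self) -> np.ndarray:
        """Per-sample proportions (columns sum to 1)."""
        return self.counts / self.counts.sum(axis=0, keepdims=True)

    def subset_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return FeatureTable(
            taxon_ids=list(self.taxon_ids),
            sample_ids=list(sample_ids),
            counts=self.counts[:, idx],
        )


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a taxa x samples TSV feature table.

    Header row holds sample identifiers (first cell is the taxon-id
    column name); every other cell must parse as a nonnegative integer.
    Parse errors carry row/column coordinates.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise TableParseError(f"{path}: header has no sample columns")
        sample_ids = header[1:]
        taxon_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise TableParseError(
                    f"{path}: row {lineno} has {len(parts)} fields, "
                    f"expected {len(header)}"
                )
            taxon_ids.append(parts[0])
            row: list[int] = []
            for j, cell in enumerate(parts[1:], start=2):
                try:
                    value = int(cell)
                except ValueError as exc:
                    raise TableParseError(
                        f"{path}: non-integer count {cell!r} at row "
                        f"{lineno}, column {j} (sample "
                        f"{sample_ids[j - 2]!r})"
                    ) from exc
                if value < 0:
                    raise TableParseError(
                        f"{path}: negative count at row {lineno}, column {j}"
                    )
                row.append(value)
            rows.append(row)
    if len(taxon_ids) < 2:
        raise ValidationError(f"{path}: need at least 2 taxa")
    return FeatureTable(taxon_ids, sample_ids, np.array(rows, dtype=np.int64))


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(FEATURE_HEADER + "\t" + "\t".join(table.sample_ids) + "\n")
        for taxon, row in zip(table.taxon_ids, table.counts):
            fh.write(taxon + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_metadata(
    path: str | Path, feature_table: FeatureTable | None = None
) -> pd.DataFrame:
    """Read sample metadata (sample_id, treatment, location, block).

    Returns a DataFrame indexed by sample_id with a derived six-level
    ``group`` column.  If ``feature_table`` is given, every counted
    sample must be present.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "treatment", "location", "block"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"metadata missing columns: {sorted(missing)}")
    _check_unique(list(df["sample_id"]), "sample")
    return validate_metadata(df.set_index("sample_id"), feature_table)


def validate_metadata(
    meta: pd.DataFrame, feature_table: FeatureTable | None = None
) -> pd.DataFrame:
    """Validate an in-memory metadata frame and derive group labels."""
    meta = meta.copy()
    for sid, row in meta.iterrows():
        if row["treatment"] not in TREATMENTS:
            raise ValidationError(
                f"sample {sid!r}: unknown treatment {row['treatment']!r}; "
                f"allowed: {set(TREATMENTS)}"
            )
        if row["location"] not in LOCATIONS:
            raise ValidationError(
                f"sample {sid!r}: unknown location {row['location']!r}; "
                f"allowed: {set(LOCATIONS)}"
            )
    meta["block"] = meta["block"].astype(int)
    if (meta["block"] < 1).any():
        raise ValidationError("block numbers must be >= 1")
    meta["group"] = [
        group_label(t, l) for t, l in zip(meta["treatment"], meta["location"])
    ]
    if feature_table is not None:
        absent = [s for s in feature_table.sample_ids if s not in meta.index]
        if absent:
            raise ValidationError(
                f"samples in feature table but not metadata: {absent}"
            )
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    out = meta.reset_index().rename(columns={"index": "sample_id"})
    cols = ["sample_id", "treatment", "location", "block"]
    out[cols].to_csv(path, sep="\t", index=False)


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Read a taxonomy TSV (taxon_id + rank columns phylum..genus).

    Missing or empty ranks are stored as the explicit ``unclassified``
    sentinel.  Extra rank columns are ignored.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "taxon_id" not in df.columns:
        raise ValidationError("taxonomy table must have a 'taxon_id' column")
    _check_unique(list(df["taxon_id"]), "taxon")
    df = df.set_index("taxon_id")
    for rank in RANKS:
        if rank not in df.columns:
            df[rank] = UNCLASSIFIED
    df = df[list(RANKS)]
    return df.fillna(UNCLASSIFIED).replace("", UNCLASSIFIED)


def write_taxonomy(tax: pd.DataFrame, path: str | Path) -> None:
    tax.reset_index(names="taxon_id").to_csv(path, sep="\t", index=False)


SOIL_VARIABLES = (
    "TP", "TN", "AP", "pH", "SOC", "Cs", "WSOC", "EOC", "SN",
    "urease", "sucrase", "Pm", "phosphatase", "catalase",
)


def read_soil_table(
    path: str | Path, metadata: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Read the per-sample soil property table (sample_id + numeric columns)."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValidationError("soil table must have a 'sample_id' column")
    _check_unique([str(s) for s in df["sample_id"]], "sample")
    df = df.set_index("sample_id")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise TableParseError(f"soil column {col!r} is not numeric")
    if metadata is not None:
        absent = [s for s in metadata.index if s not in df.index]
        if absent:
            raise ValidationError(f"samples missing from soil table: {absent}")
    return df


def write_soil_table(soil: pd.DataFrame, path: str | Path) -> None:
    soil.reset_index(names="sample_id").to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# network IO


def write_network(network, path: str | Path, format: str = "graphml") -> None:
    """Write a co-occurrence network as GraphML or edge-list CSV.

    GraphML carries node attributes (taxon_id, phylum, degree) and edge
    attributes (r, q, sign); the edge list has columns
    source,target,r,q,sign.  Re-reading reproduces the graph exactly.
    """
    graph = network if isinstance(network, nx.Graph) else network.graph
    path = Path(path)
    if format == "graphml":
        g = nx.Graph()
        for node, data in graph.nodes(data=True):
            g.add_node(
                node,
                taxon_id=str(node),
                phylum=str(data.get("phylum", UNCLASSIFIED)),
                degree=int(graph.degree(node)),
            )
        for u, v, data in graph.edges(data=True):
            g.add_edge(
                u, v,
                r=float(data["r"]),
                q=float(data["q"]),
                sign=str(data["sign"]),
            )
        nx.write_graphml(g, path)
    elif format == "edgelist":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["source", "target", "r", "q", "sign"])
            for u, v, data in graph.edges(data=True):
                writer.writerow(
                    [u, v, repr(float(data["r"])), repr(float(data["q"])),
                     data["sign"]]
                )
            # isolated nodes cannot be represented in an edge list; the
            # network type drops them anyway, but guard for raw graphs
    else:
        raise ValidationError(f"unknown network format {format!r}")


def read_network(path: str | Path, format: str = "graphml") -> nx.Graph:
    """Read a network written by :func:`write_network`."""
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        out = nx.Graph()
        for node, data in g.nodes(data=True):
            out.add_node(
                node,
                phylum=data.get("phylum", UNCLASSIFIED),
            )
        for u, v, data in g.edges(data=True):
            out.add_edge(
                u, v, r=float(data["r"]), q=float(data["q"]),
                sign=str(data["sign"]),
            )
        return out
    if format == "edgelist":
        out = nx.Graph()
        with path.open(encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                out.add_edge(
                    row["source"], row["target"],
                    r=float(row["r"]), q=float(row["q"]), sign=row["sign"],
                )
        return out
    raise ValidationError(f"unknown network format {format!r}")
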