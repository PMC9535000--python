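"""Readers, writers and validated containers for every external format.

All tabular formats are tab-separated text with ``#`` comment lines
(QIIME-style: first column is the feature id, header row holds sample
ids).  Trees are Newick (parsed with scikit-bio), graphs are GraphML or
an edge-list TSV with a ``.nodes.tsv`` sidecar, and the minimal dense
BIOM-JSON variant is supported for abundance tables.  Numbers are
serialized with 12 significant digits so write/read round-trips are
value-stable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
import skbio

from . import biochem
from .errors import FormatError, ValidationError

def _fmt_float(v: float) -> str:
    """Shortest decimal representation that round-trips the float64
    exactly (Python's repr), so write/read is bitwise-stable."""
    return repr(float(v))

REALMS = ("water", "sediment")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class AbundanceTable:
    """Taxa-by-samples abundance matrix with optional realm annotation.

    ``values`` holds counts or relative abundances (``is_relative``
    distinguishes them); rows follow ``taxon_ids`` and columns
    ``sample_ids``.
    """

    taxon_ids: list
    sample_ids: list
    values: np.ndarray
    is_relative: bool = False
    realm: Optional[dict] = None  # sample id -> "water" | "sediment"

    def __post_init__(self):
        self.taxon_ids = list(map(str, self.taxon_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise FormatError("duplicate taxon ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        if len(self.taxon_ids) < 2 or len(self.sample_ids) < 2:
            raise ValidationError("need at least 2 taxa and 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite abundance values")
        neg = np.argwhere(self.values < 0)
        if neg.size:
            i, j = neg[0]
            raise ValidationError(
                f"negative abundance at taxon {self.taxon_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if self.is_relative:
            sums = self.values.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                bad = self.sample_ids[int(np.argmax(np.abs(sums - 1)))]
                raise ValidationError(
                    f"is_relative set but sample {bad!r} does not sum to 1"
                )

    @property
    def df(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxon_ids,
                            columns=self.sample_ids)

    def select_samples(self, sample_ids) -> "AbundanceTable":
        sample_ids = list(sample_ids)
        idx = [self.sample_ids.index(s) for s in sample_ids]
        realm = ({s: self.realm[s] for s in sample_ids if s in self.realm}
                 if self.realm else None)
        return AbundanceTable(self.taxon_ids, sample_ids,
                              self.values[:, idx], self.is_relative, realm)

    def select_taxa(self, taxon_ids) -> "AbundanceTable":
        taxon_ids = list(taxon_ids)
        idx = [self.taxon_ids.index(t) for t in taxon_ids]
        return AbundanceTable(taxon_ids, self.sample_ids,
                              self.values[idx, :], False, self.realm)


def to_relative(t: AbundanceTable) -> AbundanceTable:
    """Normalize each sample column to sum to one; zeros stay zero.

    Idempotent; an all-zero sample is an error naming the sample.
    """
    sums = t.values.sum(axis=0)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise ValidationError(f"sample {t.sample_ids[int(zero[0])]!r} is all zero")
    return AbundanceTable(t.taxon_ids, t.sample_ids, t.values / sums,
                          is_relative=True, realm=t.realm)


@dataclass
class SampleMetadata:
    """Per-sample geography and realm annotation."""

    df: pd.DataFrame  # indexed by sample_id

    REQUIRED = ("realm", "longitude", "latitude")

    def __post_init__(self):
        df = self.df
        if df.index.duplicated().any():
            raise FormatError("duplicate sample ids in metadata")
        for col in self.REQUIRED:
            if col not in df.columns:
                raise FormatError(f"metadata missing required column {col!r}")
        if not df["realm"].isin(REALMS).all():
            bad = df.loc[~df["realm"].isin(REALMS)].index[0]
            raise ValidationError(f"sample {bad!r} has invalid realm")
        for col in ("longitude", "latitude"):
            if not np.isfinite(df[col].astype(float)).all():
                raise ValidationError(f"non-finite {col}")
        if "depth_m" in df.columns:
            d = df["depth_m"].astype(float)
            if (d.dropna() <= 0).any():
                raise ValidationError("depth_m must be > 0 where present")

    @property
    def sample_ids(self):
        return list(self.df.index)

    def realm_samples(self, realm: str):
        return list(self.df.index[self.df["realm"] == realm])


BIOCHEM_COLUMNS = ("PRT", "CHO", "LIP", "CHLA", "PHEO")


@dataclass
class BiochemTable:
    """Sediment biochemistry: measured concentrations plus derived
    total phytopigments (PIG) and biopolymeric carbon (BPC).

    Derived columns are always recomputed from the measured ones, so the
    identities PIG = CHLA + PHEO and BPC = 0.49 PRT + 0.40 CHO + 0.75 LIP
    hold exactly.
    """

    df: pd.DataFrame  # indexed by sample_id

    def __post_init__(self):
        df = self.df
        if df.index.duplicated().any():
            raise FormatError("duplicate sample ids in biochem table")
        for col in BIOCHEM_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"biochem table missing column {col!r}")
            if (df[col].astype(float) < 0).any():
                bad = df.index[df[col].astype(float) < 0][0]
                raise ValidationError(f"negative {col} for sample {bad!r}")
        df = df.copy()
        df["PIG"] = biochem.total_phytopigments(df["CHLA"].values,
                                                df["PHEO"].values)
        df["BPC"] = biochem.biopolymeric_carbon(df["PRT"].values,
                                               df["CHO"].values,
                                               df["LIP"].values)
        self.df = df


# ---------------------------------------------------------------------------
# abundance tables
# ---------------------------------------------------------------------------

def read_abundance_table(path, format: str = "tsv",
                         is_relative: bool = False) -> AbundanceTable:
    """Read a taxa-by-samples table from TSV or minimal dense BIOM-JSON."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "tsv":
        # QIIME-style: the header row may itself start with '#'
        # ("#taxon_id\t<sample ids>"); other '#' lines are comments
        import io as _io
        lines = Path(path).read_text().splitlines()
        kept, header_seen = [], False
        for line in lines:
            if not line.strip():
                continue
            if line.startswith("#"):
                if not header_seen and "\t" in line:
                    kept.append(line.lstrip("#"))
                    header_seen = True
                continue
            header_seen = True
            kept.append(line)
        try:
            df = pd.read_csv(_io.StringIO("\n".join(kept)), sep="\t",
                             index_col=0, header=0,
                             float_precision="round_trip")
        except pd.errors.ParserError as e:  # ragged rows etc.
            raise FormatError(f"{path}: {e}") from e
        if df.index.duplicated().any() or df.columns.duplicated().any():
            raise FormatError(f"{path}: duplicate taxon or sample ids")
        try:
            values = df.astype(float).values
        except ValueError as e:
            raise FormatError(f"{path}: non-numeric body: {e}") from e
        return AbundanceTable(list(df.index), list(df.columns), values,
                              is_relative=is_relative)
    if format == "biom-json":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("matrix_type") != "dense":
            raise FormatError("only the minimal dense BIOM variant is supported")
        taxa = [r["id"] for r in doc["rows"]]
        samples = [c["id"] for c in doc["columns"]]
        values = np.asarray(doc["data"], dtype=float)
        return AbundanceTable(taxa, samples, values, is_relative=is_relative)
    raise FormatError(f"unknown abundance table format {format!r}")


def write_abundance_table(t: AbundanceTable, path, format: str = "tsv"):
    path = Path(path)
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("#taxon_id\t" + "\t".join(t.sample_ids) + "\n")
            for i, tax in enumerate(t.taxon_ids):
                row = "\t".join(_fmt_float(v) for v in t.values[i])
                fh.write(f"{tax}\t{row}\n")
    elif format == "biom-json":
        doc = {
            "format": "Biological Observation Matrix (minimal dense)",
            "matrix_type": "dense",
            "shape": [len(t.taxon_ids), len(t.sample_ids)],
            "rows": [{"id": x, "metadata": None} for x in t.taxon_ids],
            "columns": [{"id": x, "metadata": None} for x in t.sample_ids],
            "data": [[float(v) for v in row] for row in t.values],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
    else:
        raise FormatError(f"unknown abundance table format {format!r}")


# ---------------------------------------------------------------------------
# metadata / biochemistry
# ---------------------------------------------------------------------------

def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, header=0,
                     float_precision="round_trip")
    df.index = df.index.astype(str)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path):
    meta.df.to_csv(path, sep="\t", index_label="sample_id")


def read_biochem(path) -> BiochemTable:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, header=0,
                     float_precision="round_trip")
    df.index = df.index.astype(str)
    return BiochemTable(df)


def write_biochem(tab: BiochemTable, path):
    tab.df.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def read_newick(path, missing_lengths: str = "error") -> skbio.TreeNode:
    """Parse a rooted Newick tree.

    ``missing_lengths`` is ``"error"`` (default) or ``"zero"`` — branch
    lengths absent from the file either abort or default to 0.
    """
    try:
        tree = skbio.TreeNode.read(str(path), format="newick")
    except Exception as e:
        raise FormatError(f"{path}: malformed Newick: {e}") from e
    for node in tree.traverse(include_self=False):
        if node.length is None:
            if missing_lengths == "zero":
                node.length = 0.0
            else:
                raise FormatError(
                    f"{path}: node {node.name!r} has no branch length")
        elif not math.isfinite(node.length) or node.length < 0:
            raise ValidationError(
                f"{path}: invalid branch length {node.length} on "
                f"{node.name!r}")
    leaves = [lf.name for lf in tree.tips()]
    if len(set(leaves)) != len(leaves):
        raise ValidationError(f"{path}: duplicate leaf labels")
    return tree


def write_newick(tree: skbio.TreeNode, path):
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def _edge_sign(weight: float) -> str:
    return "negative" if weight < 0 else "positive"


def write_network(net: nx.Graph, path, format: str = "graphml"):
    """Write an association network; ``edge-tsv`` adds a ``.nodes.tsv``
    sidecar carrying node attributes so the round trip is lossless."""
    path = Path(path)
    net = net.copy()
    for u, v, d in net.edges(data=True):
        d.setdefault("weight", 1.0)
        d["sign"] = _edge_sign(d["weight"])
    if format == "graphml":
        nx.write_graphml(net, path)
    elif format == "edge-tsv":
        edge_keys = sorted({k for _, _, d in net.edges(data=True) for k in d})
        with open(path, "w") as fh:
            fh.write("source\ttarget\t" + "\t".join(edge_keys) + "\n")
            for u, v, d in sorted(net.edges(data=True)):
                vals = [_fmt_attr(d.get(k, "")) for k in edge_keys]
                fh.write(f"{u}\t{v}\t" + "\t".join(vals) + "\n")
        node_keys = sorted({k for _, d in net.nodes(data=True) for k in d})
        with open(str(path) + ".nodes.tsv", "w") as fh:
            fh.write("node\t" + "\t".join(node_keys) + "\n")
            for n, d in sorted(net.nodes(data=True)):
                vals = [_fmt_attr(d.get(k, "")) for k in node_keys]
                fh.write(f"{n}\t" + "\t".join(vals) + "\n")
    else:
        raise FormatError(f"unknown network format {format!r}")


def _fmt_attr(v):
    if isinstance(v, float):
        return _fmt_float(v)
    return str(v)


def read_network(path, format: str = "graphml") -> nx.Graph:
    path = Path(path)
    if format == "graphml":
        return nx.read_graphml(path)
    if format == "edge-tsv":
        edges = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
        g = nx.Graph()
        for _, row in edges.iterrows():
            attrs = {k: row[k] for k in edges.columns
                     if k not in ("source", "target") and row[k] == row[k]}
            g.add_edge(str(row["source"]), str(row["target"]), **attrs)
        nodes_path = Path(str(path) + ".nodes.tsv")
        if nodes_path.exists():
            nodes = pd.read_csv(nodes_path, sep="\t", dtype={"node": str})
            for _, row in nodes.iterrows():
                attrs = {k: row[k] for k in nodes.columns
                         if k != "node" and row[k] == row[k]}
                g.add_node(str(row["node"]), **attrs)
        return g
    raise FormatError(f"unknown network format {format!r}")
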