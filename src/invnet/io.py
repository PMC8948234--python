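"""Readers, writers, and the shared multi-omics dataset container.

Matrices are genes-as-rows / samples-as-columns TSV with a corner label
cell; gene sets follow the GMT convention (name, description, genes,
tab-separated). Output files carry provenance comment lines (tool version,
seed, config hash).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OmicsDataset",
    "GeneSetCollection",
    "read_expression",
    "read_annotations",
    "read_gmt",
    "write_matrix",
    "write_annotations",
    "write_gmt",
    "write_network",
    "write_results",
    "provenance_lines",
]

TOOL_VERSION = "invnet 0.1.0"


@dataclass
class OmicsDataset:
    """Expression plus optional CNV / methylation with shared annotations.

    ``expression`` is genes x samples on the log2 scale; ``annotations`` is
    indexed by sample (histology, nodal stage, survival time/event, age,
    sex, stage as available). Sample identifiers must agree across tables.
    """

    expression: pd.DataFrame
    annotations: pd.DataFrame | None = None
    cnv: pd.DataFrame | None = None
    methylation: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.expression.index.has_duplicates:
            raise ValueError("duplicate gene identifiers in expression")
        samples = list(self.expression.columns)
        for name in ("cnv", "methylation"):
            m = getattr(self, name)
            if m is not None:
                missing = [s for s in samples if s not in m.columns]
                if missing:
                    raise ValueError(
                        f"{name} lacks samples {missing[:5]} present in "
                        "expression")
        if self.annotations is not None:
            missing = [s for s in samples if s not in self.annotations.index]
            if missing:
                raise ValueError(
                    f"annotations lack samples {missing[:5]}")

    @property
    def samples(self) -> list[str]:
        return list(self.expression.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.expression.index)

    def require_annotation(self, column: str) -> pd.Series:
        if self.annotations is None or column not in self.annotations.columns:
            raise ValueError(
                f"annotation column '{column}' is required for this stage "
                "but is missing")
        return self.annotations.loc[self.samples, column]


@dataclass
class GeneSetCollection:
    """Named gene sets parsed from a GMT file (genes upper-cased)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str]

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


def provenance_lines(seed=None, config: dict | None = None) -> list[str]:
    lines = [f"# {TOOL_VERSION}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if config is not None:
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]
        lines.append(f"# config_hash={digest}")
    return lines


def _read_table(path, index_name: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.name is None and df.columns.size == 0:
        raise ValueError(f"{path}: malformed header")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique()[:5]
        raise ValueError(f"{path}: duplicate {index_name} identifiers "
                         f"(e.g. {list(dups)})")
    if df.isna().all(axis=None):
        raise ValueError(f"{path}: no data rows")
    return df


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples TSV matrix (comment lines ignored)."""
    df = _read_table(path, "gene")
    return df.astype(float)


def read_annotations(path) -> pd.DataFrame:
    """Read a sample-annotation TSV indexed by sample identifier."""
    return _read_table(path, "sample")


def read_gmt(path, uppercase: bool = True) -> GeneSetCollection:
    """Parse a GMT file: name TAB description TAB gene1 TAB gene2 ..."""
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    "at least one gene")
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set '{name}'")
            genes = [g.upper() if uppercase else g for g in parts[2:] if g]
            sets[name] = genes
            desc[name] = parts[1]
    return GeneSetCollection(sets=sets, descriptions=desc)


def write_matrix(df: pd.DataFrame, path, seed=None,
                 config: dict | None = None) -> None:
    """Write a genes x samples matrix as TSV with provenance comments."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in provenance_lines(seed, config):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index_label=df.index.name or "gene",
                  float_format="%.10g")


def write_annotations(df: pd.DataFrame, path, seed=None,
                      config: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in provenance_lines(seed, config):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index_label=df.index.name or "sample")


def write_gmt(collection: GeneSetCollection, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def write_network(net, path, fmt: str = "tsv", seed=None,
                  config: dict | None = None) -> None:
    """Write a consensus network as a 3-column edge list (tsv) or SIF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    edges = net.edges_frame().sort_values(["parent", "child"])
    with open(path, "w") as fh:
        if fmt == "tsv":
            for line in provenance_lines(seed, config):
                fh.write(line + "\n")
            edges.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        elif fmt == "sif":
            for _, row in edges.iterrows():
                fh.write(f"{row['parent']}\tregulates\t{row['child']}\n")
        else:
            raise ValueError(f"unknown network format: {fmt}")


def read_network_tsv(path):
    """Read a consensus-network edge list written by :func:`write_network`."""
    import networkx as nx

    from .network import ConsensusNetwork
    df = pd.read_csv(path, sep="\t", comment="#")
    g = nx.DiGraph()
    for _, row in df.iterrows():
        g.add_edge(row["parent"], row["child"],
                   frequency=float(row["frequency"]))
    roots = sorted(n for n in g.nodes if ":" in str(n))
    return ConsensusNetwork(graph=g, threshold=float("nan"),
                            root_nodes=roots)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="index")
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_results(obj, path) -> None:
    """Serialize a result mapping as JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_jsonable)
        fh.write("\n")
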