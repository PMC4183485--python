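"""Readers and writers for the edge-list, partition and table formats.

Formats:

* ``.abc`` — whitespace-separated edge list, two label columns plus an
  optional numeric weight column; lines starting with ``#`` are comments.
* ``.idx`` — two whitespace-separated columns: node label, cluster label.
* expression table — TSV, header row of sample names, first column gene IDs.
* PDB — only ATOM/CA records are consumed, via Biopython.
* node table — TSV summary of the cartography (one row per node).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Network, Partition

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "read_abc",
    "write_abc",
    "read_idx",
    "write_idx",
    "read_expression_table",
    "read_pdb_ca",
    "read_node_attributes",
    "write_node_table",
]

#: Node attribute tables are plain nested dicts: node -> {attribute: value}.
NodeAttributeTable = dict[str, dict[str, str]]


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values; missing entries are NaN, never 0."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError("expression matrix shape mismatch")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene labels")


def _tokenize(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            yield lineno, stripped.split()


def read_abc(path) -> Network:
    """Read a whitespace-separated edge list into a Network.

    One edge per non-blank line; an optional third numeric field is stored
    as the edge weight.  Duplicate lines and both orientations of an edge
    collapse to a single undirected edge; self-loop lines are dropped with
    a warning.  Nodes appear in first-seen order.
    """
    net = Network()
    for lineno, fields in _tokenize(path):
        if len(fields) < 2:
            raise ValueError(f"{path}: line {lineno}: expected 2 or 3 fields, got {len(fields)}")
        if len(fields) > 3:
            raise ValueError(f"{path}: line {lineno}: expected 2 or 3 fields, got {len(fields)}")
        u, v = fields[0], fields[1]
        net.add_node(u)
        net.add_node(v)
        if len(fields) == 3:
            try:
                w = float(fields[2])
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: third field {fields[2]!r} is not numeric") from None
            net.add_edge(u, v, weight=w)
        else:
            net.add_edge(u, v)
    return net


def write_abc(net: Network, path, header: str | None = None) -> None:
    """Write a Network as an edge list; ``read_abc`` round-trips it.

    Isolated nodes cannot be represented in an edge list: they are omitted
    with a logged warning.
    """
    isolated = [n for n in net.nodes if net.degree(n) == 0]
    if isolated:
        logger.warning("%d isolated node(s) cannot be represented in .abc output", len(isolated))
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for u, v in net.edges:
            w = net.weight(u, v)
            if w is None:
                fh.write(f"{u} {v}\n")
            else:
                fh.write(f"{u} {v} {w:g}\n")


def read_idx(path) -> Partition:
    """Read a two-column node/cluster file into a Partition.

    Cluster labels are opaque; internal module indices follow first-seen
    order.  A node listed twice with conflicting clusters is an error.
    """
    assignment: dict[str, str] = {}
    for lineno, fields in _tokenize(path):
        if len(fields) != 2:
            raise ValueError(f"{path}: line {lineno}: expected 2 fields, got {len(fields)}")
        node, cluster = fields
        if node in assignment and assignment[node] != cluster:
            raise ValueError(f"{path}: line {lineno}: node {node!r} re-assigned "
                             f"({assignment[node]!r} vs {cluster!r})")
        assignment[node] = cluster
    return Partition(assignment)


def write_idx(p: Partition, path, header: str | None = None) -> None:
    """Write a Partition as node/cluster lines; round-trips via read_idx."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for node, module in p.assignment.items():
            fh.write(f"{node} {module}\n")


def read_expression_table(path) -> ExpressionMatrix:
    """Read a TSV with sample-name header and gene-ID first column.

    Missing values ("", "NA", "NaN") are recorded as NaN, not zero.
    Ragged rows and duplicate gene IDs are errors.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        samples = header[1:]
        genes: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(samples) + 1:
                raise ValueError(f"{path}: line {lineno}: expected {len(samples) + 1} fields, "
                                 f"got {len(fields)}")
            genes.append(fields[0])
            row = []
            for cell in fields[1:]:
                cell = cell.strip()
                if cell in ("", "NA", "NaN", "nan"):
                    row.append(np.nan)
                else:
                    row.append(float(cell))
            rows.append(row)
    if len(set(genes)) != len(genes):
        dupes = sorted({g for g in genes if genes.count(g) > 1})
        raise ValueError(f"{path}: duplicate gene IDs: {dupes[:5]}")
    return ExpressionMatrix(genes, samples, np.array(rows, dtype=float).reshape(len(genes), len(samples)))


def read_pdb_ca(path, chains: set[str] | None = None) -> list[tuple[str, np.ndarray]]:
    """Extract alpha-carbon coordinates from a PDB file.

    Returns one ``(label, xyz)`` entry per residue that has a CA atom, in
    file order, labelled ``chain:resSeq[iCode]``.  HETATM residues are
    excluded; for disordered (altLoc) atoms the first location encountered
    in the file is kept.  ``chains`` optionally restricts to a chain set.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", path)
    model = next(structure.get_models())
    out: list[tuple[str, np.ndarray]] = []
    for chain in model:
        if chains is not None and chain.id not in chains:
            continue
        for residue in chain:
            hetflag, resseq, icode = residue.id
            if hetflag.strip():  # HETATM / water
                continue
            if "CA" not in residue:
                continue
            atom = residue["CA"]
            if atom.is_disordered():
                atom = atom.disordered_get_list()[0]
            label = f"{chain.id}:{resseq}{icode.strip()}"
            out.append((label, np.asarray(atom.coord, dtype=float)))
    if not out:
        raise ValueError(f"{path}: no alpha carbons")
    return out


def read_node_attributes(path) -> NodeAttributeTable:
    """Read a TSV attribute file: header 'node<TAB>attr1<TAB>...', rows keyed by node."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    key = df.columns[0]
    return {row[key]: {c: row[c] for c in df.columns[1:]} for _, row in df.iterrows()}


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def write_node_table(records, attrs: NodeAttributeTable | None = None, path=None,
                     header: str | None = None) -> None:
    """Write the cartography summary as a TSV.

    Columns: node, module, degree, kappa, z, P, region, then one column per
    attribute name in sorted order.  Floats use 6 significant digits so the
    output is diffable.  Nodes absent from ``attrs`` get empty cells.
    """
    attr_names = sorted({a for m in (attrs or {}).values() for a in m})
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        cols = ["node", "module", "degree", "kappa", "z", "P", "region"] + attr_names
        fh.write("\t".join(cols) + "\n")
        for r in records:
            row = [r.node, r.module, str(r.k), str(r.kappa), _fmt(r.z), _fmt(r.P), r.region]
            node_attrs = (attrs or {}).get(r.node, {})
            row += [node_attrs.get(a, "") for a in attr_names]
            fh.write("\t".join(row) + "\n")
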