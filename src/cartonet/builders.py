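"""Network construction: structures, expression matrices, random models.

Recipes implemented here:

* protein contact networks — an edge between residues whose Cα–Cα Euclidean
  distance falls in a closed window (default 4–8 Å, which keeps non-covalent
  contacts and excludes covalently bonded neighbours at ~3.8 Å);
* gene co-expression networks — an edge where |Pearson r| between expression
  profiles exceeds a threshold (default 0.8), on pairwise-complete samples;
* reference random models — Erdős–Rényi G(n, m) and Barabási–Albert
  preferential attachment;
* a planted-partition generator used as ground truth in cluster-recovery
  experiments.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core import Network, Partition
from .io import ExpressionMatrix

__all__ = [
    "ContactRule",
    "CoexpressionRule",
    "contact_network",
    "coexpression_network",
    "erdos_renyi_gm",
    "barabasi_albert",
    "planted_partition",
]


@dataclass
class ContactRule:
    """Closed distance window [d_min, d_max] in Å for Cα contacts."""

    d_min: float = 4.0
    d_max: float = 8.0

    def __post_init__(self) -> None:
        if not 0 <= self.d_min < self.d_max:
            raise ValueError("require 0 <= d_min < d_max")


@dataclass
class CoexpressionRule:
    """Strict absolute-Pearson-correlation threshold in (0, 1]."""

    threshold: float = 0.8

    def __post_init__(self) -> None:
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must be in (0, 1]")


def contact_network(residues, rule: ContactRule | None = None) -> Network:
    """Cα contact network: edge iff d_min <= ||xi - xj|| <= d_max (closed).

    ``residues`` is a list of (label, 3D coordinate) as produced by
    :func:`cartonet.io.read_pdb_ca`.  Every residue becomes a node even if
    it ends up isolated.
    """
    rule = rule or ContactRule()
    if len(residues) < 2:
        raise ValueError("need at least 2 residues")
    labels = [r[0] for r in residues]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate residue labels")
    coords = np.asarray([r[1] for r in residues], dtype=float)
    d = squareform(pdist(coords))
    net = Network()
    for lab in labels:
        net.add_node(lab)
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            if rule.d_min <= d[i, j] <= rule.d_max:
                net.add_edge(labels[i], labels[j])
    return net


def coexpression_network(expr: ExpressionMatrix, rule: CoexpressionRule | None = None) -> Network:
    """Co-expression network: edge iff |Pearson r| > threshold (strict).

    Correlations use pairwise-complete observations; pairs with fewer than
    3 complete samples are skipped with a warning, and zero-variance genes
    (undefined r) produce no edges.  Every gene becomes a node.
    """
    rule = rule or CoexpressionRule()
    df = pd.DataFrame(expr.values.T, columns=expr.genes)
    n_complete = (~df.isna()).astype(int).T @ (~df.isna()).astype(int)
    corr = df.corr(method="pearson", min_periods=3)
    net = Network()
    for g in expr.genes:
        net.add_node(g)
    skipped = 0
    for i, g in enumerate(expr.genes):
        for j in range(i + 1, len(expr.genes)):
            h = expr.genes[j]
            if n_complete.iloc[i, j] < 3:
                skipped += 1
                continue
            r = corr.iloc[i, j]
            if np.isfinite(r) and abs(r) > rule.threshold:
                net.add_edge(g, h)
    if skipped:
        warnings.warn(f"{skipped} gene pair(s) skipped: fewer than 3 pairwise-complete samples")
    return net


def _pair_from_index(idx: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Map linear indices of the strict upper triangle to (i, j) pairs."""
    iu, ju = np.triu_indices(n, k=1)
    return iu[idx], ju[idx]


def erdos_renyi_gm(n: int, m: int, seed: int = 0) -> Network:
    """Erdős–Rényi G(n, m): exactly m distinct edges, uniform without replacement."""
    max_m = n * (n - 1) // 2
    if m > max_m:
        raise ValueError(f"m={m} exceeds maximum {max_m} for n={n}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(max_m, size=m, replace=False)
    ii, jj = _pair_from_index(np.sort(chosen), n)
    net = Network()
    for k in range(n):
        net.add_node(f"v{k}")
    for i, j in zip(ii, jj):
        net.add_edge(f"v{i}", f"v{j}")
    return net


def barabasi_albert(n: int, m_attach: int, seed: int = 0) -> Network:
    """Barabási–Albert preferential attachment.

    Starts from a clique on m_attach+1 nodes; each subsequent node attaches
    to m_attach distinct existing nodes chosen with probability proportional
    to current degree.  Total edges: C(m_attach+1, 2) + (n-m_attach-1)*m_attach.
    """
    if not 1 <= m_attach < n:
        raise ValueError("require 1 <= m_attach < n")
    rng = np.random.default_rng(seed)
    net = Network()
    for k in range(n):
        net.add_node(f"v{k}")
    # degree-weighted sampling via a repeated-node list
    repeated: list[int] = []
    for i, j in itertools.combinations(range(m_attach + 1), 2):
        net.add_edge(f"v{i}", f"v{j}")
        repeated += [i, j]
    for new in range(m_attach + 1, n):
        targets: set[int] = set()
        while len(targets) < m_attach:
            targets.add(repeated[rng.integers(len(repeated))])
        for t in targets:
            net.add_edge(f"v{new}", f"v{t}")
            repeated += [new, t]
    return net


def planted_partition(n_modules: int, module_size: int, p_in: float, p_out: float,
                      seed: int = 0) -> tuple[Network, Partition]:
    """Planted-partition random graph with ground-truth modules.

    Within-module edges appear with probability p_in, between-module edges
    with p_out, as independent Bernoulli draws.  Returns the network and the
    planted Partition (modules labelled M0..M{n_modules-1}).
    """
    if not 0 <= p_out < p_in <= 1 and not (p_in == p_out == 0):
        raise ValueError("require 0 <= p_out < p_in <= 1")
    rng = np.random.default_rng(seed)
    n = n_modules * module_size
    labels = [f"m{i // module_size}n{i % module_size}" for i in range(n)]
    block = np.repeat(np.arange(n_modules), module_size)
    net = Network()
    for lab in labels:
        net.add_node(lab)
    iu, ju = np.triu_indices(n, k=1)
    p = np.where(block[iu] == block[ju], p_in, p_out)
    draws = rng.random(len(p)) < p
    for i, j in zip(iu[draws], ju[draws]):
        net.add_edge(labels[i], labels[j])
    part = Partition({lab: f"M{block[i]}" for i, lab in enumerate(labels)})
    return net, part
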