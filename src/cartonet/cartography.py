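"""Node role cartography in the (participation P, within-module z) plane.

Given a network and a module partition, every node i receives:

* a within-module z-score, the standardised intra-module degree
  z_i = (κ_i − mean κ) / sd κ, where κ_i is the number of links node i has
  inside its own module and the mean/sd run over the nodes of that module
  (population formula; a global mode using all nodes is also available);
* a participation coefficient.  The *original* Guimerà–Amaral definition is
  P_i = 1 − Σ_s (κ_is / k_i)², summing the squared per-module link fractions
  over all modules s; it is bounded above by 1 − 1/N for N modules.  The
  *modified* single-term variant used here by default,
  P_i = 1 − (κ_i / k_i)², depends only on the fraction of links a node keeps
  inside its own module, is independent of the module count, and reaches 1 —
  which makes strongly inter-modular ("kinless") nodes separable no matter
  how few modules exist;
* a role region R1–R7: non-hubs (z below the hub cut, default 2.5) fall in
  R1 ultra-peripheral / R2 peripheral / R3 non-hub connector / R4 non-hub
  kinless by increasing P; hubs fall in R5 provincial / R6 connector /
  R7 kinless hub.  With the modified P, the default R3/R4 boundary
  1 − 0.35² = 0.8775 makes R4 exactly the nodes with fewer than 35% of
  their links inside their own module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Network, Partition

__all__ = [
    "RegionThresholds",
    "CartographyRecord",
    "module_link_counts",
    "within_module_zscores",
    "participation_coefficients",
    "classify_node",
    "build_cartography",
    "pz_scatter",
]


@dataclass
class RegionThresholds:
    """Boundaries of the seven role regions in the (P, z) plane.

    ``z_hub`` separates hubs from non-hubs (z >= z_hub is a hub).  Non-hub
    P cuts: p1 (R1|R2), p2 (R2|R3), p3 (R3|R4); hub P cuts: p5 (R5|R6),
    p6 (R6|R7).  Upper boundaries belong to the lower region.  The default
    p3 = 1 − 0.35² encodes the 35% intra-module-link rule for R4 under the
    modified participation coefficient.
    """

    z_hub: float = 2.5
    p1: float = 0.05
    p2: float = 0.62
    # 1 - 0.35**2 written as the expression, not the decimal 0.8775, so a P
    # computed as 1 - (kappa/k)**2 with kappa/k = 0.35 lands exactly on the
    # boundary under identical floating-point arithmetic
    p3: float = 1 - 0.35**2
    p5: float = 0.30
    p6: float = 0.75

    def __post_init__(self) -> None:
        if not 0 < self.p1 < self.p2 < self.p3 < 1:
            raise ValueError("require 0 < p1 < p2 < p3 < 1")
        if not 0 < self.p5 < self.p6 < 1:
            raise ValueError("require 0 < p5 < p6 < 1")


@dataclass
class CartographyRecord:
    """Per-node summary: degree k, intra-module degree kappa, z, P, region."""

    node: str
    module: str
    k: int
    kappa: int
    z: float
    P: float
    region: str


def module_link_counts(net: Network, p: Partition) -> dict[str, dict[str, int]]:
    """For each node, its number of links into every module (κ_is).

    The counts over modules sum to the node's total degree k_i.  Modules a
    node has no link into are omitted from its map.
    """
    p.validate_over(net)
    out: dict[str, dict[str, int]] = {}
    for node in net.nodes:
        counts: dict[str, int] = {}
        for nb in net.neighbors(node):
            m = p.module_of(nb)
            counts[m] = counts.get(m, 0) + 1
        out[node] = counts
    return out


def _kappas(net: Network, p: Partition) -> dict[str, int]:
    counts = module_link_counts(net, p)
    return {n: counts[n].get(p.module_of(n), 0) for n in net.nodes}


def within_module_zscores(net: Network, p: Partition,
                          mode: str = "within_module") -> dict[str, float]:
    """Standardised intra-module degree per node.

    ``within_module`` (default): mean and sd of κ taken over the nodes of
    each module separately.  ``global``: mean and sd over all nodes.
    Population sd; sd = 0 yields z = 0 by convention.
    """
    if mode not in ("within_module", "global"):
        raise ValueError(f"unknown z mode {mode!r}")
    p.validate_over(net)
    kappa = _kappas(net, p)
    z: dict[str, float] = {}
    if mode == "global":
        vals = np.array([kappa[n] for n in net.nodes], dtype=float)
        mu, sd = vals.mean(), vals.std()
        for n in net.nodes:
            z[n] = (kappa[n] - mu) / sd if sd > 0 else 0.0
        return z
    for members in p.modules:
        members_in_net = [n for n in members if net.has_node(n)]
        if not members_in_net:
            continue
        vals = np.array([kappa[n] for n in members_in_net], dtype=float)
        mu, sd = vals.mean(), vals.std()
        for n in members_in_net:
            z[n] = (kappa[n] - mu) / sd if sd > 0 else 0.0
    return z


def participation_coefficients(net: Network, p: Partition,
                               variant: str = "modified") -> dict[str, float]:
    """Participation coefficient per node.

    ``original``: P_i = 1 − Σ_s (κ_is/k_i)² (bounded by 1 − 1/N).
    ``modified``: P_i = 1 − (κ_i/k_i)², κ_i counting only own-module links
    (unbounded by module count; reaches 1).  Isolated nodes get P = 0.
    """
    if variant not in ("original", "modified"):
        raise ValueError(f"unknown variant {variant!r}")
    counts = module_link_counts(net, p)
    out: dict[str, float] = {}
    for n in net.nodes:
        k = net.degree(n)
        if k == 0:
            out[n] = 0.0
            continue
        if variant == "original":
            out[n] = 1.0 - sum((c / k) ** 2 for c in counts[n].values())
        else:
            kappa = counts[n].get(p.module_of(n), 0)
            out[n] = 1.0 - (kappa / k) ** 2
    return out


def classify_node(z: float, P: float, th: RegionThresholds | None = None) -> str:
    """Map a (z, P) pair to its role region R1..R7 (total function).

    Hubs (z >= z_hub): R5 provincial, R6 connector, R7 kinless.
    Non-hubs: R1 ultra-peripheral, R2 peripheral, R3 non-hub connector,
    R4 non-hub kinless.  Upper P boundaries belong to the lower region.
    """
    th = th or RegionThresholds()
    if not -1e-9 <= P <= 1 + 1e-9:
        raise ValueError(f"participation coefficient {P} outside [0, 1]")
    if z >= th.z_hub:
        if P <= th.p5:
            return "R5"
        return "R6" if P <= th.p6 else "R7"
    if P <= th.p1:
        return "R1"
    if P <= th.p2:
        return "R2"
    return "R3" if P <= th.p3 else "R4"


def build_cartography(net: Network, p: Partition,
                      thresholds: RegionThresholds | None = None,
                      zmode: str = "within_module",
                      variant: str = "modified") -> list[CartographyRecord]:
    """One CartographyRecord per node, in the network's node order."""
    thresholds = thresholds or RegionThresholds()
    p.validate_over(net)
    counts = module_link_counts(net, p)
    zs = within_module_zscores(net, p, mode=zmode)
    ps = participation_coefficients(net, p, variant=variant)
    records = []
    for n in net.nodes:
        kappa = counts[n].get(p.module_of(n), 0)
        records.append(CartographyRecord(
            node=n,
            module=p.module_of(n),
            k=net.degree(n),
            kappa=kappa,
            z=zs[n],
            P=ps[n],
            region=classify_node(zs[n], ps[n], thresholds),
        ))
    return records


_REGION_COLORS = {
    "R1": "#ffffff", "R2": "#f4d03f", "R3": "#58d68d", "R4": "#1b1b1b",
    "R5": "#f5b041", "R6": "#e74c3c", "R7": "#8e44ad",
}


def pz_scatter(records, path, thresholds: RegionThresholds | None = None) -> None:
    """Scatter the nodes in the (P, z) plane, coloured by region.

    Region boundary lines are drawn from the active thresholds; the file
    format follows the path suffix (png, svg, pdf).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not records:
        raise ValueError("no records to plot")
    th = thresholds or RegionThresholds()
    fig, ax = plt.subplots(figsize=(7, 5))
    zs = [r.z for r in records]
    z_lo, z_hi = min(zs + [-1.0]) - 0.5, max(zs + [th.z_hub]) + 0.5
    for x in (th.p1, th.p2, th.p3):
        ax.plot([x, x], [z_lo, th.z_hub], color="0.6", lw=0.8, zorder=1)
    for x in (th.p5, th.p6):
        ax.plot([x, x], [th.z_hub, z_hi], color="0.6", lw=0.8, zorder=1)
    ax.axhline(th.z_hub, color="0.4", lw=1.0, zorder=1)
    for region in sorted({r.region for r in records}):
        pts = [(r.P, r.z) for r in records if r.region == region]
        ax.scatter(*zip(*pts), s=22, label=region,
                   color=_REGION_COLORS.get(region, "0.5"),
                   edgecolors="0.3", linewidths=0.4, zorder=2)
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(z_lo, z_hi)
    ax.set_xlabel("participation coefficient P")
    ax.set_ylabel("within-module z-score")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
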