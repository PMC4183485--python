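"""P-z portraits of reference random architectures.

Generates an Erdős–Rényi G(1000, 50000) network and a Barabási–Albert
scale-free network (1000 nodes), clusters each (spectral, k=2 for the
scale-free case), and writes their cartography scatters.  The scale-free
portrait spreads into high-z hubs and high-P kinless nodes; the
homogeneous random graph stays compact.
"""

from cartonet import (SpectralConfig, barabasi_albert, build_cartography,
                      erdos_renyi_gm, pz_scatter, spectral_partition)

for name, net, k in [
    ("erdos_renyi", erdos_renyi_gm(1000, 50000, seed=0), 2),
    ("barabasi_albert", barabasi_albert(1000, 3, seed=0), 2),
]:
    part = spectral_partition(net, SpectralConfig(k=k, seed=0))
    records = build_cartography(net, part)
    census = {}
    for r in records:
        census[r.region] = census.get(r.region, 0) + 1
    out = f"pz_{name}.png"
    pz_scatter(records, out)
    pmax = max(r.P for r in records)
    zmax = max(r.z for r in records)
    print(f"{name}: {net.n_edges} edges, census {dict(sorted(census.items()))}, "
          f"max P={pmax:.3f}, max z={zmax:.2f} -> {out}")
print("-> the scale-free graph spreads into high-z hubs and high-P kinless "
      "nodes; the Erdős–Rényi cloud stays compact.")
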