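#!/usr/bin/env python
"""Generate the adaptive-rewiring network ensembles and measure their topology.

For each diffusion parameter tau in {0, ..., 10}, runs 10 independently
seeded 600-step rewiring trajectories (100 nodes, 300 edges, 10% random
rewiring) and measures the final snapshot of each: modularity Q, degree
statistics, and the PBH driver-node count.  Writes a per-network table to
results/network_metrics.csv and exemplar edge lists for tau in {0, 1, 10}
to results/networks/.

Expected picture: tau=0 stays Erdos-Renyi (Q ~ 0.37-0.39, sigma ~ 2.3,
one driver node), tau=1 grows modules (Q ~ 0.84), tau=10 centralizes onto
hubs (sigma ~ 12, ~70 driver nodes).
"""

import os

import numpy as np
import pandas as pd

from netsparse.drivers import min_driver_nodes
from netsparse.io import write_edgelist
from netsparse.metrics import degree_stats, find_communities, modularity
from netsparse.netgen import RewiringConfig, generate_ensemble

SEED = 2024
N_PER_TAU = 10
OUT = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    os.makedirs(os.path.join(OUT, "networks"), exist_ok=True)
    rows = []
    for tau in range(11):
        for rep in range(N_PER_TAU):
            seed = SEED + 1000 * tau + rep
            g = generate_ensemble(
                RewiringConfig(tau=float(tau), seed=seed, n_samples=1)
            )[-1]
            ds = degree_stats(g)
            q = modularity(g, find_communities(g, seed))
            nd = min_driver_nodes(g).n_driver
            rows.append(
                dict(tau=tau, rep=rep, Q=q, degree_std=ds.degree_std,
                     mean_degree=ds.mean_degree, density=ds.density, n_driver=nd)
            )
            if tau in (0, 1, 10) and rep == 0:
                write_edgelist(g, os.path.join(OUT, "networks", f"tau{tau}.tsv"))
        sub = pd.DataFrame([r for r in rows if r["tau"] == tau])
        print(
            f"tau={tau:2d}: Q={sub.Q.mean():.3f}+-{sub.Q.std():.3f}  "
            f"sigma={sub.degree_std.mean():5.2f}+-{sub.degree_std.std():.2f}  "
            f"n_D={sub.n_driver.mean():5.1f}"
        )
    table = pd.DataFrame(rows)
    table.to_csv(os.path.join(OUT, "network_metrics.csv"), index=False)
    print(f"\nwrote {len(table)} rows to results/network_metrics.csv")


if __name__ == "__main__":
    main()
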