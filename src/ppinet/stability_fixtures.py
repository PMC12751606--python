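"""Synthetic replicate networks for the stability experiment.

Each replicate network emulates one genome's inferred network in the
regime the stability protocol probes: a deterministic backbone (standing
in for neighborhood evidence and small completed profile groups) plus
large phylogenetic-profile groups whose edges come from RIS sampling.

* ``features`` mode: profile groups stay below the RIS trigger, so every
  replicate is the identical, fully completed network — the deterministic
  limit (agreement statistics must be perfect).
* ``ml`` mode: groups exceed the trigger and are RIS-sampled with the
  replicate's seed, so replicates differ and the Top-N agreement
  statistics measure how much topology the sampling preserves.

The ``n_files`` knob mildly scales the deterministic part, emulating
conserved cores growing with more input genomes.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from ppinet.context import InteractionNetwork
from ppinet.ris import RISConfig, complete_graph_edges, ris_sample


def build_replicate_network(
    mode: str,
    n_files: int,
    replicate_seed: int,
    ris_trigger: int = 100,
    group_size: int = 150,
    n_groups: int = 2,
    n_clique_nodes: int = 60,
) -> InteractionNetwork:
    """One synthetic replicate network.

    ``ml`` mode: ``n_groups`` profile groups of ``group_size`` members
    (above the trigger) are RIS-sampled with ``replicate_seed``;
    ``features`` mode: the same groups are completed deterministically at
    a size below the trigger.  A deterministic ring plus small cliques
    (scaled by ``n_files``) form the shared backbone.
    """
    if mode not in ("features", "ml"):
        raise ValueError("mode must be 'features' or 'ml'")
    net = InteractionNetwork(genome_id=f"synthetic-{mode}")

    if mode == "features":
        group_size = min(group_size, ris_trigger)  # below trigger: deterministic
    members_of = [
        [f"g{g}_{i:04d}" for i in range(group_size)] for g in range(n_groups)
    ]
    rng = np.random.default_rng(replicate_seed)
    cfg = RISConfig(trigger=ris_trigger, seed=replicate_seed)
    for members in members_of:
        if len(members) > ris_trigger:
            edges = ris_sample(members, cfg, rng)
        else:
            edges = complete_graph_edges(members)
        for a, b in edges:
            net.add_edge(a, b, {"profile"})

    # deterministic backbone: ring over all group members + small cliques
    all_members = [m for members in members_of for m in members]
    for i, a in enumerate(all_members):
        net.add_edge(a, all_members[(i + 1) % len(all_members)], {"neighborhood"})
    n_cliques = max(1, min(n_clique_nodes // 4, n_files))
    for c in range(n_cliques):
        clique = [f"c{c}_{i}" for i in range(4)]
        for a, b in complete_graph_edges(clique):
            net.add_edge(a, b, {"neighborhood"})
        net.add_edge(clique[0], all_members[c % len(all_members)], {"neighborhood"})
    return net


def synthetic_replicate_pipeline(ris_trigger: int = 100, **kwargs) -> Callable:
    """A pipeline handle for :func:`ppinet.stability.run_stability_experiment`."""

    def pipeline(mode: str, n_files: int, replicate_seed: int) -> InteractionNetwork:
        return build_replicate_network(
            mode, n_files, replicate_seed, ris_trigger=ris_trigger, **kwargs
        )

    return pipeline
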