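"""Reduced Interaction Sampling (RIS).

A conserved phylogenetic-profile group of x proteins would, if completed,
contribute the full C(x, 2) clique of edges — for x in the hundreds this
alone dominates the network.  RIS instead (1) shuffles the group with a
seeded generator, (2) partitions it round-robin into k = floor(0.9·x)
sublists, (3) appends a few randomly chosen connector proteins to every
sublist so the sampled subgraph stays connected, and (4) emits the union
of the complete graphs within each sublist.  The output is always a
deduplicated subset of the complete pair set, identical for identical
seeds, and leaves the expected degree uniform across members (no member
is structurally privileged).

Groups at or below the trigger size are completed, not sampled.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from ppinet.io import canonical_pair


@dataclass(frozen=True)
class RISConfig:
    """Sampling knobs.

    trigger
        Sampling applies only when the group is strictly larger than this
        (default 100).
    sublist_count_fraction
        Number of sublists as a fraction of group size (default 0.9).
    connector_count
        How many members are appended to every sublist to keep the sampled
        subgraph connected (default 2).
    """

    trigger: int = 100
    sublist_count_fraction: float = 0.9
    connector_count: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trigger < 2:
            raise ValueError("trigger must be >= 2")
        if not 0 < self.sublist_count_fraction <= 1:
            raise ValueError("sublist_count_fraction must be in (0, 1]")
        if self.connector_count < 0:
            raise ValueError("connector_count must be >= 0")


def complete_graph_edges(members: Sequence[str]) -> set[tuple[str, str]]:
    """All C(n, 2) canonical undirected pairs over distinct members."""
    return {canonical_pair(a, b) for a, b in combinations(sorted(set(members)), 2)}


def ris_sample(
    members: Sequence[str],
    cfg: RISConfig | None = None,
    rng: np.random.Generator | None = None,
) -> set[tuple[str, str]]:
    """Sample edges within one profile group.

    Returns the complete graph when ``len(members) <= cfg.trigger``;
    otherwise the shuffle/subdivide/connect scheme described in the module
    docstring.  Deterministic given (members, cfg, rng state).
    """
    cfg = cfg or RISConfig()
    members = list(members)
    if len(set(members)) != len(members):
        raise ValueError("duplicate members in profile group")
    if len(members) < 2:
        raise ValueError("a profile group needs at least 2 members")
    if len(members) <= cfg.trigger:
        return complete_graph_edges(members)

    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    shuffled = list(members)
    rng.shuffle(shuffled)

    k = max(2, int(cfg.sublist_count_fraction * len(members)))
    sublists: list[list[str]] = [shuffled[i::k] for i in range(k)]

    n_connectors = min(cfg.connector_count, len(members))
    connectors = [members[i] for i in rng.choice(len(members), size=n_connectors, replace=False)]

    edges: set[tuple[str, str]] = set()
    for sub in sublists:
        block = list(dict.fromkeys(sub + connectors))
        for a, b in combinations(block, 2):
            edges.add(canonical_pair(a, b))
    return edges
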