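"""Replicate-agreement statistics for stochastic network generation.

When the interaction-sampling step (RIS) or the classifier introduces
randomness, repeated runs yield different networks.  This module measures
how stable the *important* part of the network is across R replicates:

* **MGP** (weighted global presence mean): with f_i the fraction of
  replicates whose Top-N set contains node i, MGP = 100·Σf_i²/Σf_i — a
  frequency-weighted mean presence that reaches 100% iff every appearing
  node appears in all replicates (sporadic nodes are down-weighted).
* **Pairwise Jaccard** of Top-N node sets.
* **Fleiss' kappa**, adapted to two categories (selected / not selected)
  with replicates as raters and an explicit node universe as items.
* **Kendall ratio positive**: the proportion of concordantly ordered node
  pairs between two replicate rankings, restricted to shared nodes, ties
  excluded from the denominator; averaged over replicate pairs.
* **Multi-sample KS**: the maximum two-sample Kolmogorov-Smirnov distance
  between the centrality-value distributions of any two replicates.

:func:`run_stability_experiment` drives the full grid
(modes × file counts × Top-N values × metrics) over R seeded replicates.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.stats import ks_2samp

from ppinet.netmetrics import METRICS, compute_centrality, select_top_n


@dataclass(frozen=True)
class StabilityConfig:
    """Experiment grid; the full published protocol is 2 modes × 5 file
    counts × 6 Top-N values × 3 metrics = 180 configurations at R=50."""

    replicates: int = 50
    top_n: tuple[int, ...] = (10, 25, 50, 100, 150, 200)
    metrics: tuple[str, ...] = METRICS
    modes: tuple[str, ...] = ("features", "ml")
    n_files: tuple[int, ...] = (10, 20, 30, 40, 50)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("agreement statistics need at least 2 replicates")

    @property
    def n_configurations(self) -> int:
        return len(self.modes) * len(self.n_files) * len(self.top_n) * len(self.metrics)


@dataclass
class StabilityReport:
    """Agreement statistics of one configuration across its replicates."""

    mode: str
    n_files: int
    top_n: int
    metric: str
    replicates: int
    mgp: float
    jaccard_mean: float
    jaccard_matrix: np.ndarray
    fleiss_kappa: float
    kendall_ratio_positive: float
    ks_multi: float
    degenerate: set[str] = field(default_factory=set)
    replicate_seeds: tuple[int, ...] = ()

    def row(self) -> dict:
        return {
            "mode": self.mode,
            "n_files": self.n_files,
            "top_n": self.top_n,
            "metric": self.metric,
            "replicates": self.replicates,
            "mgp": self.mgp,
            "jaccard_mean": self.jaccard_mean,
            "fleiss_kappa": self.fleiss_kappa,
            "kendall_ratio_positive": self.kendall_ratio_positive,
            "ks_multi": self.ks_multi,
            "degenerate": ";".join(sorted(self.degenerate)),
        }


def mgp(topn_sets: Sequence[set[str]]) -> float:
    """Weighted global presence mean, in percent."""
    if not topn_sets:
        raise ValueError("no replicate sets")
    union = set().union(*topn_sets)
    if not union:
        raise ValueError("all replicate sets are empty")
    r = len(topn_sets)
    freqs = np.array([sum(node in s for s in topn_sets) / r for node in sorted(union)])
    return float(100.0 * np.sum(freqs**2) / np.sum(freqs))


def pairwise_jaccard(topn_sets: Sequence[set[str]]) -> tuple[np.ndarray, float]:
    """Symmetric Jaccard matrix over replicate pairs and its off-diagonal
    mean.  Two empty sets have J = 1 (degenerate but defined)."""
    r = len(topn_sets)
    if r < 2:
        raise ValueError("pairwise Jaccard needs at least 2 replicates")
    mat = np.eye(r)
    for i, j in combinations(range(r), 2):
        a, b = topn_sets[i], topn_sets[j]
        union = a | b
        mat[i, j] = mat[j, i] = 1.0 if not union else len(a & b) / len(union)
    mean = float(np.mean([mat[i, j] for i, j in combinations(range(r), 2)]))
    return mat, mean


def fleiss_kappa(topn_sets: Sequence[set[str]], node_universe: Iterable[str]) -> float:
    """Two-category Fleiss' kappa: items = universe nodes, raters =
    replicates, categories = selected / not selected.

    Returns 1.0 when expected agreement is already perfect (every rater
    gives every item the same single category) — the degenerate case.
    """
    universe = sorted(set(node_universe))
    r = len(topn_sets)
    if r < 2:
        raise ValueError("Fleiss' kappa needs at least 2 raters")
    if not universe:
        raise ValueError("empty node universe")
    for s in topn_sets:
        if not s <= set(universe):
            raise ValueError("node universe must contain every selected node")
    # counts[i, 0] = raters not selecting item i, counts[i, 1] = selecting
    counts = np.zeros((len(universe), 2))
    for s in topn_sets:
        for i, node in enumerate(universe):
            counts[i, int(node in s)] += 1
    counts[:, 0] = r - counts[:, 1]
    p_i = (np.sum(counts**2, axis=1) - r) / (r * (r - 1))
    p_bar = float(np.mean(p_i))
    p_j = np.sum(counts, axis=0) / (len(universe) * r)
    p_e = float(np.sum(p_j**2))
    if np.isclose(p_e, 1.0):
        return 1.0
    return (p_bar - p_e) / (1 - p_e)


def kendall_ratio_positive(ranked_lists: Sequence[Sequence[str]]) -> float:
    """Mean proportion of concordant ordered pairs over replicate pairs.

    Each list ranks nodes best-first.  For each pair of replicates the
    comparison is restricted to shared nodes; pairs of replicates sharing
    fewer than 2 nodes are skipped.
    """
    if len(ranked_lists) < 2:
        raise ValueError("need at least 2 ranked lists")
    ratios = []
    for la, lb in combinations(ranked_lists, 2):
        pos_a = {node: i for i, node in enumerate(la)}
        pos_b = {node: i for i, node in enumerate(lb)}
        shared = sorted(set(pos_a) & set(pos_b))
        if len(shared) < 2:
            continue
        concordant = comparable = 0
        for x, y in combinations(shared, 2):
            da = pos_a[x] - pos_a[y]
            db = pos_b[x] - pos_b[y]
            if da == 0 or db == 0:
                continue  # ties excluded from the denominator
            comparable += 1
            if (da > 0) == (db > 0):
                concordant += 1
        if comparable:
            ratios.append(concordant / comparable)
    if not ratios:
        raise ValueError("no replicate pair shares enough nodes for ranking comparison")
    return float(np.mean(ratios))


def ks_multi(value_samples: Sequence[Sequence[float]], reduce: str = "max") -> float:
    """Multi-sample KS distance: max (default) or mean of the pairwise
    two-sample KS statistics; 0 iff all empirical distributions agree."""
    if len(value_samples) < 2:
        raise ValueError("need at least 2 samples")
    for s in value_samples:
        if len(s) == 0:
            raise ValueError("empty sample")
    stats = [
        float(ks_2samp(np.asarray(a, dtype=float), np.asarray(b, dtype=float)).statistic)
        for a, b in combinations(value_samples, 2)
    ]
    if reduce == "max":
        return max(stats)
    if reduce == "mean":
        return float(np.mean(stats))
    raise ValueError("reduce must be 'max' or 'mean'")


def derive_replicate_seeds(master_seed: int, n: int) -> tuple[int, ...]:
    """Fixed master-seed → replicate-seed derivation (recorded in reports)."""
    ss = np.random.SeedSequence(master_seed)
    return tuple(int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n))


def evaluate_replicates(
    networks: Sequence,
    top_n: int,
    metric: str,
    mode: str = "",
    n_files: int = 0,
    replicate_seeds: tuple[int, ...] = (),
) -> StabilityReport:
    """Compute the full statistic suite for one configuration's replicates."""
    cmaps = [compute_centrality(net, metric) for net in networks]
    rankings = [[node for _, node, _ in select_top_n(cm, top_n)] for cm in cmaps]
    sets = [set(r) for r in rankings]
    universe = sorted(set().union(*(cm.values.keys() for cm in cmaps)))

    degenerate: set[str] = set()
    jac_mat, jac_mean = pairwise_jaccard(sets)
    kappa = fleiss_kappa(sets, universe)
    if all(s == set(universe) for s in sets):
        degenerate.add("fleiss_all_selected")
    try:
        kendall = kendall_ratio_positive(rankings)
    except ValueError:
        kendall = float("nan")
        degenerate.add("kendall_no_shared_nodes")
    ks = ks_multi([list(cm.values.values()) for cm in cmaps])
    return StabilityReport(
        mode=mode,
        n_files=n_files,
        top_n=top_n,
        metric=metric,
        replicates=len(networks),
        mgp=mgp(sets),
        jaccard_mean=jac_mean,
        jaccard_matrix=jac_mat,
        fleiss_kappa=kappa,
        kendall_ratio_positive=kendall,
        ks_multi=ks,
        degenerate=degenerate,
        replicate_seeds=replicate_seeds,
    )


def run_stability_experiment(
    cfg: StabilityConfig,
    pipeline: Callable[[str, int, int], object],
    out_dir: str | Path | None = None,
) -> list[StabilityReport]:
    """Run the replicate grid.

    ``pipeline(mode, n_files, replicate_seed)`` must return a network
    (anything :func:`~ppinet.netmetrics.compute_centrality` accepts).
    Replicate networks are generated once per (mode, n_files) cell and
    re-scored across the Top-N × metric sub-grid.  A failing replicate
    flags its configurations and the grid proceeds.
    """
    reports: list[StabilityReport] = []
    seeds = derive_replicate_seeds(cfg.seed, cfg.replicates)
    for mode in cfg.modes:
        for n_files in cfg.n_files:
            try:
                networks = [pipeline(mode, n_files, s) for s in seeds]
            except Exception:
                for top_n in cfg.top_n:
                    for metric in cfg.metrics:
                        reports.append(
                            StabilityReport(
                                mode=mode, n_files=n_files, top_n=top_n, metric=metric,
                                replicates=0, mgp=float("nan"), jaccard_mean=float("nan"),
                                jaccard_matrix=np.empty((0, 0)), fleiss_kappa=float("nan"),
                                kendall_ratio_positive=float("nan"), ks_multi=float("nan"),
                                degenerate={"replicate_failure"}, replicate_seeds=seeds,
                            )
                        )
                continue
            for top_n in cfg.top_n:
                for metric in cfg.metrics:
                    report = evaluate_replicates(
                        networks, top_n, metric, mode=mode, n_files=n_files,
                        replicate_seeds=seeds,
                    )
                    reports.append(report)
    if out_dir is not None:
        write_stability_csv(reports, Path(out_dir) / "stability.csv")
    return reports


def write_stability_csv(reports: Sequence[StabilityReport], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [r.row() for r in reports]
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)


def write_topn_csv(rows: Sequence[tuple[int, str, float]], path: str | Path) -> None:
    """Per-replicate Top-N table: (rank, node, value) rows."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["rank", "node", "value"])
        writer.writerows(rows)
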