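"""End-to-end run: proteomes in, one interaction network per genome out.

Stages: featurize every proteome → build the similarity predicate for the
chosen mode (Features threshold matching or the trained random forest) →
presence profiles across genomes → profile edges (RIS-sampled above the
trigger) and neighborhood edges → assembled, deduplicated networks → DOT
file per genome plus a JSON manifest recording configuration, seeds,
versions and per-stage counts.  Results are a pure function of (inputs,
configuration, master seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ppinet.context import (
    InteractionNetwork,
    NeighborhoodConfig,
    ProfileConfig,
    assemble_network,
    build_presence_profiles,
    neighborhood_interactions,
    profile_interactions,
)
from ppinet.features import FEATURE_LAYOUT_VERSION, featurize_many
from ppinet.io import (
    ProteinRecord,
    PropensityTable,
    load_default_propensity_table,
    read_proteome_fasta,
    write_network_dot,
)
from ppinet.ris import RISConfig
from ppinet.similarity import (
    FeatureMatchConfig,
    SimilarityModel,
    match_matrix,
    predict_matrix,
)

logger = logging.getLogger(__name__)


class FeaturePredicate:
    """Features-mode similarity over precomputed feature matrices."""

    def __init__(self, feature_matrices: dict[str, np.ndarray], cfg: FeatureMatchConfig):
        self.features = feature_matrices
        self.cfg = cfg

    def __call__(self, a: ProteinRecord, b: ProteinRecord) -> bool:
        va = self.features[a.genome_id][a.position]
        vb = self.features[b.genome_id][b.position]
        return bool(np.sum(np.abs(va - vb) <= self.cfg.tolerance) >= self.cfg.min_matches)

    def matrix(self, recs_a, recs_b) -> np.ndarray:
        A = self.features[recs_a[0].genome_id][[r.position for r in recs_a]]
        B = self.features[recs_b[0].genome_id][[r.position for r in recs_b]]
        return match_matrix(A, B, self.cfg)


class ModelPredicate:
    """ML-mode similarity over precomputed feature matrices."""

    def __init__(self, feature_matrices: dict[str, np.ndarray], model: SimilarityModel):
        self.features = feature_matrices
        self.model = model

    def __call__(self, a: ProteinRecord, b: ProteinRecord) -> bool:
        return bool(
            self.matrix([a], [b])[0, 0]
        )

    def matrix(self, recs_a, recs_b) -> np.ndarray:
        A = self.features[recs_a[0].genome_id][[r.position for r in recs_a]]
        B = self.features[recs_b[0].genome_id][[r.position for r in recs_b]]
        return predict_matrix(self.model, A, B)


@dataclass
class RunConfig:
    """Everything a run depends on; defaults are the tool's defaults."""

    input_dir: str | Path | None = None
    mode: str = "features"  # "features" or "ml"
    model_path: str | Path | None = None
    profile: ProfileConfig = field(default_factory=ProfileConfig)
    neighborhood: NeighborhoodConfig = field(default_factory=NeighborhoodConfig)
    ris: RISConfig = field(default_factory=RISConfig)
    feature_match: FeatureMatchConfig = field(default_factory=FeatureMatchConfig)
    output_dir: str | Path | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("features", "ml"):
            raise ValueError("mode must be 'features' or 'ml'")
        if self.mode == "ml" and self.model_path is None:
            raise ValueError("ml mode requires a model path (--model)")


def run_pipeline(
    cfg: RunConfig,
    genomes: list[list[ProteinRecord]] | None = None,
    table: PropensityTable | None = None,
    similar=None,
) -> tuple[dict[str, InteractionNetwork], dict]:
    """Run the full inference and return (networks per genome, manifest).

    ``genomes`` may be passed directly (otherwise every ``*.fasta`` /
    ``*.fa`` / ``*.faa`` file of ``cfg.input_dir`` is read; record order is
    gene order).  ``similar`` overrides the mode's predicate — used to
    inject a ground-truth predicate in validation runs.  When
    ``cfg.output_dir`` is set, one DOT file per genome and a
    ``manifest.json`` are written there.
    """
    if genomes is None:
        if cfg.input_dir is None:
            raise ValueError("either genomes or cfg.input_dir is required")
        paths = sorted(
            p for p in Path(cfg.input_dir).iterdir() if p.suffix in (".fasta", ".fa", ".faa")
        )
        if len(paths) < 2:
            raise ValueError(f"{cfg.input_dir}: need at least 2 genome FASTA files")
        genomes = [read_proteome_fasta(p) for p in paths]
    if len(genomes) < 2:
        raise ValueError("need at least 2 genomes")

    table = table or load_default_propensity_table()
    features = {g[0].genome_id: featurize_many(g, table) for g in genomes}

    if similar is None:
        if cfg.mode == "features":
            similar = FeaturePredicate(features, cfg.feature_match)
        else:
            model = SimilarityModel.load(cfg.model_path)
            if model.feature_layout_version != FEATURE_LAYOUT_VERSION:
                raise ValueError(
                    f"model layout {model.feature_layout_version!r} does not match "
                    f"featurizer {FEATURE_LAYOUT_VERSION!r}"
                )
            similar = ModelPredicate(features, model)

    presence = build_presence_profiles(genomes, similar)

    networks: dict[str, InteractionNetwork] = {}
    counts: dict[str, dict[str, int]] = {}
    for genome in genomes:
        gid = genome[0].genome_id
        ris_cfg = RISConfig(
            trigger=self_trigger(cfg),
            sublist_count_fraction=cfg.ris.sublist_count_fraction,
            connector_count=cfg.ris.connector_count,
            seed=cfg.seed,
        )
        profile_edges = profile_interactions(
            presence.genome(gid), cfg.profile, ris_cfg, seed=cfg.seed
        )
        others = [g for g in genomes if g[0].genome_id != gid]
        neigh_edges = neighborhood_interactions(genome, others, similar, cfg.neighborhood)
        net = assemble_network(
            {"profile": profile_edges, "neighborhood": neigh_edges},
            genome_id=gid,
            valid_ids={r.id for r in genome},
        )
        networks[gid] = net
        counts[gid] = {
            "proteins": len(genome),
            "profile_edges": len(profile_edges),
            "neighborhood_edges": len(neigh_edges),
            "nodes": len(net.nodes),
            "edges": net.n_edges,
        }

    from ppinet import __version__

    manifest = {
        "version": __version__,
        "feature_layout": FEATURE_LAYOUT_VERSION,
        "mode": cfg.mode,
        "seed": cfg.seed,
        "profile": asdict(cfg.profile),
        "neighborhood": asdict(cfg.neighborhood),
        "ris": asdict(cfg.ris),
        "feature_match": asdict(cfg.feature_match),
        "genomes": sorted(networks),
        "counts": counts,
    }

    if cfg.output_dir is not None:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for gid, net in networks.items():
            write_network_dot(net, out / f"{gid}.dot")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    return networks, manifest


def self_trigger(cfg: RunConfig) -> int:
    """The RIS trigger actually applied: the profile channel owns it."""
    return cfg.profile.ris_trigger if cfg.profile.ris_trigger is not None else max(2, cfg.ris.trigger)
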