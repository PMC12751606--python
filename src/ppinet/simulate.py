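"""Synthetic multi-genome proteomes with full ground truth.

The generator emulates the statistical structure the inference pipeline
assumes: families of homologous proteins at a controlled expected pairwise
identity (around the 65% labeling threshold used for classifier training),
gene order conserved across genomes up to seeded local shuffles, and
per-family presence/absence patterns that create phylogenetic-profile
groups of any desired size (including groups above the RIS trigger).

The substitution model is deliberately minimal: each ortholog is derived
from its family's ancestral sequence by independent per-site replacement
with a residue drawn from the background composition (no indels), so
"identity" of a pair is exactly the fraction of equal sites and every
label is analytically controllable without any alignment engine.  The
per-site replacement probability is ``1 - sqrt(target identity)``, which
makes the expected pairwise identity of two orthologs hit the target (up
to the small chance of two sites being replaced by the same residue).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ppinet.io import STANDARD_AMINO_ACIDS, ProteinRecord

GenomeSubset = tuple[int, ...]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic proteome set.

    presence_pattern
        One genome-index subset per family; families absent from a genome
        simply do not appear there.  ``None`` means every family is present
        in every genome (``n_families`` families).
    family_identity
        Target expected pairwise identity of two orthologs of one family.
    order_shuffle_rate
        Per-position probability of swapping adjacent genes in each
        genome's gene order (0 = perfectly conserved order).
    """

    n_genomes: int = 5
    n_families: int = 200
    family_identity: float = 0.8
    order_shuffle_rate: float = 0.0
    presence_pattern: tuple[GenomeSubset, ...] | None = None
    protein_length: int = 150
    residue_composition: tuple[float, ...] = field(
        default_factory=lambda: tuple([1 / 20] * 20)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 2:
            raise ValueError("need at least 2 genomes")
        if not 0 <= self.family_identity <= 1:
            raise ValueError("family_identity must be in [0, 1]")
        if not 0 <= self.order_shuffle_rate <= 1:
            raise ValueError("order_shuffle_rate must be in [0, 1]")
        if len(self.residue_composition) != 20 or not np.isclose(
            sum(self.residue_composition), 1.0
        ):
            raise ValueError("residue_composition must be 20 frequencies summing to 1")
        if self.protein_length < 3:
            raise ValueError("protein_length must be >= 3")
        if self.presence_pattern is not None:
            for subset in self.presence_pattern:
                if not subset:
                    raise ValueError("every family must be present in at least one genome")
                if any(g < 0 or g >= self.n_genomes for g in subset):
                    raise ValueError("presence_pattern indexes a genome that does not exist")

    @property
    def patterns(self) -> tuple[GenomeSubset, ...]:
        if self.presence_pattern is not None:
            return self.presence_pattern
        return tuple(tuple(range(self.n_genomes)) for _ in range(self.n_families))


@dataclass
class SimulatedProteomes:
    """Generated genomes plus every piece of ground truth."""

    config: SimulationConfig
    genomes: list[list[ProteinRecord]]
    genome_ids: list[str]
    family_of: dict[str, int]  # protein key (genome:id) -> family index
    true_profiles: dict[int, tuple[bool, ...]]  # family -> presence bits
    identities: dict[tuple[str, str], float]  # ortholog pair keys -> measured identity

    def truth_predicate(self) -> "TruthPredicate":
        return TruthPredicate(self.family_of)

    def write_fasta(self, out_dir: str | Path) -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for gid, records in zip(self.genome_ids, self.genomes):
            path = out_dir / f"{gid}.fasta"
            with path.open("w") as fh:
                for rec in records:
                    fh.write(
                        f">{rec.id} family={self.family_of[rec.key]} "
                        f"seed={self.config.seed}\n{rec.sequence}\n"
                    )
            paths.append(path)
        return paths


class TruthPredicate:
    """Ground-truth similarity: two proteins are similar iff same family."""

    def __init__(self, family_of: dict[str, int]):
        self.family_of = family_of

    def __call__(self, a: ProteinRecord, b: ProteinRecord) -> bool:
        return self.family_of[a.key] == self.family_of[b.key]

    def matrix(self, recs_a, recs_b) -> np.ndarray:
        fa = np.array([self.family_of[r.key] for r in recs_a])
        fb = np.array([self.family_of[r.key] for r in recs_b])
        return fa[:, None] == fb[None, :]


def _measured_identity(a: str, b: str) -> float:
    return sum(x == y for x, y in zip(a, b)) / len(a)


def simulate_proteome_set(cfg: SimulationConfig) -> SimulatedProteomes:
    """Generate the genomes and ground truth for one configuration.

    Deterministic given the config (including its seed); the same config
    twice yields byte-identical FASTA output.
    """
    rng = np.random.default_rng(cfg.seed)
    comp = np.asarray(cfg.residue_composition)
    alphabet = np.frombuffer(STANDARD_AMINO_ACIDS.encode(), dtype="S1")
    patterns = cfg.patterns
    n_fam = len(patterns)
    genome_ids = [f"genome{g:02d}" for g in range(cfg.n_genomes)]

    # per-site replacement probability targeting the expected pairwise identity
    mut_p = 1.0 - float(np.sqrt(cfg.family_identity))

    ancestors = rng.choice(alphabet, size=(n_fam, cfg.protein_length), p=comp)
    copies: dict[tuple[int, int], str] = {}
    for fam, subset in enumerate(patterns):
        for g in subset:
            seq = ancestors[fam].copy()
            mask = rng.random(cfg.protein_length) < mut_p
            if mask.any():
                seq[mask] = rng.choice(alphabet, size=int(mask.sum()), p=comp)
            copies[(fam, g)] = seq.tobytes().decode()

    genomes: list[list[ProteinRecord]] = []
    family_of: dict[str, int] = {}
    for g, gid in enumerate(genome_ids):
        fams = [fam for fam, subset in enumerate(patterns) if g in subset]
        order = list(range(len(fams)))
        for i in range(len(order) - 1):
            if rng.random() < cfg.order_shuffle_rate:
                order[i], order[i + 1] = order[i + 1], order[i]
        records = []
        for pos, idx in enumerate(order):
            fam = fams[idx]
            rec = ProteinRecord(
                id=f"p{fam:04d}",
                sequence=copies[(fam, g)],
                genome_id=gid,
                position=pos,
            )
            records.append(rec)
            family_of[rec.key] = fam
        genomes.append(records)

    true_profiles = {
        fam: tuple(g in subset for g in range(cfg.n_genomes))
        for fam, subset in enumerate(patterns)
    }
    identities: dict[tuple[str, str], float] = {}
    for fam, subset in enumerate(patterns):
        for i, ga in enumerate(subset):
            for gb in subset[i + 1 :]:
                key = (f"{genome_ids[ga]}:p{fam:04d}", f"{genome_ids[gb]}:p{fam:04d}")
                identities[key] = _measured_identity(copies[(fam, ga)], copies[(fam, gb)])

    return SimulatedProteomes(
        config=cfg,
        genomes=genomes,
        genome_ids=genome_ids,
        family_of=family_of,
        true_profiles=true_profiles,
        identities=identities,
    )


@dataclass
class PairDataset:
    """Labeled protein pairs for classifier training/evaluation."""

    pairs: list[tuple[ProteinRecord, ProteinRecord, bool]]
    identities: list[float]  # measured identity for positives, NaN for negatives

    @property
    def n_positive(self) -> int:
        return sum(1 for *_, label in self.pairs if label)

    @property
    def n_negative(self) -> int:
        return sum(1 for *_, label in self.pairs if not label)


def simulate_pair_dataset(
    cfg: SimulationConfig,
    identity_threshold: float = 0.65,
    ratio: int | None = None,
    seed: int | None = None,
) -> PairDataset:
    """Labeled pairs from a simulated proteome set.

    Positives are ortholog pairs whose *measured* identity exceeds the
    threshold; negatives are cross-family pairs.  ``ratio`` caps negatives
    at ratio × n_positive (seeded sample without replacement).
    """
    sim = simulate_proteome_set(cfg)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    by_key = {rec.key: rec for genome in sim.genomes for rec in genome}

    positives = [
        (by_key[a], by_key[b], sim.identities[(a, b)])
        for (a, b) in sorted(sim.identities)
        if sim.identities[(a, b)] > identity_threshold
    ]
    if not positives:
        raise ValueError(
            f"no ortholog pair exceeds identity {identity_threshold}; "
            "raise family_identity or lower the threshold"
        )

    all_records = sorted(by_key.values(), key=lambda r: r.key)
    n_neg_target = (ratio or cfg.n_genomes) * len(positives)
    negatives: list[tuple[ProteinRecord, ProteinRecord]] = []
    seen: set[tuple[str, str]] = set()
    attempts = 0
    while len(negatives) < n_neg_target and attempts < 50 * n_neg_target:
        attempts += 1
        i, j = rng.integers(0, len(all_records), size=2)
        a, b = all_records[i], all_records[j]
        if a.key >= b.key:
            continue
        if sim.family_of[a.key] == sim.family_of[b.key]:
            continue
        if (a.key, b.key) in seen:
            continue
        seen.add((a.key, b.key))
        negatives.append((a, b))
    if not negatives:
        raise ValueError("could not sample any cross-family negative pair")

    pairs = [(a, b, False) for a, b in negatives] + [(a, b, True) for a, b, _ in positives]
    identities = [float("nan")] * len(negatives) + [ident for *_, ident in positives]
    return PairDataset(pairs=pairs, identities=identities)
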