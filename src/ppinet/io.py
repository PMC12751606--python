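"""Readers and writers for every external representation the pipeline touches.

Proteome multi-FASTA files (one per genome; record order defines gene
order), the amino-acid propensity table, DOT network exports, plain
two-column edge lists, and the canonical undirected-pair normalization
shared by every module that handles edges.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

#: The twenty standard amino acids, alphabetical single-letter order.
STANDARD_AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Letters that may appear in real protein records but carry no propensity
#: value (ambiguity codes and rare residues).  They are tolerated in input
#: sequences; the featurizer decides how to score them.
NONSTANDARD_AMINO_ACIDS: str = "BJOUXZ"


@dataclass(frozen=True)
class ProteinRecord:
    """One protein of one genome, with its gene-order position."""

    id: str
    sequence: str
    genome_id: str
    position: int
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")

    @property
    def key(self) -> str:
        """Globally unique identifier (genome-qualified)."""
        return f"{self.genome_id}:{self.id}"


@dataclass(frozen=True)
class PropensityTable:
    """Physicochemical scales: one value per (scale, standard residue).

    ``scales`` order is significant — it fixes the feature-vector layout.
    """

    scales: tuple[str, ...]
    values: Mapping[tuple[str, str], float]

    def __post_init__(self) -> None:
        for scale in self.scales:
            for aa in STANDARD_AMINO_ACIDS:
                if (scale, aa) not in self.values:
                    raise ValueError(f"scale {scale!r} missing value for residue {aa!r}")

    def value(self, scale: str, aa: str) -> float:
        return self.values[(scale, aa)]


@dataclass
class EdgeSet:
    """An edge list as read from disk, remembering the source's convention.

    ``records`` preserves file order and duplicates; use
    :meth:`unique_undirected` for the normalized view.
    """

    records: list[tuple[str, str]] = field(default_factory=list)
    directed: bool = False

    def unique_undirected(self) -> set[tuple[str, str]]:
        return {canonical_pair(a, b) for a, b in self.records if a != b}


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Canonical key for an undirected pair: sorted endpoint tuple.

    Maps (a, b) and (b, a) to the same key; rejects self-loops.
    """
    if a == b:
        raise ValueError(f"self-loop {a!r}-{b!r} has no undirected form")
    return (a, b) if a < b else (b, a)


def read_proteome_fasta(path: str | Path, genome_id: str | None = None) -> list[ProteinRecord]:
    """Read one genome's proteins; record order defines gene order.

    The record id is the first whitespace-delimited header token.  Positions
    are consecutive 0..n-1 in file order.

    Raises
    ------
    ValueError
        on an empty file, a duplicate id, or non-letter residue characters.
    """
    path = Path(path)
    if genome_id is None:
        genome_id = path.stem
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for pos, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        seq = str(rec.seq).upper().replace("*", "")
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate protein id {rec.id!r}")
        seen.add(rec.id)
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        if not seq.isalpha():
            bad = sorted({c for c in seq if not c.isalpha()})
            raise ValueError(f"{path}: record {rec.id!r} contains non-letter characters {bad}")
        records.append(
            ProteinRecord(
                id=rec.id,
                sequence=seq,
                genome_id=genome_id,
                position=pos,
                description=rec.description,
            )
        )
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def read_propensity_table(path: str | Path) -> PropensityTable:
    """Parse a propensity table: header row of residue letters, then one
    named scale per row with 20 numbers in header column order."""
    path = Path(path)
    lines = [
        ln for ln in path.read_text().splitlines() if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise ValueError(f"{path}: empty propensity table")
    header = lines[0].split()
    columns = header[1:] if header and len(header[0]) > 1 else header
    if sorted(columns) != sorted(STANDARD_AMINO_ACIDS):
        raise ValueError(
            f"{path}: header must list the 20 standard amino acids, got {columns}"
        )
    scales: list[str] = []
    values: dict[tuple[str, str], float] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split()
        name, nums = fields[0], fields[1:]
        if len(nums) != 20:
            raise ValueError(f"{path}:{lineno}: scale {name!r} has {len(nums)} values, expected 20")
        if name in scales:
            raise ValueError(f"{path}:{lineno}: duplicate scale {name!r}")
        scales.append(name)
        for col, (aa, raw) in enumerate(zip(columns, nums), start=2):
            try:
                values[(name, aa)] = float(raw)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: column {col}: cannot parse {raw!r} as a number"
                ) from exc
    return PropensityTable(scales=tuple(scales), values=values)


def load_default_propensity_table() -> PropensityTable:
    """The bundled 10-scale table (indicator classes, masses, hydropathies)."""
    ref = resources.files("ppinet.data").joinpath("propensity.dat")
    with resources.as_file(ref) as path:
        return read_propensity_table(path)


_SANITIZE_RE = re.compile(r"[^A-Za-z0-9]")


def sanitize_dot_id(node: str) -> str:
    """Deterministic DOT-safe node identifier: non-alphanumerics become '_'."""
    return _SANITIZE_RE.sub("_", node)


def write_network_dot(network, path: str | Path) -> None:
    """Write an interaction network as an undirected DOT ``graph``.

    Edges appear once each, in canonical sorted order (equal networks
    produce byte-identical files); node ids are sanitized and quoted; the
    evidence labels of each edge go into its ``label`` attribute.
    """
    path = Path(path)
    lines = [f'graph "{sanitize_dot_id(network.genome_id)}" {{']
    for a, b in sorted(network.edges):
        sa, sb = sanitize_dot_id(a), sanitize_dot_id(b)
        evidence = sorted(network.evidence.get((a, b), ()))
        attr = f' [label="{",".join(evidence)}"]' if evidence else ""
        lines.append(f'    "{sa}" -- "{sb}"{attr};')
    lines.append("}")
    path.write_text("\n".join(lines) + "\n")


_DOT_EDGE_RE = re.compile(r'"([^"]+)"\s*--\s*"([^"]+)"(?:\s*\[label="([^"]*)"\])?')


def read_network_dot(path: str | Path):
    """Parse a DOT file written by :func:`write_network_dot` back into an
    :class:`~ppinet.context.InteractionNetwork` (round-trip support)."""
    from ppinet.context import InteractionNetwork

    path = Path(path)
    text = path.read_text()
    m = re.search(r'graph\s+"([^"]*)"', text)
    genome_id = m.group(1) if m else path.stem
    net = InteractionNetwork(genome_id=genome_id)
    for a, b, label in _DOT_EDGE_RE.findall(text):
        evidence = frozenset(label.split(",")) if label else frozenset()
        net.add_edge(a, b, evidence)
    return net


def read_edge_list(path: str | Path, directed: bool = False, delimiter: str | None = None) -> EdgeSet:
    """Read a two-column edge list (TSV/whitespace), optional header row.

    A header is recognised as a first row whose cells are among common
    column titles (node/source/target/protein a/b); data rows must have
    exactly two columns.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    header_tokens = {"node1", "node2", "source", "target", "node_a", "node_b", "protein1", "protein2"}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split(delimiter)
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            if lineno == 1 and {f.lower() for f in fields} <= header_tokens:
                continue
            records.append((fields[0], fields[1]))
    return EdgeSet(records=records, directed=directed)


def write_edge_list(pairs: Iterable[Sequence[str]], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")
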