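"""Pathway-network and gene-set input handling.

The prior-knowledge graph is a typed entity/interaction network in a
tab-delimited dialect:

* entity line: ``<etype>\\t<name>`` where etype is one of
  ``protein, complex, family, rna, mirna, abstract, other``;
* interaction line: ``<source>\\t<target>\\t<token>`` with tokens

  ========== ====================== ====
  token      relation               sign
  ========== ====================== ====
  ``-t>``    transcript-activate    +1
  ``-t|``    transcript-repress     -1
  ``-a>``    protein-activate       +1
  ``-a|``    protein-repress        -1
  ``component>`` component (complex) +1
  ``member>``    member (family)     +1
  ========== ====================== ====

Lines starting with ``#`` are comments.  Gene sets are standard GMT
(name, description, then gene symbols, tab-separated).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

__all__ = [
    "Entity",
    "Interaction",
    "PathwayNetwork",
    "GeneSetCollection",
    "PathwayParseError",
    "parse_pathway_file",
    "write_pathway_file",
    "read_gmt",
    "network_summary",
]

ETYPES = frozenset(
    {"protein", "complex", "family", "rna", "mirna", "abstract", "other"}
)

#: token -> (relation, sign)
RELATION_TOKENS: Mapping[str, tuple[str, int]] = {
    "-t>": ("transcript-activate", +1),
    "-t|": ("transcript-repress", -1),
    "-a>": ("protein-activate", +1),
    "-a|": ("protein-repress", -1),
    "component>": ("component", +1),
    "member>": ("member", +1),
}

RELATIONS = frozenset(rel for rel, _ in RELATION_TOKENS.values())
TOKEN_OF_RELATION = {rel: tok for tok, (rel, _) in RELATION_TOKENS.items()}
SIGN_OF_RELATION = {rel: sign for _, (rel, sign) in RELATION_TOKENS.items()}

#: relations acting at the transcript level (enter the target's rna layer)
TRANSCRIPT_RELATIONS = frozenset({"transcript-activate", "transcript-repress"})
#: relations acting at the protein/activity level
PROTEIN_RELATIONS = frozenset({"protein-activate", "protein-repress"})
MEMBERSHIP_RELATIONS = frozenset({"component", "member"})


class PathwayParseError(ValueError):
    """Raised on malformed pathway or GMT files; carries the line number."""


@dataclass(frozen=True, order=True)
class Entity:
    """A pathway node: protein, complex, family, rna, mirna, abstract or other."""

    name: str
    etype: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("entity name must be nonempty")
        if self.etype not in ETYPES:
            raise ValueError(f"unknown entity type {self.etype!r}")


@dataclass(frozen=True, order=True)
class Interaction:
    """A signed, typed edge between two declared entities."""

    source: str
    target: str
    relation: str

    def __post_init__(self) -> None:
        if self.relation not in RELATIONS:
            raise ValueError(f"unknown relation {self.relation!r}")

    @property
    def sign(self) -> int:
        """+1 for activating/membership relations, -1 for repressing."""
        return SIGN_OF_RELATION[self.relation]


@dataclass
class PathwayNetwork:
    """Typed entities plus signed typed interactions.

    Invariants: entity names unique; every interaction endpoint declared;
    no duplicate (source, target, relation) triples.
    """

    entities: dict[str, Entity] = field(default_factory=dict)
    interactions: list[Interaction] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[tuple[str, str, str]] = set()
        for it in self.interactions:
            for endpoint in (it.source, it.target):
                if endpoint not in self.entities:
                    raise ValueError(
                        f"interaction references undeclared entity {endpoint!r}"
                    )
            key = (it.source, it.target, it.relation)
            if key in seen:
                raise ValueError(f"duplicate interaction {key}")
            seen.add(key)
            if it.source == it.target and it.relation in MEMBERSHIP_RELATIONS:
                raise ValueError(
                    f"membership self-loop on {it.source!r} is not allowed"
                )

    # -- convenience views -------------------------------------------------
    @property
    def entity_names(self) -> list[str]:
        return list(self.entities)

    def proteins(self) -> list[str]:
        return [e.name for e in self.entities.values() if e.etype == "protein"]

    def etype_of(self, name: str) -> str:
        return self.entities[name].etype

    def neighbors(self, name: str) -> list[str]:
        """Direct partners in either direction, any relation, sorted."""
        out: set[str] = set()
        for it in self.interactions:
            if it.source == name:
                out.add(it.target)
            elif it.target == name:
                out.add(it.source)
        out.discard(name)
        return sorted(out)

    def skeleton(self):
        """Undirected connectivity skeleton over all interaction types."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.entities)
        g.add_edges_from((it.source, it.target) for it in self.interactions)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PathwayNetwork):
            return NotImplemented
        return (
            set(self.entities.values()) == set(other.entities.values())
            and set(self.interactions) == set(other.interactions)
        )


@dataclass
class GeneSetCollection:
    """Named gene sets with free-text descriptions (GMT contents)."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def drop(self, name: str) -> "GeneSetCollection":
        """Return a copy without the named set (e.g. a root ontology term)."""
        sets = {k: v for k, v in self.sets.items() if k != name}
        desc = {k: v for k, v in self.descriptions.items() if k != name}
        return GeneSetCollection(sets, desc)


def parse_pathway_file(path: str | Path) -> PathwayNetwork:
    """Parse the tab-delimited pathway dialect into a validated network.

    Entity lines need not precede the interactions that reference them —
    referential integrity is checked after reading the whole file.
    Duplicate interactions collapse to one with a warning.
    """
    path = Path(path)
    entities: dict[str, Entity] = {}
    interactions: list[Interaction] = []
    seen_edges: set[tuple[str, str, str]] = set()
    n_dupes = 0

    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 2:
                etype, name = fields
                if etype not in ETYPES:
                    raise PathwayParseError(
                        f"{path}:{lineno}: unknown entity type {etype!r}"
                    )
                if name in entities:
                    if entities[name].etype != etype:
                        raise PathwayParseError(
                            f"{path}:{lineno}: entity {name!r} redeclared "
                            f"with conflicting type {etype!r}"
                        )
                    continue
                entities[name] = Entity(name=name, etype=etype)
            elif len(fields) == 3:
                source, target, token = fields
                if token not in RELATION_TOKENS:
                    raise PathwayParseError(
                        f"{path}:{lineno}: unknown relation token {token!r}"
                    )
                relation, _ = RELATION_TOKENS[token]
                key = (source, target, relation)
                if key in seen_edges:
                    n_dupes += 1
                    continue
                seen_edges.add(key)
                interactions.append(
                    Interaction(source=source, target=target, relation=relation)
                )
            else:
                raise PathwayParseError(
                    f"{path}:{lineno}: expected 2 (entity) or 3 (interaction) "
                    f"tab-separated fields, got {len(fields)}"
                )

    if n_dupes:
        warnings.warn(
            f"{path}: collapsed {n_dupes} duplicate interaction line(s)",
            stacklevel=2,
        )
    for it in interactions:
        for endpoint in (it.source, it.target):
            if endpoint not in entities:
                raise PathwayParseError(
                    f"{path}: interaction {it.source}->{it.target} "
                    f"({it.relation}) references undeclared entity {endpoint!r}"
                )
    return PathwayNetwork(entities=entities, interactions=interactions)


def write_pathway_file(net: PathwayNetwork, path: str | Path) -> None:
    """Emit the same dialect the parser reads; round-trips bit-exactly."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for name in sorted(net.entities):
            fh.write(f"{net.entities[name].etype}\t{name}\n")
        for it in sorted(net.interactions):
            fh.write(f"{it.source}\t{it.target}\t{TOKEN_OF_RELATION[it.relation]}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one gene set per line, ``name\\tdesc\\tgene...``.

    Duplicate genes within a line are deduplicated; a duplicate set name
    is an error.
    """
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise PathwayParseError(
                    f"{path}:{lineno}: GMT line needs >=3 fields, got {len(fields)}"
                )
            name, desc = fields[0], fields[1]
            if name in sets:
                raise PathwayParseError(
                    f"{path}:{lineno}: duplicate gene-set name {name!r}"
                )
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise PathwayParseError(f"{path}:{lineno}: gene set {name!r} empty")
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for name in sets.sets:
            desc = sets.descriptions.get(name, "")
            genes = "\t".join(sorted(sets.sets[name]))
            fh.write(f"{name}\t{desc}\t{genes}\n")


def network_summary(net: PathwayNetwork) -> dict:
    """Entity and interaction totals, broken down by type and relation.

    Per-category counts always partition the totals exactly.
    """
    by_etype = Counter(e.etype for e in net.entities.values())
    by_relation = Counter(it.relation for it in net.interactions)
    return {
        "n_entities": len(net.entities),
        "entities_by_type": dict(by_etype),
        "n_interactions": len(net.interactions),
        "interactions_by_relation": dict(by_relation),
    }
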