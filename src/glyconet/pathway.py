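"""Glycan-structure grammar and pathway models for IgG Fc N-glycosylation.

IgG Fc glycans are biantennary complex-type structures built from a common
core (the G0 structure) by four glycosyltransferases, each adding a single
sugar unit per reaction:

* ``B4GalT1`` adds a galactose (G0 -> G1 -> G2),
* ``ST6Gal1`` adds a sialic acid onto a galactose (S1, S2),
* ``FUT8``    adds the core fucose (F),
* ``MGAT3``   adds the bisecting GlcNAc (N).

A glycan name such as ``G2FS1`` encodes the structure: two galactoses, core
fucose present, no bisecting GlcNAc, one sialic acid.  Because sialic acid
attaches to galactose, every valid structure satisfies ``sia <= gal``.

A :class:`PathwayModel` is a set of single-addition reactions over a panel
of structures.  The known pathway ships as a versioned JSON fixture
(:func:`load_pathway`); rule-based extensions (:class:`Rule`,
:func:`extend_model`, :func:`enumerate_models`) generate the candidate
pathway variants whose fit to the data is scored downstream.
"""

from __future__ import annotations

import itertools
import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "ENZYMES",
    "SUBCLASSES",
    "GlycanStructure",
    "Glycoform",
    "Reaction",
    "Rule",
    "PathwayModel",
    "GlycanNameError",
    "PathwayValidationError",
    "parse_glycan_name",
    "parse_glycoform",
    "single_addition",
    "load_pathway",
    "load_rules",
    "known_pathway",
    "default_rules",
    "candidate_reactions",
    "extend_model",
    "enumerate_models",
    "pathway_distance",
]

ENZYMES = ("FUT8", "B4GalT1", "MGAT3", "ST6Gal1")
SUBCLASSES = ("IgG1", "IgG2", "IgG4")

_NAME_RE = re.compile(r"^G(?P<gal>[0-2])(?P<fuc>F?)(?P<bis>N?)(?:S(?P<sia>[12]))?$")


class GlycanNameError(ValueError):
    """Raised when a glycan name does not parse or violates an invariant."""


class PathwayValidationError(ValueError):
    """Raised when a pathway definition fails validation."""


@dataclass(frozen=True, order=True)
class GlycanStructure:
    """A biantennary complex-type IgG glycan structure.

    Attributes
    ----------
    gal : int
        Number of galactoses (0-2).
    fuc : bool
        Core fucose present.
    bis : bool
        Bisecting GlcNAc present.
    sia : int
        Number of sialic acids (0-2); sialic acid attaches to galactose,
        so ``sia <= gal``.
    """

    gal: int
    fuc: bool = False
    bis: bool = False
    sia: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.gal <= 2:
            raise GlycanNameError(f"gal must be in 0..2, got {self.gal}")
        if not 0 <= self.sia <= 2:
            raise GlycanNameError(f"sia must be in 0..2, got {self.sia}")
        if self.sia > self.gal:
            raise GlycanNameError(
                f"sialic acid requires galactose: sia={self.sia} > gal={self.gal}"
            )

    @property
    def name(self) -> str:
        s = f"G{self.gal}"
        if self.fuc:
            s += "F"
        if self.bis:
            s += "N"
        if self.sia:
            s += f"S{self.sia}"
        return s

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


def parse_glycan_name(name: str) -> GlycanStructure:
    """Parse a glycan name like ``G0``, ``G2FS1`` or ``G1FN``.

    Grammar: ``G[0-2] [F] [N] [S1|S2]`` (tokens in this order).

    Raises
    ------
    GlycanNameError
        If the name is malformed or encodes sialylation without
        sufficient galactosylation (``sia > gal``).
    """
    m = _NAME_RE.match(name.strip())
    if m is None:
        raise GlycanNameError(f"malformed glycan name {name!r}")
    return GlycanStructure(
        gal=int(m.group("gal")),
        fuc=bool(m.group("fuc")),
        bis=bool(m.group("bis")),
        sia=int(m.group("sia") or 0),
    )


@dataclass(frozen=True, order=True)
class Glycoform:
    """A glycan structure attached to a specific IgG subclass."""

    subclass: str
    structure: GlycanStructure

    def __post_init__(self) -> None:
        if self.subclass not in SUBCLASSES:
            raise GlycanNameError(
                f"unknown IgG subclass {self.subclass!r}; expected one of {SUBCLASSES}"
            )

    @property
    def label(self) -> str:
        return f"{self.subclass}_{self.structure.name}"

    def __str__(self) -> str:  # pragma: no cover
        return self.label


def parse_glycoform(label: str) -> Glycoform:
    """Parse a glycoform label such as ``IgG1_G0F`` (space also accepted)."""
    parts = re.split(r"[_\s]+", label.strip(), maxsplit=1)
    if len(parts) != 2:
        raise GlycanNameError(f"malformed glycoform label {label!r}")
    return Glycoform(subclass=parts[0], structure=parse_glycan_name(parts[1]))


def single_addition(a: GlycanStructure, b: GlycanStructure) -> str | None:
    """Return the enzyme that converts ``a`` into ``b`` by one addition.

    Returns ``None`` if ``b`` does not differ from ``a`` by exactly one
    added sugar unit (one galactose, one sialic acid, the core fucose or
    the bisecting GlcNAc).
    """
    dgal = b.gal - a.gal
    dsia = b.sia - a.sia
    dfuc = int(b.fuc) - int(a.fuc)
    dbis = int(b.bis) - int(a.bis)
    deltas = (dgal, dfuc, dbis, dsia)
    if sorted(deltas) != [0, 0, 0, 1]:
        return None
    if dgal == 1:
        return "B4GalT1"
    if dsia == 1:
        return "ST6Gal1"
    if dfuc == 1:
        return "FUT8"
    return "MGAT3"


@dataclass(frozen=True, order=True)
class Reaction:
    """A single-sugar-unit enzymatic addition ``substrate -> product``."""

    substrate: GlycanStructure
    product: GlycanStructure
    enzyme: str

    def __post_init__(self) -> None:
        enzyme = single_addition(self.substrate, self.product)
        if enzyme is None:
            raise PathwayValidationError(
                f"{self.substrate.name} -> {self.product.name} is not a "
                "single-sugar-unit addition"
            )
        if enzyme != self.enzyme:
            raise PathwayValidationError(
                f"{self.substrate.name} -> {self.product.name} is performed by "
                f"{enzyme}, not {self.enzyme}"
            )

    def __str__(self) -> str:  # pragma: no cover
        return f"{self.substrate.name} -> {self.product.name} ({self.enzyme})"


# predicate keys understood by Rule.matches
_PRED_KEYS = {"gal_min", "gal_max", "sia_min", "sia_max", "fuc", "bis"}


@dataclass(frozen=True)
class Rule:
    """A family of candidate reactions sharing an enzyme and a substrate
    feature predicate (e.g. G1 = galactosylation of sialylated glycans)."""

    id: str
    enzyme: str
    predicate: Mapping[str, object]
    description: str = ""

    def __post_init__(self) -> None:
        if self.enzyme not in ENZYMES:
            raise PathwayValidationError(f"unknown enzyme {self.enzyme!r}")
        unknown = set(self.predicate) - _PRED_KEYS
        if unknown:
            raise PathwayValidationError(
                f"rule {self.id}: unknown predicate keys {sorted(unknown)}"
            )

    def matches(self, s: GlycanStructure) -> bool:
        p = self.predicate
        if "gal_min" in p and s.gal < p["gal_min"]:
            return False
        if "gal_max" in p and s.gal > p["gal_max"]:
            return False
        if "sia_min" in p and s.sia < p["sia_min"]:
            return False
        if "sia_max" in p and s.sia > p["sia_max"]:
            return False
        if "fuc" in p and s.fuc is not bool(p["fuc"]):
            return False
        if "bis" in p and s.bis is not bool(p["bis"]):
            return False
        return True

    def members(self, model: "PathwayModel") -> frozenset[Reaction]:
        """Candidate reactions of ``model`` performed by this rule's enzyme
        on substrates satisfying the predicate."""
        return frozenset(
            r
            for r in candidate_reactions(model)
            if r.enzyme == self.enzyme and self.matches(r.substrate)
        )


@dataclass(frozen=True)
class PathwayModel:
    """A set of single-addition reactions over a glycan panel.

    ``panel`` holds every structure drawn in the pathway (including
    unmeasured intermediates); ``measured`` restricts the panel per IgG
    subclass to the glycoforms quantified by the assay.
    """

    panel: frozenset[GlycanStructure]
    reactions: frozenset[Reaction]
    measured: Mapping[str, frozenset[GlycanStructure]] = field(default_factory=dict)
    rule_ids: frozenset[str] = frozenset()
    name: str = "pathway"

    def __post_init__(self) -> None:
        for r in self.reactions:
            if r.substrate not in self.panel or r.product not in self.panel:
                raise PathwayValidationError(
                    f"reaction {r} has an endpoint outside the panel"
                )
        for sub, structs in self.measured.items():
            if sub not in SUBCLASSES:
                raise PathwayValidationError(f"unknown subclass {sub!r}")
            extra = set(structs) - set(self.panel)
            if extra:
                raise PathwayValidationError(
                    f"measured structures not in panel for {sub}: "
                    f"{sorted(s.name for s in extra)}"
                )

    # -- graph views ---------------------------------------------------

    def graph(self) -> nx.Graph:
        """Undirected reaction graph (only path lengths are used)."""
        g = nx.Graph()
        g.add_nodes_from(self.panel)
        for r in self.reactions:
            g.add_edge(r.substrate, r.product, enzyme=r.enzyme)
        return g

    def distances(self) -> dict[GlycanStructure, dict[GlycanStructure, int]]:
        return dict(nx.all_pairs_shortest_path_length(self.graph()))

    def glycoforms(self) -> list[Glycoform]:
        """All measured glycoforms, ordered by subclass then structure name."""
        out: list[Glycoform] = []
        for sub in SUBCLASSES:
            for s in sorted(self.measured.get(sub, ()), key=lambda x: x.name):
                out.append(Glycoform(sub, s))
        return out

    @property
    def label(self) -> str:
        return "+".join(sorted(self.rule_ids)) if self.rule_ids else "known"


def load_pathway(path: str | Path | None = None) -> PathwayModel:
    """Load and validate a pathway definition JSON file.

    With no argument, loads the packaged known-pathway fixture.
    Every reaction edge must pass the single-addition check.
    """
    if path is None:
        text = (
            resources.files("glyconet.data").joinpath("known_pathway.json").read_text()
        )
        doc = json.loads(text)
    else:
        doc = json.loads(Path(path).read_text())
    panel = frozenset(parse_glycan_name(n) for n in doc["panel"])
    reactions = set()
    for sub_name, prod_name, enzyme in doc["reactions"]:
        s, p = parse_glycan_name(sub_name), parse_glycan_name(prod_name)
        reactions.add(Reaction(s, p, enzyme))  # raises if not a single addition
    measured = {
        sub: frozenset(parse_glycan_name(n) for n in names)
        for sub, names in doc.get("measured", {}).items()
    }
    return PathwayModel(
        panel=panel,
        reactions=frozenset(reactions),
        measured=measured,
        name=doc.get("name", "pathway"),
    )


def load_rules(path: str | Path | None = None) -> list[Rule]:
    """Load rule definitions; defaults to the packaged six-rule fixture."""
    if path is None:
        text = resources.files("glyconet.data").joinpath("rules.json").read_text()
        doc = json.loads(text)
    else:
        doc = json.loads(Path(path).read_text())
    return [
        Rule(
            id=r["id"],
            enzyme=r["enzyme"],
            predicate=dict(r["predicate"]),
            description=r.get("description", ""),
        )
        for r in doc["rules"]
    ]


def known_pathway() -> PathwayModel:
    """The packaged known IgG glycosylation pathway."""
    return load_pathway(None)


def default_rules() -> list[Rule]:
    """The packaged six extension rules F1, F2, F3, G1, N1, N2."""
    return load_rules(None)


def candidate_reactions(model: PathwayModel) -> frozenset[Reaction]:
    """All single-addition reactions over the panel absent from the model."""
    existing = model.reactions
    out = set()
    for a, b in itertools.permutations(model.panel, 2):
        enzyme = single_addition(a, b)
        if enzyme is None:
            continue
        r = Reaction(a, b, enzyme)
        if r not in existing:
            out.add(r)
    return frozenset(out)


def extend_model(model: PathwayModel, rules: Iterable[Rule]) -> PathwayModel:
    """Extend ``model`` with the member reactions of ``rules`` (idempotent)."""
    rules = list(rules)
    added: set[Reaction] = set()
    ids: set[str] = set(model.rule_ids)
    for rule in rules:
        if not isinstance(rule, Rule):
            raise PathwayValidationError(f"unknown rule {rule!r}")
        added |= rule.members(model)
        ids.add(rule.id)
    return PathwayModel(
        panel=model.panel,
        reactions=model.reactions | frozenset(added),
        measured=model.measured,
        rule_ids=frozenset(ids),
        name=model.name,
    )


def enumerate_models(
    model: PathwayModel, rules: Sequence[Rule]
) -> list[PathwayModel]:
    """All 2^k extensions of ``model`` over subsets of ``rules``.

    The empty subset yields the base model itself; each returned model is
    labeled by its rule-id set.
    """
    out = []
    for k in range(len(rules) + 1):
        for combo in itertools.combinations(rules, k):
            out.append(extend_model(model, combo))
    return out


def pathway_distance(
    model: PathwayModel, a: GlycanStructure, b: GlycanStructure
) -> float:
    """Minimum number of enzymatic steps between two panel structures.

    The reaction graph is treated as undirected; returns ``0`` iff
    ``a == b`` and ``inf`` if the structures are disconnected.
    """
    for s in (a, b):
        if s not in model.panel:
            raise PathwayValidationError(f"structure {s.name} not in panel")
    try:
        return float(nx.shortest_path_length(model.graph(), a, b))
    except nx.NetworkXNoPath:
        return float("inf")
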