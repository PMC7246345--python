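"""Evolutionary hierarchy, enzyme functional domains, residue annotation.

The evolutionary side classifies sequences top-down into a strict
superfamily > subgroup > family tree; only family-level nodes are
monofunctional.  The enzyme functional domain (EFD) is the pivot between
that hierarchy and the chemistry: the smallest contiguous sequence span
required for a specific function, linked to exactly one overall reaction
and carrying the functional (catalytic) residues.  Residue annotations use
a closed role vocabulary (general acid/base, proton shuttle, metal ligand,
...) shipped as a data file; bidirectional roles (a residue acting as both
general acid and general base over the full restoring transformation) are
part of the vocabulary.  Residue conservation is propagated upward through
the tree as far as the associated alignment columns support it: a node
gains a conserved slot only when every descendant EFD has a residue in that
alignment column, recording the residue type when unanimous and role-only
conservation otherwise.

Persistence is flat structured text (one TSV per entity kind), desk-scale
and diffable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .reactions import Reaction, ReactionScheme


class Level(str, Enum):
    SUPERFAMILY = "superfamily"
    SUBGROUP = "subgroup"
    FAMILY = "family"


_PARENT_LEVEL = {
    Level.FAMILY: Level.SUBGROUP,
    Level.SUBGROUP: Level.SUPERFAMILY,
    Level.SUPERFAMILY: None,
}


def residue_roles() -> frozenset[str]:
    """The closed functional-residue role vocabulary (packaged data file)."""
    text = resources.files("enznet.data").joinpath("residue_roles.txt").read_text()
    return frozenset(
        line.strip() for line in text.splitlines() if line.strip() and not line.startswith("#")
    )


@dataclass
class FunctionalResidue:
    """A catalytic residue: 1-based position, type, mechanistic role."""

    position: int
    amino_acid: str
    role: str
    alignment_column: Optional[str] = None

    def __post_init__(self) -> None:
        if self.role not in residue_roles():
            warnings.warn(
                f"residue role {self.role!r} is not in the shipped vocabulary; "
                "accepted with a warning",
                stacklevel=2,
            )


@dataclass
class ConservedSlot:
    """A residue slot conserved across every descendant EFD of a node."""

    alignment_column: str
    role: str
    amino_acid: Optional[str] = None  # None: role conserved, type is not


@dataclass
class HierarchyNode:
    name: str
    level: Level
    parent: Optional["HierarchyNode"] = None
    conserved_residues: list[ConservedSlot] = field(default_factory=list)

    def __post_init__(self) -> None:
        want = _PARENT_LEVEL[self.level]
        if want is None:
            if self.parent is not None:
                raise ValueError(f"superfamily {self.name!r} cannot have a parent")
        elif self.parent is not None and self.parent.level is not want:
            raise ValueError(
                f"{self.level.value} {self.name!r} must hang under a "
                f"{want.value}, got {self.parent.level.value}"
            )


@dataclass
class EnzymeFunctionalDomain:
    """The smallest contiguous sequence span performing one overall reaction."""

    efd_id: str
    protein_accession: str
    family: str  # family-level node name
    reaction_id: str
    sequence_span: tuple[int, int] = (1, 1)
    functional_residues: list[FunctionalResidue] = field(default_factory=list)

    def __post_init__(self) -> None:
        start, end = self.sequence_span
        if start > end or start < 1:
            raise ValueError(
                f"EFD {self.efd_id}: invalid sequence span {self.sequence_span}"
            )
        for r in self.functional_residues:
            if not (start <= r.position <= end):
                raise ValueError(
                    f"EFD {self.efd_id}: residue position {r.position} outside "
                    f"span {self.sequence_span}"
                )


class Hierarchy:
    """A strict family -> subgroup -> superfamily tree."""

    def __init__(self, nodes: Iterable[HierarchyNode] = ()):
        self.nodes: dict[str, HierarchyNode] = {}
        for n in nodes:
            self.add(n)

    def add(self, node: HierarchyNode) -> HierarchyNode:
        if node.name in self.nodes:
            raise ValueError(f"duplicate hierarchy node name {node.name!r}")
        self.nodes[node.name] = node
        return node

    def children(self, node: HierarchyNode) -> list[HierarchyNode]:
        return [n for n in self.nodes.values() if n.parent is node]

    def families_under(self, node: HierarchyNode) -> list[HierarchyNode]:
        if node.level is Level.FAMILY:
            return [node]
        out: list[HierarchyNode] = []
        for child in self.children(node):
            out.extend(self.families_under(child))
        return out

    def lineage(self, family_name: str) -> dict[str, str]:
        """family/subgroup/superfamily names for a family-level node."""
        node = self.nodes.get(family_name)
        out = {"family": "", "subgroup": "", "superfamily": ""}
        while node is not None:
            out[node.level.value] = node.name
            node = node.parent
        return out


# --------------------------------------------------------------------------
# Conservation propagation
# --------------------------------------------------------------------------


def propagate_conservation(
    hierarchy: Hierarchy, efds: Sequence[EnzymeFunctionalDomain]
) -> Hierarchy:
    """Attach conserved residue slots to every node, bottom-up.

    A slot is attached to a node iff every descendant EFD carries a residue
    in that alignment column with a unanimous role; the residue type is
    recorded only when unanimous (type conservation implies the stronger
    claim).  EFDs lacking alignment columns are excluded with a warning.
    The resulting slot sets are monotone: a node's slots are a subset of
    each child's.
    """
    by_family: dict[str, list[EnzymeFunctionalDomain]] = {}
    for efd in efds:
        if not any(r.alignment_column for r in efd.functional_residues):
            warnings.warn(
                f"EFD {efd.efd_id} has no alignment columns; excluded from "
                "conservation propagation",
                stacklevel=2,
            )
            continue
        by_family.setdefault(efd.family, []).append(efd)

    for node in hierarchy.nodes.values():
        node.conserved_residues = []
        members = [
            efd
            for fam in hierarchy.families_under(node)
            for efd in by_family.get(fam.name, [])
        ]
        if not members:
            continue
        columns: Optional[set[str]] = None
        for efd in members:
            cols = {r.alignment_column for r in efd.functional_residues if r.alignment_column}
            columns = cols if columns is None else (columns & cols)
        for col in sorted(columns or ()):
            roles = set()
            types = set()
            for efd in members:
                for r in efd.functional_residues:
                    if r.alignment_column == col:
                        roles.add(r.role)
                        types.add(r.amino_acid)
            if len(roles) != 1:
                continue  # not even the role is conserved in this column
            node.conserved_residues.append(
                ConservedSlot(
                    alignment_column=col,
                    role=roles.pop(),
                    amino_acid=types.pop() if len(types) == 1 else None,
                )
            )
    return hierarchy


# --------------------------------------------------------------------------
# Annotation table and EC handling
# --------------------------------------------------------------------------


def ec_truncations(ec: Optional[str]) -> dict[str, str]:
    """EC digit-wise truncations; malformed strings map to 'unassigned'.

    The third EC digit designates an overall enzyme reaction, the fourth the
    substrate specificity, so truncation by digit is the natural way to map
    reactions onto coarser chemistry classes.
    """
    out = {k: "unassigned" for k in ("ec1", "ec2", "ec3", "ec4")}
    if not ec:
        return out
    parts = ec.strip().split(".")
    if not 3 <= len(parts) <= 4 or not all(p.isdigit() or p == "-" for p in parts):
        return out
    for i, key in enumerate(("ec1", "ec2", "ec3", "ec4")):
        if i < len(parts) and parts[i] != "-":
            out[key] = ".".join(parts[: i + 1])
    return out


def annotation_table(
    efds: Sequence[EnzymeFunctionalDomain],
    hierarchy: Hierarchy,
    reactions: Sequence[Reaction] = (),
) -> pd.DataFrame:
    """One row per EFD: lineage labels plus EC truncations of its reaction.

    A reaction shared by families in two subgroups yields one row per EFD
    with the same reaction id, which is how shared-reaction nodes acquire
    multiple subgroup labels downstream.
    """
    ec_by_reaction = {r.reaction_id: r.ec_number for r in reactions}
    rows = []
    for efd in efds:
        lineage = hierarchy.lineage(efd.family)
        ec = ec_by_reaction.get(efd.reaction_id)
        row = {
            "entity_id": efd.efd_id,
            "protein_accession": efd.protein_accession,
            "reaction_id": efd.reaction_id,
            "family": lineage["family"] or efd.family,
            "subgroup": lineage["subgroup"] or "unassigned",
            "superfamily": lineage["superfamily"] or "unassigned",
            "ec_number": ec or "unassigned",
        }
        row.update(ec_truncations(ec))
        rows.append(row)
    return pd.DataFrame(rows)


def validate(
    hierarchy: Hierarchy,
    efds: Sequence[EnzymeFunctionalDomain] = (),
    schemes: Sequence[ReactionScheme] = (),
    reactions: Sequence[Reaction] = (),
) -> list[str]:
    """Enumerate dangling references (returns a list of human-readable issues)."""
    issues: list[str] = []
    family_names = {
        n.name for n in hierarchy.nodes.values() if n.level is Level.FAMILY
    }
    efd_ids = {e.efd_id for e in efds}
    reaction_ids = {r.reaction_id for r in reactions}
    for node in hierarchy.nodes.values():
        if node.parent is not None and node.parent.name not in hierarchy.nodes:
            issues.append(f"node {node.name!r}: dangling parent {node.parent.name!r}")
    for efd in efds:
        if efd.family not in family_names:
            issues.append(f"EFD {efd.efd_id}: unknown family {efd.family!r}")
        if reaction_ids and efd.reaction_id not in reaction_ids:
            issues.append(f"EFD {efd.efd_id}: unknown reaction {efd.reaction_id!r}")
    for scheme in schemes:
        if reaction_ids and scheme.reaction_id not in reaction_ids:
            issues.append(
                f"scheme {scheme.scheme_id}: unknown reaction {scheme.reaction_id!r}"
            )
        for ref in scheme.efd_refs:
            if efd_ids and ref not in efd_ids:
                issues.append(f"scheme {scheme.scheme_id}: unknown EFD {ref!r}")
    return issues


# --------------------------------------------------------------------------
# Flat-file persistence (TSV per entity kind)
# --------------------------------------------------------------------------


def save_ontology(
    directory,
    hierarchy: Hierarchy,
    efds: Sequence[EnzymeFunctionalDomain] = (),
    schemes: Sequence[ReactionScheme] = (),
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "name": n.name,
                "level": n.level.value,
                "parent": n.parent.name if n.parent else "",
            }
            for n in hierarchy.nodes.values()
        ]
    ).to_csv(directory / "hierarchy.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "efd_id": e.efd_id,
                "protein_accession": e.protein_accession,
                "family": e.family,
                "reaction_id": e.reaction_id,
                "span_start": e.sequence_span[0],
                "span_end": e.sequence_span[1],
            }
            for e in efds
        ]
    ).to_csv(directory / "efds.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "efd_id": e.efd_id,
                "position": r.position,
                "amino_acid": r.amino_acid,
                "role": r.role,
                "alignment_column": r.alignment_column or "",
            }
            for e in efds
            for r in e.functional_residues
        ]
    ).to_csv(directory / "residues.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "scheme_id": s.scheme_id,
                "reaction_id": s.reaction_id,
                "efd_refs": ",".join(s.efd_refs),
                "mechanism_notes": s.mechanism_notes,
            }
            for s in schemes
        ]
    ).to_csv(directory / "schemes.tsv", sep="\t", index=False)


def load_ontology(directory):
    """Load (hierarchy, efds, schemes) written by :func:`save_ontology`."""
    directory = Path(directory)
    hier_df = pd.read_csv(directory / "hierarchy.tsv", sep="\t", keep_default_na=False)
    hierarchy = Hierarchy()
    pending = list(hier_df.to_dict("records"))
    while pending:
        progressed = False
        rest = []
        for row in pending:
            if not row["parent"]:
                hierarchy.add(HierarchyNode(name=row["name"], level=Level(row["level"])))
                progressed = True
            elif row["parent"] in hierarchy.nodes:
                hierarchy.add(
                    HierarchyNode(
                        name=row["name"],
                        level=Level(row["level"]),
                        parent=hierarchy.nodes[row["parent"]],
                    )
                )
                progressed = True
            else:
                rest.append(row)
        if not progressed:
            raise ValueError(f"hierarchy has unresolvable parents: {rest}")
        pending = rest

    res_df = pd.read_csv(directory / "residues.tsv", sep="\t", keep_default_na=False)
    residues: dict[str, list[FunctionalResidue]] = {}
    for row in res_df.to_dict("records"):
        residues.setdefault(row["efd_id"], []).append(
            FunctionalResidue(
                position=int(row["position"]),
                amino_acid=row["amino_acid"],
                role=row["role"],
                alignment_column=row["alignment_column"] or None,
            )
        )
    efd_df = pd.read_csv(directory / "efds.tsv", sep="\t", keep_default_na=False)
    efds = [
        EnzymeFunctionalDomain(
            efd_id=row["efd_id"],
            protein_accession=row["protein_accession"],
            family=row["family"],
            reaction_id=row["reaction_id"],
            sequence_span=(int(row["span_start"]), int(row["span_end"])),
            functional_residues=residues.get(row["efd_id"], []),
        )
        for row in efd_df.to_dict("records")
    ]
    schemes_path = directory / "schemes.tsv"
    schemes: list[ReactionScheme] = []
    if schemes_path.exists():
        sch_df = pd.read_csv(schemes_path, sep="\t", keep_default_na=False)
        schemes = [
            ReactionScheme(
                scheme_id=row["scheme_id"],
                reaction_id=row["reaction_id"],
                efd_refs=[r for r in str(row["efd_refs"]).split(",") if r],
                mechanism_notes=row["mechanism_notes"],
            )
            for row in sch_df.to_dict("records")
        ]
    return hierarchy, efds, schemes
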