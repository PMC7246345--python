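"""Overall enzyme reactions: schemes, directionality, EC linkage, RXN I/O.

An overall reaction is the chemistry-side unit of classification: substrate
and product molecule lists, a directionality tag (reversible is the curation
default; unknown renders as ``?``), an optional EC number and external
cross-references held as opaque identifiers.  A reaction may be exhibited by
several reaction schemes (mechanisms) but is recorded once; deduplication is
supported by a canonical reaction key built from component canonical SMILES.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import pandas as pd

from .chem import Molecule, MoleculeParseError

logger = logging.getLogger(__name__)


class Directionality(str, Enum):
    FORWARD = "forward"
    BACKWARD = "backward"
    REVERSIBLE = "reversible"  # curation default
    UNKNOWN = "unknown"  # rendered as '?'

    @property
    def arrow(self) -> str:
        return {
            Directionality.FORWARD: "->",
            Directionality.BACKWARD: "<-",
            Directionality.REVERSIBLE: "<=>",
            Directionality.UNKNOWN: "?",
        }[self]


class ReactionType(str, Enum):
    COGNATE = "cognate"
    GENERIC = "generic"  # contains generic R-group (wildcard) atoms


@dataclass
class Reaction:
    """An overall reaction: substrates, products, direction, EC linkage."""

    reaction_id: str
    substrates: list[Molecule]
    products: list[Molecule]
    name: str = ""
    directionality: Directionality = Directionality.REVERSIBLE
    reaction_type: ReactionType = ReactionType.COGNATE
    ec_number: Optional[str] = None
    external_refs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.substrates or not self.products:
            raise ValueError(
                f"reaction {self.reaction_id!r}: substrate and product lists "
                "must both be non-empty"
            )
        if self.reaction_type is ReactionType.COGNATE and any(
            a.element == "*" for m in self.substrates + self.products for a in m.atoms
        ):
            self.reaction_type = ReactionType.GENERIC
        imbalance = reaction_atom_balance(self)
        if any(imbalance.values()):
            logger.warning(
                "reaction %s is not atom balanced: %s",
                self.reaction_id,
                dict(imbalance),
            )

    def reversed(self) -> "Reaction":
        flip = {
            Directionality.FORWARD: Directionality.BACKWARD,
            Directionality.BACKWARD: Directionality.FORWARD,
        }
        return Reaction(
            reaction_id=self.reaction_id,
            substrates=list(self.products),
            products=list(self.substrates),
            name=self.name,
            directionality=flip.get(self.directionality, self.directionality),
            reaction_type=self.reaction_type,
            ec_number=self.ec_number,
            external_refs=dict(self.external_refs),
        )

    def to_smiles(self) -> str:
        return (
            ".".join(m.smiles for m in self.substrates)
            + ">>"
            + ".".join(m.smiles for m in self.products)
        )

    def __repr__(self) -> str:
        return f"<Reaction {self.reaction_id} {self.to_smiles()}>"


@dataclass
class ReactionScheme:
    """A mechanism-level view: one overall reaction, the EFDs exhibiting it."""

    scheme_id: str
    reaction_id: str
    efd_refs: list[str] = field(default_factory=list)
    mechanism_notes: str = ""


# --------------------------------------------------------------------------
# Parsing / writing
# --------------------------------------------------------------------------


def parse_reaction_smiles(
    text: str, reaction_id: str = "", **kwargs
) -> Reaction:
    """Parse reaction SMILES ``s1.s2>>p1`` into a :class:`Reaction`."""
    if ">>" not in text:
        raise MoleculeParseError(f"missing '>>' separator in reaction SMILES: {text!r}")
    left, right = text.split(">>", 1)
    if not left.strip() or not right.strip():
        raise MoleculeParseError(f"empty reaction side in {text!r}")
    subs = [Molecule.from_smiles(s) for s in left.split(".") if s.strip()]
    prods = [Molecule.from_smiles(s) for s in right.split(".") if s.strip()]
    return Reaction(
        reaction_id=reaction_id or text, substrates=subs, products=prods, **kwargs
    )


def parse_rxn(text: str, reaction_id: str = "", **kwargs) -> Reaction:
    """Parse MDL RXN V2000 text.

    The counts line declares substrate/product component numbers; a mismatch
    with the embedded MOL blocks is a parse error.
    """
    lines = text.splitlines()
    if not lines or not lines[0].startswith("$RXN"):
        raise MoleculeParseError("RXN text must start with '$RXN' (line 1)")
    try:
        counts = lines[4].split()
        n_sub, n_prod = int(counts[0]), int(counts[1])
    except (IndexError, ValueError) as exc:
        raise MoleculeParseError(f"bad RXN counts line (line 5): {lines[4:5]}") from exc
    blocks = text.split("$MOL\n")[1:]
    if len(blocks) != n_sub + n_prod:
        raise MoleculeParseError(
            f"RXN counts line declares {n_sub}+{n_prod} components but "
            f"{len(blocks)} $MOL blocks found"
        )
    mols = [Molecule.from_molblock(b) for b in blocks]
    name = lines[1].strip() if len(lines) > 1 else ""
    return Reaction(
        reaction_id=reaction_id or name or "rxn",
        substrates=mols[:n_sub],
        products=mols[n_sub:],
        name=kwargs.pop("name", name),
        **kwargs,
    )


def write_rxn(reaction: Reaction) -> str:
    """Serialize to MDL RXN V2000 text."""
    parts = [
        "$RXN",
        reaction.name or reaction.reaction_id,
        "  enznet",
        "",
        f"{len(reaction.substrates):3d}{len(reaction.products):3d}",
    ]
    for mol in reaction.substrates + reaction.products:
        parts.append("$MOL")
        parts.append(mol.to_molblock().rstrip("\n"))
    return "\n".join(parts) + "\n"


# --------------------------------------------------------------------------
# Balance and identity
# --------------------------------------------------------------------------


def reaction_atom_balance(reaction: Reaction) -> Counter:
    """Per-element (substrate minus product) atom-count deltas, H included.

    An all-zero map means the reaction is balanced.  Imbalance is reported,
    never raised: curated cognate reactions should balance, generic R-group
    reactions may not.
    """
    delta: Counter = Counter()
    for m in reaction.substrates:
        delta.update(m.element_counts())
    for m in reaction.products:
        delta.subtract(m.element_counts())
    return Counter({el: d for el, d in delta.items() if d != 0})


def is_heavy_atom_balanced(reaction: Reaction) -> bool:
    return all(el == "H" for el in reaction_atom_balance(reaction))


def reaction_key(reaction: Reaction) -> str:
    """Canonical reaction key supporting the annotated-once rule.

    Sorted canonical SMILES of each side joined with ``>>``; reversible and
    unknown-direction reactions are normalized to the lexicographically
    smaller orientation so that a reaction and its reverse deduplicate.
    """
    left = ".".join(sorted(m.smiles for m in reaction.substrates))
    right = ".".join(sorted(m.smiles for m in reaction.products))
    key = f"{left}>>{right}"
    if reaction.directionality in (Directionality.REVERSIBLE, Directionality.UNKNOWN):
        rev = f"{right}>>{left}"
        key = min(key, rev)
    return key


def pair_key(id1: str, id2: str) -> str:
    """Stable key for the unordered pair of reaction/entity identifiers."""
    a, b = sorted((id1, id2))
    return f"{a}|{b}"


def deduplicate_reactions(reactions: Sequence[Reaction]) -> list[Reaction]:
    """Keep the first reaction per canonical key (annotated-once rule)."""
    seen: dict[str, Reaction] = {}
    for r in reactions:
        seen.setdefault(reaction_key(r), r)
    return list(seen.values())


# --------------------------------------------------------------------------
# Catalog export ("Browse by Reaction" style table)
# --------------------------------------------------------------------------


def reaction_catalog(
    reactions: Sequence[Reaction],
    schemes: Sequence[ReactionScheme] = (),
    efd_counts: Optional[dict[str, int]] = None,
) -> pd.DataFrame:
    """Tabulate reactions with type, EC, directionality and entity counts."""
    scheme_counts: Counter = Counter(s.reaction_id for s in schemes)
    efd_counts = efd_counts or {}
    rows = []
    for r in reactions:
        rows.append(
            {
                "reaction_id": r.reaction_id,
                "name": r.name,
                "reaction_type": r.reaction_type.value,
                "ec_number": r.ec_number or "",
                "directionality": r.directionality.value,
                "n_substrates": len(r.substrates),
                "n_products": len(r.products),
                "n_schemes": scheme_counts.get(r.reaction_id, 0),
                "n_efds": efd_counts.get(r.reaction_id, 0),
            }
        )
    return pd.DataFrame(rows)
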