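"""Molecules as attributed heavy-atom graphs, circular fingerprints, Tanimoto.

Molecules are parsed and written through RDKit (SMILES and MDL MOL V2000);
hydrogens are implicit and folded into per-atom hydrogen counts.  The
fingerprint is a multiset of hashed circular-environment features: for every
seed atom and every radius ``0..r`` one feature encoding the canonically
labeled subgraph within that graph distance of the seed.  Hashing is a stable
(blake2b) digest of the environment signature, so fingerprints are
reproducible across runs and platforms and independent of atom input order.
"""

from __future__ import annotations

import hashlib
from collections import Counter, deque
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

RDLogger.DisableLog("rdApp.*")  # parse errors are re-raised as Python errors


class MoleculeParseError(ValueError):
    """Raised for syntactically malformed SMILES or MOL input."""


class MoleculeValidationError(ValueError):
    """Raised for syntactically valid but chemically impossible input."""


class AtomStereo(str, Enum):
    NONE = "none"
    R = "R"
    S = "S"
    UNSPECIFIED = "unspecified"


class BondStereo(str, Enum):
    NONE = "none"
    E = "E"
    Z = "Z"
    UNSPECIFIED = "unspecified"


class BondOrder(str, Enum):
    SINGLE = "single"
    DOUBLE = "double"
    TRIPLE = "triple"
    AROMATIC = "aromatic"


_RD_ORDER = {
    Chem.BondType.SINGLE: BondOrder.SINGLE,
    Chem.BondType.DOUBLE: BondOrder.DOUBLE,
    Chem.BondType.TRIPLE: BondOrder.TRIPLE,
    Chem.BondType.AROMATIC: BondOrder.AROMATIC,
}


@dataclass(frozen=True)
class Atom:
    """A heavy atom: element symbol, charge, implicit-H count, CIP flag."""

    element: str
    index: int
    formal_charge: int = 0
    n_hydrogens: int = 0
    stereo: AtomStereo = AtomStereo.NONE


@dataclass(frozen=True)
class Bond:
    """A bond between two heavy atoms (unordered endpoint pair)."""

    endpoints: tuple[int, int]  # sorted atom indices
    order: BondOrder
    stereo: BondStereo = BondStereo.NONE


def _atom_from_rdkit(a: Chem.Atom) -> Atom:
    if a.GetChiralTag() == Chem.ChiralType.CHI_UNSPECIFIED:
        stereo = AtomStereo.NONE
    else:
        cip = a.GetPropsAsDict().get("_CIPCode")
        stereo = AtomStereo(cip) if cip in ("R", "S") else AtomStereo.UNSPECIFIED
    return Atom(
        element="*" if a.GetAtomicNum() == 0 else a.GetSymbol(),
        index=a.GetIdx(),
        formal_charge=a.GetFormalCharge(),
        n_hydrogens=a.GetTotalNumHs(),
        stereo=stereo,
    )


def _bond_from_rdkit(b: Chem.Bond) -> Bond:
    st = b.GetStereo()
    if st in (Chem.BondStereo.STEREOE, Chem.BondStereo.STEREOTRANS):
        stereo = BondStereo.E
    elif st in (Chem.BondStereo.STEREOZ, Chem.BondStereo.STEREOCIS):
        stereo = BondStereo.Z
    else:
        # STEREOANY ("either"/crossed bonds) is normalized to no-stereo: the
        # toolkit compares stereo by flag and treats unknown like absent.
        stereo = BondStereo.NONE
    i, j = sorted((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
    return Bond(endpoints=(i, j), order=_RD_ORDER[b.GetBondType()], stereo=stereo)


class Molecule:
    """An identity-keyed heavy-atom graph backed by an RDKit mol.

    Construct via :meth:`from_smiles`, :meth:`from_molblock` or
    :func:`parse_molecule`.  ``atoms`` and ``bonds`` are immutable views used
    by the fingerprint and atom-mapping machinery; ``smiles`` is the RDKit
    canonical SMILES and serves as the canonical-form key.
    """

    __slots__ = ("identifier", "_rdmol", "_atoms", "_bonds", "_smiles", "_adj")

    def __init__(self, rdmol: Chem.Mol, identifier: str = ""):
        Chem.AssignStereochemistry(rdmol, cleanIt=True, force=True)
        self.identifier = identifier
        self._rdmol = rdmol
        self._atoms = tuple(_atom_from_rdkit(a) for a in rdmol.GetAtoms())
        self._bonds = tuple(
            sorted(
                (_bond_from_rdkit(b) for b in rdmol.GetBonds()),
                key=lambda b: b.endpoints,
            )
        )
        self._smiles = Chem.MolToSmiles(rdmol)
        adj: dict[int, list[tuple[int, Bond]]] = {a.index: [] for a in self._atoms}
        for b in self._bonds:
            i, j = b.endpoints
            adj[i].append((j, b))
            adj[j].append((i, b))
        self._adj = adj

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_smiles(cls, smiles: str, identifier: str = "") -> "Molecule":
        raw = Chem.MolFromSmiles(smiles, sanitize=False)
        if raw is None:
            raise MoleculeParseError(f"unparseable SMILES: {smiles!r}")
        try:
            Chem.SanitizeMol(raw)
        except Exception as exc:  # noqa: BLE001 - RDKit raises several types
            raise MoleculeValidationError(f"invalid structure {smiles!r}: {exc}") from exc
        return cls(raw, identifier=identifier)

    @classmethod
    def from_molblock(cls, text: str, identifier: str = "") -> "Molecule":
        raw = Chem.MolFromMolBlock(text, sanitize=False, removeHs=False)
        if raw is None:
            raise MoleculeParseError("unparseable MOL block (check counts line / V2000 tag)")
        try:
            Chem.SanitizeMol(raw)
            raw = Chem.RemoveHs(raw)
        except Exception as exc:  # noqa: BLE001
            raise MoleculeValidationError(f"invalid MOL structure: {exc}") from exc
        if not identifier:
            identifier = (text.splitlines() or [""])[0].strip()
        return cls(raw, identifier=identifier)

    def to_smiles(self) -> str:
        return self._smiles

    def to_molblock(self) -> str:
        mol = Chem.Mol(self._rdmol)
        # Mark stereo-capable double bonds without assigned stereo as
        # "either" so the 2D coordinates written below do not smuggle in
        # cis/trans assignments on re-parse.
        Chem.FindPotentialStereoBonds(mol)
        AllChem.Compute2DCoords(mol)  # wedge bonds need coordinates for stereo
        mol.SetProp("_Name", self.identifier or "")
        return Chem.MolToMolBlock(mol)

    # ----------------------------------------------------------- properties

    @property
    def atoms(self) -> tuple[Atom, ...]:
        return self._atoms

    @property
    def bonds(self) -> tuple[Bond, ...]:
        return self._bonds

    @property
    def smiles(self) -> str:
        return self._smiles

    @property
    def n_atoms(self) -> int:
        return len(self._atoms)

    def neighbors(self, idx: int) -> list[tuple[int, Bond]]:
        return self._adj[idx]

    def bond_between(self, i: int, j: int) -> Optional[Bond]:
        for k, b in self._adj[i]:
            if k == j:
                return b
        return None

    def element_counts(self, include_hydrogens: bool = True) -> Counter:
        counts: Counter = Counter(a.element for a in self._atoms)
        if include_hydrogens:
            h = sum(a.n_hydrogens for a in self._atoms)
            if h:
                counts["H"] += h
        return counts

    def canonicalize(self) -> "Molecule":
        """Return the canonical-atom-order form (idempotent)."""
        return Molecule.from_smiles(self._smiles, identifier=self.identifier)

    def canonical_ranks(self) -> tuple[int, ...]:
        """A deterministic total order on atoms (tie-broken canonical ranks)."""
        return tuple(Chem.CanonicalRankAtoms(self._rdmol, breakTies=True))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Molecule) and self._smiles == other._smiles

    def __hash__(self) -> int:
        return hash(self._smiles)

    def __repr__(self) -> str:
        ident = f" {self.identifier!r}" if self.identifier else ""
        return f"<Molecule{ident} {self._smiles}>"


def parse_molecule(source: str, identifier: str = "") -> Molecule:
    """Parse SMILES or MDL MOL V2000 text (format auto-detected)."""
    if "V2000" in source or "M  END" in source or "\n" in source.strip():
        return Molecule.from_molblock(source, identifier=identifier)
    return Molecule.from_smiles(source.strip(), identifier=identifier)


def write_molecule(mol: Molecule, format: str = "SMILES") -> str:
    """Serialize to ``SMILES`` or ``MOL`` (MDL V2000) text."""
    fmt = format.upper()
    if fmt == "SMILES":
        return mol.to_smiles()
    if fmt == "MOL":
        return mol.to_molblock()
    raise ValueError(f"unsupported molecule format: {format!r}")


# --------------------------------------------------------------------------
# Circular fingerprints
# --------------------------------------------------------------------------

DEFAULT_RADIUS = 2


def _stable_hash(payload: str) -> int:
    return int.from_bytes(hashlib.blake2b(payload.encode(), digest_size=8).digest(), "big")


@dataclass(frozen=True)
class Fingerprint:
    """A multiset of hashed circular-environment features.

    The feature count grows with molecule size and radius; two fingerprints
    are comparable only when computed at the same radius with the same
    hashing scheme (enforced by :func:`tanimoto`).
    """

    features: Counter
    radius: int

    def __len__(self) -> int:
        return sum(self.features.values())

    def as_set(self) -> frozenset:
        return frozenset(self.features)


def _environment_signature(
    mol: Molecule, seed: int, ball: Mapping[int, int]
) -> str:
    """Canonical signature of the subgraph induced on ``ball`` (atom -> dist).

    Weisfeiler-Lehman refinement seeded with (element, charge, H count,
    stereo flag, distance-from-seed layer); invariant under atom reordering.
    """
    labels = {
        v: f"{mol.atoms[v].element}|{mol.atoms[v].formal_charge}|"
        f"{mol.atoms[v].n_hydrogens}|{mol.atoms[v].stereo.value}|d{d}"
        for v, d in ball.items()
    }
    edges = []
    for v in ball:
        for u, b in mol.neighbors(v):
            if u in ball and u > v:
                edges.append((v, u, b))
    for _ in range(max(1, len(ball))):
        new = {}
        for v in ball:
            nbrs = sorted(
                f"{b.order.value}~{labels[u]}"
                for u, b in mol.neighbors(v)
                if u in ball
            )
            new[v] = hashlib.blake2b(
                ("@".join([labels[v]] + nbrs)).encode(), digest_size=8
            ).hexdigest()
        if new == labels:
            break
        labels = new
    edge_sigs = sorted(
        "-".join(sorted((labels[v], labels[u])) + [b.order.value, b.stereo.value])
        for v, u, b in edges
    )
    return ";".join([labels[seed], ",".join(sorted(labels.values())), ",".join(edge_sigs)])


def circular_fingerprint(
    mol: Molecule,
    radius: int = DEFAULT_RADIUS,
    atom_subset: Optional[Iterable[int]] = None,
    tags: Sequence[str] = (),
    seed_tags: Optional[Mapping[int, Sequence[str]]] = None,
) -> Fingerprint:
    """Circular fingerprint seeded at ``atom_subset`` (default: all atoms).

    One feature per (seed atom, radius 0..``radius``): a stable hash of the
    canonical signature of the environment within that graph distance of the
    seed.  ``tags`` (global) and ``seed_tags`` (per seed atom) are extra
    strings mixed into each feature hash; the reaction-center metric uses
    them to tag features by reaction side and bond-change kind.
    """
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    if atom_subset is None:
        seeds = [a.index for a in mol.atoms]
    else:
        seeds = sorted(set(atom_subset))
        bad = [s for s in seeds if s < 0 or s >= mol.n_atoms]
        if bad:
            raise ValueError(f"atom_subset indices out of range: {bad}")
    features: Counter = Counter()
    for seed in seeds:
        extra = tuple(tags) + tuple(seed_tags.get(seed, ()) if seed_tags else ())
        dist = {seed: 0}
        queue = deque([seed])
        while queue:
            v = queue.popleft()
            if dist[v] == radius:
                continue
            for u, _ in mol.neighbors(v):
                if u not in dist:
                    dist[u] = dist[v] + 1
                    queue.append(u)
        for r in range(radius + 1):
            ball = {v: d for v, d in dist.items() if d <= r}
            sig = _environment_signature(mol, seed, ball)
            features[_stable_hash(f"env|r{r}|{sig}|{'|'.join(extra)}")] += 1
    return Fingerprint(features=features, radius=radius)


def tanimoto(a: Fingerprint, b: Fingerprint, multiset: bool = True) -> float:
    """Tanimoto similarity |A n B| / |A u B| over feature multisets.

    ``multiset=False`` switches to set semantics (duplicate environments
    collapsed).  Two empty fingerprints score 0.0 (disjoint by convention).
    """
    if a.radius != b.radius:
        raise ValueError(f"incompatible fingerprint radii: {a.radius} != {b.radius}")
    fa, fb = a.features, b.features
    if not multiset:
        fa, fb = Counter(set(fa)), Counter(set(fb))
    inter = sum((fa & fb).values())
    union = sum((fa | fb).values())
    return inter / union if union else 0.0
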