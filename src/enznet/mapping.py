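"""Atom-atom mapping, bond-change extraction, and reaction similarity.

The mapping is an element-respecting bijection between the heavy atoms of
the substrate and product sides of a balanced reaction, chosen to minimize
the number of implied bond changes (minimum chemical distance).  The search
is a depth-first branch-and-bound over element-partitioned assignments with
an admissible incident-bond lower bound and an explicit node-expansion
budget; among equal-cost mappings the lexicographically smallest under
canonical atom ranks is returned, making results deterministic and
independent of input atom order.

Three pairwise reaction similarity metrics are built on top of the mapping:

* ``reaction_center_similarity`` -- Tanimoto between circular fingerprints
  seeded only at reaction-center atoms (substrate- and product-side
  environments pooled, features tagged by side and change kind);
* ``bond_change_similarity``     -- Tanimoto between environment-free
  multisets of bond-change descriptors (kind + element pair + orders, plus
  per-element implicit-hydrogen deltas);
* ``small_molecule_similarity``  -- optimal one-to-one assignment between
  whole-molecule fingerprints of the chosen reaction side(s).

Reversible (and unknown-direction) reactions are orientation-normalized
before comparison so that a reaction written in either direction yields the
same scores.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import linear_sum_assignment

from .chem import (
    AtomStereo,
    BondOrder,
    BondStereo,
    DEFAULT_RADIUS,
    Fingerprint,
    Molecule,
    circular_fingerprint,
    tanimoto,
)
from .reactions import (
    Directionality,
    Reaction,
    is_heavy_atom_balanced,
    pair_key,
    reaction_atom_balance,
)

AtomCoord = tuple[int, int]  # (molecule index, atom index) on one side

DEFAULT_BUDGET = 500_000


class MappingError(ValueError):
    """Raised when a reaction cannot be atom-mapped."""


class MappingBudgetError(MappingError):
    """Raised when the branch-and-bound node-expansion budget is exhausted."""


class ChangeKind(str, Enum):
    FORMED = "formed"
    CLEAVED = "cleaved"
    ORDER_CHANGED = "order_changed"
    STEREO_CHANGED = "stereo_changed"


@dataclass(frozen=True)
class AtomMapping:
    """A bijection between substrate and product heavy-atom coordinates."""

    pairs: tuple[tuple[AtomCoord, AtomCoord], ...]
    cost: int

    def as_dict(self) -> dict[AtomCoord, AtomCoord]:
        return dict(self.pairs)

    def inverse(self) -> "AtomMapping":
        return AtomMapping(
            pairs=tuple(sorted((p, s) for s, p in self.pairs)), cost=self.cost
        )


@dataclass(frozen=True)
class BondChange:
    """One chemical change implied by the mapping.

    Formed changes carry product atoms only, cleaved changes substrate atoms
    only; order changes carry both with ``order_before != order_after``.
    Stereo changes cover both bond (E/Z) flags and atom (R/S) flags; an
    atom-stereo change is recorded with a single-coordinate tuple.
    """

    kind: ChangeKind
    elements: tuple[str, ...]
    substrate_atoms: Optional[tuple[AtomCoord, ...]] = None
    product_atoms: Optional[tuple[AtomCoord, ...]] = None
    order_before: Optional[BondOrder] = None
    order_after: Optional[BondOrder] = None

    def descriptor(self) -> tuple:
        """Environment-free descriptor: kind + sorted element pair + orders."""
        return (
            self.kind.value,
            self.elements,
            self.order_before.value if self.order_before else "",
            self.order_after.value if self.order_after else "",
        )


# --------------------------------------------------------------------------
# Atom-atom mapping search
# --------------------------------------------------------------------------


def _atom_flags(stereo: AtomStereo) -> AtomStereo:
    return AtomStereo.NONE if stereo is AtomStereo.UNSPECIFIED else stereo


def _bond_flags(stereo: BondStereo) -> BondStereo:
    return BondStereo.NONE if stereo is BondStereo.UNSPECIFIED else stereo


class _Side:
    """Flattened one-side view of a reaction with canonical atom order."""

    def __init__(self, molecules: Sequence[Molecule]):
        self.molecules = molecules
        order = sorted(range(len(molecules)), key=lambda i: (molecules[i].smiles, i))
        self.coords: list[AtomCoord] = []
        self.canon_pos: dict[AtomCoord, int] = {}
        for mi in order:
            ranks = molecules[mi].canonical_ranks()
            for ai in sorted(range(molecules[mi].n_atoms), key=lambda a: ranks[a]):
                self.canon_pos[(mi, ai)] = len(self.coords)
                self.coords.append((mi, ai))

    def atom(self, coord: AtomCoord):
        return self.molecules[coord[0]].atoms[coord[1]]

    def neighbors(self, coord: AtomCoord):
        mi, ai = coord
        return [((mi, u), b) for u, b in self.molecules[mi].neighbors(ai)]

    def bond(self, a: AtomCoord, b: AtomCoord):
        if a[0] != b[0]:
            return None
        return self.molecules[a[0]].bond_between(a[1], b[1])

    def incident_profile(self, coord: AtomCoord) -> Counter:
        return Counter(
            (b.order.value, self.atom(n).element) for n, b in self.neighbors(coord)
        )


def _elements_match(e1: str, e2: str) -> bool:
    return e1 == e2 or e1 == "*" or e2 == "*"


def _pair_lower_bound(sub: _Side, prod: _Side, s: AtomCoord, p: AtomCoord) -> int:
    """Admissible bound on bond changes incident to the pair s -> p."""
    ps, pp = sub.incident_profile(s), prod.incident_profile(p)
    inter = sum((ps & pp).values())
    return max(sum(ps.values()), sum(pp.values())) - inter


def _reaction_structure_key(reaction: Reaction) -> tuple:
    """Exact ordered graph identity of both sides (atom order included).

    Two reactions with equal keys have identical atom coordinates, so a
    memoized mapping transfers verbatim.
    """
    return (
        tuple((m.atoms, m.bonds) for m in reaction.substrates),
        tuple((m.atoms, m.bonds) for m in reaction.products),
    )


_MAPPING_CACHE: dict[tuple, AtomMapping] = {}
_MAPPING_CACHE_MAX = 4096


def map_atoms(reaction: Reaction, budget: int = DEFAULT_BUDGET) -> AtomMapping:
    """Minimum-chemical-distance atom mapping of a heavy-atom-balanced reaction.

    Returns the element-respecting bijection minimizing the number of implied
    bond changes (stereo-flag changes included); ties are broken toward the
    lexicographically smallest mapping under canonical atom ranks.  Raises
    :class:`MappingError` for unbalanced reactions and
    :class:`MappingBudgetError` if the search budget is exceeded.
    """
    if not is_heavy_atom_balanced(reaction):
        raise MappingError(
            f"reaction {reaction.reaction_id!r} is not heavy-atom balanced "
            f"(delta {dict(reaction_atom_balance(reaction))}); run "
            "reaction_atom_balance and fix the components first"
        )
    cache_key = _reaction_structure_key(reaction)
    cached = _MAPPING_CACHE.get(cache_key)
    if cached is not None:
        return cached
    sub = _Side(reaction.substrates)
    prod = _Side(reaction.products)
    n = len(sub.coords)

    # candidate product atoms per substrate atom, canonical order
    candidates: list[list[AtomCoord]] = []
    for s in sub.coords:
        es = sub.atom(s).element
        cands = [p for p in prod.coords if _elements_match(es, prod.atom(p).element)]
        if not cands:
            raise MappingError(
                f"no product atom available for substrate atom {s} ({es})"
            )
        candidates.append(cands)

    lb_pair = {
        (i, p): _pair_lower_bound(sub, prod, sub.coords[i], p)
        for i in range(n)
        for p in candidates[i]
    }

    # Admissible bound on the increment charged when position i is assigned:
    # every substrate bond from s_i to an earlier-ordered atom is either
    # preserved (requiring a same-(order, element) bond at the candidate) or
    # costs at least one change, so the multiset deficit is a lower bound.
    pos_of = {s: i for i, s in enumerate(sub.coords)}
    earlier_profile: list[Counter] = []
    for i, s in enumerate(sub.coords):
        earlier_profile.append(
            Counter(
                (b.order.value, sub.atom(nb).element)
                for nb, b in sub.neighbors(s)
                if pos_of[nb] < i
            )
        )
    full_profile = {p: prod.incident_profile(p) for p in prod.coords}
    has_wildcard = any(
        a.element == "*" for m in reaction.substrates + reaction.products for a in m.atoms
    )
    if has_wildcard:  # wildcards defeat element-profile reasoning; stay admissible
        lb_charge = {(i, p): 0 for i in range(n) for p in candidates[i]}
    else:
        lb_charge = {
            (i, p): sum((earlier_profile[i] - full_profile[p]).values())
            for i in range(n)
            for p in candidates[i]
        }
    static_min = [min(lb_charge[(i, p)] for p in candidates[i]) for i in range(n)]
    suffix_lb = [0] * (n + 1)
    for i in range(n - 1, -1, -1):
        suffix_lb[i] = suffix_lb[i + 1] + static_min[i]

    sub_nbrs = [sub.neighbors(s) for s in sub.coords]
    prod_nbr_map = {p: prod.neighbors(p) for p in prod.coords}

    # Second admissible bound: an unsettled substrate bond (charged at the
    # later-position endpoint, still unassigned at depth i) is either
    # preserved by an unsettled product bond with the same (order, element
    # pair) or costs at least one change, and symmetrically for unsettled
    # product bonds; the larger multiset deficit bounds the remaining cost.
    def _bond_key(side: _Side, a: AtomCoord, bcoord: AtomCoord, b) -> tuple:
        e1, e2 = sorted((side.atom(a).element, side.atom(bcoord).element))
        return (b.order.value, e1, e2)

    sub_bond_items = []  # (charge position, key)
    for mi, mol in enumerate(reaction.substrates):
        for b in mol.bonds:
            c1, c2 = (mi, b.endpoints[0]), (mi, b.endpoints[1])
            pos = max(pos_of[c1], pos_of[c2])
            sub_bond_items.append((pos, _bond_key(sub, c1, c2, b)))
    sub_rem_at: list[Counter] = [Counter() for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        sub_rem_at[i] = sub_rem_at[i + 1] + Counter(
            k for pos, k in sub_bond_items if pos == i
        )
    prod_bond_list = []  # (c1, c2, key)
    for mi, mol in enumerate(reaction.products):
        for b in mol.bonds:
            c1, c2 = (mi, b.endpoints[0]), (mi, b.endpoints[1])
            prod_bond_list.append((c1, c2, _bond_key(prod, c1, c2, b)))

    def bond_multiset_bound(i: int, inv: dict) -> int:
        if has_wildcard:
            return 0
        s_rem = sub_rem_at[i]
        p_rem = Counter(
            k for c1, c2, k in prod_bond_list if c1 not in inv or c2 not in inv
        )
        return max(
            sum((s_rem - p_rem).values()), sum((p_rem - s_rem).values())
        )

    def increment(i: int, p: AtomCoord, assign: dict, inv: dict) -> int:
        s = sub.coords[i]
        cost = 0
        for (sn, sb) in sub_nbrs[i]:
            pn = assign.get(sn)
            if pn is None:
                continue
            pb = prod.bond(p, pn)
            if pb is None:
                cost += 1  # cleaved
            elif pb.order is not sb.order:
                cost += 1  # order change
            elif _bond_flags(pb.stereo) is not _bond_flags(sb.stereo):
                cost += 1  # bond stereo change
        for (pn, _pb) in prod_nbr_map[p]:
            sn = inv.get(pn)
            if sn is not None and sub.bond(s, sn) is None:
                cost += 1  # formed
        sa, pa = sub.atom(s), prod.atom(p)
        if sa.element != "*" and pa.element != "*":
            if _atom_flags(sa.stereo) is not _atom_flags(pa.stereo):
                cost += 1  # atom stereo change
        return cost

    # greedy pass for the initial upper bound (optimality not assumed)
    g_assign: dict[AtomCoord, AtomCoord] = {}
    g_inv: dict[AtomCoord, AtomCoord] = {}
    g_cost = 0
    for i in range(n):
        best_p, best_key, best_p_inc = None, None, 0
        for p in candidates[i]:
            if p in g_inv:
                continue
            inc = increment(i, p, g_assign, g_inv)
            key = (inc + lb_pair[(i, p)], prod.canon_pos[p])
            if best_key is None or key < best_key:
                best_key, best_p, best_p_inc = key, p, inc
        g_assign[sub.coords[i]] = best_p
        g_inv[best_p] = sub.coords[i]
        g_cost += best_p_inc

    # Iterative deepening on the cost target: for the first feasible target
    # the first solution found by the lexicographic DFS is the
    # lexicographically smallest minimum-cost mapping.
    best_assign: Optional[dict[AtomCoord, AtomCoord]] = None
    expansions = 0
    assign: dict[AtomCoord, AtomCoord] = {}
    inv: dict[AtomCoord, AtomCoord] = {}

    def dfs(i: int, cost: int, target: int) -> bool:
        nonlocal best_assign, expansions
        if i == n:
            best_assign = dict(assign)
            return True
        if cost + max(suffix_lb[i], bond_multiset_bound(i, inv)) > target:
            return False
        for p in candidates[i]:
            if p in inv:
                continue
            expansions += 1
            if expansions > budget:
                raise MappingBudgetError(
                    f"atom-mapping search budget of {budget} node expansions "
                    f"exceeded for reaction {reaction.reaction_id!r}"
                )
            inc = increment(i, p, assign, inv)
            if cost + inc + suffix_lb[i + 1] > target:
                continue
            s = sub.coords[i]
            assign[s] = p
            inv[p] = s
            if dfs(i + 1, cost + inc, target):
                return True
            del assign[s]
            del inv[p]
        return False

    root_lb = max(suffix_lb[0], bond_multiset_bound(0, {}))
    for target in range(root_lb, g_cost + 1):
        if dfs(0, 0, target):
            break
    if best_assign is None:  # pragma: no cover - greedy always yields a mapping
        best_assign = g_assign
    pairs = tuple(sorted(best_assign.items()))
    result = AtomMapping(pairs=pairs, cost=_mapping_cost(reaction, best_assign))
    if len(_MAPPING_CACHE) < _MAPPING_CACHE_MAX:
        _MAPPING_CACHE[cache_key] = result
    return result


def _mapping_cost(reaction: Reaction, assign: dict[AtomCoord, AtomCoord]) -> int:
    return len(extract_bond_changes(reaction, AtomMapping(tuple(sorted(assign.items())), 0)))


def mapping_key(reaction: Reaction, mapping: AtomMapping) -> tuple:
    """Canonical-coordinate form of a mapping (input-order independent)."""
    sub = _Side(reaction.substrates)
    prod = _Side(reaction.products)
    return tuple(
        sorted((sub.canon_pos[s], prod.canon_pos[p]) for s, p in mapping.pairs)
    )


# --------------------------------------------------------------------------
# Bond changes, reaction center, hydrogen deltas
# --------------------------------------------------------------------------


def extract_bond_changes(reaction: Reaction, mapping: AtomMapping) -> list[BondChange]:
    """All bond changes implied by the mapping: formed, cleaved, order, stereo.

    Heavy-atom graphs only: implicit-hydrogen count changes are *not* bond
    changes (see :func:`hydrogen_deltas`).  An order change on a bond
    suppresses any accompanying stereo-flag comparison for that bond.
    """
    sub = _Side(reaction.substrates)
    prod = _Side(reaction.products)
    fwd = mapping.as_dict()
    inv = {p: s for s, p in fwd.items()}
    for s in sub.coords:
        if s not in fwd:
            raise MappingError(f"mapping does not cover substrate atom {s}")
    for p in prod.coords:
        if p not in inv:
            raise MappingError(f"mapping does not cover product atom {p}")

    changes: list[BondChange] = []
    for mi, mol in enumerate(reaction.substrates):
        for b in mol.bonds:
            s1, s2 = (mi, b.endpoints[0]), (mi, b.endpoints[1])
            p1, p2 = fwd[s1], fwd[s2]
            pb = prod.bond(p1, p2)
            elems = tuple(sorted((sub.atom(s1).element, sub.atom(s2).element)))
            if pb is None:
                changes.append(
                    BondChange(
                        kind=ChangeKind.CLEAVED,
                        elements=elems,
                        substrate_atoms=(s1, s2),
                        order_before=b.order,
                    )
                )
            elif pb.order is not b.order:
                changes.append(
                    BondChange(
                        kind=ChangeKind.ORDER_CHANGED,
                        elements=elems,
                        substrate_atoms=(s1, s2),
                        product_atoms=tuple(sorted((p1, p2))),
                        order_before=b.order,
                        order_after=pb.order,
                    )
                )
            elif _bond_flags(pb.stereo) is not _bond_flags(b.stereo):
                changes.append(
                    BondChange(
                        kind=ChangeKind.STEREO_CHANGED,
                        elements=elems,
                        substrate_atoms=(s1, s2),
                        product_atoms=tuple(sorted((p1, p2))),
                        order_before=b.order,
                        order_after=pb.order,
                    )
                )
    for mi, mol in enumerate(reaction.products):
        for b in mol.bonds:
            p1, p2 = (mi, b.endpoints[0]), (mi, b.endpoints[1])
            s1, s2 = inv[p1], inv[p2]
            if sub.bond(s1, s2) is None:
                elems = tuple(sorted((prod.atom(p1).element, prod.atom(p2).element)))
                changes.append(
                    BondChange(
                        kind=ChangeKind.FORMED,
                        elements=elems,
                        product_atoms=(p1, p2),
                        order_after=b.order,
                    )
                )
    for s, p in mapping.pairs:
        sa, pa = sub.atom(s), prod.atom(p)
        if sa.element == "*" or pa.element == "*":
            continue
        if _atom_flags(sa.stereo) is not _atom_flags(pa.stereo):
            changes.append(
                BondChange(
                    kind=ChangeKind.STEREO_CHANGED,
                    elements=(sa.element,),
                    substrate_atoms=(s,),
                    product_atoms=(p,),
                )
            )
    changes.sort(key=lambda c: (c.kind.value, c.substrate_atoms or (), c.product_atoms or ()))
    return changes


def hydrogen_deltas(reaction: Reaction, mapping: AtomMapping) -> Counter:
    """Implicit-hydrogen count changes per mapped atom, as descriptors.

    Heavy-atom graphs cannot host explicit H bonds, so proton gains/losses
    are reported as auxiliary ``("h_delta", element, delta)`` descriptors
    rather than :class:`BondChange` entries.
    """
    sub = _Side(reaction.substrates)
    prod = _Side(reaction.products)
    deltas: Counter = Counter()
    for s, p in mapping.pairs:
        sa, pa = sub.atom(s), prod.atom(p)
        d = pa.n_hydrogens - sa.n_hydrogens
        if d:
            deltas[("h_delta", sa.element if sa.element != "*" else pa.element, d)] += 1
    return deltas


def reaction_center_atoms(
    reaction: Reaction,
    changes: Sequence[BondChange],
    mapping: Optional[AtomMapping] = None,
) -> dict[str, set[AtomCoord]]:
    """Atoms participating in any bond change, on both sides via the mapping."""
    if mapping is None:
        mapping = map_atoms(reaction)
    fwd = mapping.as_dict()
    inv = {p: s for s, p in fwd.items()}
    sub_side: set[AtomCoord] = set()
    prod_side: set[AtomCoord] = set()
    for c in changes:
        if c.substrate_atoms:
            sub_side.update(c.substrate_atoms)
            prod_side.update(fwd[a] for a in c.substrate_atoms)
        if c.product_atoms:
            prod_side.update(c.product_atoms)
            sub_side.update(inv[a] for a in c.product_atoms)
    return {"substrates": sub_side, "products": prod_side}


# --------------------------------------------------------------------------
# Orientation normalization and cached per-reaction analysis
# --------------------------------------------------------------------------


def _reverse_descriptor(desc: tuple) -> tuple:
    if desc[0] == "h_delta":
        return (desc[0], desc[1], -desc[2])
    kind, elements, before, after = desc
    if kind == ChangeKind.FORMED.value:
        return (ChangeKind.CLEAVED.value, elements, after, before)
    if kind == ChangeKind.CLEAVED.value:
        return (ChangeKind.FORMED.value, elements, after, before)
    return (kind, elements, after, before)


def reverse_descriptors(desc: Counter) -> Counter:
    return Counter({_reverse_descriptor(d): c for d, c in desc.items()})


class ReactionAnalysis:
    """Cached mapping, bond changes and fingerprints for one reaction.

    Reversible and unknown-direction reactions are orientation-normalized:
    the orientation whose sorted bond-change descriptor multiset is
    lexicographically smaller is used for all downstream comparisons (ties
    broken on component canonical SMILES), so a reaction and its reverse
    produce identical scores.  Explicitly directional reactions keep their
    stated direction (backward reactions are flipped to forward).
    """

    def __init__(self, reaction: Reaction, budget: int = DEFAULT_BUDGET):
        self.reaction = reaction
        work = (
            reaction.reversed()
            if reaction.directionality is Directionality.BACKWARD
            else reaction
        )
        mapping = map_atoms(work, budget=budget)
        changes = extract_bond_changes(work, mapping)
        desc = Counter(c.descriptor() for c in changes) + hydrogen_deltas(work, mapping)
        if reaction.directionality in (
            Directionality.REVERSIBLE,
            Directionality.UNKNOWN,
        ):
            rev_desc = reverse_descriptors(desc)
            fwd_key = sorted(map(repr, desc.elements()))
            rev_key = sorted(map(repr, rev_desc.elements()))
            flip = rev_key < fwd_key
            if rev_key == fwd_key:
                left = ".".join(sorted(m.smiles for m in work.substrates))
                right = ".".join(sorted(m.smiles for m in work.products))
                flip = right < left
            if flip:
                work = work.reversed()
                mapping = mapping.inverse()
                changes = extract_bond_changes(work, mapping)
                desc = rev_desc
        self.oriented = work
        self.mapping = mapping
        self.changes = changes
        self.change_descriptors = desc
        self.center = reaction_center_atoms(work, changes, mapping)
        self._center_fp: dict[int, Fingerprint] = {}
        self._mol_fps: dict[int, tuple[list[Fingerprint], list[Fingerprint]]] = {}

    def _kinds_at(self, side: str) -> dict[AtomCoord, tuple[str, ...]]:
        kinds: dict[AtomCoord, set[str]] = {}
        fwd = self.mapping.as_dict()
        inv = {p: s for s, p in fwd.items()}
        for c in self.changes:
            coords: set[AtomCoord] = set()
            if side == "sub":
                if c.substrate_atoms:
                    coords.update(c.substrate_atoms)
                if c.product_atoms:
                    coords.update(inv[a] for a in c.product_atoms)
            else:
                if c.product_atoms:
                    coords.update(c.product_atoms)
                if c.substrate_atoms:
                    coords.update(fwd[a] for a in c.substrate_atoms)
            for a in coords:
                kinds.setdefault(a, set()).add(c.kind.value)
        return {a: tuple(sorted(k)) for a, k in kinds.items()}

    def center_fingerprint(self, radius: int = DEFAULT_RADIUS) -> Fingerprint:
        """Pooled, side- and change-kind-tagged reaction-center fingerprint."""
        if radius not in self._center_fp:
            features: Counter = Counter()
            for side, tag, mols in (
                ("sub", "side:sub", self.oriented.substrates),
                ("prod", "side:prod", self.oriented.products),
            ):
                kinds = self._kinds_at(side)
                per_mol: dict[int, dict[int, tuple[str, ...]]] = {}
                for (mi, ai), kk in kinds.items():
                    per_mol.setdefault(mi, {})[ai] = kk
                for mi, seeds in per_mol.items():
                    fp = circular_fingerprint(
                        mols[mi],
                        radius=radius,
                        atom_subset=seeds.keys(),
                        tags=(tag,),
                        seed_tags={a: ("kinds:" + "+".join(k),) for a, k in seeds.items()},
                    )
                    features.update(fp.features)
            self._center_fp[radius] = Fingerprint(features=features, radius=radius)
        return self._center_fp[radius]

    def molecule_fingerprints(
        self, radius: int = DEFAULT_RADIUS
    ) -> tuple[list[Fingerprint], list[Fingerprint]]:
        if radius not in self._mol_fps:
            self._mol_fps[radius] = (
                [circular_fingerprint(m, radius=radius) for m in self.oriented.substrates],
                [circular_fingerprint(m, radius=radius) for m in self.oriented.products],
            )
        return self._mol_fps[radius]


def analyze(reaction: Union[Reaction, ReactionAnalysis], budget: int = DEFAULT_BUDGET) -> ReactionAnalysis:
    if isinstance(reaction, ReactionAnalysis):
        return reaction
    return ReactionAnalysis(reaction, budget=budget)


# --------------------------------------------------------------------------
# The three reaction similarity metrics
# --------------------------------------------------------------------------


class Metric(str, Enum):
    REACTION_CENTER = "reaction_center"
    BOND_CHANGE = "bond_change"
    SMALL_MOLECULE = "small_molecule"


@dataclass(frozen=True)
class ReactionSimilarityScore:
    metric: Metric
    value: float

    def __float__(self) -> float:
        return self.value


def reaction_center_similarity(
    r1: Union[Reaction, ReactionAnalysis],
    r2: Union[Reaction, ReactionAnalysis],
    radius: int = DEFAULT_RADIUS,
) -> ReactionSimilarityScore:
    """Tanimoto between side/kind-tagged reaction-center fingerprints.

    The most nuanced of the three metrics: it sees both the bond changes and
    the chemical environment around the atoms at which they occur.
    """
    a1, a2 = analyze(r1), analyze(r2)
    value = tanimoto(a1.center_fingerprint(radius), a2.center_fingerprint(radius))
    return ReactionSimilarityScore(Metric.REACTION_CENTER, value)


def bond_change_similarity(
    r1: Union[Reaction, ReactionAnalysis],
    r2: Union[Reaction, ReactionAnalysis],
) -> ReactionSimilarityScore:
    """Tanimoto between environment-free bond-change descriptor multisets."""
    a1, a2 = analyze(r1), analyze(r2)
    d1, d2 = a1.change_descriptors, a2.change_descriptors
    union = sum((d1 | d2).values())
    value = (sum((d1 & d2).values()) / union) if union else 0.0
    return ReactionSimilarityScore(Metric.BOND_CHANGE, value)


def _assignment_score(fps1: list[Fingerprint], fps2: list[Fingerprint]) -> float:
    if not fps1 or not fps2:
        return 0.0
    sim = np.array([[tanimoto(a, b) for b in fps2] for a in fps1])
    rows, cols = linear_sum_assignment(-sim)
    return float(sim[rows, cols].sum()) / max(len(fps1), len(fps2))


def small_molecule_similarity(
    r1: Union[Reaction, ReactionAnalysis],
    r2: Union[Reaction, ReactionAnalysis],
    side: str = "all",
    radius: int = DEFAULT_RADIUS,
) -> ReactionSimilarityScore:
    """Whole-molecule similarity of the chosen reaction side(s).

    Molecules of the chosen side are matched one-to-one (optimal assignment
    maximizing summed pairwise Tanimoto); the summed similarity is divided by
    the larger molecule count, so unmatched molecules contribute zero.
    ``side='all'`` averages the substrate- and product-side scores.
    """
    if side not in ("substrates", "products", "all"):
        raise ValueError(f"side must be substrates|products|all, got {side!r}")
    a1, a2 = analyze(r1), analyze(r2)
    s1, p1 = a1.molecule_fingerprints(radius)
    s2, p2 = a2.molecule_fingerprints(radius)
    if side == "substrates":
        value = _assignment_score(s1, s2)
    elif side == "products":
        value = _assignment_score(p1, p2)
    else:
        value = 0.5 * (_assignment_score(s1, s2) + _assignment_score(p1, p2))
    return ReactionSimilarityScore(Metric.SMALL_MOLECULE, value)


_METRIC_FUNCS = {
    Metric.REACTION_CENTER: lambda a, b, radius: reaction_center_similarity(a, b, radius),
    Metric.BOND_CHANGE: lambda a, b, radius: bond_change_similarity(a, b),
    Metric.SMALL_MOLECULE: lambda a, b, radius: small_molecule_similarity(a, b, radius=radius),
}


def pairwise_scores(
    reactions: Sequence[Reaction],
    metric: Union[Metric, str] = Metric.REACTION_CENTER,
    radius: int = DEFAULT_RADIUS,
    budget: int = DEFAULT_BUDGET,
):
    """All-by-all pairwise similarity table (id1, id2, score DataFrame)."""
    import pandas as pd

    metric = Metric(metric)
    analyses = [ReactionAnalysis(r, budget=budget) for r in reactions]
    func = _METRIC_FUNCS[metric]
    rows = []
    for i in range(len(analyses)):
        for j in range(i + 1, len(analyses)):
            score = func(analyses[i], analyses[j], radius).value
            rows.append(
                {
                    "id1": reactions[i].reaction_id,
                    "id2": reactions[j].reaction_id,
                    "score": score,
                }
            )
    return pd.DataFrame(rows, columns=["id1", "id2", "score"])


class ScoreStore:
    """Flat pairwise-score store keyed by the unordered reaction-id pair."""

    def __init__(self, metric: str = ""):
        self.metric = metric
        self._scores: dict[str, tuple[str, str, float]] = {}

    def put(self, id1: str, id2: str, score: float) -> None:
        a, b = sorted((id1, id2))
        self._scores[pair_key(a, b)] = (a, b, float(score))

    def get(self, id1: str, id2: str) -> Optional[float]:
        entry = self._scores.get(pair_key(id1, id2))
        return entry[2] if entry else None

    def __len__(self) -> int:
        return len(self._scores)

    def items(self):
        return [(a, b, s) for a, b, s in self._scores.values()]

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.items(), columns=["id1", "id2", "score"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path, metric: str = "") -> "ScoreStore":
        import pandas as pd

        store = cls(metric=metric)
        for _, row in pd.read_csv(path, sep="\t").iterrows():
            store.put(str(row["id1"]), str(row["id2"]), float(row["score"]))
        return store


def mapping_report(reaction: Reaction, budget: int = DEFAULT_BUDGET) -> dict:
    """JSON-ready mapping + bond-change report for one reaction."""
    mapping = map_atoms(reaction, budget=budget)
    changes = extract_bond_changes(reaction, mapping)
    center = reaction_center_atoms(reaction, changes, mapping)
    return {
        "reaction_id": reaction.reaction_id,
        "reaction_smiles": reaction.to_smiles(),
        "cost": mapping.cost,
        "mapping": [
            {"substrate": list(s), "product": list(p)} for s, p in mapping.pairs
        ],
        "bond_changes": [
            {
                "kind": c.kind.value,
                "elements": list(c.elements),
                "substrate_atoms": [list(a) for a in c.substrate_atoms] if c.substrate_atoms else None,
                "product_atoms": [list(a) for a in c.product_atoms] if c.product_atoms else None,
                "order_before": c.order_before.value if c.order_before else None,
                "order_after": c.order_after.value if c.order_after else None,
            }
            for c in changes
        ],
        "hydrogen_deltas": [
            {"element": el, "delta": d, "count": n}
            for (_, el, d), n in sorted(hydrogen_deltas(reaction, mapping).items())
        ],
        "reaction_center": {
            "substrates": sorted(map(list, center["substrates"])),
            "products": sorted(map(list, center["products"])),
        },
    }
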