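"""Synthetic superfamily generator and curated worked-example reactions.

The generator emulates a functionally diverse enzyme superfamily: a shared
scaffold idiom (small acid-sugar-like chains), several subgroups, each with
one or more monofunctional reaction families, and a library of elimination/
isomerization-style transforms mirroring the reaction repertoire of such
superfamilies (dehydration, ammonia elimination, racemization,
cycloisomerization, lactonization, tautomerization, decarboxylation,
dehydrohalogenation).  Each transform is an explicit rewrite with a known
bond-change ground truth emitted alongside the reaction, so the atom-mapping
machinery can be tested against generator truth as well as brute force.

``chem_evo_agreement`` controls how often a subgroup's families use the
subgroup's designated transform (1.0: subgroup membership predicts the
chemistry; 0.0: transforms are assigned independently of subgroup).
Structure similarity is simulated, not computed from 3D: within-subgroup
and between-subgroup scores are drawn from configurable normal
distributions clipped to [0, 1], emulating TM-score-like tables produced by
external structure alignment.  Generated reactions carry an explicit
forward direction (the generator defines each transform left-to-right) and
are always atom-balanced.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chem import Molecule
from .mapping import Metric, pairwise_scores
from .networks import SimilarityMatrix, SimilarityNetwork, build_network
from .ontology import (
    EnzymeFunctionalDomain,
    FunctionalResidue,
    Hierarchy,
    HierarchyNode,
    Level,
)
from .reactions import Directionality, Reaction, ReactionScheme, write_rxn

# Default edge thresholds for fixture-scale networks.  The simulated
# structure scores are TM-score-like; the reaction threshold sits between
# the maximum between-transform bond-change similarity (0.6 in this
# transform library) and the within-transform score of 1.0.
DEFAULT_STRUCTURE_THRESHOLD = 0.7
DEFAULT_REACTION_THRESHOLD = 0.8


@dataclass(frozen=True)
class Transform:
    """A parameterized rewrite with a fixed bond-change ground truth."""

    name: str
    ec3: str  # EC class.subclass.sub-subclass of the transformation
    substrate_template: str  # SMILES with a {tail} slot
    product_templates: tuple[str, ...]
    truth: tuple[tuple, ...]  # BondChange descriptors

    def build(self, tail: str) -> tuple[list[Molecule], list[Molecule]]:
        subs = [Molecule.from_smiles(self.substrate_template.format(tail=tail))]
        prods = [
            Molecule.from_smiles(t.format(tail=tail)) for t in self.product_templates
        ]
        return subs, prods

    def truth_counter(self) -> Counter:
        return Counter(self.truth)


_CLV = lambda e1, e2: ("cleaved", tuple(sorted((e1, e2))), "single", "")
_FRM = lambda e1, e2: ("formed", tuple(sorted((e1, e2))), "", "single")
_ORD = lambda e1, e2, a, b: ("order_changed", tuple(sorted((e1, e2))), a, b)
_STE = lambda e: ("stereo_changed", (e,), "", "")

TRANSFORMS: dict[str, Transform] = {
    t.name: t
    for t in (
        Transform(
            "dehydration",
            "4.2.1",
            "OC(=O)C(O)C{tail}",
            ("OC(=O)C=C{tail}", "O"),
            (_CLV("C", "O"), _ORD("C", "C", "single", "double")),
        ),
        Transform(
            "ammonia_elimination",
            "4.3.1",
            "OC(=O)C(N)C{tail}",
            ("OC(=O)C=C{tail}", "N"),
            (_CLV("C", "N"), _ORD("C", "C", "single", "double")),
        ),
        Transform(
            "dehydrochlorination",
            "4.5.1",
            "OC(=O)C(Cl)C{tail}",
            ("OC(=O)C=C{tail}", "Cl"),
            (_CLV("C", "Cl"), _ORD("C", "C", "single", "double")),
        ),
        Transform(
            "racemization",
            "5.1.2",
            "OC(=O)[C@@H](O){tail}",
            ("OC(=O)[C@H](O){tail}",),
            (_STE("C"),),
        ),
        Transform(
            "cycloisomerization",
            "5.5.1",
            "OC(=O)C=CC=C{tail}",
            ("O=C1C=CC(C{tail})O1",),
            (_FRM("C", "O"), _ORD("C", "C", "double", "single")),
        ),
        Transform(
            "lactonization",
            "3.1.1",
            "OC(=O)CCC(O){tail}",
            ("O=C1CCC({tail})O1", "O"),
            (_FRM("C", "O"), _CLV("C", "O")),
        ),
        Transform(
            "tautomerization",
            "5.3.2",
            "OC(=O)C(O)=C{tail}",
            ("OC(=O)C(=O)C{tail}",),
            (
                _ORD("C", "C", "double", "single"),
                _ORD("C", "O", "single", "double"),
            ),
        ),
        Transform(
            "decarboxylation",
            "4.1.1",
            "OC(=O)C(O){tail}",
            ("OC{tail}", "O=C=O"),
            (_CLV("C", "C"), _ORD("C", "O", "single", "double")),
        ),
    )
}

TRANSFORM_NAMES = tuple(TRANSFORMS)


def tail_library() -> list[str]:
    """Deterministic library of scaffold tails distinguishing families."""
    tails: list[str] = []
    for k in range(1, 7):
        for suffix in ("", "O", "OC", "C(C)C"):
            tails.append("C" * k + suffix)
    for i in range(1, 5):
        for j in range(3):
            tails.append("C" * i + "C(C)" + "C" * j)
    seen: list[str] = []
    for t in tails:
        if t not in seen:
            seen.append(t)
    return seen


@dataclass
class FixtureSpec:
    """Generation parameters for one synthetic superfamily.

    ``chem_evo_agreement`` is the probability that a family uses its
    subgroup's designated transform instead of a random one.
    ``subgroup_transforms`` overrides the designation: one list of transform
    names per subgroup, cycled over the subgroup's families (used to plant
    a subgroup whose chemistry splits across clusters).
    """

    n_subgroups: int = 4
    families_per_subgroup: int = 6
    reactions_per_family: int = 1  # families are monofunctional; >1 tests violations
    chem_evo_agreement: float = 1.0
    seed: int = 0
    within_structure_score: tuple[float, float] = (0.9, 0.03)  # mean, sd
    between_structure_score: tuple[float, float] = (0.35, 0.08)
    subgroup_transforms: Optional[list[list[str]]] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.chem_evo_agreement <= 1.0:
            raise ValueError("chem_evo_agreement must lie in [0, 1]")
        if min(self.n_subgroups, self.families_per_subgroup, self.reactions_per_family) < 1:
            raise ValueError("counts must be positive")


@dataclass
class FixtureBundle:
    spec: FixtureSpec
    reactions: list[Reaction]
    truth: pd.DataFrame  # entity_id, subgroup, family, transform, ec
    truth_changes: dict[str, Counter]  # entity_id -> bond-change descriptors
    structure_scores: SimilarityMatrix
    hierarchy: Hierarchy
    efds: list[EnzymeFunctionalDomain]
    schemes: list[ReactionScheme]

    def subgroup_labels(self) -> dict[str, str]:
        return dict(zip(self.truth["entity_id"], self.truth["subgroup"]))


def generate_superfamily(spec: FixtureSpec) -> FixtureBundle:
    """Generate a toy superfamily bundle, reproducibly from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    tails = tail_library()
    needed = spec.families_per_subgroup * spec.reactions_per_family
    if needed > len(tails):
        raise ValueError(
            f"spec needs {needed} distinct scaffold tails per subgroup but the "
            f"library holds {len(tails)}; impossible without duplicate reactions"
        )
    if spec.subgroup_transforms is not None:
        if len(spec.subgroup_transforms) != spec.n_subgroups:
            raise ValueError("subgroup_transforms must list one entry per subgroup")
        for names in spec.subgroup_transforms:
            for name in names:
                if name not in TRANSFORMS:
                    raise ValueError(f"unknown transform {name!r}")

    superfamily = HierarchyNode(name="SYNSF", level=Level.SUPERFAMILY)
    hierarchy = Hierarchy([superfamily])
    reactions: list[Reaction] = []
    efds: list[EnzymeFunctionalDomain] = []
    schemes: list[ReactionScheme] = []
    truth_rows: list[dict] = []
    truth_changes: dict[str, Counter] = {}
    efd_counter = 0

    for g in range(spec.n_subgroups):
        subgroup_name = f"SG{g:02d}"
        subgroup = hierarchy.add(
            HierarchyNode(name=subgroup_name, level=Level.SUBGROUP, parent=superfamily)
        )
        designated = TRANSFORM_NAMES[g % len(TRANSFORM_NAMES)]
        tail_order = list(rng.permutation(len(tails)))
        tail_cursor = 0
        for f in range(spec.families_per_subgroup):
            family_name = f"{subgroup_name}_F{f:02d}"
            hierarchy.add(
                HierarchyNode(name=family_name, level=Level.FAMILY, parent=subgroup)
            )
            if spec.subgroup_transforms is not None:
                tname = spec.subgroup_transforms[g][f % len(spec.subgroup_transforms[g])]
            elif rng.random() < spec.chem_evo_agreement:
                tname = designated
            else:
                tname = TRANSFORM_NAMES[rng.integers(len(TRANSFORM_NAMES))]
            transform = TRANSFORMS[tname]
            for k in range(spec.reactions_per_family):
                tail = tails[tail_order[tail_cursor]]
                tail_cursor += 1
                entity_id = (
                    family_name
                    if spec.reactions_per_family == 1
                    else f"{family_name}_r{k}"
                )
                subs, prods = transform.build(tail)
                ec = f"{transform.ec3}.{tail_order[tail_cursor - 1] + 1}"
                reaction = Reaction(
                    reaction_id=entity_id,
                    substrates=subs,
                    products=prods,
                    name=f"{tname} of scaffold {tail}",
                    directionality=Directionality.FORWARD,
                    ec_number=ec,
                )
                reactions.append(reaction)
                truth_rows.append(
                    {
                        "entity_id": entity_id,
                        "subgroup": subgroup_name,
                        "family": family_name,
                        "transform": tname,
                        "ec": ec,
                    }
                )
                truth_changes[entity_id] = transform.truth_counter()
                efd_counter += 1
                efd = EnzymeFunctionalDomain(
                    efd_id=f"EFD:{efd_counter}",
                    protein_accession=f"P{efd_counter:05d}",
                    family=family_name,
                    reaction_id=entity_id,
                    sequence_span=(1, 400),
                    functional_residues=[
                        FunctionalResidue(
                            position=195,
                            amino_acid="D" if g % 2 == 0 else "E",
                            role="general_base",
                            alignment_column="col_gb",
                        ),
                        FunctionalResidue(
                            position=247,
                            amino_acid="K",
                            role="electrostatic_stabilizer",
                            alignment_column=f"col_{subgroup_name}",
                        ),
                    ],
                )
                efds.append(efd)
                schemes.append(
                    ReactionScheme(
                        scheme_id=f"SCH:{efd_counter}",
                        reaction_id=entity_id,
                        efd_refs=[efd.efd_id],
                    )
                )

    truth = pd.DataFrame(truth_rows)
    entity_ids = list(truth["entity_id"])
    w_mean, w_sd = spec.within_structure_score
    b_mean, b_sd = spec.between_structure_score
    subgroup_of = dict(zip(truth["entity_id"], truth["subgroup"]))
    matrix = SimilarityMatrix(entity_ids=list(entity_ids), metric_name="structure_sim")
    for i in range(len(entity_ids)):
        for j in range(i + 1, len(entity_ids)):
            a, b = entity_ids[i], entity_ids[j]
            if subgroup_of[a] == subgroup_of[b]:
                score = rng.normal(w_mean, w_sd)
            else:
                score = rng.normal(b_mean, b_sd)
            matrix.set(a, b, float(np.clip(score, 0.0, 1.0)))

    return FixtureBundle(
        spec=spec,
        reactions=reactions,
        truth=truth,
        truth_changes=truth_changes,
        structure_scores=matrix,
        hierarchy=hierarchy,
        efds=efds,
        schemes=schemes,
    )


def generate_disconnect_fixture(seed: int = 0) -> tuple[FixtureBundle, dict[str, str]]:
    """A planted evolution/chemistry disconnect.

    Subgroup SG00 splits its families between two transforms that are each
    the designated chemistry of another subgroup, so its reactions land in
    two distant chemistry clusters (the split subgroup); SG01 keeps a unique
    transform (the control).  Returns the bundle and the role assignment.
    """
    spec = FixtureSpec(
        n_subgroups=4,
        families_per_subgroup=10,
        seed=seed,
        subgroup_transforms=[
            ["dehydration", "cycloisomerization"],
            ["racemization"],
            ["dehydration"],
            ["cycloisomerization"],
        ],
    )
    bundle = generate_superfamily(spec)
    return bundle, {"split": "SG00", "control": "SG01"}


# --------------------------------------------------------------------------
# Networks over a bundle
# --------------------------------------------------------------------------


def reaction_score_matrix(
    reactions: Sequence[Reaction],
    metric: Metric = Metric.BOND_CHANGE,
    radius: int = 2,
) -> SimilarityMatrix:
    df = pairwise_scores(reactions, metric=metric, radius=radius)
    matrix = SimilarityMatrix(
        entity_ids=[r.reaction_id for r in reactions], metric_name=Metric(metric).value
    )
    for _, row in df.iterrows():
        matrix.set(row["id1"], row["id2"], float(row["score"]))
    return matrix


def reaction_network(
    reactions: Sequence[Reaction],
    metric: Metric = Metric.BOND_CHANGE,
    threshold: float = DEFAULT_REACTION_THRESHOLD,
    radius: int = 2,
) -> SimilarityNetwork:
    return build_network(
        reaction_score_matrix(reactions, metric=metric, radius=radius),
        threshold=threshold,
        node_shape="square",
    )


def structure_network(
    bundle: FixtureBundle, threshold: float = DEFAULT_STRUCTURE_THRESHOLD
) -> SimilarityNetwork:
    return build_network(bundle.structure_scores, threshold=threshold, node_shape="circle")


# --------------------------------------------------------------------------
# Persistence
# --------------------------------------------------------------------------


def write_bundle(bundle: FixtureBundle, directory) -> None:
    """Write RXN files, SMILES table, ontology TSVs, score TSV, truth JSON."""
    from .ontology import save_ontology

    directory = Path(directory)
    rxn_dir = directory / "rxn"
    rxn_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in bundle.reactions:
        (rxn_dir / f"{r.reaction_id}.rxn").write_text(write_rxn(r))
        rows.append(
            {
                "reaction_id": r.reaction_id,
                "smiles": r.to_smiles(),
                "name": r.name,
                "ec_number": r.ec_number or "",
                "directionality": r.directionality.value,
            }
        )
    pd.DataFrame(rows).to_csv(directory / "reactions.tsv", sep="\t", index=False)
    bundle.structure_scores.to_tsv(directory / "structure_scores.tsv")
    bundle.truth.to_csv(directory / "truth.tsv", sep="\t", index=False)
    (directory / "truth_changes.json").write_text(
        json.dumps(
            {
                eid: [[list(desc), n] for desc, n in sorted(changes.items())]
                for eid, changes in sorted(bundle.truth_changes.items())
            },
            sort_keys=True,
            default=list,
        )
    )
    save_ontology(directory / "ontology", bundle.hierarchy, bundle.efds, bundle.schemes)


# --------------------------------------------------------------------------
# Worked examples (curated textbook structures for the named metabolites)
# --------------------------------------------------------------------------

_WORKED = [
    # id, name, reaction SMILES, EC, families/subgroups
    (
        "muconate_cycloisomerization",
        "muconate cycloisomerase",
        "OC(=O)C=CC=CC(=O)O>>O=C1C=CC(CC(=O)O)O1",
        "5.5.1.1",
        [("muconate cycloisomerase", "MLE")],
    ),
    (
        "mandelate_racemization",
        "mandelate racemase",
        "OC(=O)[C@@H](O)c1ccccc1>>OC(=O)[C@H](O)c1ccccc1",
        "5.1.2.2",
        [("mandelate racemase", "MR")],
    ),
    (
        "gluconate_dehydration",
        "gluconate dehydratase",
        "OCC(O)C(O)C(O)C(O)C(=O)O>>OCC(O)C(O)CC(=O)C(=O)O.O",
        "4.2.1.39",
        [("gluconate dehydratase", "MR")],
    ),
    (
        "osbs_dehydration",
        "o-succinylbenzoate synthase",
        "OC(=O)C1C(C(=O)CCC(=O)O)=CC=CC1O>>OC(=O)c1ccccc1C(=O)CCC(=O)O.O",
        "4.2.1.113",
        [("o-succinylbenzoate synthase", "MLE")],
    ),
    (
        "galactarate_dehydration",
        "galactarate dehydratase",
        "OC(=O)C(O)C(O)C(O)C(O)C(=O)O>>OC(=O)C(O)C(O)CC(=O)C(=O)O.O",
        "4.2.1.42",
        # one overall reaction catalyzed by families in two subgroups
        [("galactarate dehydratase", "GalD"), ("galactarate dehydratase 2", "MR")],
    ),
]


def worked_examples() -> dict[str, Reaction]:
    """Small curated reactions for named enzyme families.

    Standard textbook structures for the named metabolites, encoded as
    SMILES; identifiers and classifications follow the usual enolase-
    superfamily conventions (MLE, MR, GalD subgroups).
    """
    from .reactions import parse_reaction_smiles

    out = {}
    for rid, name, smiles, ec, _labels in _WORKED:
        out[rid] = parse_reaction_smiles(
            smiles,
            reaction_id=rid,
            name=name,
            ec_number=ec,
            directionality=Directionality.REVERSIBLE,
        )
    return out


def worked_example_labels() -> pd.DataFrame:
    """Annotation rows for the worked examples (entity_id, family, subgroup).

    The galactarate dehydration appears twice -- it is the canonical example
    of one overall reaction shared by families in two subgroups.
    """
    rows = []
    for rid, _name, _smiles, ec, labels in _WORKED:
        for family, subgroup in labels:
            rows.append(
                {"entity_id": rid, "family": family, "subgroup": subgroup, "ec": ec}
            )
    return pd.DataFrame(rows)
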