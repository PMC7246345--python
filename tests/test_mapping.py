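"""Atom mapping optimality/determinism, bond changes, the three metrics."""

import random
from collections import Counter

import pytest
from rdkit import Chem

from enznet.chem import Molecule
from enznet.mapping import (
    ChangeKind,
    MappingBudgetError,
    MappingError,
    bond_change_similarity,
    extract_bond_changes,
    hydrogen_deltas,
    map_atoms,
    mapping_key,
    pairwise_scores,
    reaction_center_atoms,
    reaction_center_similarity,
    small_molecule_similarity,
    ReactionAnalysis,
    ScoreStore,
)
from enznet.reactions import Directionality, Reaction, parse_reaction_smiles

from .oracles import brute_force_min_mapping_cost


def _descriptors(reaction):
    m = map_atoms(reaction)
    return Counter(c.descriptor() for c in extract_bond_changes(reaction, m))


class TestMapAtoms:
    def test_identity_reaction_maps_at_zero_cost(self):
        r = parse_reaction_smiles("CCO>>CCO")
        m = map_atoms(r)
        assert m.cost == 0
        assert extract_bond_changes(r, m) == []

    def test_unbalanced_reaction_refused(self):
        r = parse_reaction_smiles("CCO>>C=C")  # water product omitted
        with pytest.raises(MappingError, match="balanced"):
            map_atoms(r)

    def test_budget_exhaustion_is_explicit(self, examples):
        with pytest.raises(MappingBudgetError, match="budget"):
            map_atoms(examples["osbs_dehydration"], budget=50)

    def test_ethanol_dehydration_changes(self):
        r = parse_reaction_smiles("CCO>>C=C.O")
        m = map_atoms(r)
        assert m.cost == 2
        kinds = Counter(
            (c.kind, c.elements, str(c.order_before or ""), str(c.order_after or ""))
            for c in extract_bond_changes(r, m)
        )
        assert kinds == Counter(
            {
                (ChangeKind.CLEAVED, ("C", "O"), "BondOrder.SINGLE", ""): 1,
                (
                    ChangeKind.ORDER_CHANGED,
                    ("C", "C"),
                    "BondOrder.SINGLE",
                    "BondOrder.DOUBLE",
                ): 1,
            }
        )

    def test_racemization_single_stereo_change(self):
        r = parse_reaction_smiles("OC(=O)[C@@H](O)C>>OC(=O)[C@H](O)C")
        m = map_atoms(r)
        changes = extract_bond_changes(r, m)
        assert m.cost == 1
        assert [c.kind for c in changes] == [ChangeKind.STEREO_CHANGED]
        assert changes[0].elements == ("C",)

    def test_cost_equals_change_count_invariant(self, small_reactions):
        for r in small_reactions:
            m = map_atoms(r)
            assert m.cost == len(extract_bond_changes(r, m))

    def test_brute_force_optimality_oracle(self, small_reactions):
        """Search cost equals the exhaustive element-respecting-bijection minimum."""
        assert len(small_reactions) >= 15
        for r in small_reactions:
            assert map_atoms(r).cost == brute_force_min_mapping_cost(r), r.reaction_id

    def test_determinism_under_atom_permutation(self, small_reactions):
        rng = random.Random(7)
        for r in small_reactions[:8]:
            base = map_atoms(r)
            # re-enter every component through a randomized SMILES ordering
            subs = [
                Molecule.from_smiles(Chem.MolToSmiles(m._rdmol, doRandom=True, canonical=False))
                for m in r.substrates
            ]
            prods = [
                Molecule.from_smiles(Chem.MolToSmiles(m._rdmol, doRandom=True, canonical=False))
                for m in r.products
            ]
            rng.shuffle(subs)
            rng.shuffle(prods)
            permuted = Reaction(
                reaction_id=r.reaction_id,
                substrates=subs,
                products=prods,
                directionality=r.directionality,
            )
            other = map_atoms(permuted)
            assert other.cost == base.cost
            assert mapping_key(permuted, other) == mapping_key(r, base)

    def test_mapped_atoms_share_elements(self, small_reactions):
        for r in small_reactions:
            m = map_atoms(r)
            for (smi, sai), (pmi, pai) in m.pairs:
                es = r.substrates[smi].atoms[sai].element
                ep = r.products[pmi].atoms[pai].element
                assert es == ep


class TestReactionCenter:
    def test_empty_changes_empty_center(self):
        r = parse_reaction_smiles("CCO>>CCO")
        m = map_atoms(r)
        center = reaction_center_atoms(r, [], m)
        assert center["substrates"] == set() and center["products"] == set()

    def test_dehydration_center_is_three_atoms(self):
        r = parse_reaction_smiles("CCO>>C=C.O")
        m = map_atoms(r)
        center = reaction_center_atoms(r, extract_bond_changes(r, m), m)
        elements = sorted(
            r.substrates[mi].atoms[ai].element for mi, ai in center["substrates"]
        )
        assert elements == ["C", "C", "O"]

    def test_stereo_only_center_is_the_stereocenter(self):
        r = parse_reaction_smiles("OC(=O)[C@@H](O)C>>OC(=O)[C@H](O)C")
        m = map_atoms(r)
        center = reaction_center_atoms(r, extract_bond_changes(r, m), m)
        assert len(center["substrates"]) == 1
        ((mi, ai),) = center["substrates"]
        assert r.substrates[mi].atoms[ai].element == "C"

    def test_hydrogen_deltas_reported_separately(self):
        r = parse_reaction_smiles("CCO>>C=C.O")
        deltas = hydrogen_deltas(r, map_atoms(r))
        assert deltas == Counter({("h_delta", "C", -1): 1, ("h_delta", "O", 1): 1})


@pytest.fixture(scope="module")
def analyses(small_reactions):
    return [ReactionAnalysis(r) for r in small_reactions if r.reaction_id != "r_identity"]


class TestMetrics:

    def test_self_similarity_is_one(self, analyses):
        for a in analyses:
            assert reaction_center_similarity(a, a).value == 1.0
            assert bond_change_similarity(a, a).value == 1.0
            assert small_molecule_similarity(a, a).value == pytest.approx(1.0)

    def test_symmetry_and_bounds(self, analyses):
        for i in range(len(analyses)):
            for j in range(i + 1, len(analyses)):
                for fn in (
                    reaction_center_similarity,
                    bond_change_similarity,
                    small_molecule_similarity,
                ):
                    s_ij = fn(analyses[i], analyses[j]).value
                    s_ji = fn(analyses[j], analyses[i]).value
                    assert s_ij == pytest.approx(s_ji)
                    assert 0.0 <= s_ij <= 1.0

    def test_disjoint_chemistry_scores_zero(self):
        racem = parse_reaction_smiles(
            "OC(=O)[C@@H](O)C>>OC(=O)[C@H](O)C",
            directionality=Directionality.FORWARD,
        )
        dehydr = parse_reaction_smiles(
            "CCO>>C=C.O", directionality=Directionality.FORWARD
        )
        assert bond_change_similarity(racem, dehydr).value == 0.0
        assert reaction_center_similarity(racem, dehydr).value == 0.0

    def test_metric_separation_same_chemistry_different_scaffold(self):
        """Shared change multiset, different scaffolds: bond-change metric
        saturates at 1 while whole-molecule similarity stays below 1 -- and
        the converse pair reverses the ordering."""
        a = parse_reaction_smiles(
            "OC(=O)C(O)CC>>OC(=O)C=CC.O", directionality=Directionality.FORWARD
        )
        b = parse_reaction_smiles(
            "OC(=O)C(O)CCCCO>>OC(=O)C=CCCCO.O", directionality=Directionality.FORWARD
        )
        assert bond_change_similarity(a, b).value == 1.0
        assert small_molecule_similarity(a, b).value < 1.0
        # same substrate, different transformation
        c = parse_reaction_smiles(
            "OCC(O)CC(=O)O>>OCC=CC(=O)O.O", directionality=Directionality.FORWARD
        )
        d = parse_reaction_smiles(
            "OCC(O)CC(=O)O>>O=C1CC(O)CO1.O", directionality=Directionality.FORWARD
        )
        assert bond_change_similarity(c, d).value < 1.0
        assert small_molecule_similarity(c, d, side="substrates").value == 1.0

    def test_center_similarity_orders_related_reactions(self):
        """Two acid-sugar dehydrations differing by a remote stereocenter are
        closer than a dehydration vs a racemization on the same scaffold."""
        d1 = parse_reaction_smiles(
            "OCC(O)C(O)C(O)C(O)C(=O)O>>OCC(O)C(O)CC(=O)C(=O)O.O"
        )
        d2 = parse_reaction_smiles(
            "OC[C@H](O)C(O)C(O)C(O)C(=O)O>>OC[C@@H](O)C(O)CC(=O)C(=O)O.O"
        )
        racem = parse_reaction_smiles(
            "OCC(O)C(O)C(O)[C@H](O)C(=O)O>>OCC(O)C(O)C(O)[C@@H](O)C(=O)O"
        )
        close = reaction_center_similarity(d1, d2).value
        far = reaction_center_similarity(d1, racem).value
        assert close > far

    def test_single_molecule_side_reduces_to_molecule_tanimoto(self):
        from enznet.chem import circular_fingerprint, tanimoto

        mandelate = "OC(=O)C(O)c1ccccc1"
        galactarate = "OC(=O)C(O)C(O)C(O)C(O)C(=O)O"
        r1 = parse_reaction_smiles(
            f"{mandelate}>>{mandelate}", directionality=Directionality.FORWARD
        )
        r2 = parse_reaction_smiles(
            f"{galactarate}>>{galactarate}", directionality=Directionality.FORWARD
        )
        expected = tanimoto(
            circular_fingerprint(Molecule.from_smiles(mandelate)),
            circular_fingerprint(Molecule.from_smiles(galactarate)),
        )
        got = small_molecule_similarity(r1, r2, side="substrates").value
        assert got == pytest.approx(expected)

    def test_orientation_normalization_for_reversible(self):
        fwd = parse_reaction_smiles("CCO>>C=C.O", reaction_id="f")
        rev = parse_reaction_smiles("C=C.O>>CCO", reaction_id="b")
        assert bond_change_similarity(fwd, rev).value == 1.0
        assert reaction_center_similarity(fwd, rev).value == 1.0
        assert small_molecule_similarity(fwd, rev).value == pytest.approx(1.0)

    def test_invalid_side_rejected(self):
        r = parse_reaction_smiles("O>>O")
        with pytest.raises(ValueError):
            small_molecule_similarity(r, r, side="left")


class TestScores:
    def test_pairwise_table_shape(self, small_reactions):
        df = pairwise_scores(small_reactions[:5], metric="bond_change")
        assert len(df) == 10
        assert list(df.columns) == ["id1", "id2", "score"]

    def test_score_store_round_trip(self, tmp_path):
        store = ScoreStore(metric="bond_change")
        store.put("b", "a", 0.5)
        store.put("a", "c", 0.25)
        assert store.get("a", "b") == 0.5  # unordered-pair keying
        path = tmp_path / "scores.tsv"
        store.to_tsv(path)
        back = ScoreStore.from_tsv(path)
        assert sorted(back.items()) == sorted(store.items())
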