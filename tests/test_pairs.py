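"""Rhea pair extraction, prediction normalization, atom conservation, DRFP."""

import random
from itertools import combinations

import networkx as nx
import pytest
from rdkit import Chem

from enzchemkit.nen import Ph73Mapping
from enzchemkit.pairs import (
    ChemicalPair,
    FingerprintProviderError,
    RheaReaction,
    SmilesError,
    atom_conservation,
    compare,
    drfp_distance,
    normalize_predictions,
    read_reactions_tsv,
    rhea_pairs,
    top_compounds,
)


def rxn(rid, left, right):
    return RheaReaction(
        rid,
        [("left", c, 1) for c in left] + [("right", c, 1) for c in right],
    )


# ---------------------------------------------------------------------------
# top compounds and pair enumeration


def test_top_compounds_rejects_nonpositive_k():
    with pytest.raises(ValueError):
        top_compounds([rxn("R1", ["A"], ["B"])], k=0)


def test_top_compounds_rejects_empty_reaction_set():
    with pytest.raises(ValueError):
        top_compounds([], k=5)


def test_ubiquitous_compound_ranked_first():
    reactions = [rxn(f"R{i}", ["W", f"A{i}"], [f"B{i}"]) for i in range(5)]
    assert top_compounds(reactions, k=1) == {"W"}


def test_frequency_tie_at_rank_k_includes_all_tied():
    reactions = [
        rxn("R1", ["W", "X"], ["A"]),
        rxn("R2", ["W", "X"], ["B"]),
        rxn("R3", ["W", "X"], ["C"]),
    ]
    # W and X both occur 3 times; k=1 must include both
    assert top_compounds(reactions, k=1) == {"W", "X"}


def test_rhea_pairs_literal_all_pairs():
    pairs = rhea_pairs([rxn("R1", ["A", "B"], ["C"])])
    assert {p.ids for p in pairs} == {("A", "B"), ("A", "C"), ("B", "C")}


def test_rhea_pairs_exclusion():
    pairs = rhea_pairs([rxn("R1", ["A", "W"], ["C"])], excluded={"W"})
    assert {p.ids for p in pairs} == {("A", "C")}


def test_transport_reaction_yields_no_pairs():
    assert rhea_pairs([rxn("R1", ["A"], ["A"])]) == set()


def test_cross_side_only_switch():
    pairs = rhea_pairs([rxn("R1", ["A", "B"], ["C"])], cross_side_only=True)
    assert {p.ids for p in pairs} == {("A", "C"), ("B", "C")}


@pytest.mark.parametrize("seed", range(5))
def test_rhea_pairs_match_brute_force_enumeration(seed):
    rng = random.Random(seed)
    compounds = [f"CHEBI:{i}" for i in range(12)]
    reactions = []
    for i in range(8):
        left = rng.sample(compounds, rng.randint(1, 3))
        right = rng.sample(compounds, rng.randint(1, 3))
        reactions.append(rxn(f"R{i}", left, right))
    excluded = set(rng.sample(compounds, 3))
    got = {p.ids for p in rhea_pairs(reactions, excluded)}
    expected = set()
    for r in reactions:
        kept = [c for c in dict.fromkeys(r.ids()) if c not in excluded]
        for a, b in combinations(kept, 2):
            if a != b:
                expected.add(tuple(sorted((a, b), key=lambda x: int(x.split(":")[1]))))
    assert got == expected
    flat = {c for ids in got for c in ids}
    assert not flat & excluded
    assert all(a != b for a, b in got)


def test_read_reactions_tsv(tmp_path):
    path = tmp_path / "reactions.tsv"
    path.write_text(
        "rhea_id\tside\tchebi_id\tcoefficient\n"
        "RHEA:1\tleft\tCHEBI:1\t1\nRHEA:1\tright\tCHEBI:2\t2\n"
    )
    reactions = read_reactions_tsv(path)
    assert len(reactions) == 1
    assert reactions[0].participants == [("left", "CHEBI:1", 1),
                                         ("right", "CHEBI:2", 2)]


# ---------------------------------------------------------------------------
# prediction normalization and comparison


def test_normalize_predictions_planted_outcomes():
    ph = Ph73Mapping({"CHEBI:100": "CHEBI:101", "CHEBI:101": "CHEBI:101",
                      "CHEBI:200": "CHEBI:201", "CHEBI:201": "CHEBI:201"})
    excluded = {"CHEBI:900"}
    pairs_in = (
        # 3 excluded
        [("CHEBI:900", f"CHEBI:{i}") for i in (1, 2, 3)]
        # 2 collapse to identical after pH mapping
        + [("CHEBI:100", "CHEBI:101"), ("CHEBI:200", "CHEBI:201")]
        # 5 survive
        + [(f"CHEBI:{10 + i}", f"CHEBI:{20 + i}") for i in range(5)]
    )
    out, report = normalize_predictions(pairs_in, ph, excluded)
    assert len(out) == 5
    assert (report.n_excluded, report.n_collapsed) == (3, 2)
    assert report.reconciles()


def test_normalize_predictions_drops_non_chebi_with_count():
    out, report = normalize_predictions(
        [("MESH:D1", "CHEBI:2"), ("CHEBI:3", "CHEBI:4")], Ph73Mapping()
    )
    assert report.n_non_chebi == 1 and len(out) == 1


def test_normalize_predictions_untouched_pair_survives():
    out, report = normalize_predictions([("CHEBI:5", "CHEBI:6")], Ph73Mapping())
    assert {p.ids for p in out} == {("CHEBI:5", "CHEBI:6")}


def test_normalize_stage_counts_reconcile_randomized():
    rng = random.Random(4)
    ph = Ph73Mapping({f"CHEBI:{i}": f"CHEBI:{i // 2 * 2}" for i in range(40)})
    excluded = {f"CHEBI:{i}" for i in range(0, 40, 10)}
    pairs_in = [
        (f"CHEBI:{rng.randrange(40)}", f"CHEBI:{rng.randrange(40)}")
        for _ in range(200)
    ]
    pairs_in = [(a, b) for a, b in pairs_in if a != b]
    out, report = normalize_predictions(pairs_in, ph, excluded)
    assert report.reconciles()
    assert report.n_output == len(out)


def test_compare_subset_and_disjoint():
    ref = {ChemicalPair(ids=(f"CHEBI:{i}", f"CHEBI:{i + 1}")) for i in range(1, 9, 2)}
    assert compare(ref, ref)["All"]["pct_in_reference"] == 100.0
    other = {ChemicalPair(ids=("CHEBI:900", "CHEBI:901"))}
    assert compare(other, ref)["All"]["pct_in_reference"] == 0.0


def test_compare_hand_count():
    ref = {ChemicalPair(ids=("CHEBI:1", "CHEBI:2")),
           ChemicalPair(ids=("CHEBI:3", "CHEBI:4"))}
    pred = [ChemicalPair(ids=(f"CHEBI:{10 + i}", f"CHEBI:{20 + i}")) for i in range(6)]
    pred += [ChemicalPair(ids=("CHEBI:1", "CHEBI:2")),
             ChemicalPair(ids=("CHEBI:3", "CHEBI:4"))]
    report = compare(pred, ref)
    assert report["All"]["n_pred"] == 8
    assert report["All"]["n_shared"] == 2
    assert report["All"]["pct_in_reference"] == pytest.approx(25.0)


def test_identical_id_pair_is_invalid():
    with pytest.raises(ValueError):
        ChemicalPair(ids=("CHEBI:1", "CHEBI:1"))


def test_pair_canonical_numeric_ordering():
    assert ChemicalPair(ids=("CHEBI:100", "CHEBI:99")).ids == ("CHEBI:99", "CHEBI:100")


# ---------------------------------------------------------------------------
# atom conservation


def _exhaustive_mcs_atoms(smiles_a, smiles_b):
    """Oracle: largest connected common edge-subgraph by enumeration.

    Builds element-labelled single-bond graphs and enumerates every
    connected edge subset of the smaller graph (plus single atoms),
    checking subgraph monomorphism into the other.
    """

    def graph(smiles):
        mol = Chem.MolFromSmiles(smiles)
        g = nx.Graph()
        for atom in mol.GetAtoms():
            g.add_node(atom.GetIdx(), z=atom.GetAtomicNum())
        for bond in mol.GetBonds():
            g.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx())
        return g

    g1, g2 = graph(smiles_a), graph(smiles_b)
    if g1.number_of_nodes() > g2.number_of_nodes():
        g1, g2 = g2, g1
    node_match = nx.algorithms.isomorphism.categorical_node_match("z", 0)
    best = 0
    z2 = {d["z"] for _, d in g2.nodes(data=True)}
    if any(d["z"] in z2 for _, d in g1.nodes(data=True)):
        best = 1
    edges = list(g1.edges)
    for mask in range(1, 2 ** len(edges)):
        subset = [e for i, e in enumerate(edges) if mask >> i & 1]
        pattern = nx.Graph()
        for u, v in subset:
            pattern.add_node(u, z=g1.nodes[u]["z"])
            pattern.add_node(v, z=g1.nodes[v]["z"])
            pattern.add_edge(u, v)
        if not nx.is_connected(pattern):
            continue
        if pattern.number_of_nodes() <= best:
            continue
        gm = nx.algorithms.isomorphism.GraphMatcher(g2, pattern,
                                                    node_match=node_match)
        if gm.subgraph_is_monomorphic():
            best = pattern.number_of_nodes()
    return best


def test_identical_molecules_conserve_all_atoms():
    assert atom_conservation("CCO", "CCO").percent == pytest.approx(100.0)


def test_single_bond_reduction_equates_ethanol_acetaldehyde():
    ac = atom_conservation("CCO", "CC=O")
    assert ac.n_mcs == 3
    assert ac.percent == pytest.approx(100.0)


def test_ethanol_vs_methane():
    ac = atom_conservation("CCO", "C")
    assert (ac.n_mcs, ac.n_left, ac.n_right) == (1, 3, 1)
    assert ac.percent == pytest.approx(66.6666666, abs=1e-4)


@pytest.mark.parametrize(
    "a, b",
    [
        ("CCO", "CC=O"),
        ("CCO", "C"),
        ("C1CC1", "CCC"),          # ring vs open chain
        ("CC(C)=O", "CCO"),
        ("CC(=O)[O-]", "CC(C)=O"),
        ("OCC(O)CO", "OCCO"),
        ("C", "O"),                # no common element... C vs O
        ("c1ccccc1", "C1CCCCC1"),  # aromatic ring reduced to single bonds
    ],
)
def test_atom_conservation_matches_exhaustive_oracle(a, b):
    ac = atom_conservation(a, b)
    assert ac.n_mcs == _exhaustive_mcs_atoms(a, b)
    assert ac.n_mcs <= min(ac.n_left, ac.n_right)
    # symmetry
    assert atom_conservation(b, a).percent == pytest.approx(ac.percent)


def test_full_conservation_iff_mcs_covers_both():
    ac = atom_conservation("CCO", "CC=O")
    assert ac.percent == 100.0
    assert ac.n_mcs == ac.n_left == ac.n_right


def test_unparseable_smiles_names_side():
    with pytest.raises(SmilesError, match="right"):
        atom_conservation("CCO", "not-a-smiles")
    with pytest.raises(SmilesError, match="left"):
        atom_conservation(")(", "CCO")


# ---------------------------------------------------------------------------
# fingerprint adapter


def toy_encoder(reaction_smiles):
    out = []
    for s in reaction_smiles:
        bits = [0] * 64
        for tok in s:
            bits[hash(tok) % 64] = 1
        out.append(bits)
    return out


def test_drfp_requires_provider():
    with pytest.raises(FingerprintProviderError, match="drfp"):
        drfp_distance(("CCO", "CC=O"), ("C", "O"))


def test_drfp_identical_pairs_zero_distance():
    assert drfp_distance(("CCO", "CC=O"), ("CCO", "CC=O"), encoder=toy_encoder) == 0.0


def test_drfp_order_invariance():
    assert drfp_distance(("CC=O", "CCO"), ("CCO", "CC=O"), encoder=toy_encoder) == 0.0


def test_drfp_distance_in_unit_interval():
    d = drfp_distance(("CCO", "CC=O"),
                      ("OCC1OC(O)C(O)C(O)C1O", "CC(=O)[O-]"),
                      encoder=toy_encoder)
    assert 0.0 < d <= 1.0
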