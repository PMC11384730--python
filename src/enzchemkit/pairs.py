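"""Downstream chemical-pair processing against Rhea.

Reference pairs are extracted from Rhea reactions by removing the most
frequent compounds (water, protons, cofactors and the like, top 100 by
default), enumerating all unordered pairs of the remaining participants
within each reaction, and discarding identical-ID pairs (which arise from
transport reactions). Predicted pairs from text are normalized to pH-7.3
ChEBI forms, filtered the same way, and compared to the Rhea set.

The atom-conservation metric scores how much of a pair's atoms are shared:
both molecules are reduced to heavy-atom graphs with every bond made
single, the maximum common substructure (MCS) is computed, and

    % atom conservation = 1/2 * (n_MCS/n_L + n_MCS/n_R) * 100

where n_L and n_R are the heavy-atom counts of the two molecules. Curated
substrate/product pairs conserve most of their atoms, so the metric is a
practical noise filter for text-mined pairs; the default filter threshold
(79.76) is the mean over Rhea pairs with resolvable structures.
"""

from __future__ import annotations

import logging
import os
import re
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit.Chem import rdFMCS

from .nen import Ph73Mapping

log = logging.getLogger(__name__)

#: Mean atom conservation over structure-resolvable Rhea pairs; default
#: threshold for filtering text-mined pairs before visualization.
DEFAULT_CONSERVATION_THRESHOLD = 79.76
DEFAULT_TOP_K = 100


@dataclass
class RheaReaction:
    """One reaction: participants as (side, chebi_id, stoichiometry)."""

    rhea_id: str
    participants: list[tuple[str, str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        sides = {s for s, _, _ in self.participants}
        if self.participants and not {"left", "right"} <= sides:
            raise ValueError(
                f"{self.rhea_id}: reactions need at least one participant per side"
            )

    def ids(self, side: str | None = None) -> list[str]:
        return [c for s, c, _ in self.participants if side is None or s == side]


def _numeric(identifier: str) -> tuple[int, str]:
    digits = re.sub(r"\D", "", identifier)
    return (int(digits) if digits else 0, identifier)


@dataclass(frozen=True)
class ChemicalPair:
    """Unordered pair of distinct ChEBI IDs, canonically ordered."""

    ids: tuple[str, str]
    relation_type: str = "Conversion"
    provenance: str = ""
    score: float | None = None

    def __post_init__(self) -> None:
        a, b = self.ids
        if a == b:
            raise ValueError(f"identical-ID pair {a!r}")
        ordered = tuple(sorted(self.ids, key=_numeric))
        object.__setattr__(self, "ids", ordered)

    def key(self) -> tuple[str, str]:
        return self.ids


def read_reactions_tsv(path: str | os.PathLike) -> list[RheaReaction]:
    """Read ``rhea_id <TAB> side <TAB> chebi_id <TAB> coefficient`` rows."""
    rows: dict[str, list[tuple[str, str, int]]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("rhea_id\t"):
                continue
            rid, side, chebi, coeff = line.split("\t")[:4]
            rows.setdefault(rid, []).append((side, chebi, int(coeff)))
    return [RheaReaction(rhea_id=rid, participants=p) for rid, p in rows.items()]


def top_compounds(
    reactions: Sequence[RheaReaction], k: int = DEFAULT_TOP_K
) -> set[str]:
    """The k compounds participating in the most reactions.

    Frequency is the number of reactions a compound occurs in. Ties at
    rank k include every tied compound (logged), so the returned set may
    exceed k.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if not reactions:
        raise ValueError("empty reaction set")
    freq = Counter()
    for rxn in reactions:
        freq.update(set(rxn.ids()))
    ranked = freq.most_common()
    if len(ranked) <= k:
        return {c for c, _ in ranked}
    cutoff = ranked[k - 1][1]
    result = {c for c, n in ranked if n >= cutoff}
    if len(result) > k:
        log.warning(
            "frequency tie at rank %d: returning %d compounds", k, len(result)
        )
    return result


def rhea_pairs(
    reactions: Sequence[RheaReaction],
    excluded: set[str] | frozenset[str] = frozenset(),
    cross_side_only: bool = False,
) -> set[ChemicalPair]:
    """Enumerate reference chemical pairs from reactions.

    All unordered pairs of non-excluded participants within each reaction
    (both within- and cross-side by default; ``cross_side_only`` restricts
    to left-right pairs). Identical-ID pairs are removed; the union over
    reactions is returned.
    """
    out: set[ChemicalPair] = set()
    for rxn in reactions:
        if cross_side_only:
            candidates = [
                (l, r)
                for l in rxn.ids("left")
                for r in rxn.ids("right")
            ]
        else:
            kept_all = [c for c in rxn.ids() if c not in excluded]
            candidates = list(combinations(dict.fromkeys(kept_all), 2))
        for a, b in candidates:
            if a == b or a in excluded or b in excluded:
                continue
            out.add(ChemicalPair(ids=(a, b), provenance=rxn.rhea_id))
    return {ChemicalPair(ids=p.ids) for p in out}


@dataclass
class NormalizationReport:
    """Stage-wise accounting for :func:`normalize_predictions`."""

    n_input: int = 0
    n_non_chebi: int = 0
    n_excluded: int = 0
    n_collapsed: int = 0
    n_duplicates: int = 0
    n_output: int = 0

    def reconciles(self) -> bool:
        removed = (
            self.n_non_chebi + self.n_excluded + self.n_collapsed + self.n_duplicates
        )
        return self.n_input - removed == self.n_output


def normalize_predictions(
    pairs: Iterable[tuple[str, str] | ChemicalPair],
    ph_map: Ph73Mapping,
    excluded: set[str] | frozenset[str] = frozenset(),
) -> tuple[set[ChemicalPair], NormalizationReport]:
    """Prepare text-mined pairs for comparison against the Rhea set.

    In order: map both members to their pH-7.3 ChEBI form; drop pairs with
    any excluded (top-frequency) compound; drop pairs whose members
    collapsed to the same ID (a symptom of erroneous text spans); then
    deduplicate to unique unordered ID pairs. Non-ChEBI members cause the
    pair to be dropped, with a count in the report.
    """
    report = NormalizationReport()
    out: set[ChemicalPair] = set()
    for item in pairs:
        report.n_input += 1
        if isinstance(item, ChemicalPair):
            a, b, rtype = item.ids[0], item.ids[1], item.relation_type
        else:
            (a, b), rtype = item, "Conversion"
        if not (a.startswith("CHEBI:") and b.startswith("CHEBI:")):
            report.n_non_chebi += 1
            continue
        a, b = ph_map.apply(a), ph_map.apply(b)
        if a in excluded or b in excluded:
            report.n_excluded += 1
            continue
        if a == b:
            report.n_collapsed += 1
            continue
        pair = ChemicalPair(ids=(a, b), relation_type=rtype)
        if pair in out:
            report.n_duplicates += 1
            continue
        out.add(pair)
    report.n_output = len(out)
    assert report.reconciles()
    return out, report


def compare(
    pred_pairs: Iterable[ChemicalPair], reference_pairs: Iterable[ChemicalPair]
) -> dict[str, dict[str, float]]:
    """Overlap of predicted pairs with the reference set, per relation type.

    Returns ``{type: {"n_pred", "n_shared", "pct_in_reference"}}`` plus an
    "All" row; membership is by unordered ChEBI ID pair.
    """
    ref_keys = {p.key() for p in reference_pairs}
    by_type: dict[str, list[ChemicalPair]] = {}
    pred = list(pred_pairs)
    for p in pred:
        by_type.setdefault(p.relation_type, []).append(p)
    report: dict[str, dict[str, float]] = {}
    for rtype, group in [("All", pred)] + sorted(by_type.items()):
        keys = {p.key() for p in group}
        shared = len(keys & ref_keys)
        report[rtype] = {
            "n_pred": len(keys),
            "n_shared": shared,
            "pct_in_reference": 100.0 * shared / len(keys) if keys else 0.0,
        }
    return report


# ---------------------------------------------------------------------------
# Atom conservation


class SmilesError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


@dataclass(frozen=True)
class AtomConservation:
    """MCS atom counts and the derived conservation percentage."""

    n_mcs: int
    n_left: int
    n_right: int

    @property
    def percent(self) -> float:
        return 0.5 * (self.n_mcs / self.n_left + self.n_mcs / self.n_right) * 100.0


def _single_bond_graph(smiles: str, side: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesError(f"unparseable SMILES on {side} side: {smiles!r}")
    rw = Chem.RWMol(mol)
    for bond in rw.GetBonds():
        bond.SetBondType(Chem.BondType.SINGLE)
        bond.SetIsAromatic(False)
    for atom in rw.GetAtoms():
        atom.SetIsAromatic(False)
        atom.SetNumRadicalElectrons(0)
        atom.SetNoImplicit(True)
    out = rw.GetMol()
    Chem.SanitizeMol(
        out,
        Chem.SanitizeFlags.SANITIZE_ALL
        ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES
        ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE,
    )
    return out


def atom_conservation(smiles_l: str, smiles_r: str) -> AtomConservation:
    """Atom conservation between two molecules.

    Heavy atoms only (hydrogens implicit); both molecules are reduced to
    single-bond graphs before the MCS is computed with permissive ring
    fusion. When the MCS search finds no common bond (e.g. one molecule is
    a single atom), the largest common fragment is a single shared element
    if one exists.
    """
    mol_l = _single_bond_graph(smiles_l, "left")
    mol_r = _single_bond_graph(smiles_r, "right")
    n_l, n_r = mol_l.GetNumAtoms(), mol_r.GetNumAtoms()
    n_mcs = 0
    if mol_l.GetNumBonds() and mol_r.GetNumBonds():
        result = rdFMCS.FindMCS(
            [mol_l, mol_r],
            bondCompare=rdFMCS.BondCompare.CompareAny,
            ringMatchesRingOnly=False,
            completeRingsOnly=False,
            ringCompare=rdFMCS.RingCompare.PermissiveRingFusion,
            timeout=30,
        )
        if not result.canceled or result.numAtoms:
            n_mcs = max(result.numAtoms, 0)
    if n_mcs == 0:
        elems_l = {a.GetAtomicNum() for a in mol_l.GetAtoms()}
        elems_r = {a.GetAtomicNum() for a in mol_r.GetAtoms()}
        n_mcs = 1 if elems_l & elems_r else 0
    return AtomConservation(n_mcs=n_mcs, n_left=n_l, n_right=n_r)


# ---------------------------------------------------------------------------
# Differential reaction fingerprint adapter


class FingerprintProviderError(RuntimeError):
    """Raised when no differential-reaction-fingerprint provider is available."""


def _pair_reaction_smiles(pair: tuple[str, str]) -> str:
    a, b = sorted(pair)  # order-invariance: canonical member order
    return f"{a}>>{b}"


def drfp_distance(
    smiles_pair_a: tuple[str, str],
    smiles_pair_b: tuple[str, str],
    encoder=None,
) -> float:
    """Jaccard distance between two pairs' differential reaction fingerprints.

    A thin adapter: ``encoder`` is any callable mapping a list of reaction
    SMILES to binary fingerprint vectors (the DRFP package's encoder fits
    directly). Without an installed provider or injected encoder the
    feature is unavailable and :class:`FingerprintProviderError` is raised.
    """
    if encoder is None:
        try:
            from drfp import DrfpEncoder  # type: ignore

            encoder = DrfpEncoder.encode
        except ImportError as exc:
            raise FingerprintProviderError(
                "differential reaction fingerprints need the 'drfp' package "
                "or an injected encoder; install drfp or pass encoder="
            ) from exc
    fps = encoder(
        [_pair_reaction_smiles(smiles_pair_a), _pair_reaction_smiles(smiles_pair_b)]
    )
    fa, fb = (list(map(bool, f)) for f in fps)
    inter = sum(1 for x, y in zip(fa, fb) if x and y)
    union = sum(1 for x, y in zip(fa, fb) if x or y)
    return 1.0 - inter / union if union else 0.0
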