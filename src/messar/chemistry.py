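"""Structure handling: substructure generation, containment, similarity, MCS.

Molecules and substructures are exchanged as SMILES strings; internally
everything goes through RDKit. Substructure generation combines two routes:

* membership of *predefined* patterns (functional groups, ring systems),
* fragments obtained by *cleaving* one or two acyclic bonds of the molecule.

Fragments made only of C/H/O/N with fewer than five carbon-plus-oxygen atoms
are considered trivial and discarded; every reported substructure has at
least two heavy atoms.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import FrozenSet, Iterable, Optional

from rdkit import Chem, RDLogger
from rdkit.Chem import BRICS, DataStructs, rdFMCS

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

#: elements whose small combinations are chemically uninformative
CHON = frozenset({"C", "H", "O", "N"})

#: minimum heavy-atom count of any reported substructure
MIN_HEAVY_ATOMS = 2

#: parameters of the hashed path fingerprint used for Tanimoto similarity
FINGERPRINT_BITS = 1024
FINGERPRINT_MAX_PATH = 7


class StructureParseError(ValueError):
    """Raised when a SMILES/SMARTS string cannot be parsed."""


def load_patterns(path: Optional[str | Path] = None) -> list[str]:
    """Load a predefined substructure pattern list (one SMILES/SMARTS per line).

    Lines starting with ``#`` are comments. Without a path, a small curated
    default of common functional groups and ring systems is used.
    """
    if path is None:
        text = (
            resources.files("messar").joinpath("data/default_patterns.txt").read_text()
        )
    else:
        text = Path(path).read_text()
    out = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureParseError(f"cannot parse structure {smiles!r}")
    return mol


def canonical_smiles(smiles: str) -> str:
    """Canonical SMILES; re-canonicalization is a fixed point."""
    return Chem.MolToSmiles(mol_from_smiles(smiles))


@dataclass(frozen=True, eq=False)
class Substructure:
    """A connected molecular fragment serving as a rule head.

    ``source`` records how the fragment was obtained: matched from the
    predefined pattern list or produced by bond cleavage. Identity (equality
    and hashing) is the canonical SMILES alone, so the same fragment reached
    by both routes counts once.
    """

    smiles: str
    n_carbon: int
    n_oxygen: int
    n_heavy: int
    elements: FrozenSet[str]
    source: str = "predefined"

    def __eq__(self, other) -> bool:
        return isinstance(other, Substructure) and self.smiles == other.smiles

    def __hash__(self) -> int:
        return hash(self.smiles)

    @classmethod
    def from_smiles(cls, smiles: str, source: str = "predefined") -> "Substructure":
        mol = mol_from_smiles(smiles)
        counts = {"C": 0, "O": 0}
        elements = {"H"} if any(a.GetTotalNumHs() for a in mol.GetAtoms()) else set()
        for atom in mol.GetAtoms():
            sym = atom.GetSymbol()
            elements.add(sym)
            if sym in counts:
                counts[sym] += 1
        return cls(
            smiles=Chem.MolToSmiles(mol),
            n_carbon=counts["C"],
            n_oxygen=counts["O"],
            n_heavy=mol.GetNumHeavyAtoms(),
            elements=frozenset(elements),
            source=source,
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.smiles


def is_trivial(sub: Substructure) -> bool:
    """A C/H/O/N-only fragment with fewer than 5 C+O atoms is trivial.

    Fragments carrying any other element (halogens, S, P, ...) are never
    trivial: rare elements are informative regardless of size.
    """
    return sub.elements <= CHON and (sub.n_carbon + sub.n_oxygen) < 5


def _acceptable(sub: Substructure) -> bool:
    return sub.n_heavy >= MIN_HEAVY_ATOMS and not is_trivial(sub)


def predefined_substructures(
    mol_smiles: str, patterns: Iterable[str]
) -> set[Substructure]:
    """Subset of ``patterns`` (SMILES or SMARTS) embedded in the molecule.

    Unparsable patterns are skipped with a warning. Matched patterns are
    reported as canonical SMILES; a SMARTS pattern that cannot be rendered
    as a concrete fragment is skipped.
    """
    mol = mol_from_smiles(mol_smiles)
    found: set[Substructure] = set()
    for pat in patterns:
        query = Chem.MolFromSmarts(pat)
        if query is None or query.GetNumAtoms() == 0:
            logger.warning("skipping unparsable pattern %r", pat)
            continue
        if not mol.HasSubstructMatch(query):
            continue
        # render the pattern itself as a concrete fragment when possible
        concrete = Chem.MolFromSmiles(pat)
        if concrete is None:
            logger.warning("pattern %r matches but is not a concrete fragment", pat)
            continue
        found.add(Substructure.from_smiles(pat, source="predefined"))
    return found


def _cleavable_bonds(mol: Chem.Mol, policy: str) -> list[int]:
    """Indices of bonds eligible for cleavage.

    ``all_acyclic``: every acyclic single bond between heavy atoms.
    ``brics_bonds``: the subset of those at BRICS-defined link positions.
    """
    if policy == "brics_bonds":
        pairs = {frozenset(b[0]) for b in BRICS.FindBRICSBonds(mol)}
        return [
            b.GetIdx()
            for b in mol.GetBonds()
            if frozenset((b.GetBeginAtomIdx(), b.GetEndAtomIdx())) in pairs
        ]
    if policy != "all_acyclic":
        raise ValueError(f"unknown cleavage policy {policy!r}")
    return [
        b.GetIdx()
        for b in mol.GetBonds()
        if b.GetBondType() == Chem.BondType.SINGLE and not b.IsInRing()
    ]


def _fragments_after_cuts(mol: Chem.Mol, bond_ids: tuple[int, ...]) -> list[str]:
    frag = Chem.FragmentOnBonds(mol, list(bond_ids), addDummies=False)
    return [
        Chem.MolToSmiles(piece)
        for piece in Chem.GetMolFrags(frag, asMols=True, sanitizeFrags=False)
    ]


@lru_cache(maxsize=4096)
def _cleavage_cached(
    canon: str, max_cuts: int, policy: str
) -> frozenset[Substructure]:
    mol = mol_from_smiles(canon)
    bonds = _cleavable_bonds(mol, policy)
    out: set[Substructure] = set()

    def collect(bond_ids: tuple[int, ...], expect: int) -> None:
        pieces = _fragments_after_cuts(mol, bond_ids)
        if len(pieces) != expect:
            return  # e.g. the two cuts did not yield three fragments
        for smi in pieces:
            try:
                sub = Substructure.from_smiles(smi, source="cleavage")
            except StructureParseError:
                continue
            if _acceptable(sub):
                out.add(sub)

    for b in bonds:
        collect((b,), 2)
    if max_cuts >= 2:
        for b1, b2 in itertools.combinations(bonds, 2):
            collect((b1, b2), 3)
    return frozenset(out)


def cleavage_substructures(
    mol_smiles: str, max_cuts: int = 2, policy: str = "all_acyclic"
) -> set[Substructure]:
    """Fragments from disconnecting one or two acyclic bonds.

    One cut must yield two fragments, two cuts three fragments (cut pairs
    producing fewer are skipped, as are ring bonds which cannot split the
    molecule). ``max_cuts=0`` disables cleavage entirely — useful when only
    the predefined-pattern route is wanted.
    """
    if max_cuts not in (0, 1, 2):
        raise ValueError("max_cuts must be 0, 1 or 2")
    if max_cuts == 0:
        return set()
    return set(_cleavage_cached(canonical_smiles(mol_smiles), max_cuts, policy))


def contains_substructure(mol_smiles: str, sub: Substructure | str) -> bool:
    """True iff the fragment embeds in the molecule as a subgraph.

    Matching is element- and bond-order-aware but hydrogen-count agnostic
    (a benzene query matches the ring of toluene).
    """
    mol = mol_from_smiles(mol_smiles)
    sub_smiles = sub.smiles if isinstance(sub, Substructure) else sub
    query = Chem.MolFromSmiles(sub_smiles)
    if query is None:
        query = Chem.MolFromSmarts(sub_smiles)
    if query is None:
        raise StructureParseError(f"cannot parse substructure {sub_smiles!r}")
    return mol.HasSubstructMatch(query)


@lru_cache(maxsize=8192)
def _fingerprint(canon: str):
    return Chem.RDKFingerprint(
        mol_from_smiles(canon), maxPath=FINGERPRINT_MAX_PATH, fpSize=FINGERPRINT_BITS
    )


def tanimoto(a: Substructure | str, b: Substructure | str) -> float:
    """Tanimoto coefficient over hashed path fingerprints (1024 bits, path<=7)."""
    sa = a.smiles if isinstance(a, Substructure) else canonical_smiles(a)
    sb = b.smiles if isinstance(b, Substructure) else canonical_smiles(b)
    return DataStructs.TanimotoSimilarity(_fingerprint(sa), _fingerprint(sb))


def mcs(
    a: Substructure | str, b: Substructure | str, timeout: int = 1
) -> Optional[Substructure]:
    """Maximum common connected substructure of two fragments.

    Atoms match by element, bonds by order; charge and stereo are ignored.
    Returns ``None`` when no common subgraph with at least two heavy atoms
    exists or the per-pair time budget is exhausted.
    """
    sa = a.smiles if isinstance(a, Substructure) else canonical_smiles(a)
    sb = b.smiles if isinstance(b, Substructure) else canonical_smiles(b)
    if sa == sb:
        return a if isinstance(a, Substructure) else Substructure.from_smiles(sa)
    ma, mb = mol_from_smiles(sa), mol_from_smiles(sb)
    # complete rings only: a partial aromatic ring is not a meaningful
    # substructure and cannot be rendered as an embeddable fragment
    res = rdFMCS.FindMCS(
        [ma, mb],
        atomCompare=rdFMCS.AtomCompare.CompareElements,
        bondCompare=rdFMCS.BondCompare.CompareOrder,
        matchValences=False,
        ringMatchesRingOnly=True,
        completeRingsOnly=True,
        timeout=timeout,
    )
    if res.canceled:
        logger.warning("MCS timed out for %s / %s", sa, sb)
        return None
    if res.numAtoms < MIN_HEAVY_ATOMS:
        return None
    query = Chem.MolFromSmarts(res.smartsString)
    match = ma.GetSubstructMatch(query)
    if not match:  # pragma: no cover - FindMCS result always embeds in inputs
        return None
    # use only the bonds of the common subgraph, mapped through the match —
    # taking all bonds among matched atoms would add bonds absent from the
    # MCS and can yield a fragment not embeddable in the second molecule
    bonds = [
        ma.GetBondBetweenAtoms(
            match[b.GetBeginAtomIdx()], match[b.GetEndAtomIdx()]
        ).GetIdx()
        for b in query.GetBonds()
    ]
    smi = Chem.MolFragmentToSmiles(ma, atomsToUse=list(match), bondsToUse=bonds)
    try:
        return Substructure.from_smiles(smi, source="cleavage")
    except StructureParseError:
        # partial aromatic rings ("ccccc") do not re-parse; extract from a
        # kekulized copy instead
        ka = Chem.Mol(ma)
        Chem.Kekulize(ka, clearAromaticFlags=True)
        smi = Chem.MolFragmentToSmiles(ka, atomsToUse=list(match), bondsToUse=bonds)
        return Substructure.from_smiles(smi, source="cleavage")
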