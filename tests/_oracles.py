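"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the code paths they check: the miner oracle is a
double loop over all candidate bodies and heads, the FDR oracle a literal
count, and the common-subgraph oracle an exhaustive enumeration of connected
atom subsets. They are only feasible at tiny problem sizes.
"""

from __future__ import annotations

import itertools

from rdkit import Chem


def brute_force_mine(txns, max_body=3, min_supp_x=5, min_tp=5):
    """All (body, head) pairs meeting the thresholds, by exhaustive counting.

    Returns a set of (frozenset body, head smiles, supp_x, supp_y, tp).
    """
    universe = sorted({f for t in txns for f in t.features})
    heads = sorted(
        {s.smiles for t in txns for s in t.substructures}
    )
    head_supp = {
        h: sum(1 for t in txns if any(s.smiles == h for s in t.substructures))
        for h in heads
    }
    out = set()
    for k in range(1, max_body + 1):
        for combo in itertools.combinations(universe, k):
            body = frozenset(combo)
            supp_x = sum(1 for t in txns if body <= t.features)
            if supp_x < min_supp_x:
                continue
            for h in heads:
                tp = sum(
                    1
                    for t in txns
                    if body <= t.features
                    and any(s.smiles == h for s in t.substructures)
                )
                if tp >= min_tp:
                    out.add((body, h, supp_x, head_supp[h], tp))
    return out


def brute_force_fdr(target_scores, decoy_scores, t):
    """Literal double count of the simple FDR ratio."""
    n_t = 0
    for s in target_scores:
        if s >= t:
            n_t += 1
    n_d = 0
    for s in decoy_scores:
        if s >= t:
            n_d += 1
    if n_t == 0:
        return 0.0 if n_d == 0 else float("inf")
    return n_d / n_t


def _connected_subsets(mol, size):
    """All connected atom-index subsets of the given size."""
    adjacency = {
        a.GetIdx(): {n.GetIdx() for n in a.GetNeighbors()} for a in mol.GetAtoms()
    }
    found = set()
    for seed_atom in adjacency:
        frontier = [frozenset((seed_atom,))]
        while frontier:
            cur = frontier.pop()
            if len(cur) == size:
                found.add(cur)
                continue
            for a in cur:
                for n in adjacency[a]:
                    if n not in cur:
                        frontier.append(cur | {n})
    return found


def _subset_smiles(mol, atoms):
    bonds = [
        mol.GetBondBetweenAtoms(i, j).GetIdx()
        for i, j in itertools.combinations(sorted(atoms), 2)
        if mol.GetBondBetweenAtoms(i, j) is not None
    ]
    return Chem.MolFragmentToSmiles(mol, atomsToUse=sorted(atoms), bondsToUse=bonds)


def exhaustive_mcs_size(smiles_a, smiles_b, max_atoms=8):
    """Largest common connected subgraph, by enumerating subsets of molecule a.

    Returns (n_atoms, one witness SMILES). Element- and bond-order-matched,
    like the implementation it checks, but computed by exhaustive search.
    """
    ma, mb = Chem.MolFromSmiles(smiles_a), Chem.MolFromSmiles(smiles_b)
    best = (0, None)
    for size in range(min(max_atoms, ma.GetNumAtoms()), 1, -1):
        for atoms in _connected_subsets(ma, size):
            smi = _subset_smiles(ma, atoms)
            query = Chem.MolFromSmiles(smi, sanitize=False)
            if query is None:
                continue
            try:
                query.UpdatePropertyCache(strict=False)
            except Exception:
                continue
            if mb.HasSubstructMatch(query):
                return (size, smi)
    return best
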