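"""Synthetic labeled spectral libraries with planted feature-substructure links.

The generator emulates a curated training library: each compound is a real
molecule (SMILES), its spectrum a set of neutral fragment masses organised
in a star-shaped fragmentation tree (the molecular mass as root, one edge
per fragment). A :class:`PlantedAssociation` injects a spectral feature into
the spectra of compounds containing a given substructure with probability
``emit_prob`` (the designed recall) and into other spectra with probability
``leak_prob`` (controlling the designed precision); uniform-random noise
fragments are added on top. Mining such a library should recover the
planted emit probabilities as rule recalls up to binomial sampling error —
which is exactly what the test suite checks.

The star-tree shortcut keeps every planted mass difference realizable as a
tree edge without modelling real fragmentation chemistry; intensities are
uninformative (all 1.0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from pyteomics import mass as _pmass
from rdkit import Chem
from rdkit.Chem.Descriptors import ExactMolWt

from .chemistry import canonical_smiles, contains_substructure
from .feature_extraction import MASS, MDIFF, PROTON_MASS, SpectralFeature
from .spectra_io import SpectralLibrary, SpectrumRecord, round_mass

#: monoisotopic mass of hydrogen chloride — the neutral loss characteristic
#: of chlorinated compounds, used by the worked chloride-loss fixture
HCL_MASS = round(_pmass.calculate_mass(formula="HCl"), 4)

#: small molecules spanning common chemical families (alkanes, phenols,
#: indoles, chlorobenzenes, a steroid core), usable as a default pool
DEFAULT_MOLECULE_POOL = [
    "CCCCCCCCCC",          # decane
    "CCCCCCCCCCCC",        # dodecane
    "CCCCCCCC(C)C",        # branched alkane
    "CCCCCCCCO",           # octanol
    "CCCCCCCC(=O)O",       # octanoic acid
    "CCCCCC(=O)OCC",       # ester
    "Cc1ccccc1",           # toluene
    "CCc1ccccc1",          # ethylbenzene
    "Oc1ccccc1",           # phenol
    "Oc1ccc(C)cc1",        # cresol
    "Oc1ccc(CC)cc1",       # ethylphenol
    "COc1ccccc1",          # anisole
    "Nc1ccccc1",           # aniline
    "CNc1ccccc1",          # N-methylaniline
    "c1ccc2[nH]ccc2c1",    # indole
    "Cc1c[nH]c2ccccc12",   # methylindole
    "NCCc1c[nH]c2ccccc12", # tryptamine
    "OC(=O)Cc1c[nH]c2ccccc12",  # indoleacetic acid
    "Clc1ccccc1",          # chlorobenzene
    "Clc1ccc(C)cc1",       # chlorotoluene
    "Clc1ccc(CC)cc1",      # chloroethylbenzene
    "ClCCCCCC",            # chlorohexane
    "ClCCCCCCCC",          # chlorooctane
    "OCC1OC(O)C(O)C(O)C1O",  # hexose
    "CC(=O)NC1C(O)OC(CO)C(O)C1O",  # N-acetylhexosamine
    "CC12CCC3C(CCC4=CC(=O)CCC34)C1CCC2=O",  # androstenedione core
    "CC12CCC3C(CCC4=CC(=O)CCC34C)C1CCC2O",  # testosterone-like
    "CC(C)CC(N)C(=O)O",    # leucine
    "NC(Cc1ccccc1)C(=O)O", # phenylalanine
    "OC(=O)c1ccccc1O",     # salicylic acid
]


@dataclass(frozen=True)
class PlantedAssociation:
    """A designed feature-substructure link with known recall/precision."""

    feature: SpectralFeature
    substructure: str  # SMILES/SMARTS of the linked substructure
    emit_prob: float  # P(feature | compound contains substructure)
    leak_prob: float = 0.0  # P(feature | compound lacks substructure)

    def __post_init__(self):
        if not 0.0 <= self.leak_prob <= self.emit_prob <= 1.0:
            raise ValueError("require 0 <= leak_prob <= emit_prob <= 1")


@dataclass
class FixtureSpec:
    n_compounds: int
    molecule_pool: Sequence[str]
    associations: Sequence[PlantedAssociation] = field(default_factory=tuple)
    n_noise_features: int = 3
    mass_range: tuple[float, float] = (50.0, 500.0)
    seed: int = 0
    #: sample the pool with replacement (may repeat structures) or draw a
    #: permutation (distinct compounds; requires n_compounds <= pool size)
    replace: bool = True

    def validate(self) -> None:
        if not self.molecule_pool:
            raise ValueError("molecule pool is empty")
        if not self.replace and self.n_compounds > len(self.molecule_pool):
            raise ValueError("n_compounds exceeds pool size with replace=False")
        if self.mass_range[0] <= 0 or self.mass_range[1] <= self.mass_range[0]:
            raise ValueError("invalid mass range")
        for assoc in self.associations:
            if not any(
                _contains_cached(m, assoc.substructure)
                for m in self.molecule_pool
            ):
                raise ValueError(
                    f"substructure {assoc.substructure!r} is contained in no "
                    "pool molecule"
                )


@lru_cache(maxsize=65536)
def _contains_cached(mol_smiles: str, sub_smiles: str) -> bool:
    return contains_substructure(mol_smiles, sub_smiles)


@lru_cache(maxsize=65536)
def _exact_mass(smiles: str) -> float:
    return round_mass(ExactMolWt(Chem.MolFromSmiles(smiles)))


@lru_cache(maxsize=16384)
def _canonical_cached(smiles: str) -> str:
    return canonical_smiles(smiles)


def _containment(pool: Sequence[str], associations: Sequence[PlantedAssociation]):
    table = {}
    for smi in pool:
        table[smi] = tuple(
            _contains_cached(smi, a.substructure) for a in associations
        )
    return table


def generate_library(spec: FixtureSpec) -> SpectralLibrary:
    """Generate a labeled target library with fragmentation trees.

    Deterministic given ``spec.seed``. Each spectrum is a star tree rooted
    at the molecular monoisotopic mass: a planted MDiff feature ``d``
    becomes a fragment at root − d (so the root edge carries the loss d); a
    planted Mass feature becomes a fragment at that mass (skipped for the
    rare compound lighter than the feature). Noise fragments are uniform in
    the mass range below the root.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    pool = [_canonical_cached(s) for s in spec.molecule_pool]
    contains = _containment(pool, spec.associations)
    if spec.replace:
        indices = rng.integers(0, len(pool), size=spec.n_compounds)
    else:
        indices = rng.permutation(len(pool))[: spec.n_compounds]

    records: list[SpectrumRecord] = []
    for i, pool_idx in enumerate(indices):
        smi = pool[pool_idx]
        root = _exact_mass(smi)
        peaks: set[float] = {root}
        edges: set[tuple[float, float]] = set()

        for assoc, has_sub in zip(spec.associations, contains[smi]):
            p = assoc.emit_prob if has_sub else assoc.leak_prob
            if p <= 0.0 or rng.random() >= p:
                continue
            if assoc.feature.ftype == MDIFF:
                child = round_mass(root - assoc.feature.value)
            else:
                child = assoc.feature.value
            if 0 < child < root:
                peaks.add(child)
                edges.add((root, child))

        lo, hi = spec.mass_range
        hi = min(hi, root - 0.5)
        for _ in range(spec.n_noise_features):
            if hi <= lo:
                break
            m = round_mass(rng.uniform(lo, hi))
            if m not in peaks and 0 < m < root:
                peaks.add(m)
                edges.add((root, m))

        if not edges:
            # every spectrum needs at least one tree edge to be trainable;
            # fall back to a half-mass fragment
            child = round_mass(root / 2)
            peaks.add(child)
            edges.add((root, child))

        rec = SpectrumRecord(
            spectrum_id=f"syn{i:04d}",
            peaks=[(m, 1.0) for m in sorted(peaks)],
            precursor_mz=root,
            structure=smi,
            tree_edges=sorted(edges),
        )
        rec.validate()
        records.append(rec)
    return SpectralLibrary(records=records, label="target", masses_are_neutral=True)


def generate_query(spec: FixtureSpec, compound_index: int) -> SpectrumRecord:
    """A protonated query spectrum of one generated compound.

    The spectrum re-emits the compound's library peaks on the [M+H]+ scale
    with the precursor set; structure label and tree edges are stripped, as
    for a real unknown.
    """
    lib = generate_library(spec)
    if not 0 <= compound_index < len(lib.records):
        raise IndexError(f"compound index {compound_index} out of range")
    rec = lib.records[compound_index]
    return SpectrumRecord(
        spectrum_id=f"query_{rec.spectrum_id}",
        peaks=[(round_mass(m + PROTON_MASS), i) for m, i in rec.peaks],
        precursor_mz=round_mass(rec.precursor_mz + PROTON_MASS),
    )


# ---------------------------------------------------------------------------
# ready-made fixture families


def homologous_series(n: int, head: str = "", tail: str = "") -> list[str]:
    """n distinct molecules: linear alkyl chains decorated with head/tail groups."""
    return [head + "C" * k + tail for k in range(1, n + 1)]


def chloride_loss_spec(
    n_chlorinated: int = 30,
    n_other: int = 70,
    emit_prob: float = 1.0,
    leak_prob: float = 0.0,
    seed: int = 0,
    n_noise_features: int = 3,
) -> FixtureSpec:
    """A library of distinct compounds where the HCl-loss mass difference
    marks exactly the chlorinated compounds (at the designed probabilities).

    The pool holds ``n_chlorinated`` chloroalkanes plus alkanes and alkanols;
    the planted association links MDiff = monoisotopic mass of HCl to the
    C-Cl substructure.
    """
    pool = (
        homologous_series(n_chlorinated, tail="Cl")
        + homologous_series((n_other + 1) // 2, head="CCCC")
        + homologous_series(n_other // 2, tail="O")
    )[: n_chlorinated + n_other]
    assoc = PlantedAssociation(
        feature=SpectralFeature(MDIFF, HCL_MASS),
        substructure="CCl",
        emit_prob=emit_prob,
        leak_prob=leak_prob,
    )
    return FixtureSpec(
        n_compounds=n_chlorinated + n_other,
        molecule_pool=pool,
        associations=(assoc,),
        n_noise_features=n_noise_features,
        seed=seed,
        replace=False,
    )


def multi_family_spec(
    n_per_family: int = 25,
    emit_prob: float = 0.8,
    leak_prob: float = 0.0,
    seed: int = 0,
    n_noise_features: int = 3,
) -> FixtureSpec:
    """Four chemical families, each marked by characteristic planted features.

    Chloroalkanes lose HCl; alkylphenols lose water and emit the phenol
    fragment mass; alkylindoles lose HCN and emit the indole fragment mass;
    alkyl benzoic acids lose CO2 and formic acid. Eight planted
    feature-substructure associations in total, all at the same designed
    recall (``emit_prob``).
    """
    losses = _pmass.calculate_mass
    families: list[tuple[str, str, list[SpectralFeature]]] = [
        (
            "",  # chloroalkanes
            "Cl",
            [SpectralFeature(MDIFF, HCL_MASS)],
        ),
        (
            "Oc1ccccc1",
            "",
            [
                SpectralFeature(MDIFF, losses(formula="H2O")),
                SpectralFeature(MASS, losses(formula="C6H6O")),
            ],
        ),
        (
            "c1ccc2[nH]ccc2c1",
            "",
            [
                SpectralFeature(MDIFF, losses(formula="HCN")),
                SpectralFeature(MASS, losses(formula="C8H7N")),
            ],
        ),
        (
            "OC(=O)c1ccccc1",
            "",
            [
                SpectralFeature(MDIFF, losses(formula="CO2")),
                SpectralFeature(MDIFF, losses(formula="CH2O2")),
            ],
        ),
    ]
    pool: list[str] = []
    associations: list[PlantedAssociation] = []
    for head, tail, feats in families:
        pool.extend(homologous_series(n_per_family, head=head, tail=tail))
        sub = (head + tail) if (head + tail) != "Cl" else "CCl"
        for f in feats:
            associations.append(
                PlantedAssociation(
                    feature=f,
                    substructure=sub,
                    emit_prob=emit_prob,
                    leak_prob=leak_prob,
                )
            )
    return FixtureSpec(
        n_compounds=len(pool),
        molecule_pool=pool,
        associations=tuple(associations),
        n_noise_features=n_noise_features,
        seed=seed,
        replace=False,
    )


#: the substructure patterns matching the multi-family fixture's planted heads
MULTI_FAMILY_PATTERNS = ["CCl", "Oc1ccccc1", "c1ccc2[nH]ccc2c1", "OC(=O)c1ccccc1"]


def write_ground_truth(spec: FixtureSpec, path) -> None:
    """Dump the planted associations (the generative ground truth) as JSON."""
    payload = {
        "n_compounds": spec.n_compounds,
        "seed": spec.seed,
        "associations": [
            {
                "ftype": a.feature.ftype,
                "value": a.feature.value,
                "substructure": a.substructure,
                "emit_prob": a.emit_prob,
                "leak_prob": a.leak_prob,
            }
            for a in spec.associations
        ],
    }
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=2)
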