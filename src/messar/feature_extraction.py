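"""Discretized spectral features: fragment masses and mass differences.

Two feature types exist. ``Mass`` is the neutral exact mass of a fragment;
``MDiff`` is the difference between two fragment masses (a neutral loss when
the fragments are parent and child of a fragmentation-tree edge). Feature
identity for mining is the pair (type, value rounded to 4 decimals): training
masses are formula-derived neutral masses, so equal features collide exactly
after rounding.

Target training uses only fragmentation-tree nodes and edges — the losses
along tree edges correspond to fragmentation reactions, whereas all-pairs
mass differences are dominated by structurally meaningless combinations.
Decoy training samples a fraction of all pairwise differences to mimic the
feature load of the target side. Query spectra, which have no trees, use all
fragments and all pairwise differences (including precursor-fragment losses).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .spectra_io import MASS_DECIMALS, SpectrumRecord, round_mass

#: monoisotopic mass of a proton, Da
PROTON_MASS = 1.00728

MASS = "Mass"
MDIFF = "MDiff"


@dataclass(frozen=True, order=True)
class SpectralFeature:
    ftype: str  # Mass | MDiff
    value: float  # Da, neutral scale, rounded to 4 decimals

    def __post_init__(self):
        if self.ftype not in (MASS, MDIFF):
            raise ValueError(f"unknown feature type {self.ftype!r}")
        if self.value <= 0:
            raise ValueError("feature value must be positive")
        object.__setattr__(self, "value", round_mass(self.value))

    def __str__(self) -> str:
        return f"{self.ftype}:{self.value:.{MASS_DECIMALS}f}"

    @classmethod
    def parse(cls, token: str) -> "SpectralFeature":
        ftype, _, value = token.partition(":")
        return cls(ftype, float(value))


@dataclass
class FeatureSet:
    spectrum_id: str
    features: frozenset[SpectralFeature]


def all_mass_differences(peaks: Iterable[float]) -> set[SpectralFeature]:
    """One MDiff per unordered pair of peaks; fewer than 2 peaks give none."""
    masses = sorted({round_mass(m) for m in peaks})
    return {
        SpectralFeature(MDIFF, round_mass(b - a))
        for a, b in itertools.combinations(masses, 2)
        if b - a > 0
    }


def extract_target_features(rec: SpectrumRecord) -> FeatureSet:
    """Tree nodes as Mass features, tree-edge losses as MDiff features."""
    if not rec.tree_edges:
        raise ValueError(
            f"{rec.spectrum_id}: no fragmentation-tree edges; target training "
            "requires trees (use extract_query_features for raw spectra)"
        )
    feats: set[SpectralFeature] = set()
    for parent, child in rec.tree_edges:
        feats.add(SpectralFeature(MASS, parent))
        feats.add(SpectralFeature(MASS, child))
        feats.add(SpectralFeature(MDIFF, round_mass(parent - child)))
    return FeatureSet(rec.spectrum_id, frozenset(feats))


def extract_decoy_features(
    rec: SpectrumRecord, fraction: float = 0.2, seed: int = 0
) -> FeatureSet:
    """Random sample of ``floor(fraction * C(n,2))`` (min 1) pairwise MDiffs.

    Sampling is uniform without replacement and deterministic given the seed.
    """
    universe = sorted(all_mass_differences(rec.peak_masses))
    if not universe:
        return FeatureSet(rec.spectrum_id, frozenset())
    k = min(len(universe), max(1, int(fraction * len(universe))))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(universe), size=k, replace=False)
    return FeatureSet(rec.spectrum_id, frozenset(universe[i] for i in idx))


def extract_query_features(
    rec: SpectrumRecord, assume_protonated: bool = True
) -> FeatureSet:
    """Features of a raw query spectrum.

    Mass features are the peaks neutralized by one proton under the [M+H]+
    assumption (positive ion mode); MDiff features are all pairwise peak
    differences plus precursor-fragment losses when the precursor m/z is
    known. The proton cancels in differences, so MDiffs are charge-agnostic.
    """
    shift = PROTON_MASS if assume_protonated else 0.0
    feats: set[SpectralFeature] = {
        SpectralFeature(MASS, round_mass(m - shift))
        for m in rec.peak_masses
        if m - shift > 0
    }
    feats |= all_mass_differences(rec.peak_masses)
    if rec.precursor_mz is not None:
        for m in rec.peak_masses:
            d = round_mass(rec.precursor_mz - m)
            if d > 0:
                feats.add(SpectralFeature(MDIFF, d))
    return FeatureSet(rec.spectrum_id, frozenset(feats))


def features_match(
    q: SpectralFeature, r: SpectralFeature, ppm: float = 20.0
) -> bool:
    """True iff types agree and the values lie within ``ppm`` of the reference."""
    if q.ftype != r.ftype:
        return False
    return abs(q.value - r.value) <= ppm * 1e-6 * r.value


def write_feature_sets(feature_sets: Iterable[FeatureSet], path) -> None:
    with open(path, "w") as handle:
        handle.write("spectrum_id\tftype\tvalue\n")
        for fs in feature_sets:
            for f in sorted(fs.features):
                handle.write(f"{fs.spectrum_id}\t{f.ftype}\t{f.value:.4f}\n")


def cluster_features_ppm(
    values: Iterable[float], ppm: float = 20.0
) -> dict[float, float]:
    """Greedy single-linkage clustering of raw feature values at a ppm tolerance.

    Returns a map from each input value to its cluster representative (the
    cluster mean, rounded). Intended for raw (non-tree) libraries whose
    masses are not formula-derived and therefore do not collide exactly.
    """
    ordered = sorted(set(round_mass(v) for v in values))
    mapping: dict[float, float] = {}
    cluster: list[float] = []

    def flush():
        if cluster:
            center = round_mass(sum(cluster) / len(cluster))
            for v in cluster:
                mapping[v] = center

    for v in ordered:
        if cluster and (v - cluster[-1]) > ppm * 1e-6 * v:
            flush()
            cluster = []
        cluster.append(v)
    flush()
    return mapping
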