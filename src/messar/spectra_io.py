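"""Reading, writing and merging spectral libraries.

Libraries are MGF files (``BEGIN IONS``/``END IONS`` blocks) with two
non-standard header keys, ``SMILES=`` and ``INCHIKEY=``, carrying the
structure annotation of each spectrum. Fragmentation-tree edges arrive in a
separate TSV keyed by spectrum id.

Training libraries carry *neutral* masses (formula-annotated fragments);
raw query spectra carry protonated m/z values. The per-library flag
``masses_are_neutral`` records which convention applies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

from pyteomics import mgf as _mgf

from .chemistry import StructureParseError, canonical_smiles

logger = logging.getLogger(__name__)

#: number of decimals defining fragment-mass identity
MASS_DECIMALS = 4


def round_mass(m: float) -> float:
    return round(float(m), MASS_DECIMALS)


@dataclass
class SpectrumRecord:
    """One (possibly merged) spectrum with optional structure annotation."""

    spectrum_id: str
    peaks: list[tuple[float, float]]
    precursor_mz: Optional[float] = None
    structure: Optional[str] = None
    inchikey_block1: Optional[str] = None
    tree_edges: list[tuple[float, float]] = field(default_factory=list)

    @property
    def peak_masses(self) -> list[float]:
        return [m for m, _ in self.peaks]

    def structure_key(self) -> Optional[str]:
        """Identity used for merging: InChIKey block 1, else canonical SMILES."""
        if self.inchikey_block1:
            return self.inchikey_block1
        if self.structure:
            try:
                return canonical_smiles(self.structure)
            except StructureParseError:
                return self.structure
        return None

    def validate(self) -> None:
        masses = [round_mass(m) for m, _ in self.peaks]
        if any(m <= 0 for m in masses):
            raise ValueError(f"{self.spectrum_id}: non-positive peak mass")
        if len(set(masses)) != len(masses):
            raise ValueError(f"{self.spectrum_id}: duplicate peak masses")
        mass_set = set(masses)
        for parent, child in self.tree_edges:
            if parent <= child:
                raise ValueError(f"{self.spectrum_id}: edge parent <= child")
            if round_mass(parent) not in mass_set or round_mass(child) not in mass_set:
                raise ValueError(f"{self.spectrum_id}: edge mass not among peaks")


@dataclass
class SpectralLibrary:
    records: list[SpectrumRecord]
    label: str = "target"  # target | decoy | query
    masses_are_neutral: bool = True

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class SkipReport:
    """Counts of records/lines rejected while reading."""

    empty_blocks: int = 0
    bad_peak_lines: int = 0
    bad_edges: int = 0


def read_mgf(
    path: str | Path, kind: str = "target", report: Optional[SkipReport] = None
) -> SpectralLibrary:
    """Read an MGF file into a library.

    Blocks without any peak are rejected and counted in the skip report;
    ``SMILES``/``INCHIKEY`` headers populate the structure fields. The
    InChIKey first block (14 characters before the first dash) is used for
    structure identity.
    """
    report = report if report is not None else SkipReport()
    records: list[SpectrumRecord] = []
    with _mgf.MGF(str(path), convert_arrays=0) as reader:
        for i, entry in enumerate(reader):
            params = entry.get("params", {})
            masses = entry.get("m/z array") or []
            intens = entry.get("intensity array") or []
            if len(masses) == 0:
                report.empty_blocks += 1
                logger.warning("%s: block %d has no peaks, skipped", path, i)
                continue
            if len(intens) < len(masses):
                intens = list(intens) + [0.0] * (len(masses) - len(intens))
            peaks, seen = [], set()
            for m, inten in zip(masses, intens):
                rm = round_mass(m)
                if rm <= 0:
                    report.bad_peak_lines += 1
                    continue
                if rm in seen:
                    continue
                seen.add(rm)
                peaks.append((rm, float(inten)))
            pepmass = params.get("pepmass")
            precursor = None
            if pepmass:
                precursor = float(pepmass[0] if isinstance(pepmass, tuple) else pepmass)
            inchikey = params.get("inchikey")
            records.append(
                SpectrumRecord(
                    spectrum_id=str(params.get("title", f"spectrum_{i}")),
                    peaks=peaks,
                    precursor_mz=precursor,
                    structure=params.get("smiles"),
                    inchikey_block1=inchikey.split("-")[0][:14] if inchikey else None,
                )
            )
    return SpectralLibrary(
        records=records, label=kind, masses_are_neutral=(kind != "query")
    )


def write_mgf(lib: SpectralLibrary, path: str | Path) -> None:
    """Write a library back to MGF, preserving structure annotations."""
    spectra = []
    for rec in lib.records:
        params: dict = {"title": rec.spectrum_id}
        if rec.precursor_mz is not None:
            params["pepmass"] = rec.precursor_mz
        if rec.structure:
            params["smiles"] = rec.structure
        if rec.inchikey_block1:
            params["inchikey"] = rec.inchikey_block1
        spectra.append(
            {
                "params": params,
                "m/z array": [m for m, _ in rec.peaks],
                "intensity array": [i for _, i in rec.peaks],
            }
        )
    with open(path, "w") as handle:
        _mgf.write(spectra, handle)


def merge_by_structure(lib: SpectralLibrary) -> SpectralLibrary:
    """Combine spectra of the same compound; duplicated fragments are kept once.

    Identity is the InChIKey first block when available, otherwise the
    canonical structure string. Fragments equal after rounding to 4 decimals
    are duplicates; tree edges are unioned. Records without any structure
    label are passed through unmerged with a warning.
    """
    groups: dict[str, list[SpectrumRecord]] = {}
    unlabeled: list[SpectrumRecord] = []
    order: list[str] = []
    for rec in lib.records:
        key = rec.structure_key()
        if key is None:
            logger.warning("%s has no structure label, left unmerged", rec.spectrum_id)
            unlabeled.append(rec)
            continue
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(rec)

    merged: list[SpectrumRecord] = []
    for key in order:
        members = groups[key]
        peaks: dict[float, float] = {}
        edges: set[tuple[float, float]] = set()
        for rec in members:
            for m, inten in rec.peaks:
                rm = round_mass(m)
                peaks[rm] = max(inten, peaks.get(rm, 0.0))
            edges.update((round_mass(p), round_mass(c)) for p, c in rec.tree_edges)
        first = members[0]
        merged.append(
            SpectrumRecord(
                spectrum_id=first.spectrum_id,
                peaks=sorted(peaks.items()),
                precursor_mz=first.precursor_mz,
                structure=first.structure,
                inchikey_block1=first.inchikey_block1,
                tree_edges=sorted(edges),
            )
        )
    return SpectralLibrary(
        records=merged + unlabeled,
        label=lib.label,
        masses_are_neutral=lib.masses_are_neutral,
    )


def read_tree_edges(
    path: str | Path, report: Optional[SkipReport] = None
) -> dict[str, list[tuple[float, float]]]:
    """Read a fragmentation-tree edge TSV (spectrum_id, parent_mass, child_mass).

    Rows with parent <= child are rejected. A header row is recognised and
    skipped.
    """
    report = report if report is not None else SkipReport()
    edges: dict[str, list[tuple[float, float]]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                report.bad_edges += 1
                continue
            sid, raw_parent, raw_child = parts[0], parts[1], parts[2]
            try:
                parent, child = float(raw_parent), float(raw_child)
            except ValueError:
                if lineno == 0:
                    continue  # header
                report.bad_edges += 1
                continue
            if parent <= child:
                report.bad_edges += 1
                logger.warning("%s line %d: parent <= child, rejected", path, lineno)
                continue
            edges.setdefault(sid, []).append((round_mass(parent), round_mass(child)))
    return edges


def attach_tree_edges(
    lib: SpectralLibrary,
    edges: dict[str, list[tuple[float, float]]],
    report: Optional[SkipReport] = None,
) -> SpectralLibrary:
    """Attach tree edges to matching records; edges naming unknown masses are dropped."""
    report = report if report is not None else SkipReport()
    out = []
    for rec in lib.records:
        rec_edges = edges.get(rec.spectrum_id)
        if not rec_edges:
            out.append(rec)
            continue
        mass_set = {round_mass(m) for m in rec.peak_masses}
        kept = []
        for parent, child in rec_edges:
            if parent in mass_set and child in mass_set:
                kept.append((parent, child))
            else:
                report.bad_edges += 1
                logger.warning(
                    "%s: edge (%s, %s) references unknown mass", rec.spectrum_id, parent, child
                )
        out.append(replace(rec, tree_edges=sorted(set(rec.tree_edges) | set(kept))))
    return SpectralLibrary(
        records=out, label=lib.label, masses_are_neutral=lib.masses_are_neutral
    )


def write_tree_edges(
    edges: dict[str, list[tuple[float, float]]], path: str | Path
) -> None:
    with open(path, "w") as handle:
        handle.write("spectrum_id\tparent_mass\tchild_mass\n")
        for sid, pairs in edges.items():
            for parent, child in pairs:
                handle.write(f"{sid}\t{parent:.4f}\t{child:.4f}\n")
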