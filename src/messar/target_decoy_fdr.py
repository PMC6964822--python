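"""Target-decoy FDR estimation and recall-threshold filtering of rules.

A decoy library keeps every compound label but decouples the spectra from
the structures: each record's peaks are replaced by an equal-sized random
draw from the pooled peaks of all *other* records. Rules mined from such a
library can only reflect chance co-occurrence, so the ratio

    FDR(t) = #{decoy rules with recall >= t} / #{target rules with recall >= t}

(the "simple FDR", with 0/0 taken as 0) estimates the fraction of spurious
target rules accepted at a recall threshold t. The final database keeps
target rules with recall strictly above the smallest threshold achieving
the requested FDR level.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .rule_mining import Rule
from .spectra_io import SpectralLibrary, SpectrumRecord, round_mass


@dataclass
class FdrCurve:
    thresholds: list[float]  # sorted ascending
    n_target_kept: list[int]
    n_decoy_kept: list[int]
    fdr: list[float]

    def write_tsv(self, path) -> None:
        with open(path, "w") as handle:
            handle.write("threshold\tn_target\tn_decoy\tfdr\n")
            for t, nt, nd, f in zip(
                self.thresholds, self.n_target_kept, self.n_decoy_kept, self.fdr
            ):
                handle.write(f"{t:.6f}\t{nt}\t{nd}\t{f:.6f}\n")


def make_decoy_library(lib: SpectralLibrary, seed: int) -> SpectralLibrary:
    """Randomized library: labels kept, peaks drawn from the other records' pool.

    Per-record peak counts are preserved exactly; the draw is without
    replacement from the multiset of all peaks of the other records, with
    collisions after rounding resolved by re-draws so that each decoy
    spectrum still has unique peak masses. Fragmentation trees are dropped:
    decoy features are sampled from all pairwise mass differences instead.
    """
    if len(lib.records) < 2:
        raise ValueError("decoy generation needs at least 2 records")
    rng = np.random.default_rng(seed)
    all_peaks = [m for rec in lib.records for m in rec.peak_masses]
    offsets = np.cumsum([0] + [len(rec.peaks) for rec in lib.records])
    records = []
    for i, rec in enumerate(lib.records):
        pool = np.array(all_peaks[: offsets[i]] + all_peaks[offsets[i + 1]:])
        n = len(rec.peaks)
        order = rng.permutation(len(pool))
        chosen: list[float] = []
        seen: set[float] = set()
        for j in order:
            m = round_mass(pool[j])
            if m in seen:
                continue
            seen.add(m)
            chosen.append(m)
            if len(chosen) == n:
                break
        records.append(
            SpectrumRecord(
                spectrum_id=rec.spectrum_id,
                peaks=[(m, 1.0) for m in sorted(chosen)],
                precursor_mz=rec.precursor_mz,
                structure=rec.structure,
                inchikey_block1=rec.inchikey_block1,
                tree_edges=[],
            )
        )
    return SpectralLibrary(
        records=records, label="decoy", masses_are_neutral=lib.masses_are_neutral
    )


def fdr_at_threshold(
    target_recalls: Sequence[float], decoy_recalls: Sequence[float], t: float
) -> float:
    """#{decoy >= t} / #{target >= t}, with 0 when both counts are 0."""
    n_target = sum(1 for r in target_recalls if r >= t)
    n_decoy = sum(1 for r in decoy_recalls if r >= t)
    if n_target == 0:
        return 0.0 if n_decoy == 0 else float("inf")
    return n_decoy / n_target


def fdr_curve(
    target_recalls: Sequence[float], decoy_recalls: Sequence[float]
) -> FdrCurve:
    thresholds = sorted(set(target_recalls) | set(decoy_recalls))
    nt, nd, fdrs = [], [], []
    for t in thresholds:
        nt.append(sum(1 for r in target_recalls if r >= t))
        nd.append(sum(1 for r in decoy_recalls if r >= t))
        fdrs.append(fdr_at_threshold(target_recalls, decoy_recalls, t))
    return FdrCurve(thresholds, nt, nd, fdrs)


def recall_threshold_for_fdr(
    target_recalls: Sequence[float],
    decoy_recalls: Sequence[float],
    alpha: float = 0.01,
) -> float:
    """Smallest observed target recall t with FDR(t) <= alpha.

    Scans the observed target-recall values ascending and returns the first
    achieving the level; raises when even the strictest threshold fails.
    """
    if not target_recalls:
        raise ValueError("no target recalls")
    for t in sorted(set(target_recalls)):
        f = fdr_at_threshold(target_recalls, decoy_recalls, t)
        if f <= alpha:
            return t
    raise ValueError(
        f"no recall threshold achieves FDR <= {alpha}; try a larger alpha"
    )


def filter_rules(rules: Sequence[Rule], t: float) -> list[Rule]:
    """Target-origin rules with recall strictly above the threshold."""
    return [r for r in rules if r.origin == "target" and r.recall > t]


def qvalues(fdrs: Sequence[float], thresholds: Sequence[float]) -> list[float]:
    """Optional monotone transform: q(t) = min FDR over thresholds >= t."""
    out = [0.0] * len(fdrs)
    running = float("inf")
    for i in range(len(fdrs) - 1, -1, -1):
        running = min(running, fdrs[i])
        out[i] = running
    return out
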