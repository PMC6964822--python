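"""Association rule mining over (spectral features, substructures) transactions.

Each transaction joins one compound's spectral feature set with the set of
substructures generated from its structure. A rule ``X => Y`` has a body of
one to three co-occurring spectral features and a single substructure head.
Viewing the rule as a binary classifier over the library gives the standard
confusion matrix:

* ``Supp(X) = TP + FP`` — spectra containing the feature set X,
* ``Supp(Y) = TP + FN`` — compounds containing the substructure Y,
* ``precision = TP / Supp(X)``, ``recall = TP / Supp(Y)``.

Bodies are enumerated apriori-style (features only — heads never enter the
itemset lattice, since a body must contain only features and a head exactly
one substructure), then each frequent body is crossed with every
sufficiently co-occurring substructure.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .chemistry import (
    Substructure,
    cleavage_substructures,
    predefined_substructures,
    StructureParseError,
)
from .feature_extraction import FeatureSet, SpectralFeature
from .spectra_io import SpectralLibrary

logger = logging.getLogger(__name__)

#: default thresholds: a rule must be supported by at least 5 spectra and
#: have at least 5 true positives, mirroring the TP >= 5 evaluability bar
MIN_SUPP_X = 5
MIN_TP = 5
MAX_BODY = 3


@dataclass
class Transaction:
    spectrum_id: str
    features: frozenset[SpectralFeature]
    substructures: frozenset[Substructure]


@dataclass
class Rule:
    rule_id: int
    body: frozenset[SpectralFeature]
    head: Substructure
    supp_x: int
    supp_y: int
    tp: int
    origin: str = "target"  # target | decoy

    @property
    def precision(self) -> float:
        return self.tp / self.supp_x if self.supp_x else float("nan")

    @property
    def recall(self) -> float:
        return self.tp / self.supp_y if self.supp_y else float("nan")

    def body_token(self) -> str:
        return ";".join(str(f) for f in sorted(self.body))


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int
    evaluable: bool = True

    @property
    def supp_x(self) -> int:
        return self.tp + self.fp

    @property
    def supp_y(self) -> int:
        return self.tp + self.fn

    @property
    def precision(self) -> Optional[float]:
        return self.tp / self.supp_x if self.supp_x else None

    @property
    def recall(self) -> Optional[float]:
        return self.tp / self.supp_y if self.supp_y else None


def substructures_for_molecule(
    smiles: str,
    patterns: Sequence[str],
    max_cuts: int = 2,
    cleavage_policy: str = "all_acyclic",
) -> frozenset[Substructure]:
    """Predefined-pattern matches plus cleavage fragments, filtered."""
    subs = predefined_substructures(smiles, patterns)
    subs |= cleavage_substructures(smiles, max_cuts=max_cuts, policy=cleavage_policy)
    return frozenset(subs)


def build_transactions(
    lib: SpectralLibrary,
    feature_sets: Iterable[FeatureSet],
    patterns: Sequence[str],
    max_cuts: int = 2,
    cleavage_policy: str = "all_acyclic",
) -> list[Transaction]:
    """One transaction per labeled record; unparsable structures are excluded."""
    by_id = {fs.spectrum_id: fs for fs in feature_sets}
    # substructure sets are deterministic per structure: compute once per SMILES
    cache: dict[str, frozenset[Substructure]] = {}
    txns: list[Transaction] = []
    for rec in lib.records:
        fs = by_id.get(rec.spectrum_id)
        if fs is None:
            logger.warning("%s: no feature set, excluded", rec.spectrum_id)
            continue
        if not rec.structure:
            logger.warning("%s: no structure label, excluded", rec.spectrum_id)
            continue
        if rec.structure not in cache:
            try:
                cache[rec.structure] = substructures_for_molecule(
                    rec.structure, patterns, max_cuts, cleavage_policy
                )
            except StructureParseError:
                logger.warning("%s: unparsable structure, excluded", rec.spectrum_id)
                cache[rec.structure] = None  # type: ignore[assignment]
        subs = cache[rec.structure]
        if subs is None:
            continue
        txns.append(Transaction(rec.spectrum_id, fs.features, subs))
    return txns


def _frequent_itemsets(
    txns: Sequence[Transaction], max_body: int, min_supp: int
) -> dict[frozenset[SpectralFeature], int]:
    """Apriori enumeration of feature itemsets of size <= max_body."""
    counts: dict[frozenset[SpectralFeature], int] = {}
    singles: dict[SpectralFeature, int] = {}
    for t in txns:
        for f in t.features:
            singles[f] = singles.get(f, 0) + 1
    frequent_items = {f for f, c in singles.items() if c >= min_supp}
    for f in frequent_items:
        counts[frozenset((f,))] = singles[f]

    prev_level = set(counts)
    for size in range(2, max_body + 1):
        level: dict[frozenset[SpectralFeature], int] = {}
        for t in txns:
            present = sorted(f for f in t.features if f in frequent_items)
            if len(present) < size:
                continue
            for combo in itertools.combinations(present, size):
                cand = frozenset(combo)
                # anti-monotonicity: all (size-1)-subsets must be frequent
                if size > 2 and any(
                    cand - {f} not in prev_level for f in cand
                ):
                    continue
                level[cand] = level.get(cand, 0) + 1
        level = {c: n for c, n in level.items() if n >= min_supp}
        counts.update(level)
        prev_level = set(level)
        if not prev_level:
            break
    return counts


def mine_rules(
    txns: Sequence[Transaction],
    max_body: int = MAX_BODY,
    min_supp_x: int = MIN_SUPP_X,
    min_tp: int = MIN_TP,
    origin: str = "target",
) -> list[Rule]:
    """Mine all rules (body of <= max_body features, one substructure head).

    ``supp_x`` counts transactions containing the body, ``supp_y`` counts
    compounds containing the head, ``tp`` counts both. Rules are sorted by
    (recall desc, precision desc, body size asc, head SMILES) and numbered
    from 1 in that order.
    """
    if not txns:
        return []
    itemsets = _frequent_itemsets(txns, max_body, min_supp_x)
    head_support: dict[Substructure, int] = {}
    for t in txns:
        for s in t.substructures:
            head_support[s] = head_support.get(s, 0) + 1

    raw: list[tuple[frozenset[SpectralFeature], Substructure, int, int, int]] = []
    for body, supp_x in itemsets.items():
        co: dict[Substructure, int] = {}
        for t in txns:
            if body <= t.features:
                for s in t.substructures:
                    co[s] = co.get(s, 0) + 1
        for head, tp in co.items():
            if tp >= min_tp:
                raw.append((body, head, supp_x, head_support[head], tp))

    raw.sort(
        key=lambda r: (
            -(r[4] / r[3]),  # recall desc
            -(r[4] / r[2]),  # precision desc
            len(r[0]),  # body size asc
            r[1].smiles,  # head lexicographic
            tuple(sorted(r[0])),
        )
    )
    return [
        Rule(rule_id=i + 1, body=b, head=h, supp_x=sx, supp_y=sy, tp=tp, origin=origin)
        for i, (b, h, sx, sy, tp) in enumerate(raw)
    ]


def evaluate_rule(rule: Rule, txns: Sequence[Transaction]) -> ConfusionMatrix:
    """Exact confusion matrix of a rule on an independent transaction set.

    Rules with fewer than ``MIN_TP`` true positives on the evaluation set are
    flagged not evaluable (too rare to assess), as are rules whose body never
    occurs (precision undefined).
    """
    tp = fp = fn = tn = 0
    heads_by_smiles = rule.head.smiles
    for t in txns:
        has_x = rule.body <= t.features
        has_y = any(s.smiles == heads_by_smiles for s in t.substructures)
        if has_x and has_y:
            tp += 1
        elif has_x:
            fp += 1
        elif has_y:
            fn += 1
        else:
            tn += 1
    evaluable = tp >= MIN_TP and (tp + fp) > 0
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn, evaluable=evaluable)


# ---------------------------------------------------------------------------
# rule database serialization

RULE_COLUMNS = [
    "rule_id",
    "origin",
    "body",
    "head",
    "supp_x",
    "supp_y",
    "tp",
    "precision",
    "recall",
]


def write_rules(
    rules: Iterable[Rule], path, config_fingerprint: str = ""
) -> None:
    with open(path, "w") as handle:
        if config_fingerprint:
            handle.write(f"# config: {config_fingerprint}\n")
        handle.write("\t".join(RULE_COLUMNS) + "\n")
        for r in rules:
            handle.write(
                f"{r.rule_id}\t{r.origin}\t{r.body_token()}\t{r.head.smiles}\t"
                f"{r.supp_x}\t{r.supp_y}\t{r.tp}\t{r.precision:.6f}\t{r.recall:.6f}\n"
            )


def read_rules(path) -> tuple[list[Rule], str]:
    """Read a rule TSV; returns (rules, config fingerprint header or '')."""
    rules: list[Rule] = []
    fingerprint = ""
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if line.startswith("# config:"):
                fingerprint = line[len("# config:"):].strip()
                continue
            if not line or line.startswith("rule_id"):
                continue
            (rid, origin, body, head, sx, sy, tp, _prec, _rec) = line.split("\t")
            rules.append(
                Rule(
                    rule_id=int(rid),
                    body=frozenset(
                        SpectralFeature.parse(tok) for tok in body.split(";")
                    ),
                    head=Substructure.from_smiles(head),
                    supp_x=int(sx),
                    supp_y=int(sy),
                    tp=int(tp),
                    origin=origin,
                )
            )
    return rules, fingerprint
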