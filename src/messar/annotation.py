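"""Substructure recommendation for query spectra from the rule database.

A rule matches a query when *every* feature of its body finds a query
feature of the same type within the ppm tolerance (bodies are conjunctions
of co-occurring features). Matched rules, ranked by recall, can then be
aggregated:

* ``naive`` — rules with identical heads are pooled;
* ``exhaustive`` — every pair of matched rules whose heads have Tanimoto
  similarity above 0.5 is replaced by the pair's maximum common
  substructure; identical MCS strings are merged and scored by the summed
  recall of all contributing rules (each rule counted once);
* ``fast`` — exhaustive aggregation restricted to the 20 highest-recall
  matches.

Recommendations smaller than 5 heavy atoms are dropped at reporting time
(they rarely help structure elucidation) and the remainder ranked by score.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .chemistry import Substructure, mcs, tanimoto
from .feature_extraction import FeatureSet, SpectralFeature, features_match
from .rule_mining import Rule

logger = logging.getLogger(__name__)

DEFAULT_PPM = 20.0
SIM_THRESHOLD = 0.5
MIN_REPORT_HEAVY_ATOMS = 5
FAST_TOP_N = 20


@dataclass
class RuleMatch:
    rule: Rule
    matched_features: dict[SpectralFeature, SpectralFeature]  # body item -> query item


@dataclass
class Recommendation:
    substructure: Substructure
    score: float  # sum of recall over contributing rules
    contributing_rule_ids: frozenset[int]
    rank: int = 0


def match_rules(
    query: FeatureSet, db: Sequence[Rule], ppm: float = DEFAULT_PPM
) -> list[RuleMatch]:
    """Rules whose every body feature is found in the query, by descending recall."""
    matches: list[RuleMatch] = []
    for rule in db:
        assignment: dict[SpectralFeature, SpectralFeature] = {}
        for body_feat in rule.body:
            hit = next(
                (q for q in query.features if features_match(q, body_feat, ppm)), None
            )
            if hit is None:
                break
            assignment[body_feat] = hit
        else:
            matches.append(RuleMatch(rule, assignment))
    matches.sort(key=lambda m: (-m.rule.recall, m.rule.rule_id))
    return matches


def _rank(recs: list[Recommendation]) -> list[Recommendation]:
    recs.sort(
        key=lambda r: (-r.score, -r.substructure.n_heavy, r.substructure.smiles)
    )
    for i, r in enumerate(recs):
        r.rank = i + 1
    return recs


def aggregate_naive(
    matches: Sequence[RuleMatch], small_filter: int = 0
) -> list[Recommendation]:
    """Pool rules recommending the identical substructure; score = summed recall."""
    groups: dict[str, list[Rule]] = {}
    heads: dict[str, Substructure] = {}
    for m in matches:
        key = m.rule.head.smiles
        groups.setdefault(key, []).append(m.rule)
        heads[key] = m.rule.head
    recs = [
        Recommendation(
            substructure=heads[key],
            score=sum(r.recall for r in rules),
            contributing_rule_ids=frozenset(r.rule_id for r in rules),
        )
        for key, rules in groups.items()
        if heads[key].n_heavy >= small_filter
    ]
    return _rank(recs)


def aggregate_exhaustive(
    matches: Sequence[RuleMatch],
    sim_threshold: float = SIM_THRESHOLD,
    small_filter: int = MIN_REPORT_HEAVY_ATOMS,
) -> list[Recommendation]:
    """MCS aggregation over all analogous rule pairs.

    Pairs of matched rules whose heads exceed the Tanimoto threshold
    contribute their MCS; rules appearing in no analogous pair pass through
    with their own head. A rule's recall counts once per distinct
    recommendation even when several pairs yield the same MCS.
    """
    rules = [m.rule for m in matches]
    mcs_groups: dict[str, set[int]] = {}
    mcs_struct: dict[str, Substructure] = {}
    in_pair: set[int] = set()
    for a, b in itertools.combinations(rules, 2):
        if tanimoto(a.head, b.head) <= sim_threshold:
            continue
        common = mcs(a.head, b.head)
        if common is None:
            logger.warning(
                "no MCS for analogous pair %s / %s", a.head.smiles, b.head.smiles
            )
            continue
        in_pair.update((a.rule_id, b.rule_id))
        mcs_groups.setdefault(common.smiles, set()).update((a.rule_id, b.rule_id))
        mcs_struct[common.smiles] = common

    by_id = {r.rule_id: r for r in rules}
    recs: list[Recommendation] = []
    for key, ids in mcs_groups.items():
        recs.append(
            Recommendation(
                substructure=mcs_struct[key],
                score=sum(by_id[i].recall for i in ids),
                contributing_rule_ids=frozenset(ids),
            )
        )
    # singletons pass through with their own head; identical heads pooled
    passthrough: dict[str, list[Rule]] = {}
    for r in rules:
        if r.rule_id not in in_pair:
            passthrough.setdefault(r.head.smiles, []).append(r)
    for key, group in passthrough.items():
        recs.append(
            Recommendation(
                substructure=group[0].head,
                score=sum(r.recall for r in group),
                contributing_rule_ids=frozenset(r.rule_id for r in group),
            )
        )
    recs = [r for r in recs if r.substructure.n_heavy >= small_filter]
    return _rank(recs)


def aggregate_fast(
    matches: Sequence[RuleMatch],
    sim_threshold: float = SIM_THRESHOLD,
    small_filter: int = MIN_REPORT_HEAVY_ATOMS,
) -> list[Recommendation]:
    """Exhaustive aggregation on the 20 most sensitive (highest-recall) matches."""
    top = sorted(matches, key=lambda m: (-m.rule.recall, m.rule.rule_id))[:FAST_TOP_N]
    return aggregate_exhaustive(top, sim_threshold, small_filter)


def aggregate(
    matches: Sequence[RuleMatch], mode: str = "exhaustive", **kwargs
) -> list[Recommendation]:
    if mode == "naive":
        return aggregate_naive(matches, **kwargs)
    if mode == "exhaustive":
        return aggregate_exhaustive(matches, **kwargs)
    if mode == "fast":
        return aggregate_fast(matches, **kwargs)
    raise ValueError(f"unknown aggregation mode {mode!r}")


@dataclass
class MotifAnnotation:
    status: str  # "annotated" | "no annotation"
    substructure: Optional[Substructure] = None
    score: float = 0.0
    contributing_rule_ids: frozenset[int] = field(default_factory=frozenset)


def annotate_motif(
    motif_features: Sequence[tuple[str, float, float]],
    db: Sequence[Rule],
    top_k: int = 50,
    ppm: float = DEFAULT_PPM,
) -> MotifAnnotation:
    """Annotate a pattern of co-occurring features (fragments/losses).

    The ``top_k`` most probable features are matched against the rule
    database (type agreement plus ppm window). Rules sharing the same body
    feature set compete: the highest recall wins; exact recall ties are
    resolved by taking the MCS of the tied heads. The reported annotation is
    the most frequent structure across the selected rules.
    """
    ranked = sorted(motif_features, key=lambda t: -t[2])[:top_k]
    query = FeatureSet(
        "motif",
        frozenset(SpectralFeature(ftype, value) for ftype, value, _ in ranked),
    )
    matches = match_rules(query, db, ppm)
    if not matches:
        return MotifAnnotation(status="no annotation")

    by_body: dict[frozenset[SpectralFeature], list[Rule]] = {}
    for m in matches:
        by_body.setdefault(m.rule.body, []).append(m.rule)

    selected: list[tuple[Substructure, list[Rule]]] = []
    for body, rules in by_body.items():
        best = max(r.recall for r in rules)
        tied = [r for r in rules if r.recall == best]
        if len(tied) == 1:
            selected.append((tied[0].head, tied))
        else:
            common: Optional[Substructure] = tied[0].head
            for r in tied[1:]:
                if common is None:
                    break
                common = mcs(common, r.head)
            if common is not None:
                selected.append((common, tied))

    if not selected:
        return MotifAnnotation(status="no annotation")

    freq: dict[str, list[tuple[Substructure, list[Rule]]]] = {}
    for sub, rules in selected:
        freq.setdefault(sub.smiles, []).append((sub, rules))
    best_key = max(freq, key=lambda k: (len(freq[k]), k))
    winners = freq[best_key]
    contributing = {r.rule_id for _, rules in winners for r in rules}
    by_id = {m.rule.rule_id: m.rule for m in matches}
    return MotifAnnotation(
        status="annotated",
        substructure=winners[0][0],
        score=sum(by_id[i].recall for i in contributing),
        contributing_rule_ids=frozenset(contributing),
    )


def write_recommendations(recs: Sequence[Recommendation], path) -> None:
    with open(path, "w") as handle:
        handle.write("rank\tsubstructure\tscore\tcontributing_rule_ids\n")
        for r in recs:
            ids = ",".join(str(i) for i in sorted(r.contributing_rule_ids))
            handle.write(f"{r.rank}\t{r.substructure.smiles}\t{r.score:.6f}\t{ids}\n")
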