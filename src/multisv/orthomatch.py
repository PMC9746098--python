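"""Orthogonal-validation matching between a query and a validation call set.

Encodes the clustering criteria used to corroborate calls against an
independent technology (optical mapping): sized SV types need both calls above
a resolution floor (500 bp), >50% reciprocal size similarity, and breakends
within 10 kb; translocations only need breakends within 50 kb, orientation
ignored.  Assignment is greedy one-to-one by ascending breakend distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core import CallSet, SVRecord, size_similarity
from .merge import MergedSV, _UnionFind


@dataclass(frozen=True)
class MatchRule:
    svtypes: frozenset
    min_size_bp: int = 500
    size_similarity_min: float | None = 0.5
    max_distance_bp: int = 10_000
    ignore_orientation: bool = True

    def __post_init__(self):
        if self.size_similarity_min is not None and not (
            0 < self.size_similarity_min <= 1
        ):
            raise ValueError("size_similarity_min must be in (0, 1]")
        if self.max_distance_bp <= 0:
            raise ValueError("max_distance_bp must be positive")


def default_rules() -> list[MatchRule]:
    """Optical-mapping validation criteria."""
    return [
        MatchRule(svtypes=frozenset({"DEL", "INS", "INV", "DUP"})),
        MatchRule(
            svtypes=frozenset({"TRA", "BND"}),
            min_size_bp=0,
            size_similarity_min=None,
            max_distance_bp=50_000,
        ),
    ]


def evaluation_rules() -> list[MatchRule]:
    """Same criteria with the size floor dropped to the 50 bp SV definition
    (the 500 bp floor reflects optical-mapping resolution, not the SVs)."""
    return [
        MatchRule(svtypes=frozenset({"DEL", "INS", "INV", "DUP"}), min_size_bp=50),
        MatchRule(
            svtypes=frozenset({"TRA", "BND"}),
            min_size_bp=0,
            size_similarity_min=None,
            max_distance_bp=50_000,
        ),
    ]


def _rule_for(svtype: str, rules: list[MatchRule]) -> MatchRule | None:
    for rule in rules:
        if svtype in rule.svtypes:
            return rule
    return None


def _types_compatible(a: str, b: str) -> bool:
    if a == b:
        return True
    # translocation orientation/dialect is not considered
    return {a, b} <= {"TRA", "BND"}


def match_distance(a: SVRecord, b: SVRecord) -> float:
    """Max of the two breakend distances; infinite when chromosomes differ."""
    if a.bnd1.chrom != b.bnd1.chrom or a.bnd2.chrom != b.bnd2.chrom:
        return float("inf")
    return float(
        max(abs(a.bnd1.pos - b.bnd1.pos), abs(a.bnd2.pos - b.bnd2.pos))
    )


def pair_matches(a: SVRecord, b: SVRecord, rules: list[MatchRule]) -> bool:
    """Symmetric pairwise match predicate."""
    if not _types_compatible(a.svtype, b.svtype):
        return False
    rule = _rule_for(a.svtype, rules)
    if rule is None:
        return False
    if a.svtype not in ("TRA", "BND"):
        if a.size < rule.min_size_bp or b.size < rule.min_size_bp:
            return False
        if rule.size_similarity_min is not None:
            if size_similarity(a.size, b.size) <= rule.size_similarity_min:
                return False
    return match_distance(a, b) <= rule.max_distance_bp


@dataclass
class MatchResult:
    pairs: list[tuple[SVRecord, SVRecord]]
    status: dict  # query id -> 'matched' | 'unmatched' | 'ineligible'
    details: list[dict] = field(default_factory=list)

    @property
    def n_matched(self) -> int:
        return len(self.pairs)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.details)


def match_calls(
    query: list[SVRecord],
    validation: list[SVRecord],
    rules: list[MatchRule] | None = None,
) -> MatchResult:
    """Greedy one-to-one matching of query calls to validation calls.

    Queries below a rule's size floor are 'ineligible'.  Candidate pairs are
    assigned in ascending breakend distance (ties by query then validation
    input order), so the assignment is deterministic.
    """
    rules = rules if rules is not None else default_rules()
    status: dict = {}
    eligible: list[int] = []
    for qi, q in enumerate(query):
        rule = _rule_for(q.svtype, rules)
        if rule is None or (
            q.svtype not in ("TRA", "BND") and q.size < rule.min_size_bp
        ):
            status[q.id] = "ineligible"
        else:
            status[q.id] = "unmatched"
            eligible.append(qi)

    cand = []
    for qi in eligible:
        q = query[qi]
        for vi, v in enumerate(validation):
            if pair_matches(q, v, rules):
                cand.append((match_distance(q, v), qi, vi))
    cand.sort()

    used_q: set[int] = set()
    used_v: set[int] = set()
    pairs = []
    details = []
    for dist, qi, vi in cand:
        if qi in used_q or vi in used_v:
            continue
        used_q.add(qi)
        used_v.add(vi)
        q, v = query[qi], validation[vi]
        status[q.id] = "matched"
        pairs.append((q, v))
        details.append(
            {
                "query_id": q.id,
                "svtype": q.svtype,
                "status": "matched",
                "matched_id": v.id,
                "distance_bp": dist,
                "size_similarity": size_similarity(q.size, v.size)
                if q.svtype not in ("TRA", "BND")
                else None,
            }
        )
    for q in query:
        if status[q.id] != "matched":
            details.append(
                {
                    "query_id": q.id,
                    "svtype": q.svtype,
                    "status": status[q.id],
                    "matched_id": None,
                    "distance_bp": None,
                    "size_similarity": None,
                }
            )
    return MatchResult(pairs=pairs, status=status, details=details)


def replicate_consensus(
    callsets: list[CallSet],
    min_replicates: int = 2,
    rules: list[MatchRule] | None = None,
    normal: list[SVRecord] | None = None,
) -> list[SVRecord]:
    """Calls reproduced in at least ``min_replicates`` replicate call sets.

    Records across replicates are clustered with the pairwise match predicate
    (transitive closure); a cluster is kept when it spans enough distinct
    replicates, and its earliest record (replicate order, then position) is
    reported.  When a ``normal`` call list is given, clusters matching any
    normal call are dropped (tumor-only filtering).
    """
    if len(callsets) < min_replicates:
        raise ValueError(
            f"need at least {min_replicates} call sets, got {len(callsets)}"
        )
    rules = rules if rules is not None else default_rules()
    tagged = [
        (rec, ci) for ci, cs in enumerate(callsets) for rec in cs.records
    ]
    uf = _UnionFind(len(tagged))
    for i in range(len(tagged)):
        for j in range(i + 1, len(tagged)):
            if pair_matches(tagged[i][0], tagged[j][0], rules):
                uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(len(tagged)):
        groups.setdefault(uf.find(i), []).append(i)

    out = []
    for comp in groups.values():
        reps = {tagged[i][1] for i in comp}
        if len(reps) < min_replicates:
            continue
        members = [tagged[i] for i in comp]
        rec = min(members, key=lambda t: (t[1], t[0].sort_key()))[0]
        if normal and any(pair_matches(rec, nr, rules) for nr in normal):
            continue
        out.append(rec)
    out.sort(key=SVRecord.sort_key)
    return out
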