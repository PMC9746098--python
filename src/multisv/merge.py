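"""Windowed merging, somatic subtraction, and reciprocal-size clustering.

Merging follows the Survivor-style rule: two calls of the same type are
linkable when both breakend distances fall within the size class's merge
window; merged groups are the connected components of the linkable relation,
so (as with Survivor) two members of one group may individually violate the
pairwise rule through a chain of intermediates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import (
    CallSet,
    GenomicRegionSet,
    Provenance,
    SizeClassConfig,
    SVRecord,
    is_primary_chrom,
    size_class_of,
    size_similarity,
)


@dataclass
class MergedSV:
    """A cluster of concordant SV calls with full provenance."""

    representative: SVRecord
    members: list[tuple[SVRecord, Provenance]]
    size_class: int

    @property
    def svtype(self) -> str:
        return self.representative.svtype

    @property
    def n_replicates(self) -> int:
        return len({p.callset_key for _, p in self.members})

    @property
    def n_tools(self) -> int:
        return len({p.tool_key for _, p in self.members})

    @property
    def n_platforms(self) -> int:
        return len({p.platform for _, p in self.members})

    def sort_key(self):
        return self.representative.sort_key()


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def linkable(
    a: SVRecord,
    b: SVRecord,
    window: int,
    same_type_required: bool = True,
    min_size_sim: float | None = None,
    strict_sim: bool = False,
) -> bool:
    """The pairwise merge predicate.

    Breakend distances must both be within ``window`` (chromosomes matching
    pairwise; records are stored with canonically ordered breakends, so TRA
    comparison is orientation-free).  INS always adds a >=50% size-similarity
    requirement; ``min_size_sim`` adds one for the other sized types
    (``strict_sim`` switches >= to >, used by the reciprocal clustering rule).
    TRA/BND are exempt from size tests.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if same_type_required and a.svtype != b.svtype:
        return False
    if a.is_translocation_like != b.is_translocation_like:
        return False
    if a.bnd1.chrom != b.bnd1.chrom or a.bnd2.chrom != b.bnd2.chrom:
        return False
    if a.svtype == "INS" or b.svtype == "INS":
        if abs(a.bnd1.pos - b.bnd1.pos) > window:
            return False
        sim = size_similarity(a.size, b.size)
        if min_size_sim is not None and strict_sim:
            return sim > min_size_sim
        return sim >= 0.5
    if (
        abs(a.bnd1.pos - b.bnd1.pos) > window
        or abs(a.bnd2.pos - b.bnd2.pos) > window
    ):
        return False
    if a.is_translocation_like:
        return True
    if min_size_sim is not None:
        sim = size_similarity(a.size, b.size)
        return sim > min_size_sim if strict_sim else sim >= min_size_sim
    return True


def split_by_size_and_type(
    callset: CallSet, cfg: SizeClassConfig | None = None
) -> dict[tuple[int, bool], CallSet]:
    """Partition a call set into (size class, is-translocation) buckets."""
    cfg = cfg or SizeClassConfig()
    buckets: dict[tuple[int, bool], CallSet] = {}
    for rec in callset.records:
        idx, _ = size_class_of(rec, cfg)
        key = (idx, rec.is_translocation_like)
        if key not in buckets:
            buckets[key] = CallSet(provenance=callset.provenance, records=[])
        buckets[key].records.append(rec)
    return buckets


def _components(items: list, pred, prune=None) -> list[list[int]]:
    """Connected components of the pairwise predicate (transitive closure).

    ``prune(a, b)`` may declare that, with items sorted, b and everything
    after it cannot link to a (position-sorted inputs turn the scan from
    quadratic into near-linear without changing the result).
    """
    uf = _UnionFind(len(items))
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            if prune is not None and prune(items[i], items[j]):
                break
            if pred(items[i], items[j]):
                uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(len(items)):
        groups.setdefault(uf.find(i), []).append(i)
    return list(groups.values())


def _pick_representative(members: list[tuple[SVRecord, Provenance]], pred) -> SVRecord:
    """Member supported by the most other members; ties by pos1 then id."""
    recs = [r for r, _ in members]
    best = None
    best_key = None
    for rec in recs:
        degree = sum(1 for other in recs if other is not rec and pred(rec, other))
        key = (-degree, rec.bnd1.sort_key(), rec.id)
        if best_key is None or key < best_key:
            best, best_key = rec, key
    return best


def merge_calls(
    callsets: list[CallSet],
    window: int,
    same_type_required: bool = True,
    cfg: SizeClassConfig | None = None,
) -> list[MergedSV]:
    """Merge call sets from one (size class, TRA) bucket at the given window.

    Returns connected components of the linkable relation, each carrying every
    member record with its provenance.  Output is sorted by representative
    coordinates, so the result is order-invariant under input permutation.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    cfg = cfg or SizeClassConfig()
    tagged: list[tuple[SVRecord, Provenance]] = []
    for cs in callsets:
        for rec in cs.records:
            tagged.append((rec, cs.provenance))
    tagged.sort(key=lambda t: (t[0].sort_key(), t[1].callset_key))

    def pred(x, y):
        return linkable(x[0], y[0], window, same_type_required)

    def prune(x, y):
        a, b = x[0], y[0]
        if a.bnd1.chrom != b.bnd1.chrom:
            return True
        return b.bnd1.pos - a.bnd1.pos > window

    merged = []
    for comp in _components(tagged, pred, prune=prune):
        members = [tagged[i] for i in comp]
        rep = _pick_representative(
            members, lambda a, b: linkable(a, b, window, same_type_required)
        )
        merged.append(
            MergedSV(representative=rep, members=members,
                     size_class=size_class_of(rep, cfg)[0])
        )
    merged.sort(key=MergedSV.sort_key)
    return merged


def somatic_subtract(
    tumor: list[MergedSV], normal: list[MergedSV], window: int
) -> list[MergedSV]:
    """Drop tumor clusters whose representative is linkable to a normal one."""
    out = []
    for t in tumor:
        hit = any(
            linkable(t.representative, n.representative, window) for n in normal
        )
        if not hit:
            out.append(t)
    return out


def cluster_merged(
    svs: list[MergedSV], cfg: SizeClassConfig | None = None
) -> list[MergedSV]:
    """Cluster merged SVs of the same type with >50% reciprocal size similarity.

    Breakend distances must fall within the pair's size-class window, taken
    from the smaller member's class (TRA/BND use the large-class window and are
    exempt from the size test).  Clusters are connected components; members and
    provenance counts are unioned.
    """
    cfg = cfg or SizeClassConfig()

    def pair_window(a: MergedSV, b: MergedSV) -> int:
        if a.representative.is_translocation_like:
            return cfg.large_window
        return cfg.window_of_class(min(a.size_class, b.size_class))

    def pred(a: MergedSV, b: MergedSV) -> bool:
        return linkable(
            a.representative,
            b.representative,
            pair_window(a, b),
            same_type_required=True,
            min_size_sim=0.5,
            strict_sim=True,
        )

    svs = sorted(svs, key=MergedSV.sort_key)
    maxw = max([w for _, _, w in cfg.classes] + [cfg.large_window])

    def prune(a: MergedSV, b: MergedSV) -> bool:
        ra, rb = a.representative, b.representative
        if ra.bnd1.chrom != rb.bnd1.chrom:
            return True
        return rb.bnd1.pos - ra.bnd1.pos > maxw

    clustered = []
    for comp in _components(svs, pred, prune=prune):
        members: list[tuple[SVRecord, Provenance]] = []
        for i in comp:
            members.extend(svs[i].members)
        window = cfg.window_of_class(min(svs[i].size_class for i in comp))
        rep = _pick_representative(
            members,
            lambda a, b: linkable(a, b, window, min_size_sim=0.5, strict_sim=True),
        )
        clustered.append(
            MergedSV(representative=rep, members=members,
                     size_class=size_class_of(rep, cfg)[0])
        )
    clustered.sort(key=MergedSV.sort_key)
    return clustered


def filter_regions(
    svs: list[MergedSV],
    regions: list[GenomicRegionSet],
    primary_only: bool = True,
) -> list[MergedSV]:
    """Remove clusters with a breakend inside any region or on a non-primary
    (ALT) contig, judged on the representative call."""
    out = []
    for sv in svs:
        rep = sv.representative
        if primary_only and not (
            is_primary_chrom(rep.bnd1.chrom) and is_primary_chrom(rep.bnd2.chrom)
        ):
            continue
        if any(rs.overlaps_record(rep) for rs in regions):
            continue
        out.append(sv)
    return out


def merged_to_dataframe(svs: list[MergedSV]):
    """Cluster membership table (one row per member)."""
    import pandas as pd

    rows = []
    for cid, sv in enumerate(svs):
        rep = sv.representative
        for rec, prov in sv.members:
            rows.append(
                {
                    "cluster_id": cid,
                    "svtype": rep.svtype,
                    "chrom1": rep.bnd1.chrom,
                    "pos1": rep.bnd1.pos,
                    "chrom2": rep.bnd2.chrom,
                    "pos2": rep.bnd2.pos,
                    "size": rep.size,
                    "member_id": rec.id,
                    "platform": prov.platform,
                    "tool": prov.tool,
                    "replicate": prov.replicate,
                }
            )
    return pd.DataFrame(rows)
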