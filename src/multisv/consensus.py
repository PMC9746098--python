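"""Calling frequencies, consensus scores, and call-set selection.

For each merged SV the per-tool frequency is the fraction of that tool's
replicate call sets containing the SV; the per-platform frequency is the
fraction of the platform's (tool, replicate) call sets containing it; and the
consensus score is the sum of the per-tool frequencies.  The initial call set
requires support in >=2 replicate call sets; the high-confidence set
additionally requires >=2 platforms and >=2 tools and removes calls in
normal-LOH regions.

Tools are identified by (platform, tool) throughout: the same caller run on
two platforms contributes two distinct tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core import GenomicRegionSet, Provenance
from .merge import MergedSV, filter_regions


class CensusError(KeyError):
    """A member's provenance is not present in the replicate census."""


@dataclass
class ReplicateCensus:
    """Number of replicate call sets contributed per (platform, tool)."""

    replicates: dict  # (platform, tool) -> replicate count

    @classmethod
    def from_callsets(cls, callsets) -> "ReplicateCensus":
        reps: dict = {}
        for cs in callsets:
            p = cs.provenance
            reps.setdefault(p.tool_key, set()).add(p.replicate)
        return cls({k: len(v) for k, v in sorted(reps.items())})

    def platform_total(self, platform: str) -> int:
        return sum(n for (plat, _), n in self.replicates.items() if plat == platform)

    @property
    def platforms(self) -> list[str]:
        return sorted({plat for plat, _ in self.replicates})

    @property
    def n_tools(self) -> int:
        return len(self.replicates)


@dataclass
class ConsensusRecord:
    merged: MergedSV
    tool_freq: dict = field(default_factory=dict)
    platform_freq: dict = field(default_factory=dict)
    consensus_score: float = 0.0
    initial: bool = False
    high_confidence: bool = False


def tool_frequency(merged: MergedSV, census: ReplicateCensus) -> dict:
    """Per-tool detection frequency: replicates supporting / replicates run.

    Tools with no supporting member are absent from the map (not 0 entries).
    """
    support: dict = {}
    for _, prov in merged.members:
        if prov.tool_key not in census.replicates:
            raise CensusError(f"{prov.tool_key} missing from replicate census")
        support.setdefault(prov.tool_key, set()).add(prov.replicate)
    return {
        key: len(reps) / census.replicates[key] for key, reps in sorted(support.items())
    }


def platform_frequency(merged: MergedSV, census: ReplicateCensus) -> dict:
    """Per-platform frequency: supporting (tool, replicate) call sets divided
    by the platform's total call-set count."""
    support: dict = {}
    for _, prov in merged.members:
        if prov.tool_key not in census.replicates:
            raise CensusError(f"{prov.tool_key} missing from replicate census")
        support.setdefault(prov.platform, set()).add((prov.tool, prov.replicate))
    return {
        plat: len(keys) / census.platform_total(plat)
        for plat, keys in sorted(support.items())
    }


def consensus_score(tool_freqs: dict) -> float:
    return float(sum(tool_freqs.values()))


def score_records(
    merged: list[MergedSV], census: ReplicateCensus
) -> list[ConsensusRecord]:
    out = []
    for sv in merged:
        tf = tool_frequency(sv, census)
        out.append(
            ConsensusRecord(
                merged=sv,
                tool_freq=tf,
                platform_freq=platform_frequency(sv, census),
                consensus_score=consensus_score(tf),
            )
        )
    return out


def select_initial(
    records: list[ConsensusRecord],
    blacklist: GenomicRegionSet | None = None,
    min_replicates: int = 2,
) -> list[ConsensusRecord]:
    """Initial call set: >=2 supporting replicate call sets, off-blacklist,
    primary chromosomes only."""
    regions = [blacklist] if blacklist is not None else []
    kept_merged = set(
        id(m)
        for m in filter_regions([r.merged for r in records], regions)
    )
    out = []
    for rec in records:
        if rec.merged.n_replicates >= min_replicates and id(rec.merged) in kept_merged:
            rec.initial = True
            out.append(rec)
    return out


def select_high_confidence(
    records: list[ConsensusRecord],
    loh: GenomicRegionSet | None = None,
    min_platforms: int = 2,
    min_tools: int = 2,
) -> list[ConsensusRecord]:
    """High-confidence set: >=2 platforms AND >=2 tools agree, outside LOH."""
    regions = [loh] if loh is not None else []
    candidates = [
        r
        for r in records
        if r.initial
        and r.merged.n_platforms >= min_platforms
        and r.merged.n_tools >= min_tools
    ]
    kept_merged = set(
        id(m) for m in filter_regions([r.merged for r in candidates], regions)
    )
    out = []
    for rec in candidates:
        if id(rec.merged) in kept_merged:
            rec.high_confidence = True
            out.append(rec)
    return out


def exclude_platform_calls(merged: list[MergedSV], predicate) -> list[MergedSV]:
    """Remove member contributions matching ``predicate(provenance, record)``
    before scoring; clusters left empty are dropped and counts recomputed."""
    out = []
    for sv in merged:
        members = [(r, p) for r, p in sv.members if not predicate(p, r)]
        if not members:
            continue
        if len(members) == len(sv.members):
            out.append(sv)
            continue
        rep = sv.representative
        if all(r is not rep for r, _ in members):
            rep = min(members, key=lambda m: (m[0].bnd1.sort_key(), m[0].id))[0]
        out.append(MergedSV(representative=rep, members=members, size_class=sv.size_class))
    return out


def tenx_small_deletion_filter(min_size: int = 20000):
    """Predicate excluding Long Ranger deletions below ``min_size`` (their
    replicate concordance is too low to trust)."""

    def predicate(prov: Provenance, rec) -> bool:
        return (
            prov.platform == "TenX"
            and prov.tool == "LongRanger"
            and rec.svtype == "DEL"
            and rec.size < min_size
        )

    return predicate


def consensus_to_dataframe(records: list[ConsensusRecord]) -> pd.DataFrame:
    tools = sorted({k for r in records for k in r.tool_freq})
    platforms = sorted({k for r in records for k in r.platform_freq})
    rows = []
    for cid, r in enumerate(records):
        rep = r.merged.representative
        row = {
            "cluster_id": cid,
            "svtype": rep.svtype,
            "chrom1": rep.bnd1.chrom,
            "pos1": rep.bnd1.pos,
            "chrom2": rep.bnd2.chrom,
            "pos2": rep.bnd2.pos,
            "size": rep.size,
            "n_replicates": r.merged.n_replicates,
            "n_tools": r.merged.n_tools,
            "n_platforms": r.merged.n_platforms,
            "consensus_score": r.consensus_score,
            "initial": r.initial,
            "high_confidence": r.high_confidence,
        }
        for key in tools:
            row[f"freq_tool_{key[0]}_{key[1]}"] = r.tool_freq.get(key, 0.0)
        for plat in platforms:
            row[f"freq_platform_{plat}"] = r.platform_freq.get(plat, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)
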