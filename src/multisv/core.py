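"""Core domain types for structural-variant call sets.

A structural variant (SV) is stored as a pair of breakends plus a type and a
size.  Intra-chromosomal DEL/DUP/INV records keep ``size == pos2 - pos1``;
insertions are anchored at a single position and carry the inserted length;
translocations (TRA) and unresolved breakend records (BND) have size 0 and are
excluded from all size-based logic.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

from intervaltree import IntervalTree

SVTYPES = ("DEL", "DUP", "INS", "INV", "TRA", "BND")
INTRA_SIZED = ("DEL", "DUP", "INV")
PLATFORMS = ("Illumina", "TenX", "PacBio", "ONT", "HiC", "Bionano")
SAMPLES = ("tumor", "normal")

#: minimum SV size considered (smaller events are indels, out of scope)
MIN_SV_SIZE = 50

_CHROM_RE = re.compile(r"^(chr)?([0-9]+|[XYM]|MT)$", re.IGNORECASE)


def chrom_sort_key(chrom: str):
    """Natural ordering: chr1 < chr2 < ... < chr10 < chrX < chrY < chrM."""
    m = _CHROM_RE.match(chrom)
    if m:
        body = m.group(2).upper()
        if body.isdigit():
            return (0, int(body), "")
        return (0, {"X": 23, "Y": 24, "M": 25, "MT": 25}[body], "")
    return (1, 0, chrom)


def is_primary_chrom(chrom: str) -> bool:
    """True for chr1..chr22, chrX/Y/M (with or without the ``chr`` prefix)."""
    return _CHROM_RE.match(chrom) is not None


class SubThresholdError(ValueError):
    """Raised for non-TRA/BND records smaller than the 50 bp SV floor."""


@dataclass(frozen=True, order=True)
class Breakend:
    chrom: str
    pos: int  # 1-based
    orient: str | None = None  # '+' / '-' or None when the caller gave none

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("breakend chromosome must be non-empty")
        if self.pos < 1:
            raise ValueError(f"breakend position must be >= 1, got {self.pos}")
        if self.orient not in (None, "+", "-"):
            raise ValueError(f"invalid orientation {self.orient!r}")

    def sort_key(self):
        return (chrom_sort_key(self.chrom), self.pos)


@dataclass
class SVRecord:
    """One structural variant with two breakends.

    Breakends are canonicalized on construction: intra-chromosomal records get
    ``pos1 <= pos2`` and TRA/BND records are ordered by (chromosome, position).
    """

    id: str
    svtype: str
    bnd1: Breakend
    bnd2: Breakend
    size: int = -1
    filter: str = "PASS"
    info: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.svtype not in SVTYPES:
            raise ValueError(f"unknown SV type {self.svtype!r}")
        if self.svtype == "INS":
            if self.size < 0:
                raise ValueError("INS records need an explicit inserted length")
            self.bnd2 = self.bnd1
        elif self.svtype in INTRA_SIZED:
            if self.bnd1.chrom != self.bnd2.chrom:
                raise ValueError(f"{self.svtype} breakends must share a chromosome")
            if self.bnd2.pos < self.bnd1.pos:
                self.bnd1, self.bnd2 = self.bnd2, self.bnd1
            span = self.bnd2.pos - self.bnd1.pos
            if self.size < 0:
                self.size = span
            elif self.size != span:
                raise ValueError(
                    f"{self.svtype} size {self.size} != breakend span {span}"
                )
        else:  # TRA / BND
            if self.bnd2.sort_key() < self.bnd1.sort_key():
                self.bnd1, self.bnd2 = self.bnd2, self.bnd1
            self.size = 0
        if self.svtype == "TRA" and self.bnd1.chrom == self.bnd2.chrom:
            raise ValueError("TRA breakends must be on different chromosomes")

    @property
    def is_translocation_like(self) -> bool:
        return self.svtype in ("TRA", "BND")

    def coord_key(self):
        return (
            self.svtype,
            self.bnd1.chrom,
            self.bnd1.pos,
            self.bnd2.chrom,
            self.bnd2.pos,
            self.size,
        )

    def sort_key(self):
        return (self.bnd1.sort_key(), self.bnd2.sort_key(), self.svtype, self.id)


@dataclass(frozen=True)
class Provenance:
    """Origin of a call set: one (platform, tool, replicate, sample) run."""

    platform: str
    tool: str
    replicate: str
    sample: str

    def __post_init__(self):
        if self.sample not in SAMPLES:
            raise ValueError(f"sample must be one of {SAMPLES}, got {self.sample!r}")
        for f in ("platform", "tool", "replicate"):
            if not getattr(self, f):
                raise ValueError(f"provenance field {f!r} must be set")

    @property
    def tool_key(self):
        """Tool identity; the same caller on two platforms counts twice."""
        return (self.platform, self.tool)

    @property
    def callset_key(self):
        return (self.platform, self.tool, self.replicate)


@dataclass
class CallSet:
    provenance: Provenance
    records: list[SVRecord] = field(default_factory=list)
    #: reader bookkeeping: parsed / rejected / filtered / deduplicated counts
    stats: dict = field(default_factory=dict)

    def sort(self) -> "CallSet":
        self.records.sort(key=SVRecord.sort_key)
        return self

    def validate(self):
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("record ids must be unique within a call set")
        keys = [r.sort_key() for r in self.records]
        if keys != sorted(keys):
            raise ValueError("records must be sorted by (chrom1, pos1)")

    def __len__(self):
        return len(self.records)


@dataclass(frozen=True)
class SizeClassConfig:
    """Size classes and their merge windows.

    ``classes`` are (lower, upper, window) with upper-inclusive boundaries: a
    100 bp SV belongs to the 50-100 bp class.  SVs above the last upper bound,
    and all TRA/BND records, map to the large class with ``large_window``.
    """

    classes: tuple = (
        (50, 100, 50),
        (100, 500, 100),
        (500, 1000, 500),
        (1000, 30000, 1000),
    )
    large_window: int = 10000

    def __post_init__(self):
        prev_hi = None
        for lo, hi, win in self.classes:
            if lo >= hi or win <= 0:
                raise ValueError("malformed size class")
            if prev_hi is not None and lo != prev_hi:
                raise ValueError("size classes must be contiguous")
            prev_hi = hi

    @property
    def n_classes(self) -> int:
        return len(self.classes) + 1

    @property
    def large_index(self) -> int:
        return len(self.classes)

    def class_of_size(self, size: int) -> tuple[int, int]:
        if size < self.classes[0][0]:
            raise SubThresholdError(f"SV size {size} below {self.classes[0][0]} bp")
        for idx, (lo, hi, win) in enumerate(self.classes):
            if size <= hi:
                return idx, win
        return self.large_index, self.large_window

    def window_of_class(self, idx: int) -> int:
        if idx == self.large_index:
            return self.large_window
        return self.classes[idx][2]


def size_class_of(sv: SVRecord, cfg: SizeClassConfig | None = None) -> tuple[int, int]:
    """Map an SV to its (size class index, merge window in bp).

    TRA/BND always fall in the large class regardless of their (zero) size.
    """
    cfg = cfg or SizeClassConfig()
    if sv.is_translocation_like:
        return cfg.large_index, cfg.large_window
    return cfg.class_of_size(sv.size)


class GenomicRegionSet:
    """Labelled set of 0-based half-open genomic intervals with point queries."""

    def __init__(self, regions, label: str = ""):
        self.label = label
        self.regions = []
        self._trees: dict[str, IntervalTree] = {}
        for chrom, start, end in regions:
            if start >= end:
                raise ValueError(f"empty region {chrom}:{start}-{end}")
            self.regions.append((chrom, int(start), int(end)))
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end)

    def __len__(self):
        return len(self.regions)

    def contains(self, chrom: str, pos: int) -> bool:
        """Point query with a 1-based coordinate."""
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlaps_point(pos - 1))

    def overlaps_record(self, sv: SVRecord) -> bool:
        return self.contains(sv.bnd1.chrom, sv.bnd1.pos) or self.contains(
            sv.bnd2.chrom, sv.bnd2.pos
        )


def size_similarity(a: int, b: int) -> float:
    """Reciprocal size similarity min/max; 0 if either size is non-positive."""
    if a <= 0 or b <= 0:
        return 0.0
    return min(a, b) / max(a, b)
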