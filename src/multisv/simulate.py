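"""Synthetic data with the statistical structure the pipeline assumes.

Generates (a) a diploid truth SV set with somatic and germline events over a
toy genome, (b) emulated multi-platform caller outputs with size/type
dependent sensitivity, breakpoint jitter and false positives, (c) Hi-C
contact matrices with a distance-decay Poisson background plus canonical
quadrant signals at rearrangement junctions, and (d) a tumor-purity /
sequencing-depth titration series with a Poisson supporting-read detection
model.  Every generator is deterministic given its seed.

The default platform profiles are simulation parameters, not measured
values: they encode the qualitative behaviour of the platforms (long reads
more sensitive to insertions and sub-kilobase events, short reads strong on
mid-size deletions, proximity ligation blind below the megabase scale).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .core import Breakend, CallSet, MIN_SV_SIZE, Provenance, SVRecord
from .hic import ContactMatrix
from .vcfio import TRUTH_INFO_KEY

SOMATIC_COUNTS = {"DEL": 60, "DUP": 20, "INS": 45, "INV": 12, "TRA": 12, "BND": 3}
GERMLINE_COUNTS = {"DEL": 120, "DUP": 40, "INS": 90, "INV": 24, "TRA": 4, "BND": 2}
SIZE_RANGES = {
    "DEL": (50, 100_000),
    "DUP": (500, 200_000),
    "INS": (50, 10_000),
    "INV": (50, 100_000),
}


@dataclass
class GenomeModel:
    chromosomes: dict  # name -> length bp
    blacklist: list = field(default_factory=list)  # (chrom, start0, end0)

    def __post_init__(self):
        for name, length in self.chromosomes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")

    @property
    def total_bp(self) -> int:
        return sum(self.chromosomes.values())

    @classmethod
    def toy(cls, n_chroms: int = 3, length: int = 20_000_000,
            blacklist_fraction: float = 0.02, seed: int = 0) -> "GenomeModel":
        chroms = {f"chr{i + 1}": length for i in range(n_chroms)}
        blacklist = []
        if blacklist_fraction > 0:
            rng = np.random.default_rng(seed)
            tile = 100_000
            n_tiles = int(round(blacklist_fraction * n_chroms * length / tile))
            names = list(chroms)
            for _ in range(n_tiles):
                c = names[rng.integers(len(names))]
                start = int(rng.integers(0, length - tile))
                blacklist.append((c, start, start + tile))
        return cls(chroms, sorted(blacklist))


@dataclass
class TruthSet:
    somatic: list[SVRecord]
    germline: list[SVRecord]
    seed: int

    def all_records(self) -> list[SVRecord]:
        return self.somatic + self.germline

    def by_id(self) -> dict:
        return {r.id: r for r in self.all_records()}


def _log_uniform(rng, lo: float, hi: float) -> int:
    return int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))


class PlacementError(RuntimeError):
    """Genome too small to place the requested events without overlap."""


def simulate_truth(
    genome: GenomeModel,
    somatic_counts: dict | None = None,
    germline_counts: dict | None = None,
    size_ranges: dict | None = None,
    seed: int = 0,
    tra_reciprocal_frac: float = 0.5,
    max_tries: int = 1000,
) -> TruthSet:
    """Place non-overlapping somatic and germline SVs outside the blacklist.

    Sizes are log-uniform within per-type bounds.  Somatic and germline
    events share one occupancy map, so the two sets are disjoint by
    construction, and everything is reproducible from the seed.
    """
    somatic_counts = SOMATIC_COUNTS if somatic_counts is None else somatic_counts
    germline_counts = GERMLINE_COUNTS if germline_counts is None else germline_counts
    size_ranges = SIZE_RANGES if size_ranges is None else size_ranges
    rng = np.random.default_rng(seed)

    occupied: dict[str, IntervalTree] = {c: IntervalTree() for c in genome.chromosomes}
    black: dict[str, IntervalTree] = {c: IntervalTree() for c in genome.chromosomes}
    for c, s, e in genome.blacklist:
        black[c].addi(s, e)
    names = list(genome.chromosomes)
    weights = np.array([genome.chromosomes[c] for c in names], dtype=float)
    weights /= weights.sum()

    def place_interval(length: int) -> tuple[str, int] | None:
        for _ in range(max_tries):
            chrom = names[rng.choice(len(names), p=weights)]
            limit = genome.chromosomes[chrom] - length - 1
            if limit < 1:
                continue
            start = int(rng.integers(1, limit))
            if occupied[chrom].overlaps(start - 1, start + length) or black[
                chrom
            ].overlaps(start - 1, start + length):
                continue
            occupied[chrom].addi(start - 1, start + length)
            return chrom, start
        return None

    def build(prefix: str, counts: dict) -> list[SVRecord]:
        records = []
        for svtype in ("DEL", "DUP", "INS", "INV", "TRA", "BND"):
            for k in range(counts.get(svtype, 0)):
                rid = f"{prefix}_{svtype.lower()}_{k:04d}"
                if svtype in ("DEL", "DUP", "INV"):
                    lo, hi = size_ranges[svtype]
                    size = max(_log_uniform(rng, lo, hi), MIN_SV_SIZE)
                    spot = place_interval(size)
                    if spot is None:
                        raise PlacementError(f"cannot place {rid} (size {size})")
                    chrom, start = spot
                    records.append(
                        SVRecord(rid, svtype, Breakend(chrom, start),
                                 Breakend(chrom, start + size), info={})
                    )
                elif svtype == "INS":
                    lo, hi = size_ranges["INS"]
                    size = max(_log_uniform(rng, lo, hi), MIN_SV_SIZE)
                    spot = place_interval(100)
                    if spot is None:
                        raise PlacementError(f"cannot place {rid}")
                    chrom, start = spot
                    b = Breakend(chrom, start)
                    records.append(SVRecord(rid, "INS", b, b, size=size, info={}))
                elif svtype == "TRA":
                    spots = [place_interval(100), place_interval(100)]
                    if None in spots:
                        raise PlacementError(f"cannot place {rid}")
                    (c1, p1), (c2, p2) = spots
                    tries = 0
                    while c1 == c2 and tries < max_tries:
                        spot = place_interval(100)
                        if spot is None:
                            raise PlacementError(f"cannot place {rid}")
                        c2, p2 = spot
                        tries += 1
                    if c1 == c2:
                        raise PlacementError(f"cannot place {rid} across chromosomes")
                    reciprocal = bool(rng.random() < tra_reciprocal_frac)
                    records.append(
                        SVRecord(rid, "TRA", Breakend(c1, p1), Breakend(c2, p2),
                                 info={"reciprocal": reciprocal})
                    )
                else:  # BND: intra-chromosomal junction with no simple type
                    spot1 = place_interval(100)
                    if spot1 is None:
                        raise PlacementError(f"cannot place {rid}")
                    chrom, p1 = spot1
                    limit = genome.chromosomes[chrom] - 101
                    p2 = None
                    for _ in range(max_tries):
                        cand = int(rng.integers(1, limit))
                        if abs(cand - p1) < 100_000:
                            continue
                        if not occupied[chrom].overlaps(cand - 1, cand + 100) and not (
                            black[chrom].overlaps(cand - 1, cand + 100)
                        ):
                            occupied[chrom].addi(cand - 1, cand + 100)
                            p2 = cand
                            break
                    if p2 is None:
                        raise PlacementError(f"cannot place {rid}")
                    records.append(
                        SVRecord(rid, "BND", Breakend(chrom, p1),
                                 Breakend(chrom, p2), info={})
                    )
        return records

    somatic = build("som", somatic_counts)
    germline = build("germ", germline_counts)
    return TruthSet(somatic=somatic, germline=germline, seed=seed)


@dataclass
class PlatformProfile:
    """Per-platform emulation parameters (simulation defaults, not claims)."""

    platform: str
    tools: dict  # tool name -> replicate count
    #: svtype -> ((size_upper_bp, detection_probability), ...); the last tier
    #: is open-ended.  Types absent from the map are never called.
    sensitivity: dict
    breakpoint_jitter_sd: float = 20.0
    size_jitter_frac: float = 0.05
    fp_rate_per_mb: float = 0.2
    fp_size_range: tuple = (50, 100_000)

    def detect_prob(self, svtype: str, size: int) -> float:
        tiers = self.sensitivity.get(svtype)
        if not tiers:
            return 0.0
        for upper, p in tiers:
            if size <= upper:
                return p
        return tiers[-1][1]


INF = float("inf")


def default_profiles() -> list[PlatformProfile]:
    return [
        PlatformProfile(
            "Illumina",
            tools={"TNscope": 3, "Delly": 3, "Novobreak": 3, "Manta": 3},
            sensitivity={
                "DEL": ((1000, 0.85), (30_000, 0.75), (INF, 0.5)),
                "DUP": ((30_000, 0.7), (INF, 0.45)),
                "INS": ((1000, 0.3), (INF, 0.05)),
                "INV": ((INF, 0.6),),
                "TRA": ((INF, 0.6),),
                "BND": ((INF, 0.5),),
            },
            breakpoint_jitter_sd=15.0,
            fp_rate_per_mb=0.3,
        ),
        PlatformProfile(
            "TenX",
            tools={"LongRanger": 2, "GrocSVs": 2},
            sensitivity={
                "DEL": ((20_000, 0.35), (INF, 0.7)),
                "DUP": ((INF, 0.35),),
                "INV": ((INF, 0.25),),
                "TRA": ((INF, 0.6),),
                "BND": ((INF, 0.3),),
            },
            breakpoint_jitter_sd=100.0,
            fp_rate_per_mb=0.25,
        ),
        PlatformProfile(
            "PacBio",
            tools={"PBSV": 1, "Sniffles": 1},
            sensitivity={
                "DEL": ((INF, 0.9),),
                "DUP": ((INF, 0.7),),
                "INS": ((10_000, 0.9), (INF, 0.4)),
                "INV": ((INF, 0.8),),
                "TRA": ((INF, 0.7),),
                "BND": ((INF, 0.6),),
            },
            breakpoint_jitter_sd=20.0,
        ),
        PlatformProfile(
            "ONT",
            tools={"Sniffles": 1, "NanoSV": 1},
            sensitivity={
                "DEL": ((INF, 0.85),),
                "DUP": ((INF, 0.65),),
                "INS": ((10_000, 0.85), (INF, 0.35)),
                "INV": ((INF, 0.75),),
                "TRA": ((INF, 0.7),),
                "BND": ((INF, 0.6),),
            },
            breakpoint_jitter_sd=30.0,
        ),
        PlatformProfile(
            "HiC",
            tools={"Selva": 1},
            sensitivity={
                # proximity ligation only resolves megabase-scale events
                "DEL": ((1_000_000, 0.0), (INF, 0.5)),
                "DUP": ((1_000_000, 0.0), (INF, 0.5)),
                "INV": ((1_000_000, 0.0), (INF, 0.4)),
                "TRA": ((INF, 0.8),),
                "BND": ((INF, 0.3),),
            },
            breakpoint_jitter_sd=25_000.0,
            fp_rate_per_mb=0.05,
            fp_size_range=(1_000_000, 5_000_000),
        ),
    ]


def bionano_profile() -> PlatformProfile:
    """Orthogonal optical-mapping validation platform (500 bp resolution)."""
    return PlatformProfile(
        "Bionano",
        tools={"Saphyr": 3},
        sensitivity={
            "DEL": ((500, 0.0), (INF, 0.75)),
            "DUP": ((500, 0.0), (INF, 0.7)),
            "INS": ((500, 0.0), (INF, 0.75)),
            "INV": ((500, 0.0), (INF, 0.65)),
            "TRA": ((INF, 0.7),),
        },
        breakpoint_jitter_sd=500.0,
        fp_rate_per_mb=0.1,
        fp_size_range=(500, 500_000),
    )


def _jitter_record(rec: SVRecord, rng, jitter_sd: float, size_frac: float,
                   genome: GenomeModel, new_id: str) -> SVRecord:
    info = {TRUTH_INFO_KEY: rec.id}
    if rec.svtype in ("TRA", "BND"):
        p1 = max(1, rec.bnd1.pos + int(round(rng.normal(0, jitter_sd))))
        p2 = max(1, rec.bnd2.pos + int(round(rng.normal(0, jitter_sd))))
        p1 = min(p1, genome.chromosomes[rec.bnd1.chrom])
        p2 = min(p2, genome.chromosomes[rec.bnd2.chrom])
        return SVRecord(new_id, rec.svtype, Breakend(rec.bnd1.chrom, p1),
                        Breakend(rec.bnd2.chrom, p2), filter="PASS", info=info)
    size = max(MIN_SV_SIZE, int(round(rec.size * (1 + rng.normal(0, size_frac)))))
    p1 = max(1, rec.bnd1.pos + int(round(rng.normal(0, jitter_sd))))
    if rec.svtype == "INS":
        p1 = min(p1, genome.chromosomes[rec.bnd1.chrom])
        b = Breakend(rec.bnd1.chrom, p1)
        return SVRecord(new_id, "INS", b, b, size=size, filter="PASS", info=info)
    p1 = min(p1, genome.chromosomes[rec.bnd1.chrom] - size)
    p1 = max(1, p1)
    return SVRecord(new_id, rec.svtype, Breakend(rec.bnd1.chrom, p1),
                    Breakend(rec.bnd1.chrom, p1 + size), filter="PASS", info=info)


def emulate_callsets(
    truth: TruthSet,
    genome: GenomeModel,
    profiles: list[PlatformProfile] | None = None,
    seed: int = 0,
) -> list[CallSet]:
    """Emulate tumor and normal caller outputs for every platform/tool/replicate.

    Each truth SV enters a call set with the profile's type/size sensitivity;
    called breakpoints get Gaussian jitter and multiplicative size noise;
    false positives arrive at the profile's per-megabase rate.  Germline
    events appear in tumor and normal call sets, somatic only in tumor.  The
    emitted records carry their truth id in INFO so evaluation can compute
    exact recall.
    """
    profiles = default_profiles() if profiles is None else profiles
    rng = np.random.default_rng(seed)
    names = list(genome.chromosomes)
    callsets = []
    for profile in profiles:
        for tool, n_reps in sorted(profile.tools.items()):
            for rep in range(1, n_reps + 1):
                for sample in ("tumor", "normal"):
                    prov = Provenance(profile.platform, tool, str(rep), sample)
                    pool = (
                        truth.somatic + truth.germline
                        if sample == "tumor"
                        else truth.germline
                    )
                    records = []
                    for rec in pool:
                        p = profile.detect_prob(rec.svtype, rec.size)
                        if p <= 0 or rng.random() >= p:
                            continue
                        new_id = f"{profile.platform}_{tool}_r{rep}_{sample}_{rec.id}"
                        records.append(
                            _jitter_record(rec, rng, profile.breakpoint_jitter_sd,
                                           profile.size_jitter_frac, genome, new_id)
                        )
                    n_fp = rng.poisson(profile.fp_rate_per_mb * genome.total_bp / 1e6)
                    # false positives take the types this caller emits
                    fp_types = sorted(
                        t for t in profile.sensitivity if t != "BND"
                    ) or ["DEL"]
                    for k in range(int(n_fp)):
                        svtype = fp_types[int(rng.integers(len(fp_types)))]
                        fid = f"{profile.platform}_{tool}_r{rep}_{sample}_fp{k:03d}"
                        if svtype == "TRA":
                            c1, c2 = rng.choice(len(names), size=2, replace=False)
                            records.append(
                                SVRecord(
                                    fid, "TRA",
                                    Breakend(names[c1], int(rng.integers(1, genome.chromosomes[names[c1]]))),
                                    Breakend(names[c2], int(rng.integers(1, genome.chromosomes[names[c2]]))),
                                )
                            )
                        else:
                            lo, hi = profile.fp_size_range
                            size = _log_uniform(rng, max(lo, MIN_SV_SIZE), hi)
                            chrom = names[int(rng.integers(len(names)))]
                            limit = genome.chromosomes[chrom] - size - 1
                            if limit < 2:
                                continue
                            start = int(rng.integers(1, limit))
                            if svtype == "INS":
                                b = Breakend(chrom, start)
                                records.append(SVRecord(fid, "INS", b, b, size=size))
                            else:
                                records.append(
                                    SVRecord(fid, svtype, Breakend(chrom, start),
                                             Breakend(chrom, start + size))
                                )
                    cs = CallSet(provenance=prov, records=records).sort()
                    callsets.append(cs)
    return callsets


def simulate_hic(
    genome: GenomeModel,
    w: int = 50_000,
    depth: float = 5.0,
    truth_svs=(),
    signal_factor: float = 0.0,
    seed: int = 0,
    inter_depth_frac: float = 0.1,
    signal_extent_bins: int = 10,
) -> ContactMatrix:
    """Poisson contact matrix with distance decay and implanted junctions.

    Background intensity is ``depth / (1 + d/w)`` for intra-chromosomal bin
    pairs at distance d and ``inter_depth_frac * depth`` between chromosomes.
    Each truth TRA/DEL/INV/DUP/BND junction adds its canonical quadrant
    pattern at ``signal_factor`` times the local background over
    ``signal_extent_bins`` bins.  The returned matrix is exactly symmetric
    and deterministic given the seed.
    """
    M = ContactMatrix(genome.chromosomes, w=w)
    n = M.n
    cidx = M.bin_chrom
    local = np.arange(n) - np.array([M.offsets[M.chroms[c][0]] for c in cidx])
    same = cidx[:, None] == cidx[None, :]
    dist = np.abs(local[:, None] - local[None, :])
    lam = np.where(same, depth / (1.0 + dist), inter_depth_frac * depth)

    if signal_factor > 0:
        E = signal_extent_bins
        for rec in truth_svs:
            if rec.svtype == "INS":
                continue
            try:
                b1 = M.bin_of(rec.bnd1.chrom, rec.bnd1.pos)
                b2 = M.bin_of(rec.bnd2.chrom, rec.bnd2.pos)
            except (KeyError, ValueError):
                continue
            if b1 > b2:
                b1, b2 = b2, b1
            if rec.svtype == "DEL":
                quads = ("mp",)
            elif rec.svtype == "INV":
                quads = ("mm", "pp")
            elif rec.svtype == "DUP":
                quads = ("pp", "mm", "mp", "pm")
            elif rec.svtype == "TRA":
                quads = ("pp", "mm") if rec.info.get("reciprocal", True) else ("pp",)
            else:  # BND
                quads = ("pp",)
            chromA = M.chroms[M.bin_chrom[b1]][0]
            chromB = M.chroms[M.bin_chrom[b2]][0]
            lo1, hi1 = M.chrom_range(chromA)
            lo2, hi2 = M.chrom_range(chromB)
            spans = {
                "pp": (b1, min(b1 + E, hi1 - 1), b2, min(b2 + E, hi2 - 1)),
                "mm": (max(b1 - E, lo1), b1, max(b2 - E, lo2), b2),
                "mp": (max(b1 - E, lo1), b1, b2, min(b2 + E, hi2 - 1)),
                "pm": (b1, min(b1 + E, hi1 - 1), max(b2 - E, lo2), b2),
            }
            for q in quads:
                a0, a1, c0, c1 = spans[q]
                lam[a0 : a1 + 1, c0 : c1 + 1] += (
                    signal_factor * lam[a0 : a1 + 1, c0 : c1 + 1]
                )
                lam[c0 : c1 + 1, a0 : a1 + 1] = lam[a0 : a1 + 1, c0 : c1 + 1].T

    rng = np.random.default_rng(seed)
    draw = rng.poisson(np.triu(lam))
    M.counts = draw + np.triu(draw, 1).T
    return M


def simulate_purity_series(
    truth: TruthSet,
    purities=(0.05, 0.10, 0.20, 0.50, 0.75, 1.0),
    depths=(10, 30, 50, 100, 200, 300),
    het_fraction: float = 0.5,
    capture_eff: float = 0.3,
    min_support: int = 3,
    seed: int = 0,
) -> dict:
    """Tumor purity x sequencing depth titration of a single caller.

    A somatic SV is detected when its supporting-read count, Poisson with
    mean ``depth x purity x het_fraction x capture_eff``, reaches
    ``min_support``; germline SVs use purity 1.  One latent uniform per SV is
    shared across the whole grid (a titration dilutes the same library), so
    the read counts are comonotone across conditions while each draw is
    exactly Poisson-distributed.
    """
    if not all(0 < p <= 1 for p in purities):
        raise ValueError("purities must lie in (0, 1]")
    if not all(d > 0 for d in depths):
        raise ValueError("depths must be positive")
    rng = np.random.default_rng(seed)
    latent = {rec.id: rng.random() for rec in truth.somatic + truth.germline}
    somatic_ids = {r.id for r in truth.somatic}

    series = {}
    for purity in purities:
        for depth in depths:
            records = []
            for rec in truth.somatic + truth.germline:
                eff_purity = purity if rec.id in somatic_ids else 1.0
                mu = depth * eff_purity * het_fraction * capture_eff
                reads = int(stats.poisson.ppf(latent[rec.id], mu)) if mu > 0 else 0
                if reads < min_support:
                    continue
                clone = SVRecord(
                    rec.id, rec.svtype, rec.bnd1, rec.bnd2,
                    size=rec.size if rec.svtype == "INS" else -1,
                    info={TRUTH_INFO_KEY: rec.id, "support": reads},
                )
                records.append(clone)
            prov = Provenance("Illumina", "TNscope", "1", "tumor")
            series[(purity, depth)] = CallSet(provenance=prov, records=records).sort()
    return series
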