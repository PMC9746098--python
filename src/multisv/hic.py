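"""Hi-C contact-matrix rearrangement detection.

The genome is divided into non-overlapping bins of width ``w`` and read pairs
mapping with MAPQ above a threshold are tabulated into a symmetric count
matrix N_ij.  A rearrangement junction produces a contrast between the
north-east/south-west and north-west/south-east local quadrants around a bin
pair.  With Poisson-distributed local counts, two z-scores capture that
contrast::

    Z+ = (N+ - N-) / sqrt(N-)        Z- = (N- - N+) / sqrt(N+)

where N+ sums the NE and SW quadrants up to a range R and N- the NW and SE
quadrants (each sum includes the center cell in both of its two terms, which
is how the formulas read; the double count cancels in the numerator).  Bin
pairs where max(Z+, Z-) exceeds a threshold and is a local maximum within 3
bins are candidate junctions; candidates are filtered by a deterministic
score/mass rule, refined to finer breakpoints with exponentially decaying
quadrant kernels, and classified from their four-quadrant coverage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import chrom_sort_key

DEFAULT_BIN_WIDTH = 50_000
DEFAULT_MAPQ_MIN = 20
DEFAULT_QUADRANT_RANGE = 10  # bins; never stated upstream, configurable
DEFAULT_Z_MIN = 1.0
DEFAULT_LOCAL_MAX_RANGE = 3  # bins (the "3w" rule)
DEFAULT_REFINE_HALF_WINDOW = 2_000_000  # bp
#: deterministic candidate filter defaults; see docs/methods.md for the
#: Poisson tail analysis behind them
DEFAULT_MIN_SCORE = 6.0
DEFAULT_MIN_QUADRANT_MASS = 50

EVENT_CLASSES = (
    "reciprocal_translocation",
    "nonreciprocal_translocation",
    "deletion",
    "inversion",
    "segmental_duplication",
    "unclassified",
)


class ContactMatrix:
    """Symmetric binned Hi-C read-pair counts over a concatenated genome."""

    def __init__(self, chrom_sizes, w: int = DEFAULT_BIN_WIDTH,
                 mapq_min: int = DEFAULT_MAPQ_MIN):
        if w <= 0:
            raise ValueError("bin width must be positive")
        self.w = int(w)
        self.mapq_min = int(mapq_min)
        self.chroms = list(chrom_sizes.items())
        self.chrom_sizes = dict(self.chroms)
        self._nbins = {c: -(-length // self.w) for c, length in self.chroms}
        self.offsets = {}
        off = 0
        for c, _ in self.chroms:
            self.offsets[c] = off
            off += self._nbins[c]
        self.n = off
        self.counts = np.zeros((self.n, self.n), dtype=np.int64)
        #: chromosome index of each global bin
        self.bin_chrom = np.concatenate(
            [np.full(self._nbins[c], k, dtype=np.int32) for k, (c, _) in enumerate(self.chroms)]
        ) if self.n else np.zeros(0, dtype=np.int32)
        self.skipped = {"low_mapq": 0, "unknown_chrom": 0, "out_of_range": 0}

    # -- addressing ---------------------------------------------------------
    def bin_of(self, chrom: str, pos: int) -> int:
        if chrom not in self.offsets:
            raise KeyError(chrom)
        if not (1 <= pos <= self.chrom_sizes[chrom]):
            raise ValueError(f"{chrom}:{pos} outside chromosome")
        return self.offsets[chrom] + (pos - 1) // self.w

    def locus_of(self, b: int) -> tuple[str, int]:
        """Chromosome and bin-center coordinate (1-based) of a global bin."""
        chrom, _ = self.chroms[self.bin_chrom[b]]
        local = b - self.offsets[chrom]
        return chrom, local * self.w + self.w // 2

    def chrom_range(self, chrom: str) -> tuple[int, int]:
        """Global [start, end) bin range of a chromosome."""
        start = self.offsets[chrom]
        return start, start + self._nbins[chrom]

    # -- construction -------------------------------------------------------
    def add_pair(self, chromA, posA, mapqA, chromB, posB, mapqB):
        if mapqA <= self.mapq_min or mapqB <= self.mapq_min:
            self.skipped["low_mapq"] += 1
            return
        if chromA not in self.offsets or chromB not in self.offsets:
            self.skipped["unknown_chrom"] += 1
            return
        try:
            i = self.bin_of(chromA, posA)
            j = self.bin_of(chromB, posB)
        except ValueError:
            self.skipped["out_of_range"] += 1
            return
        self.counts[i, j] += 1
        self.counts[j, i] += 1

    @classmethod
    def from_pairs(cls, pairs, chrom_sizes, w=DEFAULT_BIN_WIDTH,
                   mapq_min=DEFAULT_MAPQ_MIN) -> "ContactMatrix":
        """Bin an iterable of (chromA, posA, mapqA, chromB, posB, mapqB)."""
        M = cls(chrom_sizes, w=w, mapq_min=mapq_min)
        for chromA, posA, mapqA, chromB, posB, mapqB in pairs:
            M.add_pair(chromA, int(posA), int(mapqA), chromB, int(posB), int(mapqB))
        return M

    @classmethod
    def from_pairs_file(cls, path, chrom_sizes, w=DEFAULT_BIN_WIDTH,
                        mapq_min=DEFAULT_MAPQ_MIN) -> "ContactMatrix":
        def gen():
            with open(path) as fh:
                for line in fh:
                    if line.startswith("#") or not line.strip():
                        continue
                    f = line.split()
                    yield f[0], int(f[1]), int(f[2]), f[3], int(f[4]), int(f[5])

        return cls.from_pairs(gen(), chrom_sizes, w=w, mapq_min=mapq_min)

    # -- triplet text container --------------------------------------------
    def to_triplets(self, path) -> str:
        """Sparse upper-triangle triplet text with a self-describing header."""
        with open(path, "w") as fh:
            fh.write(f"#w={self.w}\n#mapq_min={self.mapq_min}\n")
            for chrom, length in self.chroms:
                fh.write(f"#chrom={chrom}\t{length}\n")
            iu = np.triu_indices(self.n)
            vals = self.counts[iu]
            nz = vals > 0
            for i, j, v in zip(iu[0][nz], iu[1][nz], vals[nz]):
                fh.write(f"{i}\t{j}\t{v}\n")
        return str(path)

    @classmethod
    def from_triplets(cls, path) -> "ContactMatrix":
        w = mapq_min = None
        chrom_sizes: dict[str, int] = {}
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    key, _, val = line[1:].partition("=")
                    if key == "w":
                        w = int(val)
                    elif key == "mapq_min":
                        mapq_min = int(val)
                    elif key == "chrom":
                        name, size = val.split("\t")
                        chrom_sizes[name] = int(size)
                    continue
                i, j, v = line.split("\t")
                rows.append((int(i), int(j), int(v)))
        if w is None or not chrom_sizes:
            raise ValueError("triplet file lacks a #w= / #chrom= header")
        M = cls(chrom_sizes, w=w, mapq_min=mapq_min if mapq_min is not None else DEFAULT_MAPQ_MIN)
        for i, j, v in rows:
            if not (0 <= i < M.n and 0 <= j < M.n):
                raise ValueError(f"bin pair ({i},{j}) outside the {M.n}-bin genome")
            M.counts[i, j] += v
            if i != j:
                M.counts[j, i] += v
        return M

    def validate_symmetry(self):
        if not np.array_equal(self.counts, self.counts.T):
            raise ValueError("contact matrix is not symmetric")


@dataclass
class JunctionCandidate:
    i: int
    j: int
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    n_plus: float
    n_minus: float
    z_plus: float
    z_minus: float
    score: float
    refined_bp1: tuple | None = None  # (chrom, pos)
    refined_bp2: tuple | None = None
    refine_fallback: bool = False
    event_class: str | None = None
    quadrant_coverage: dict = field(default_factory=dict)


def quadrant_sums(M: ContactMatrix, i: int, j: int, R: int) -> tuple[int, int]:
    """N+ (NE+SW) and N- (NW+SE) quadrant sums around bin pair (i, j).

    Each sum runs from the center up to range R inclusive and truncates at the
    matrix edges; the center cell appears in both terms of each sum, exactly
    as the defining formulas state.
    """
    if R < 1:
        raise ValueError("quadrant range R must be >= 1")
    C = M.counts
    n = M.n

    def rect(a0, a1, b0, b1):
        a0, b0 = max(a0, 0), max(b0, 0)
        a1, b1 = min(a1, n - 1), min(b1, n - 1)
        if a0 > a1 or b0 > b1:
            return 0
        return int(C[a0 : a1 + 1, b0 : b1 + 1].sum())

    n_plus = rect(i, i + R, j, j + R) + rect(i - R, i, j - R, j)
    n_minus = rect(i - R, i, j, j + R) + rect(i, i + R, j - R, j)
    return n_plus, n_minus


def z_scores(n_plus: float, n_minus: float) -> tuple[float, float]:
    """Poisson quadrant z-scores; zero denominators are floored at 1."""
    zp = (n_plus - n_minus) / math.sqrt(max(n_minus, 1))
    zm = (n_minus - n_plus) / math.sqrt(max(n_plus, 1))
    return zp, zm


def _quadrant_sum_fields_rect(C: np.ndarray, R: int):
    """Vectorized N+/N- over every cell of a (possibly rectangular) block,
    via a summed-area table; quadrant windows truncate at block edges."""
    nr, nc = C.shape
    S = np.zeros((nr + 1, nc + 1), dtype=np.float64)
    S[1:, 1:] = C.cumsum(axis=0).cumsum(axis=1)
    ridx = np.arange(nr)
    cidx = np.arange(nc)

    def rect(di0, di1, dj0, dj1):
        a = np.clip(ridx + di0, 0, nr - 1)
        b = np.clip(ridx + di1, 0, nr - 1)
        c = np.clip(cidx + dj0, 0, nc - 1)
        d = np.clip(cidx + dj1, 0, nc - 1)
        return (
            S[np.ix_(b + 1, d + 1)]
            - S[np.ix_(a, d + 1)]
            - S[np.ix_(b + 1, c)]
            + S[np.ix_(a, c)]
        )

    n_plus = rect(0, R, 0, R) + rect(-R, 0, -R, 0)
    n_minus = rect(-R, 0, 0, R) + rect(0, R, -R, 0)
    return n_plus, n_minus


def find_candidates(
    M: ContactMatrix,
    R: int = DEFAULT_QUADRANT_RANGE,
    Z_min: float = DEFAULT_Z_MIN,
    local_max_range_bins: int = DEFAULT_LOCAL_MAX_RANGE,
    diag_suppress_bins: int | None = None,
) -> list[JunctionCandidate]:
    """Scan the matrix for candidate junctions.

    Quadrant sums are evaluated within each chromosome-pair block (a junction
    contrast is only meaningful against that pair's background), and the scan
    emits upper-triangle bin pairs whose score S = max(Z+, Z-) exceeds
    ``Z_min`` and is a local maximum within a Chebyshev range of
    ``local_max_range_bins``.  Two systematic-bias guards apply:

    * intra-chromosomal pairs within ``diag_suppress_bins`` of the diagonal
      (default 3R) are suppressed — the NW/SE quadrants extend 2R bins along
      the distance axis, and the convexity of the contact decay inflates Z-
      for several more bins beyond that;
    * block-corner positions where *both* quadrant axes truncate are skipped,
      because the N+/N- areas become asymmetric there and the raw-sum
      contrast is biased by construction (single-edge truncation is
      area-balanced and kept).

    Tied plateaus yield one candidate (first in scan order).  Candidates are
    sorted by descending score.
    """
    if R < 1:
        raise ValueError("quadrant range R must be >= 1")
    if M.n == 0:
        return []
    diag = 3 * R if diag_suppress_bins is None else diag_suppress_bins
    size = 2 * local_max_range_bins + 1
    r = local_max_range_bins

    raw: list[tuple[float, int, int, float, float, float, float]] = []
    names = [c for c, _ in M.chroms]
    for a, chromA in enumerate(names):
        r0, r1 = M.chrom_range(chromA)
        for chromB in names[a:]:
            c0, c1 = M.chrom_range(chromB)
            block = M.counts[r0:r1, c0:c1]
            nr, nc = block.shape
            if nr == 0 or nc == 0:
                continue
            n_plus, n_minus = _quadrant_sum_fields_rect(block, R)
            zp = (n_plus - n_minus) / np.sqrt(np.maximum(n_minus, 1.0))
            zm = (n_minus - n_plus) / np.sqrt(np.maximum(n_plus, 1.0))
            score = np.maximum(zp, zm)

            bi = np.arange(nr)[:, None]
            bj = np.arange(nc)[None, :]
            row_trunc = (bi < R) | (bi > nr - 1 - R)
            col_trunc = (bj < R) | (bj > nc - 1 - R)
            valid = ~(row_trunc & col_trunc)
            if chromA == chromB:
                valid &= (bj - bi) > diag  # upper triangle + diagonal band
            masked = np.where(valid, score, -np.inf)
            local_max = ndimage.maximum_filter(masked, size=size,
                                               mode="constant", cval=-np.inf)
            cand = (masked > Z_min) & (masked >= local_max)
            for bi_, bj_ in zip(*np.nonzero(cand)):
                raw.append(
                    (float(score[bi_, bj_]), r0 + int(bi_), c0 + int(bj_),
                     float(n_plus[bi_, bj_]), float(n_minus[bi_, bj_]),
                     float(zp[bi_, bj_]), float(zm[bi_, bj_]))
                )

    raw.sort(key=lambda t: (-t[0], t[1], t[2]))
    kept: list[tuple[int, int]] = []
    out: list[JunctionCandidate] = []
    for score_v, i, j, npl, nmi, zpv, zmv in raw:
        if any(abs(i - ki) <= r and abs(j - kj) <= r for ki, kj in kept):
            continue  # tied plateau: keep one representative
        kept.append((i, j))
        c1, p1 = M.locus_of(i)
        c2, p2 = M.locus_of(j)
        out.append(
            JunctionCandidate(
                i=i, j=j, chrom1=c1, pos1=p1, chrom2=c2, pos2=p2,
                n_plus=npl, n_minus=nmi, z_plus=zpv, z_minus=zmv, score=score_v,
            )
        )
    return out


def balanced_contrast(n_plus: float, n_minus: float) -> float:
    """Two-sample Poisson contrast |N+ - N-| / sqrt(N+ + N-).

    Unlike Z+/Z-, whose sqrt(N-) denominator under-normalizes when the two
    quadrant sums have similar means (a 6-threshold there corresponds to only
    ~4 Gaussian sigma), this statistic is calibrated under the null and is
    used by the deterministic candidate filter.
    """
    total = n_plus + n_minus
    if total <= 0:
        return 0.0
    return abs(n_plus - n_minus) / math.sqrt(total)


def filter_candidates(
    cands: list[JunctionCandidate],
    min_score: float = DEFAULT_MIN_SCORE,
    min_quadrant_mass: float = DEFAULT_MIN_QUADRANT_MASS,
    min_balanced_z: float | None = None,
) -> list[JunctionCandidate]:
    """Deterministic stand-in for the upstream CNN candidate classifier.

    Keeps candidates with score >= ``min_score``, supporting read-pair mass
    max(N+, N-) >= ``min_quadrant_mass``, and a balanced quadrant contrast of
    at least ``min_balanced_z`` (defaults to ``min_score``); the last guard
    removes the near-symmetric fluctuations that the one-sided z-scores
    over-rate.  All thresholds at 0 make this the identity.
    """
    if min_balanced_z is None:
        min_balanced_z = min_score
    return [
        c
        for c in cands
        if c.score >= min_score
        and max(c.n_plus, c.n_minus) >= min_quadrant_mass
        and balanced_contrast(c.n_plus, c.n_minus) >= min_balanced_z
    ]


@dataclass
class RefinedBreakpoint:
    bp1: tuple  # (chrom, pos)
    bp2: tuple
    kernel: str  # 'plus' or 'minus'
    fallback: bool = False


def refine_breakpoint(
    M: ContactMatrix,
    chrom1: str,
    pos1: int,
    chrom2: str,
    pos2: int,
    half_window_bp: int = DEFAULT_REFINE_HALF_WINDOW,
    decay_bp: float | None = None,
) -> RefinedBreakpoint:
    """Refine a candidate junction with exponential quadrant kernels.

    Two kernels with values exp(-(|dx|+|dy|)/decay) — one supported on the
    NE/SW quadrants, one on NW/SE — are cross-correlated with the contact
    submatrix extending ``half_window_bp`` to each side of the candidate
    (truncated at chromosome ends).  The larger of the two correlation maxima
    gives the refined breakpoint at the bin resolution of ``M``; ties break
    toward the NE/SW kernel and then the smallest coordinates.  ``M`` may be a
    finer-binned matrix than the one the candidate was found in.
    """
    w = M.w
    decay_bp = 5 * w if decay_bp is None else float(decay_bp)
    hw = max(1, int(half_window_bp // w))
    b1, b2 = M.bin_of(chrom1, pos1), M.bin_of(chrom2, pos2)
    lo1, hi1 = M.chrom_range(chrom1)
    lo2, hi2 = M.chrom_range(chrom2)
    r0, r1 = max(b1 - hw, lo1), min(b1 + hw, hi1 - 1)
    c0, c1 = max(b2 - hw, lo2), min(b2 + hw, hi2 - 1)
    sub = M.counts[r0 : r1 + 1, c0 : c1 + 1].astype(np.float64)
    if sub.size == 0 or sub.sum() == 0:
        return RefinedBreakpoint((chrom1, pos1), (chrom2, pos2), "plus", fallback=True)

    kh = max(3, int(round(3 * decay_bp / w)))
    dx, dy = np.meshgrid(np.arange(-kh, kh + 1), np.arange(-kh, kh + 1),
                         indexing="ij")
    base = np.exp(-(np.abs(dx) + np.abs(dy)) * w / decay_bp)
    mask_plus = ((dx >= 0) & (dy >= 0)) | ((dx <= 0) & (dy <= 0))
    mask_minus = ((dx >= 0) & (dy <= 0)) | ((dx <= 0) & (dy >= 0))
    surf_p = ndimage.correlate(sub, base * mask_plus, mode="constant", cval=0.0)
    surf_m = ndimage.correlate(sub, base * mask_minus, mode="constant", cval=0.0)

    max_p, max_m = surf_p.max(), surf_m.max()
    if max_p >= max_m:
        surf, kernel = surf_p, "plus"
    else:
        surf, kernel = surf_m, "minus"
    flat = int(np.argmax(surf))  # row-major: smallest coordinates on ties
    ai, aj = np.unravel_index(flat, surf.shape)
    bp1 = M.locus_of(r0 + int(ai))
    bp2 = M.locus_of(c0 + int(aj))
    return RefinedBreakpoint(bp1, bp2, kernel)


@dataclass
class EventCall:
    event_class: str
    quadrant_coverage: dict  # labels 'pp','mm','mp','pm' -> mean count per cell
    background: dict  # per-quadrant background level (shared for inter-chrom)


def classify_event(
    M: ContactMatrix,
    chrom1: str,
    bp1: int,
    chrom2: str,
    bp2: int,
    R: int = DEFAULT_QUADRANT_RANGE,
    theta: float = 2.5,
) -> EventCall:
    """Classify a refined junction from its four-quadrant coverage.

    Quadrant means are measured over R bins on each side of the breakpoint
    pair; the background is the median cell count in a 3R-wide frame around
    the quadrant windows (falling back to the frame mean when the median is
    zero, as it is in sparse regimes).  A quadrant is elevated when its mean
    exceeds ``theta`` times the background.  Quadrant labels: 'pp' means
    counts at positions past bp1 and past bp2, 'mp' before bp1 / past bp2,
    and so on.
    """
    b1, b2 = M.bin_of(chrom1, bp1), M.bin_of(chrom2, bp2)
    intra = chrom1 == chrom2
    if (b2, chrom_sort_key(chrom2)) < (b1, chrom_sort_key(chrom1)):
        chrom1, bp1, b1, chrom2, bp2, b2 = chrom2, bp2, b2, chrom1, bp1, b1
    lo1, hi1 = M.chrom_range(chrom1)
    lo2, hi2 = M.chrom_range(chrom2)

    def mean_rect(a0, a1, b0, b1_):
        a0, b0 = max(a0, lo1), max(b0, lo2)
        a1, b1_ = min(a1, hi1 - 1), min(b1_, hi2 - 1)
        if a0 > a1 or b0 > b1_:
            return 0.0
        block = M.counts[a0 : a1 + 1, b0 : b1_ + 1]
        return float(block.mean())

    # windows exclude the breakpoint row/column itself: junction templates
    # fill their quadrant up to the corner, and including the boundary cells
    # would leak each pattern into its neighbouring quadrants
    coverage = {
        "pp": mean_rect(b1 + 1, b1 + R, b2 + 1, b2 + R),
        "mm": mean_rect(b1 - R, b1 - 1, b2 - R, b2 - 1),
        "mp": mean_rect(b1 - R, b1 - 1, b2 + 1, b2 + R),
        "pm": mean_rect(b1 + 1, b1 + R, b2 - R, b2 - 1),
    }

    f = 2 * R
    fr0, fr1 = max(b1 - f, lo1), min(b1 + f, hi1 - 1)
    fc0, fc1 = max(b2 - f, lo2), min(b2 + f, hi2 - 1)
    frame = M.counts[fr0 : fr1 + 1, fc0 : fc1 + 1].astype(np.float64)
    inner = np.zeros_like(frame, dtype=bool)
    ir0, ir1 = max(b1 - R, fr0) - fr0, min(b1 + R, fr1) - fr0
    ic0, ic1 = max(b2 - R, fc0) - fc0, min(b2 + R, fc1) - fc0
    inner[ir0 : ir1 + 1, ic0 : ic1 + 1] = True
    ring = ~inner

    def ring_level(mask) -> float:
        cells = frame[mask]
        if cells.size == 0:
            return 0.0
        level = float(np.median(cells))
        # sparse regimes have a zero median; fall back to the mean
        return level if level > 0 else float(cells.mean())

    if intra:
        # contact intensity decays with diagonal offset, so each quadrant is
        # compared against ring cells from its own distance band
        rows = np.arange(fr0, fr1 + 1)[:, None]
        cols = np.arange(fc0, fc1 + 1)[None, :]
        offset = np.abs(cols - rows).astype(np.float64)
        d = abs(b2 - b1)
        band_center = {"pp": d, "mm": d, "mp": d + R, "pm": max(d - R, 0)}
        background = {}
        for q, center in band_center.items():
            band = ring & (np.abs(offset - center) <= R)
            background[q] = ring_level(band if band.any() else ring)
    else:
        level = ring_level(ring)
        background = {q: level for q in coverage}

    elevated = {
        q for q, cov in coverage.items() if cov > theta * background[q] and cov > 0
    }

    if not elevated:
        cls = "unclassified"
    elif elevated == {"pp", "mm", "mp", "pm"}:
        cls = "segmental_duplication"
    elif not intra:
        if len(elevated) == 1:
            cls = "nonreciprocal_translocation"
        elif elevated in ({"pp", "mm"}, {"mp", "pm"}):
            cls = "reciprocal_translocation"
        else:
            cls = "unclassified"
    else:
        if elevated == {"mp"}:
            cls = "deletion"  # joins sequence left of bp1 to right of bp2
        elif elevated == {"pp", "mm"}:
            cls = "inversion"  # butterfly pattern along the junction diagonal
        else:
            cls = "unclassified"
    return EventCall(cls, coverage, background)


def detect_junctions(
    M: ContactMatrix,
    R: int = DEFAULT_QUADRANT_RANGE,
    Z_min: float = DEFAULT_Z_MIN,
    local_max_range_bins: int = DEFAULT_LOCAL_MAX_RANGE,
    min_score: float = DEFAULT_MIN_SCORE,
    min_quadrant_mass: float = DEFAULT_MIN_QUADRANT_MASS,
    refine_matrix: ContactMatrix | None = None,
    half_window_bp: int = DEFAULT_REFINE_HALF_WINDOW,
    decay_bp: float | None = None,
    theta: float = 2.5,
) -> list[JunctionCandidate]:
    """Full detector: scan, filter, refine, classify.

    ``refine_matrix`` may supply a finer-binned matrix for breakpoint
    refinement; by default the detection matrix is reused.
    """
    cands = find_candidates(M, R=R, Z_min=Z_min,
                            local_max_range_bins=local_max_range_bins)
    cands = filter_candidates(cands, min_score=min_score,
                              min_quadrant_mass=min_quadrant_mass)
    fine = refine_matrix or M
    for cand in cands:
        ref = refine_breakpoint(
            fine, cand.chrom1, cand.pos1, cand.chrom2, cand.pos2,
            half_window_bp=half_window_bp, decay_bp=decay_bp,
        )
        cand.refined_bp1, cand.refined_bp2 = ref.bp1, ref.bp2
        cand.refine_fallback = ref.fallback
        call = classify_event(
            fine, ref.bp1[0], ref.bp1[1], ref.bp2[0], ref.bp2[1],
            R=R, theta=theta,
        )
        cand.event_class = call.event_class
        cand.quadrant_coverage = call.quadrant_coverage
    return cands


def candidates_to_dataframe(cands: list[JunctionCandidate]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "bin_i": c.i, "bin_j": c.j,
                "chrom1": c.chrom1, "pos1": c.pos1,
                "chrom2": c.chrom2, "pos2": c.pos2,
                "n_plus": c.n_plus, "n_minus": c.n_minus,
                "z_plus": c.z_plus, "z_minus": c.z_minus, "score": c.score,
                "refined_chrom1": c.refined_bp1[0] if c.refined_bp1 else None,
                "refined_pos1": c.refined_bp1[1] if c.refined_bp1 else None,
                "refined_chrom2": c.refined_bp2[0] if c.refined_bp2 else None,
                "refined_pos2": c.refined_bp2[1] if c.refined_bp2 else None,
                "event_class": c.event_class,
            }
            for c in cands
        ]
    )


def candidates_to_bedpe(cands: list[JunctionCandidate], path, w: int) -> str:
    """Write refined junctions as BEDPE (0-based half-open bin intervals)."""
    with open(path, "w") as fh:
        for k, c in enumerate(cands):
            ch1, p1 = c.refined_bp1 or (c.chrom1, c.pos1)
            ch2, p2 = c.refined_bp2 or (c.chrom2, c.pos2)
            s1, s2 = (p1 - 1) // w * w, (p2 - 1) // w * w
            fh.write(
                f"{ch1}\t{s1}\t{s1 + w}\t{ch2}\t{s2}\t{s2 + w}\t"
                f"junction_{k}\t{c.score:.4f}\t.\t.\t{c.event_class or '.'}\n"
            )
    return str(path)
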