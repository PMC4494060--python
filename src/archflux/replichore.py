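"""Replichore architecture: GC skew, ori/ter detection, distances, growth rates.

On a circular bacterial chromosome the two replication forks proceed from the
origin (*ori*) to the terminus (*ter*).  The leading strand is typically
G-rich, so the windowed GC skew (G-C)/(G+C) changes sign at *ori* and *ter*
and the cumulative skew curve attains extrema there: with the G-rich-leading
convention, a minimum at *ori* and a maximum at *ter*.

The module also carries the two small growth-physiology calculations used to
interpret replichore architecture: the exponential-phase doubling time from an
OD time series, and the dimensionless replication ratio
``R = (replichore replication time) / (minimal doubling time)``; values of R
above ~0.5 signal overlapping replication rounds and gene-dosage gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_io import CircularGenome, GeneRecord

__all__ = [
    "SkewProfile",
    "OriTerCall",
    "GrowthFit",
    "ReplicationParams",
    "gc_skew_profile",
    "detect_ori_ter",
    "find_dif_sites",
    "distance_to_ori",
    "estimate_doubling_time",
    "replication_ratio_R",
    "NoReplichoreSignal",
    "NoGrowthDetected",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class NoReplichoreSignal(ValueError):
    """Cumulative GC skew too flat to call ori/ter."""


class NoGrowthDetected(ValueError):
    """No window of the growth curve shows a positive log-linear slope."""


@dataclass
class SkewProfile:
    """Windowed GC-skew profile of one circular genome."""

    genome_id: str
    window: int
    step: int
    centers: np.ndarray  # window centre positions, bp
    skew: np.ndarray  # (G-C)/(G+C) per window, in [-1, 1]
    cumulative: np.ndarray  # running sum of skew
    zero_gc: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))
    gc_count: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    genome_length: int = 0


@dataclass
class OriTerCall:
    ori: int
    ter: int
    uncertainty_bp: int  # one window


@dataclass
class GrowthFit:
    """Log-linear fit of the exponential phase of a growth curve."""

    slope: float  # per minute, of ln(OD)
    intercept: float
    doubling_time: float  # minutes; ln(2)/slope
    window: tuple[float, float]  # (t_start, t_end), minutes
    r_squared: float
    n_points: int


@dataclass
class ReplicationParams:
    genome_length: int
    replication_speed: float  # nt/s
    doubling_time: float  # minutes
    R: float  # dimensionless, full precision
    R_rounded: float  # reported to 2 decimals


def _encode(sequence: str) -> np.ndarray:
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return arr


def gc_skew_profile(genome: CircularGenome, window: int = 10_000, step: int = 1_000) -> SkewProfile:
    """Windowed GC skew (G-C)/(G+C) with circular wrap-around.

    Windows with no G or C yield skew 0 and are flagged in ``zero_gc``.
    The cumulative series is the running sum of window skews.
    """
    if genome.sequence is None:
        raise ValueError(f"genome {genome.id!r} has no sequence")
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    L = genome.length
    if window > L:
        raise ValueError(f"window {window} exceeds genome length {L}")
    arr = _encode(genome.sequence)
    is_g = (arr == ord("G")).astype(np.int64)
    is_c = (arr == ord("C")).astype(np.int64)
    # circular prefix sums over a doubled sequence
    cg = np.concatenate([[0], np.cumsum(np.concatenate([is_g, is_g]))])
    cc = np.concatenate([[0], np.cumsum(np.concatenate([is_c, is_c]))])
    starts = np.arange(0, L, step)
    g = cg[starts + window] - cg[starts]
    c = cc[starts + window] - cc[starts]
    denom = g + c
    zero = denom == 0
    skew = np.where(zero, 0.0, (g - c) / np.where(zero, 1, denom))
    centers = (starts + window // 2) % L
    return SkewProfile(
        genome_id=genome.id,
        window=window,
        step=step,
        centers=centers,
        skew=skew,
        cumulative=np.cumsum(skew),
        zero_gc=zero,
        gc_count=denom,
        genome_length=L,
    )


def detect_ori_ter(
    profile: SkewProfile,
    polarity: str = "g_leading",
    flat_tolerance: float = 2.0,
) -> OriTerCall:
    """Locate ori and ter at the extrema of the cumulative GC skew.

    With ``polarity="g_leading"`` (leading strand G-rich) the cumulative-skew
    minimum is called ori and the maximum ter; ``"c_leading"`` flips the
    assignment.

    The flat-curve guard is scale-free: under a skew-less genome the window
    skews are pure binomial sampling noise with standard deviation about
    1/sqrt(G+C per window), so a profile whose window-skew standard deviation
    stays below ``flat_tolerance`` times that sampling noise carries no
    replichore signal and raises :class:`NoReplichoreSignal`.
    """
    if len(profile.centers) < 10:
        raise ValueError("profile too short: need >= 10 windows")
    cum = profile.cumulative
    amplitude = float(cum.max() - cum.min())
    sd = float(np.std(profile.skew))
    noise = float(np.mean(1.0 / np.sqrt(np.maximum(profile.gc_count, 1))))
    if sd < flat_tolerance * noise or amplitude == 0.0:
        raise NoReplichoreSignal(
            f"window-skew sd {sd:.3g} below {flat_tolerance} x expected "
            f"sampling noise ({noise:.3g}): no replichore signal"
        )
    lo = int(profile.centers[int(np.argmin(cum))])
    hi = int(profile.centers[int(np.argmax(cum))])
    if polarity == "g_leading":
        ori, ter = lo, hi
    elif polarity == "c_leading":
        ori, ter = hi, lo
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    return OriTerCall(ori=ori, ter=ter, uncertainty_bp=profile.window)


def _motif_mask(motif: str) -> np.ndarray:
    """Boolean (len(motif), 256) table: allowed ASCII codes per position."""
    mask = np.zeros((len(motif), 256), dtype=bool)
    for j, ch in enumerate(motif.upper()):
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC character {ch!r} in motif")
        for base in IUPAC[ch]:
            mask[j, ord(base)] = True
    return mask


def _scan_strand(codes: np.ndarray, motif: str, L: int) -> np.ndarray:
    """Mismatch count of the motif at each circular start position."""
    mask = _motif_mask(motif)
    m = len(motif)
    ext = np.concatenate([codes, codes[: m - 1]])
    mism = np.zeros(L, dtype=np.int32)
    for j in range(m):
        mism += ~mask[j][ext[j : j + L]]
    return mism


def find_dif_sites(
    genome: CircularGenome,
    motif: str,
    max_mismatch: int = 0,
) -> list[tuple[int, str, int]]:
    """All circular matches of an IUPAC motif on both strands.

    Returns (position, strand, mismatches) triples; the position is the match
    start on the forward strand in forward coordinates for both strands.
    """
    if not motif:
        raise ValueError("empty motif")
    if genome.sequence is None:
        raise ValueError(f"genome {genome.id!r} has no sequence")
    codes = _encode(genome.sequence)
    L = genome.length
    hits: list[tuple[int, str, int]] = []
    fwd = _scan_strand(codes, motif, L)
    for pos in np.nonzero(fwd <= max_mismatch)[0]:
        hits.append((int(pos), "+", int(fwd[pos])))
    # a reverse-strand occurrence equals a forward match of the motif's
    # reverse complement
    rc = motif.upper().translate(_COMPLEMENT)[::-1]
    rev = _scan_strand(codes, rc, L)
    for pos in np.nonzero(rev <= max_mismatch)[0]:
        hits.append((int(pos), "-", int(rev[pos])))
    hits.sort()
    return hits


def distance_to_ori(gene: GeneRecord, genome: CircularGenome) -> int:
    """Shortest circular distance (bp) from the gene midpoint to ori.

    Computed as min(d, L-d) with d = |midpoint - ori| mod L; the result lies
    in [0, L/2].
    """
    if genome.ori is None:
        raise ValueError(f"genome {genome.id!r}: ori not set")
    L = genome.length
    d = abs(gene.midpoint(L) - genome.ori) % L
    return int(min(d, L - d))


def _ols_log(t: np.ndarray, ln_od: np.ndarray) -> tuple[float, float, float]:
    res = stats.linregress(t, ln_od)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def estimate_doubling_time(
    times: "list[float] | np.ndarray",
    od: "list[float] | np.ndarray",
    window: tuple[float, float] | None = None,
    min_points: int = 4,
) -> GrowthFit:
    """Doubling time from ordinary least squares of ln(OD) on time (minutes).

    With an explicit ``window`` the fit uses the points inside it (>= 3
    required, all OD > 0).  Without one, the exponential phase is selected
    automatically: among all contiguous runs of at least ``min_points``
    positive-OD points whose log-linear slope is positive, the run with the
    highest R-squared wins, longer runs breaking ties.  A non-positive best
    slope raises :class:`NoGrowthDetected`.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(od, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and od must be equal-length 1-D sequences")

    if window is not None:
        sel = (t >= window[0]) & (t <= window[1])
        if sel.sum() < 3:
            raise ValueError("fewer than 3 points in the requested window")
        if (y[sel] <= 0).any():
            raise ValueError("non-positive OD inside the requested window")
        slope, intercept, r2 = _ols_log(t[sel], np.log(y[sel]))
        if slope <= 0:
            raise NoGrowthDetected("no growth detected in the requested window")
        return GrowthFit(
            slope, intercept, float(np.log(2) / slope),
            (float(t[sel].min()), float(t[sel].max())), r2, int(sel.sum()),
        )

    n = len(t)
    best: tuple[float, int, float, float, int, int] | None = None
    # (r2, length, slope, intercept, i, j): maximise r2, then length, then -i
    for i in range(n):
        for j in range(i + min_points, n + 1):
            seg_y = y[i:j]
            if (seg_y <= 0).any():
                continue
            slope, intercept, r2 = _ols_log(t[i:j], np.log(seg_y))
            if slope <= 0 or not np.isfinite(r2):
                continue
            key = (round(r2, 12), j - i, -i)
            if best is None or key > (best[0], best[1], -best[4]):
                best = (round(r2, 12), j - i, slope, intercept, i, j)
    if best is None:
        raise NoGrowthDetected("no growth detected")
    r2, _, slope, intercept, i, j = best
    return GrowthFit(
        slope, intercept, float(np.log(2) / slope),
        (float(t[i]), float(t[j - 1])), float(r2), j - i,
    )


def replication_ratio_R(
    genome_length: int,
    speed: float,
    doubling_time: float,
) -> ReplicationParams:
    """Replication ratio R = (L/2 / speed) / (doubling_time in seconds).

    ``speed`` is the fork speed in nucleotides per second and
    ``doubling_time`` the minimal doubling time in minutes.  R compares the
    time needed to replicate one replichore with the doubling time.
    """
    if genome_length <= 0 or speed <= 0 or doubling_time <= 0:
        raise ValueError("all inputs must be positive")
    replichore_seconds = (genome_length / 2.0) / speed
    R = replichore_seconds / (doubling_time * 60.0)
    return ReplicationParams(
        genome_length=int(genome_length),
        replication_speed=float(speed),
        doubling_time=float(doubling_time),
        R=R,
        R_rounded=round(R, 2),
    )
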