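"""Paired-wall cleavage-site calling from a four-sample end-count quartet.

The pipeline is: library-size scaling of the quartet, sliding-window
smoothing of the two mock (-IP) controls, division of each +IP track by
its smoothed mock (copy-number / sequencing-depth correction), a
position-wise count-ratio significance test of treated against untreated,
and detection of position pairs (i, i+5) — two enriched 3'-end walls
flanking the enzyme's 4-bp 5'-overhang — that both pass the test.
Replicate sets are merged by exact coordinate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.special import betainc, gammaln

from .ends_profiles import EndProfile, combined_n3e

GAP = 4  # enzyme leaves 4-bp 5'-overhangs; walls sit at i and i+5


@dataclass
class SampleQuartet:
    """The four linked samples of one replicate.

    treated_ip (+A+IP), treated_mock (+A-IP), untreated_ip (-A+IP) and
    untreated_mock (-A-IP), where A is the trapping poison and IP the
    immunoprecipitation step.
    """

    treated_ip: EndProfile
    treated_mock: EndProfile
    untreated_ip: EndProfile
    untreated_mock: EndProfile
    condition: str = ""
    replicate: int = 0

    _ROLES = ("treated_ip", "treated_mock", "untreated_ip", "untreated_mock")

    def __post_init__(self):
        lengths = {getattr(self, r).genome_length for r in self._ROLES}
        if len(lengths) != 1:
            raise ValueError("all four profiles must share the genome length")

    def profiles(self) -> dict:
        return {r: getattr(self, r) for r in self._ROLES}


@dataclass
class CallerConfig:
    alpha: float = 0.0025
    smoothing_window: int = 200_000
    gap: int = GAP
    count_policy: str = "continuous"  # or "rounded"
    min_replicate_support: int = 2
    epsilon: float = 1e-9
    circular: bool = True
    strand_split: bool = False

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.gap != GAP:
            raise ValueError(
                f"gap is fixed at {GAP} bp by the enzyme's overhang; got {self.gap}"
            )
        if self.count_policy not in ("continuous", "rounded"):
            raise ValueError(f"unknown count_policy {self.count_policy!r}")


@dataclass
class NormalizedPair:
    """Mock-normalized treated and control tracks with an exclusion mask."""

    treated_norm: np.ndarray
    control_norm: np.ndarray
    mask: np.ndarray  # True where a position is excluded

    def __post_init__(self):
        if not (len(self.treated_norm) == len(self.control_norm) == len(self.mask)):
            raise ValueError("arrays must share the genome length")


@dataclass(frozen=True)
class GCSCall:
    """One called cleavage site: walls at (i, i+5), overhang [p0, p0+4)."""

    left_wall: int
    right_wall: int
    position: int  # p0, first base of the 4-bp overhang
    n3e_strength: float
    p_left: float
    p_right: float
    replicate_support: int = 1
    condition: str = ""

    def __post_init__(self):
        if self.position != self.left_wall + 1:
            raise ValueError("p0 must be left_wall + 1")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def library_scale(quartet: SampleQuartet) -> SampleQuartet:
    """Scale each profile to the smallest library in the quartet.

    Each profile is divided by its own total and multiplied by the lowest
    total across the four samples, so all per-profile sums equal
    min(totals) and the smallest-library sample is unchanged.
    """
    totals = {r: p.total_fragments for r, p in quartet.profiles().items()}
    for role, t in totals.items():
        if t <= 0:
            raise ValueError(f"sample {role!r} has no aligned fragments")
    lowest = min(totals.values())
    scaled = {r: getattr(quartet, r).scaled(lowest / totals[r]) for r in quartet._ROLES}
    return replace(quartet, **scaled)


def smooth_profile(values, window: int, circular: bool = True) -> np.ndarray:
    """Centered moving average with the window clipped to the track length."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty array")
    if window < 1:
        raise ValueError("window must be >= 1")
    window = min(window, values.size)
    if window == 1:
        return values.copy()
    mode = "wrap" if circular else "nearest"
    return uniform_filter1d(values, size=window, mode=mode)


def normalize_to_mock(ip, mock_smoothed, epsilon: float = 1e-9):
    """Divide an +IP track by its smoothed mock; mask unusable positions."""
    ip = np.asarray(ip, dtype=float)
    mock_smoothed = np.asarray(mock_smoothed, dtype=float)
    if ip.shape != mock_smoothed.shape:
        raise ValueError("ip and mock arrays must share length")
    mask = mock_smoothed <= epsilon
    if mask.all():
        raise ValueError("mock library unusable: all positions masked")
    out = np.zeros_like(ip)
    np.divide(ip, mock_smoothed, out=out, where=~mask)
    return out, mask


def normalize_quartet(quartet: SampleQuartet, config: CallerConfig) -> NormalizedPair:
    """Full two-step normalization: library scaling then mock division."""
    scaled = library_scale(quartet)
    t_ip = combined_n3e(scaled.treated_ip)
    t_mock = combined_n3e(scaled.treated_mock)
    u_ip = combined_n3e(scaled.untreated_ip)
    u_mock = combined_n3e(scaled.untreated_mock)
    t_mock_s = smooth_profile(t_mock, config.smoothing_window, config.circular)
    u_mock_s = smooth_profile(u_mock, config.smoothing_window, config.circular)
    treated, m1 = normalize_to_mock(t_ip, t_mock_s, config.epsilon)
    control, m2 = normalize_to_mock(u_ip, u_mock_s, config.epsilon)
    return NormalizedPair(treated_norm=treated, control_norm=control, mask=m1 | m2)


# ---------------------------------------------------------------------------
# Audic-Claverie count-ratio test
# ---------------------------------------------------------------------------

def ac_pmf(x, y, n1: float = 1.0, n2: float = 1.0):
    """p(y | x) = (n2/n1)^y (x+y)! / (x! y! (1+n2/n1)^(x+y+1)).

    Evaluated through log-gamma so real-valued (normalized) counts are
    accepted.  For integer counts this is the negative binomial
    NB(r = x+1, p = n1/(n1+n2)) mass at y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    r = n2 / n1
    logp = (
        y * math.log(r)
        + gammaln(x + y + 1)
        - gammaln(x + 1)
        - gammaln(y + 1)
        - (x + y + 1) * math.log1p(r)
    )
    return np.exp(logp)


def ac_pvalue(x, y, n1: float = 1.0, n2: float = 1.0):
    """Upper-tail probability P(Y >= y | x) of the count-ratio test.

    Uses the regularized incomplete beta identity for the negative
    binomial survival function, which extends smoothly to real x and y:
    P(Y >= y | x) = I_q(y, x+1) with q = n2/(n1+n2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    q = n2 / (n1 + n2)
    y_safe = np.where(y > 0, y, 1.0)
    tail = betainc(y_safe, x + 1.0, q)
    return np.where(y > 0, tail, 1.0)[()] if np.ndim(tail) else float(
        tail if y > 0 else 1.0
    )


def ac_min_significant(x, n1: float, n2: float, alpha: float) -> int:
    """Smallest integer y whose upper-tail probability is below alpha."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    y = 1
    while True:
        if float(np.asarray(ac_pvalue(x, y, n1, n2))) < alpha:
            return y
        y += 1
        if y > 10_000_000:  # pragma: no cover
            raise RuntimeError("no significant count below 1e7; check inputs")


# ---------------------------------------------------------------------------
# Calling
# ---------------------------------------------------------------------------

def call_gcs(pair: NormalizedPair, config: CallerConfig) -> list[GCSCall]:
    """Detect paired enriched walls (i, i+5) flanking the 4-bp overhang.

    A site is emitted at every i where treated_norm significantly exceeds
    control_norm at both i and i+5 (no merging of adjacent passing i).
    Library sizes for the test are equal by construction after scaling,
    so the equal-size form of the test applies.
    """
    treated = np.asarray(pair.treated_norm, dtype=float)
    control = np.asarray(pair.control_norm, dtype=float)
    if config.count_policy == "rounded":
        treated = np.rint(treated)
        control = np.rint(control)
    n = len(treated)
    offset = config.gap + 1  # wall spacing

    pvals = np.asarray(ac_pvalue(control, treated))
    sig = (pvals < config.alpha) & ~pair.mask

    if config.circular:
        sig_right = np.roll(sig, -offset)
        p_right_arr = np.roll(pvals, -offset)
        treated_right = np.roll(treated, -offset)
        candidates = np.flatnonzero(sig & sig_right)
    else:
        candidates = np.flatnonzero(sig[: n - offset] & sig[offset:])
        p_right_arr = np.empty(n)
        p_right_arr[: n - offset] = pvals[offset:]
        treated_right = np.empty(n)
        treated_right[: n - offset] = treated[offset:]

    calls = []
    for i in candidates:
        i = int(i)
        # coordinates are left unwrapped (right_wall may exceed the genome
        # length by <= 5 bp near the origin of a circular genome)
        calls.append(
            GCSCall(
                left_wall=i,
                right_wall=i + offset,
                position=i + 1,
                n3e_strength=float((treated[i] + treated_right[i]) / 2.0),
                p_left=float(pvals[i]),
                p_right=float(p_right_arr[i]),
            )
        )
    return calls


def merge_replicates(
    call_sets: Sequence[Sequence[GCSCall]], min_support: int = 2
) -> list[GCSCall]:
    """Keep sites whose p0 recurs in at least ``min_support`` replicates.

    A surviving call's strength is the mean over its supporting
    replicates; its p-values are the worst (largest) across them.
    """
    if len(call_sets) < min_support:
        raise ValueError(
            f"need at least {min_support} replicate sets, got {len(call_sets)}"
        )
    by_pos: dict[int, list[GCSCall]] = {}
    for calls in call_sets:
        seen = set()
        for c in calls:
            if c.position in seen:  # a replicate supports a position once
                continue
            seen.add(c.position)
            by_pos.setdefault(c.position, []).append(c)
    merged = []
    for p0 in sorted(by_pos):
        group = by_pos[p0]
        if len(group) < min_support:
            continue
        first = group[0]
        merged.append(
            GCSCall(
                left_wall=first.left_wall,
                right_wall=first.right_wall,
                position=p0,
                n3e_strength=float(np.mean([c.n3e_strength for c in group])),
                p_left=max(c.p_left for c in group),
                p_right=max(c.p_right for c in group),
                replicate_support=len(group),
                condition=first.condition,
            )
        )
    return merged


def process_quartet(quartet: SampleQuartet, config: CallerConfig) -> list[GCSCall]:
    """normalize_quartet + call_gcs, tagging calls with the condition."""
    pair = normalize_quartet(quartet, config)
    calls = call_gcs(pair, config)
    return [replace(c, condition=quartet.condition) for c in calls]


def write_calls_tsv(calls: Sequence[GCSCall], contig_id: str, path) -> None:
    """BED-like TSV: contig, p0, p0+4, id, strength, '.', p_left, p_right, support."""
    with open(path, "w") as fh:
        fh.write(
            "#contig\tstart\tend\tid\tn3e_strength\tstrand\tp_left\tp_right\tsupport\n"
        )
        for k, c in enumerate(calls):
            fh.write(
                f"{contig_id}\t{c.position}\t{c.position + 4}\tgcs_{k}\t"
                f"{c.n3e_strength:.6g}\t.\t{c.p_left:.6g}\t{c.p_right:.6g}\t"
                f"{c.replicate_support}\n"
            )


def read_calls_tsv(path) -> list[GCSCall]:
    calls = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            p0 = int(f[1])
            calls.append(
                GCSCall(
                    left_wall=p0 - 1,
                    right_wall=p0 + 4,
                    position=p0,
                    n3e_strength=float(f[4]),
                    p_left=float(f[6]),
                    p_right=float(f[7]),
                    replicate_support=int(f[8]),
                )
            )
    return calls
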