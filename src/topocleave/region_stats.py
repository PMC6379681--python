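"""Enrichment and comparison statistics for called sites vs genome regions.

All tests are exact small-count tests: binomial tails for interval
enrichment and genome-bin scans, Fisher's exact test for 2x2 region
count tables, the exact conditional (binomial) test for comparing two
Poisson-distributed signal sums, and a sign-type binomial test on
per-site strength ratios between conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .gcs_caller import GCSCall

logger = logging.getLogger(__name__)


@dataclass
class IntervalSet:
    """Named set of 0-based half-open genomic intervals."""

    name: str
    intervals: list  # (start, end) or (start, end, strand)

    def __post_init__(self):
        for iv in self.intervals:
            s, e = iv[0], iv[1]
            if e <= s or s < 0:
                raise ValueError(f"invalid interval ({s}, {e}) in {self.name!r}")

    def merged(self) -> list[tuple[int, int]]:
        """Overlap-merged intervals for length accounting."""
        ivs = sorted((iv[0], iv[1]) for iv in self.intervals)
        out = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        return out

    @property
    def total_length(self) -> int:
        return sum(e - s for s, e in self.merged())

    def contains(self, positions) -> np.ndarray:
        positions = np.asarray(positions)
        hit = np.zeros(len(positions), dtype=bool)
        for s, e in self.merged():
            hit |= (positions >= s) & (positions < e)
        return hit

    @classmethod
    def from_bed(cls, path, name: str = None) -> "IntervalSet":
        ivs = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                strand = f[5].strip() if len(f) > 5 else "."
                ivs.append((int(f[1]), int(f[2]), strand))
        return cls(name=name or str(path), intervals=ivs)


@dataclass
class TUAnnotation:
    """A transcription unit with its strand and expression level."""

    id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    expression: float = 0.0

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"TU {self.id!r} needs a '+' or '-' strand")
        if self.end <= self.start:
            raise ValueError(f"TU {self.id!r} has an empty span")
        if self.expression < 0:
            raise ValueError("expression must be >= 0")


@dataclass
class EnrichmentResult:
    name: str
    observed: int
    n: int
    p: float
    expected: float
    fold: float
    p_over: float
    p_under: float


@dataclass
class BinEnvelope:
    bins: int
    edges: np.ndarray
    counts: np.ndarray
    lower: int
    upper: int
    flags: list  # per bin: 'low' | 'high' | 'ok'


def _positions(calls_or_positions) -> np.ndarray:
    if len(calls_or_positions) and isinstance(calls_or_positions[0], GCSCall):
        return np.array([c.position for c in calls_or_positions])
    return np.asarray(calls_or_positions)


def binomial_enrichment(
    positions, interval_set: IntervalSet, genome_length: int
) -> EnrichmentResult:
    """Exact binomial test of site counts inside an interval set.

    Under the uniform null each of the n sites lands inside with
    probability p = merged length / genome length.
    """
    positions = _positions(positions)
    n = len(positions)
    if n == 0:
        raise ValueError("no positions supplied")
    length = interval_set.total_length
    p = length / genome_length
    if not 0 < p < 1:
        raise ValueError(
            f"interval set {interval_set.name!r} covers p={p} of the genome"
        )
    k = int(interval_set.contains(positions).sum())
    return EnrichmentResult(
        name=interval_set.name,
        observed=k,
        n=n,
        p=p,
        expected=n * p,
        fold=k / (n * p),
        p_over=float(stats.binom.sf(k - 1, n, p)),
        p_under=float(stats.binom.cdf(k, n, p)),
    )


def binomial_two_sided(k: int, n: int, p: float) -> float:
    """Two-sided binomial p by the minimum-likelihood method."""
    pmf = stats.binom.pmf(np.arange(n + 1), n, p)
    total = float(pmf[pmf <= pmf[k] * (1 + 1e-12)].sum())
    return 1.0 if total >= 1.0 - 1e-12 else total


def genome_bin_scan(
    positions, genome_length: int, bins: int = 10, q=(0.0005, 0.9995)
) -> BinEnvelope:
    """Counts per equal-width genome bin with an exact binomial envelope.

    The envelope is the exact integer inverse CDF of Binomial(n, 1/bins)
    at the two quantiles; bins whose counts fall outside deviate
    significantly from the uniform expectation.
    """
    positions = _positions(positions)
    n = len(positions)
    if n < 1:
        raise ValueError("need at least one position")
    if bins < 2:
        raise ValueError("need at least 2 bins")
    if bins > genome_length:
        raise ValueError("more bins than genome positions")
    width = genome_length // bins
    edges = np.array([i * width for i in range(bins)] + [genome_length])
    counts = np.histogram(positions % genome_length, bins=edges)[0]
    lower = int(stats.binom.ppf(q[0], n, 1.0 / bins))
    upper = int(stats.binom.ppf(q[1], n, 1.0 / bins))
    flags = [
        "low" if c < lower else ("high" if c > upper else "ok") for c in counts
    ]
    return BinEnvelope(
        bins=bins, edges=edges, counts=counts, lower=lower, upper=upper, flags=flags
    )


def fisher_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]]."""
    for v in (a, b, c, d):
        if v < 0 or v != int(v):
            raise ValueError("table entries must be non-negative integers")
    if a + b + c + d == 0:
        logger.warning("degenerate all-zero 2x2 table; p = 1")
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def poisson_conditional_test(k1: int, k2: int, t1: float, t2: float):
    """Exact conditional test for two Poisson counts with exposures t1, t2.

    Conditional on the total, k1 ~ Binomial(k1 + k2, t1/(t1+t2)).
    Returns (p_one_sided_greater, p_two_sided).
    """
    if t1 <= 0 or t2 <= 0:
        raise ValueError("exposures must be positive")
    k1, k2 = int(round(k1)), int(round(k2))
    if k1 < 0 or k2 < 0:
        raise ValueError("counts must be non-negative")
    n = k1 + k2
    if n == 0:
        logger.warning("both counts zero; p = 1")
        return 1.0, 1.0
    p = t1 / (t1 + t2)
    one_sided = float(stats.binom.sf(k1 - 1, n, p))
    two_sided = binomial_two_sided(k1, n, p)
    return one_sided, two_sided


# ---------------------------------------------------------------------------
# Transcription-unit compartments
# ---------------------------------------------------------------------------

COMPARTMENTS = ("upstream", "body_start", "body_end", "downstream")


def _tu_compartments(tu: TUAnnotation, us_width: int, ds_width: int):
    mid = (tu.start + tu.end) // 2
    if tu.strand == "+":
        return {
            "upstream": (tu.start - us_width, tu.start),
            "body_start": (tu.start, mid),
            "body_end": (mid, tu.end),
            "downstream": (tu.end, tu.end + ds_width),
        }
    return {
        "upstream": (tu.end, tu.end + us_width),
        "body_start": (mid, tu.end),
        "body_end": (tu.start, mid),
        "downstream": (tu.start - ds_width, tu.start),
    }


def _stratify(tus: Sequence[TUAnnotation], expression_strata: int):
    if expression_strata <= 1:
        return {"all": list(tus)}
    expr = np.array([t.expression for t in tus])
    edges = np.quantile(expr, np.linspace(0, 1, expression_strata + 1))
    out = {}
    for s in range(expression_strata):
        lo, hi = edges[s], edges[s + 1]
        if s == expression_strata - 1:
            members = [t for t in tus if lo <= t.expression <= hi]
        else:
            members = [t for t in tus if lo <= t.expression < hi]
        out[f"stratum_{s}"] = members
    return out


def associate_with_tus(
    calls,
    tus: Sequence[TUAnnotation],
    genome_length: int,
    us_width: int = 5000,
    ds_width: int = 5000,
    expression_strata: int = 1,
):
    """Assign sites to strand-aware TU compartments and test enrichment.

    Compartments per TU: upstream (us_width before the promoter), first
    and second halves of the body, and downstream (ds_width past the
    terminator), all following the direction of transcription.  A site
    inside compartments of several TUs goes to the TU whose nearest
    boundary is closest; exact ties are counted in both and flagged.
    Counts are normalised by compartment length through the binomial
    enrichment test.
    """
    positions = _positions(calls)
    results = {}
    for stratum, members in _stratify(tus, expression_strata).items():
        if not members:
            continue
        comp_hits = {c: [] for c in COMPARTMENTS}
        ties = 0
        for pos in positions:
            hits = []  # (distance to nearest TU boundary, tu, compartment)
            for tu in members:
                for comp, (s, e) in _tu_compartments(tu, us_width, ds_width).items():
                    if s <= pos < e:
                        dist = min(abs(pos - tu.start), abs(pos - tu.end))
                        hits.append((dist, tu.id, comp))
            if not hits:
                continue
            hits.sort()
            best = [h for h in hits if h[0] == hits[0][0]]
            if len(best) > 1 and len({h[1] for h in best}) > 1:
                ties += 1
            seen = set()
            for _, tu_id, comp in best:
                if comp not in seen:
                    comp_hits[comp].append(pos)
                    seen.add(comp)
        comp_results = {}
        for comp in COMPARTMENTS:
            ivs = [
                tuple(np.clip(_tu_compartments(t, us_width, ds_width)[comp], 0, genome_length))
                for t in members
            ]
            ivs = [(int(s), int(e)) for s, e in ivs if e > s]
            if not ivs:
                continue
            iset = IntervalSet(name=f"{stratum}:{comp}", intervals=ivs)
            try:
                comp_results[comp] = binomial_enrichment(positions, iset, genome_length)
            except ValueError:
                continue
        results[stratum] = {
            "counts": {c: len(v) for c, v in comp_hits.items()},
            "ties": ties,
            "enrichment": comp_results,
        }
    return results


def compare_shared_gcs(
    calls_a: Sequence[GCSCall],
    calls_b: Sequence[GCSCall],
    region: IntervalSet = None,
):
    """Sign-type binomial test on strength ratios of shared sites.

    Sites present in both sets (exact p0 match) get ratio
    strength_b / strength_a; within the region, m sites out of s have
    ratio < 1 (exact ties dropped) and the one-sided p is the
    Binomial(s, 1/2) lower tail at m.
    """
    by_a = {c.position: c for c in calls_a}
    shared = [(by_a[c.position], c) for c in calls_b if c.position in by_a]
    if region is not None:
        pos = np.array([a.position for a, _ in shared])
        if len(pos):
            keep = region.contains(pos)
            shared = [sh for sh, k in zip(shared, keep) if k]
    if not shared:
        raise ValueError("no shared calls in the region")
    rows = []
    n_less = n_ties = 0
    for a, b in shared:
        ratio = b.n3e_strength / a.n3e_strength
        rows.append((a.position, a.n3e_strength, b.n3e_strength, ratio))
        if ratio == 1.0:
            n_ties += 1
        elif ratio < 1.0:
            n_less += 1
    s = len(rows) - n_ties
    if n_ties:
        logger.info("dropped %d exact-tie ratios from the sign test", n_ties)
    if s == 0:
        p_less = p_greater = 1.0
    else:
        p_less = float(stats.binom.sf(n_less - 1, s, 0.5))  # tendency ratio < 1
        p_greater = float(stats.binom.sf(s - n_less - 1, s, 0.5))
    return {
        "shared": len(rows),
        "informative": s,
        "n_ratio_below_1": n_less,
        "p_below": p_less,
        "p_above": p_greater,
        "table": rows,
    }


def score_set_comparison(scores_a, scores_b):
    """Routine library statistics for score-set comparisons."""
    t = stats.ttest_ind(scores_a, scores_b, equal_var=False)
    return {"t": float(t.statistic), "p": float(t.pvalue)}


def score_correlation(x, y):
    r = stats.pearsonr(x, y)
    return {"r": float(r.statistic), "p": float(r.pvalue)}


def read_tus_tsv(path) -> list[TUAnnotation]:
    """TU table: id, start, end, strand, expression (TSV with header)."""
    tus = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            tus.append(
                TUAnnotation(
                    id=f[0], start=int(f[1]), end=int(f[2]), strand=f[3],
                    expression=float(f[4]) if len(f) > 4 else 0.0,
                )
            )
    return tus
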