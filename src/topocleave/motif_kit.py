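"""Degenerate 130-bp binding-motif construction, scanning and periodicity.

Sites are summarised as a position probability matrix (PPM) over a fixed
window of offsets -63..66 around the cleavage position p0, with the
double-strand cut falling between offsets -1/0 and +3/+4.  The PPM is
converted to a log2-odds weight matrix (PWM) for scanning; sequences are
scored on both strands and the per-position strand maximum is the
"score".  A G/C-content track derived from the PPM carries the phased
~10-11 bp periodicity in the flanking arms, estimated here by a
least-squares sinusoid grid fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .ends_profiles import GenomeSequence
from .gcs_caller import GCSCall

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT_IDX = np.array([3, 2, 1, 0, 4])  # A<->T, C<->G, N->N

UNIFORM_BACKGROUND = np.full(4, 0.25)


@dataclass(frozen=True)
class MotifWindow:
    """Fixed offsets of the motif window relative to the site position p0."""

    upstream: int = 63  # offsets -63..-1
    downstream: int = 67  # offsets 0..66
    mask_start: int = 0  # bias-masked offsets (inclusive)
    mask_end: int = 3
    central: tuple = (-16, 19)
    flank_left: tuple = (-63, -17)
    flank_right: tuple = (20, 66)

    @property
    def length(self) -> int:
        return self.upstream + self.downstream

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.upstream, self.downstream)

    def mask_columns(self) -> np.ndarray:
        """Window column indices corresponding to the masked offsets."""
        return np.arange(self.mask_start + self.upstream, self.mask_end + self.upstream + 1)

    def flank_columns(self) -> np.ndarray:
        off = self.offsets
        keep = ((off >= self.flank_left[0]) & (off <= self.flank_left[1])) | (
            (off >= self.flank_right[0]) & (off <= self.flank_right[1])
        )
        return np.flatnonzero(keep)


DEFAULT_WINDOW = MotifWindow()


@dataclass
class PPM:
    """4 x W position probability matrix over A, C, G, T."""

    matrix: np.ndarray
    column_counts: np.ndarray = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise ValueError("PPM must be a 4 x W matrix")
        if np.any(self.matrix < 0):
            raise ValueError("PPM entries must be non-negative")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("every PPM column must sum to 1")
        if self.column_counts is None:
            self.column_counts = np.zeros(self.matrix.shape[1])

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=0))


@dataclass
class PWM:
    """4 x W log2-odds matrix with its background and pseudocount."""

    matrix: np.ndarray
    background: np.ndarray
    pseudocount: float

    @property
    def width(self) -> int:
        return self.matrix.shape[1]


def extract_site_sequences(
    genome: GenomeSequence,
    calls: Sequence[GCSCall],
    window: MotifWindow = DEFAULT_WINDOW,
) -> list[str]:
    """Forward-strand sequences over [p0 - 63, p0 + 67) for each site."""
    if not calls:
        raise ValueError("empty call list")
    seqs = []
    for c in calls:
        p0 = c.position % genome.length
        start, end = p0 - window.upstream, p0 + window.downstream
        try:
            seqs.append(genome.fetch(start, end))
        except ValueError:
            import logging

            logging.getLogger(__name__).warning(
                "site at p0=%d skipped: window off linear genome end", p0
            )
    if not seqs:
        raise ValueError("no extractable windows for any call")
    return seqs


def sequences_to_indices(sequences: Sequence[str]) -> np.ndarray:
    """Encode sequences as int codes A=0 C=1 G=2 T=3, anything else 4."""
    lut = np.full(256, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    arr = np.frombuffer("".join(sequences).encode("ascii"), dtype=np.uint8)
    return lut[arr].reshape(len(sequences), -1)


def build_ppm(sequences: Sequence[str]) -> PPM:
    """Column-wise base frequencies; N bases drop out of their column."""
    if not sequences:
        raise ValueError("need at least one sequence")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError("sequences must have equal lengths")
    idx = sequences_to_indices(sequences)
    counts = np.stack([(idx == b).sum(axis=0) for b in range(4)]).astype(float)
    denom = counts.sum(axis=0)
    if np.any(denom == 0):
        raise ValueError("a column has no unambiguous bases")
    return PPM(matrix=counts / denom, column_counts=denom)


def gc_track(ppm: PPM) -> np.ndarray:
    """Per-column frequency of G or C."""
    return ppm.matrix[_BASE_INDEX["G"]] + ppm.matrix[_BASE_INDEX["C"]]


def mask_ppm_columns(ppm: PPM, columns: np.ndarray, background: np.ndarray) -> PPM:
    """Overwrite the given columns with the background composition."""
    background = np.asarray(background, dtype=float)
    if not np.isclose(background.sum(), 1.0):
        raise ValueError("background must sum to 1")
    m = ppm.matrix.copy()
    m[:, columns] = background[:, None]
    return PPM(matrix=m, column_counts=ppm.column_counts.copy())


def build_combined_motif(
    per_condition_calls: Mapping[str, Sequence[GCSCall]],
    genome: GenomeSequence,
    top_n: int = 732,
    window: MotifWindow = DEFAULT_WINDOW,
    background: np.ndarray = None,
    dedup: str = "position",
) -> PPM:
    """Pool the strongest sites across conditions into one masked PPM.

    Per condition the ``top_n`` calls with the highest strength are taken
    (all calls if fewer); the pool is deduplicated — by genomic position
    by default — and the resulting PPM has its columns at the masked
    offsets (0..3, the poison-biased cleavage core) overwritten with the
    genome background composition.
    """
    if background is None:
        background = genome_composition(genome)
    pooled: list[GCSCall] = []
    for cond, calls in per_condition_calls.items():
        if not calls:
            raise ValueError(f"condition {cond!r} has no calls")
        top = sorted(calls, key=lambda c: c.n3e_strength, reverse=True)[:top_n]
        pooled.extend(top)
    if dedup == "position":
        seen, unique = set(), []
        for c in pooled:
            if c.position not in seen:
                seen.add(c.position)
                unique.append(c)
        sequences = extract_site_sequences(genome, unique, window)
    elif dedup == "sequence":
        sequences = list(dict.fromkeys(extract_site_sequences(genome, pooled, window)))
    else:
        raise ValueError(f"unknown dedup mode {dedup!r}")
    if not sequences:
        raise ValueError("empty pooled sequence set")
    ppm = build_ppm(sequences)
    return mask_ppm_columns(ppm, window.mask_columns(), background)


def genome_composition(genome: GenomeSequence) -> np.ndarray:
    """Baseline A/C/G/T frequencies of the genome (N excluded)."""
    idx = sequences_to_indices([genome.sequence])[0]
    counts = np.array([(idx == b).sum() for b in range(4)], dtype=float)
    return counts / counts.sum()


def ppm_to_pwm(ppm: PPM, background=None, pseudocount: float = 1e-4) -> PWM:
    """log2((ppm + pseudocount) / (background + pseudocount)) per cell."""
    background = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    if np.any(background <= 0):
        raise ValueError("background entries must be positive")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount == 0 and np.any(ppm.matrix == 0):
        raise ValueError(
            "PPM contains zero cells; use a pseudocount > 0 to avoid -inf weights"
        )
    matrix = np.log2((ppm.matrix + pseudocount) / (background[:, None] + pseudocount))
    return PWM(matrix=matrix, background=background, pseudocount=pseudocount)


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def _augmented_pwm(pwm: PWM) -> np.ndarray:
    """5 x W matrix whose 5th row scores ambiguous bases.

    An N contributes the background-weighted average of the column's
    cell values.
    """
    avg = (pwm.background[:, None] * pwm.matrix).sum(axis=0)
    return np.vstack([pwm.matrix, avg])


def _strand_scores(idx: np.ndarray, aug: np.ndarray) -> np.ndarray:
    w = aug.shape[1]
    n_pos = idx.size - w + 1
    scores = np.zeros(n_pos)
    for j in range(w):
        scores += aug[idx[j : j + n_pos], j]
    return scores


def scan_sequence(seq: str, pwm: PWM, circular: bool = False):
    """Score every window of ``seq`` on both strands.

    Returns (positions, forward, reverse, best), where at each start
    position ``forward`` is the PWM sum over the window, ``reverse`` is
    the score of the window's reverse complement, and the per-position
    score is their maximum; ``best`` is the maximum over positions.
    For circular sequences the scan wraps through the origin.
    """
    w = pwm.width
    if circular:
        if len(seq) < w:
            raise ValueError(f"sequence length {len(seq)} < motif width {w}")
        idx_full = sequences_to_indices([seq + seq[: w - 1]])[0]
        n_pos = len(seq)
    else:
        if len(seq) < w:
            raise ValueError(f"sequence length {len(seq)} < motif width {w}")
        idx_full = sequences_to_indices([seq])[0]
        n_pos = len(seq) - w + 1
    aug = _augmented_pwm(pwm)
    fwd = _strand_scores(idx_full[: n_pos + w - 1], aug)
    # reverse-complement of each window, aligned to the same start
    rc_idx = _COMPLEMENT_IDX[idx_full[: n_pos + w - 1]][::-1]
    rev = _strand_scores(rc_idx, aug)[::-1]
    per_position = np.maximum(fwd, rev)
    return np.arange(n_pos), fwd, rev, float(per_position.max())


def best_score(seq: str, pwm: PWM) -> float:
    return scan_sequence(seq, pwm)[3]


# ---------------------------------------------------------------------------
# GC periodicity
# ---------------------------------------------------------------------------

@dataclass
class PeriodFit:
    period: float
    amplitude: float
    phase: float
    offset_mean: float
    residual: float
    significant: bool
    null_amplitude_q95: float


def _fit_grid(y: np.ndarray, x: np.ndarray, periods: np.ndarray):
    """Least-squares a*cos + b*sin + c fit for every period on the grid.

    y may be (n,) or (n, m) for m tracks at once; returns amplitudes of
    shape (len(periods), m) and residual sums of squares likewise.
    """
    y2 = y if y.ndim == 2 else y[:, None]
    amps = np.empty((len(periods), y2.shape[1]))
    rss = np.empty_like(amps)
    for k, p in enumerate(periods):
        c = np.cos(2 * np.pi * x / p)
        s = np.sin(2 * np.pi * x / p)
        a = np.column_stack([c, s, np.ones_like(x)])
        coef, res, *_ = np.linalg.lstsq(a, y2, rcond=None)
        amps[k] = np.hypot(coef[0], coef[1])
        pred = a @ coef
        rss[k] = ((y2 - pred) ** 2).sum(axis=0)
    return amps, rss


def estimate_period(
    gc: np.ndarray,
    offsets: np.ndarray = None,
    window: MotifWindow = DEFAULT_WINDOW,
    period_grid=(8.0, 14.0, 0.01),
    n_shuffles: int = 1000,
    seed: int = 0,
) -> PeriodFit:
    """Dominant period of the flanking GC modulation by sinusoid grid fit.

    Fits a*cos(2*pi*x/P + phi) + c over the flanking offsets for every P
    on the grid and returns the residual-minimising P.  Significance of
    the amplitude is assessed against ``n_shuffles`` random permutations
    of the track values (max null amplitude over the same grid).
    """
    gc = np.asarray(gc, dtype=float)
    if offsets is None:
        cols = window.flank_columns()
        x = window.offsets[cols].astype(float)
        y = gc[cols]
    else:
        x = np.asarray(offsets, dtype=float)
        y = gc
    if len(x) < 20:
        raise ValueError("need at least 20 points for the period fit")
    lo, hi, step = period_grid
    periods = np.arange(lo, hi + step / 2, step)

    if np.ptp(y) == 0:
        return PeriodFit(
            period=float("nan"), amplitude=0.0, phase=0.0, offset_mean=float(y[0]),
            residual=0.0, significant=False, null_amplitude_q95=float("nan"),
        )

    amps, rss = _fit_grid(y, x, periods)
    k = int(rss[:, 0].argmin())
    best_p = float(periods[k])
    # recover phase at best period
    c = np.cos(2 * np.pi * x / best_p)
    s = np.sin(2 * np.pi * x / best_p)
    a = np.column_stack([c, s, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(a, y, rcond=None)
    amplitude = float(np.hypot(coef[0], coef[1]))
    phase = float(np.arctan2(-coef[1], coef[0]))

    rng = np.random.default_rng(seed)
    shuffled = np.stack([rng.permutation(y) for _ in range(n_shuffles)], axis=1)
    null_amps, _ = _fit_grid(shuffled, x, periods[::10])  # coarse grid for the null
    null_max = null_amps.max(axis=0)
    q95 = float(np.quantile(null_max, 0.95))
    return PeriodFit(
        period=best_p,
        amplitude=amplitude,
        phase=phase,
        offset_mean=float(coef[2]),
        residual=float(rss[k, 0]),
        significant=amplitude > q95,
        null_amplitude_q95=q95,
    )


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def write_matrix_tsv(matrix: np.ndarray, path, window: MotifWindow = DEFAULT_WINDOW):
    """Rows of offset, A, C, G, T for a 4 x W PPM or PWM matrix."""
    offsets = window.offsets if matrix.shape[1] == window.length else np.arange(
        matrix.shape[1]
    )
    with open(path, "w") as fh:
        fh.write("offset\tA\tC\tG\tT\n")
        for j, off in enumerate(offsets):
            cells = "\t".join(f"{matrix[b, j]:.6g}" for b in range(4))
            fh.write(f"{off}\t{cells}\n")


def read_ppm_tsv(path) -> PPM:
    rows = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if line.strip():
                rows.append([float(v) for v in line.split("\t")[1:5]])
    m = np.array(rows).T
    sums = m.sum(axis=0)
    if np.any(sums <= 0) or np.any(np.abs(sums - 1.0) > 1e-3):
        raise ValueError("TSV columns are not probability columns")
    return PPM(matrix=m / sums)  # renormalize away file-precision loss
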