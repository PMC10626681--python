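"""Sliding-window codon-usage measures: %MinMax, geometric mean, GC content.

%MinMax places a window's average codon usage between the least-used (−100)
and most-used (+100) synonymous alternatives.  With f the frequency per
thousand of each codon and, per position, f_max / f_min / f_avg the maximum /
minimum / arithmetic-mean frequency within that position's synonymous family:

    X_actual = mean_f over the window,   X_max/X_min/X_avg likewise;
    %MinMax  = +100 (X_actual − X_avg) / (X_max − X_avg)   if X_actual ≥ X_avg
             = −100 (X_avg − X_actual) / (X_avg − X_min)   otherwise,

with a degenerate denominator (windows made entirely of single-codon
families, or a degenerate table) mapping to 0.  The statistic is invariant
under uniform rescaling of the table.

The geometric-mean mode is the geometric mean over the window of each
codon's family fraction (floored at a small epsilon), giving a value in
(0, 1] on a scale-free footing comparable to %MinMax's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codon_tables import (
    ALL_CODONS,
    STANDARD_CODE,
    CodonUsageTable,
    GeneticCode,
    codon_measures,
    codons_of,
)

__all__ = [
    "WindowFrame",
    "MinMaxProfile",
    "codon_windows",
    "percent_minmax",
    "geometric_mean_window",
    "minmax_profile",
    "gc_content",
    "CutArrays",
]

GEOMEAN_EPS = 1e-6

_CODON_INDEX = {c: i for i, c in enumerate(ALL_CODONS)}


@dataclass(frozen=True)
class WindowFrame:
    """A [start, start+length) codon window, 0-based, half-open."""

    start: int
    length: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.length < 1:
            raise ValueError(f"invalid window frame ({self.start}, {self.length})")


@dataclass
class MinMaxProfile:
    """Per-window values of one gene under one usage table."""

    gene_id: str
    cut_label: str
    window: int
    mode: str  # "minmax" | "geomean"
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile contains non-finite values")


def codon_windows(gene_length_codons: int, window: int) -> list[WindowFrame]:
    """Step-1 sliding frames; genes shorter than the window get one whole-gene frame."""
    if gene_length_codons < 1 or window < 1:
        raise ValueError("gene length and window must be positive")
    if gene_length_codons < window:
        return [WindowFrame(0, gene_length_codons)]
    return [WindowFrame(i, window) for i in range(gene_length_codons - window + 1)]


class CutArrays:
    """Per-codon arrays of a CUT indexed by the canonical 64-codon order.

    Precomputed once per table so profile computations are vectorized:
    ``f`` per-thousand frequency; ``fmax/fmin/favg`` family extreme /
    mean frequencies; ``log_fraction`` log family fraction (epsilon-floored).
    """

    def __init__(self, cut: CodonUsageTable, code: GeneticCode = STANDARD_CODE):
        self.cut = cut
        self.code = code
        measures = codon_measures(cut, code)
        self.measures = measures
        self.f = np.array([cut.frequency_per_thousand[c] for c in ALL_CODONS])
        fmax = np.empty(64)
        fmin = np.empty(64)
        favg = np.empty(64)
        for family in code.families.values():
            fam_f = [cut.frequency_per_thousand[c] for c in family]
            idx = [_CODON_INDEX[c] for c in family]
            fmax[idx] = max(fam_f)
            fmin[idx] = min(fam_f)
            favg[idx] = sum(fam_f) / len(fam_f)
        self.fmax, self.fmin, self.favg = fmax, fmin, favg
        frac = np.array([measures.family_fraction[c] for c in ALL_CODONS])
        self.fraction = frac
        self.log_fraction = np.log(np.maximum(frac, GEOMEAN_EPS))

    def encode(self, codons: list[str]) -> np.ndarray:
        try:
            return np.array([_CODON_INDEX[c] for c in codons], dtype=np.int64)
        except KeyError as exc:
            raise ValueError(f"unknown codon {exc.args[0]!r}") from exc


def _window_sums(x: np.ndarray, window: int) -> np.ndarray:
    """Sums of x over step-1 windows; one whole-array sum if len(x) < window."""
    n = len(x)
    if n < window:
        return np.array([x.sum()])
    c = np.concatenate([[0.0], np.cumsum(x)])
    return c[window:] - c[:-window]


def _minmax_from_sums(sa: np.ndarray, sx: np.ndarray, sn: np.ndarray,
                      sm: np.ndarray) -> np.ndarray:
    """Vectorized %MinMax from window sums of actual/max/min/mean frequencies."""
    up = sa >= sm
    num = np.where(up, sa - sm, sm - sa)
    den = np.where(up, sx - sm, sm - sn)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = 100.0 * num / den
    vals = np.where(den <= 0, 0.0, vals)
    # guard against float overshoot just past the closed-form extremes
    return np.clip(np.where(up, vals, -vals), -100.0, 100.0)


def percent_minmax(window_codons: list[str], cut: CodonUsageTable,
                   code: GeneticCode = STANDARD_CODE) -> float:
    """%MinMax of a single codon window; in [−100, 100]."""
    arrays = cut if isinstance(cut, CutArrays) else CutArrays(cut, code)
    idx = arrays.encode(window_codons)
    n = float(len(idx))
    return float(
        _minmax_from_sums(
            np.array([arrays.f[idx].sum()]) / n,
            np.array([arrays.fmax[idx].sum()]) / n,
            np.array([arrays.fmin[idx].sum()]) / n,
            np.array([arrays.favg[idx].sum()]) / n,
        )[0]
    )


def geometric_mean_window(window_codons: list[str], cut: CodonUsageTable,
                          code: GeneticCode = STANDARD_CODE) -> float:
    """Geometric mean of family fractions over a window; in (0, 1]."""
    arrays = cut if isinstance(cut, CutArrays) else CutArrays(cut, code)
    idx = arrays.encode(window_codons)
    return float(np.exp(arrays.log_fraction[idx].mean()))


def minmax_profile(gene, cut: CodonUsageTable, window: int = 18,
                   mode: str = "minmax", gene_id: str = "gene",
                   code: GeneticCode = STANDARD_CODE) -> MinMaxProfile:
    """Windowed profile of a gene under one CUT.

    ``gene`` may be an in-frame DNA string or a list of codons.  ``mode`` is
    ``"minmax"`` (%MinMax) or ``"geomean"`` (geometric-mean family fraction).
    """
    codons = codons_of(gene) if isinstance(gene, str) else list(gene)
    if window < 1:
        raise ValueError("window must be >= 1")
    if not codons:
        raise ValueError("empty gene")
    arrays = cut if isinstance(cut, CutArrays) else CutArrays(cut, code)
    idx = arrays.encode(codons)
    win_len = min(window, len(codons))
    if mode == "minmax":
        sa = _window_sums(arrays.f[idx], window) / win_len
        sx = _window_sums(arrays.fmax[idx], window) / win_len
        sn = _window_sums(arrays.fmin[idx], window) / win_len
        sm = _window_sums(arrays.favg[idx], window) / win_len
        values = _minmax_from_sums(sa, sx, sn, sm)
    elif mode == "geomean":
        values = np.exp(_window_sums(arrays.log_fraction[idx], window) / win_len)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    label = arrays.cut.organism if isinstance(cut, CutArrays) else cut.organism
    return MinMaxProfile(gene_id=gene_id, cut_label=label, window=window,
                         mode=mode, values=values)


def gc_content(sequence: str, window: int | None = 18):
    """Per-window and mean G+C fraction over sliding codon windows.

    Windows are ``window`` codons wide (``3 * window`` nucleotides), step one
    codon; ``window=None`` means one whole-gene window.  Returns
    ``(per_window, mean)``.
    """
    seq = sequence.upper()
    if any(b not in "ACGT" for b in seq):
        bad = sorted({b for b in seq if b not in "ACGT"})
        raise ValueError(f"sequence contains non-ACGT symbols: {bad}")
    if len(seq) % 3 != 0:
        raise ValueError("sequence must be in frame (length divisible by 3)")
    n_codons = len(seq) // 3
    if window is None:
        window = n_codons
    if window < 1:
        raise ValueError("window must be >= 1")
    gc = np.frombuffer(seq.encode(), dtype=np.uint8)
    gc = ((gc == ord("G")) | (gc == ord("C"))).astype(float)
    win_nt = 3 * min(window, n_codons)
    if n_codons <= window:
        per_window = np.array([gc.mean()])
    else:
        c = np.concatenate([[0.0], np.cumsum(gc)])
        starts = np.arange(0, (n_codons - window + 1) * 3, 3)
        per_window = (c[starts + win_nt] - c[starts]) / win_nt
    return per_window, float(per_window.mean())
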