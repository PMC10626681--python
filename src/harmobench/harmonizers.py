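"""Codon harmonization algorithms.

Harmonization recodes a gene with synonymous codons so that its codon-usage
pattern in a new host mimics the pattern the original gene had in its native
host (in contrast to codon *optimization*, which maximizes usage frequency).
Two algorithm families are implemented:

* **Pointwise measure matching** — each codon is independently replaced by
  the target-host synonymous codon whose usage measure is closest to the
  original codon's measure in the source host.  The measure selects the
  emulated strategy: ``rscu`` (EuGene-style), ``adaptiveness`` (Galaxy-style
  relative adaptiveness), ``family_fraction`` (CodonWizard-style relative
  usage frequency, with an optional tolerance that widens the candidate
  pool and samples stochastically).

* **Sliding-window descent** (CHARMING-style) — starting from a rank-matched
  recoding (Rodriguez initialization), single-codon substitutions are applied
  by steepest descent on the net deviation between the candidate's windowed
  profile under the target table and the original gene's profile under the
  source table, until a local optimum is reached.  Window modes: %MinMax or
  geometric mean; default window 17 codons.

All algorithms preserve the translation exactly; the terminal stop codon is
left untouched unless ``include_terminal_stop`` is set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .codon_tables import (
    ALL_CODONS,
    STANDARD_CODE,
    CodonUsageTable,
    GeneticCode,
    codon_measures,
    codons_of,
)
from .usage_metrics import CutArrays, minmax_profile, _window_sums

__all__ = [
    "HarmonizationTask",
    "HarmonizationResult",
    "rodriguez_initialize",
    "harmonize_pointwise",
    "harmonize_charming",
    "harmonize",
    "run_tool",
    "TOOL_CONFIGS",
]

_POINTWISE_MEASURES = ("family_fraction", "rscu", "adaptiveness")
_DESCENT_TOL = 1e-7


@dataclass
class HarmonizationTask:
    """One harmonization job: gene, source/target tables, algorithm settings."""

    gene: str
    source_cut: CodonUsageTable
    target_cut: CodonUsageTable
    algorithm: str = "pointwise"  # "pointwise" | "charming"
    measure: str = "family_fraction"  # pointwise only
    tolerance: float = 0.0  # pointwise only, in [0, 1]
    mode: str = "minmax"  # charming only: "minmax" | "geomean"
    window: int = 17  # charming only
    seed: int = 0
    n_solutions: int = 1  # charming only
    include_terminal_stop: bool = False

    def __post_init__(self) -> None:
        if self.algorithm not in ("pointwise", "charming"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.algorithm == "pointwise" and self.measure not in _POINTWISE_MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        if not 0.0 <= self.tolerance <= 1.0:
            raise ValueError(f"tolerance must lie in [0, 1]; got {self.tolerance}")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.n_solutions < 1:
            raise ValueError("n_solutions must be >= 1")


@dataclass
class HarmonizationResult:
    """A synonymous recoding plus provenance."""

    codons: list[str]
    task: HarmonizationTask
    substitutions: int
    objective_trace: list[float] = field(default_factory=list)
    solutions: list[tuple[tuple[str, ...], float]] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return "".join(self.codons)


def _prepare(task: HarmonizationTask, code: GeneticCode):
    """Split the gene, reject internal stops, mark recodable positions."""
    codons = codons_of(task.gene)
    aas = [code.amino_acid(c) for c in codons]
    for i, aa in enumerate(aas[:-1]):
        if aa == "*":
            raise ValueError(f"internal stop codon {codons[i]} at codon {i}")
    recode = np.ones(len(codons), dtype=bool)
    if aas and aas[-1] == "*" and not task.include_terminal_stop:
        recode[-1] = False
    return codons, recode


# ---------------------------------------------------------------------------
# Rodriguez initialization (rank matching)
# ---------------------------------------------------------------------------

def rodriguez_initialize(gene, source_cut: CodonUsageTable, target_cut: CodonUsageTable,
                         code: GeneticCode = STANDARD_CODE) -> list[str]:
    """Replace each codon by the target-host codon of equal usage rank.

    Ranks are the deterministic within-family order (descending frequency,
    lexicographic tie-break); single-codon families pass through unchanged.
    """
    codons = codons_of(gene) if isinstance(gene, str) else list(gene)
    m_src = codon_measures(source_cut, code)
    m_tgt = codon_measures(target_cut, code)
    # target family ordered by ordinal
    order_tgt = {
        aa: sorted(family, key=lambda c: m_tgt.ordinal[c])
        for aa, family in code.families.items()
    }
    out = []
    for c in codons:
        family_order = order_tgt[code.amino_acid(c)]
        out.append(family_order[m_src.ordinal[c]])
    return out


# ---------------------------------------------------------------------------
# pointwise measure-matching recoders
# ---------------------------------------------------------------------------

def harmonize_pointwise(task: HarmonizationTask,
                        code: GeneticCode = STANDARD_CODE) -> HarmonizationResult:
    """Per-position measure matching (EuGene / Galaxy / CodonWizard style).

    At tolerance 0 each position independently takes the synonymous codon
    minimizing the absolute measure difference, keeping the original on a
    tie (else lexicographic first).  At tolerance t > 0, candidates within
    ``d_min + t (d_max − d_min)`` form a pool sampled with probability
    proportional to 1/(ε + |Δmeasure|); positions are visited in seeded
    random order.
    """
    codons, recode = _prepare(task, code)
    m_src = codon_measures(task.source_cut, code).measure(task.measure)
    m_tgt = codon_measures(task.target_cut, code).measure(task.measure)
    rng = np.random.default_rng(task.seed)
    out = list(codons)
    order = np.arange(len(codons))
    if task.tolerance > 0:
        order = rng.permutation(order)
    n_sub = 0
    for p in order:
        if not recode[p]:
            continue
        orig = codons[p]
        family = code.family_of(orig)  # lexicographically sorted
        dists = np.array([abs(m_tgt[c] - m_src[orig]) for c in family])
        if task.tolerance == 0.0:
            best = dists.min()
            if abs(m_tgt[orig] - m_src[orig]) <= best + 1e-15:
                choice = orig
            else:
                choice = family[int(np.argmin(dists))]
        else:
            cutoff = dists.min() + task.tolerance * (dists.max() - dists.min())
            pool = [i for i, d in enumerate(dists) if d <= cutoff + 1e-12]
            weights = np.array([1.0 / (1e-9 + dists[i]) for i in pool])
            choice = family[pool[rng.choice(len(pool), p=weights / weights.sum())]]
        if choice != orig:
            n_sub += 1
        out[p] = choice
    return HarmonizationResult(codons=out, task=task, substitutions=n_sub)


# ---------------------------------------------------------------------------
# sliding-window descent (CHARMING style)
# ---------------------------------------------------------------------------

class _DescentState:
    """Vectorized objective machinery for the sliding-window descent.

    The objective is Σ_windows |profile(candidate, target CUT) −
    profile(original, source CUT)|.  Because synonymous substitution never
    changes a position's family, the per-window family statistics (max, min,
    mean frequency) are constants; only the sum of actual per-position
    values changes, so a single-codon move touches at most ``window``
    windows and its objective change is evaluated locally.
    """

    def __init__(self, codons, recode, target_arrays: CutArrays, target_profile,
                 window: int, mode: str, code: GeneticCode):
        self.code = code
        self.mode = mode
        L = len(codons)
        self.L = L
        self.window = window
        self.win_len = min(window, L)
        self.nW = max(L - window + 1, 1)
        self.t = np.asarray(target_profile, dtype=float)
        if len(self.t) != self.nW:
            raise ValueError("target profile length mismatch")
        self.arrays = target_arrays

        idx0 = target_arrays.encode(codons)
        if mode == "minmax":
            self.x_all = target_arrays.f
            self.sx = _window_sums(target_arrays.fmax[idx0], window)
            self.sn = _window_sums(target_arrays.fmin[idx0], window)
            self.sm = _window_sums(target_arrays.favg[idx0], window)
        elif mode == "geomean":
            self.x_all = target_arrays.log_fraction
        else:
            raise ValueError(f"unknown mode {mode!r}")

        # candidate matrix: synonymous codons per position (lexicographic)
        fams = [code.family_of(c) if recode[p] else (codons[p],)
                for p, c in enumerate(codons)]
        K = max(len(f) for f in fams)
        self.K = K
        self.cand_idx = np.full((L, K), -1, dtype=np.int64)
        self.cand_valid = np.zeros((L, K), dtype=bool)
        for p, fam in enumerate(fams):
            for k, c in enumerate(fam):
                self.cand_idx[p, k] = target_arrays.encode([c])[0]
                self.cand_valid[p, k] = True
        safe = np.where(self.cand_idx >= 0, self.cand_idx, 0)
        self.cand_x = self.x_all[safe]

        # window-affection geometry
        p_arr = np.arange(L)
        self.lo = np.minimum(np.maximum(p_arr - window + 1, 0), self.nW - 1)
        self.hi = np.minimum(p_arr, self.nW - 1)
        span = int((self.hi - self.lo).max()) + 1
        self.span = span
        self.J = self.lo[:, None] + np.arange(span)[None, :]
        self.Jmask = self.J <= self.hi[:, None]
        self.Jc = np.clip(self.J, 0, self.nW - 1)

        self.cur = np.array(idx0)
        self.x = self.x_all[self.cur]
        self.S = _window_sums(self.x, window)
        self.V = self._values(self.S, np.arange(self.nW))
        self.D = np.empty((L, K))
        self._recompute_rows(np.arange(L))

    # window value from window sums, for window indices j
    def _values(self, S, j):
        if self.mode == "geomean":
            return np.exp(S / self.win_len)
        sa = S / self.win_len
        sx = self.sx[j] / self.win_len
        sn = self.sn[j] / self.win_len
        sm = self.sm[j] / self.win_len
        up = sa >= sm
        num = np.where(up, sa - sm, sm - sa)
        den = np.where(up, sx - sm, sm - sn)
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = 100.0 * num / den
        vals = np.where(den <= 0, 0.0, vals)
        return np.clip(np.where(up, vals, -vals), -100.0, 100.0)

    @property
    def objective(self) -> float:
        return float(np.abs(self.V - self.t).sum())

    def _recompute_rows(self, P: np.ndarray) -> None:
        """Exact objective change of every candidate substitution at rows P."""
        Jc = self.Jc[P]  # (m, R)
        mask = self.Jmask[P]
        S0 = self.S[Jc]
        v0 = self.V[Jc]
        t0 = self.t[Jc]
        base = np.abs(v0 - t0) * mask  # (m, R)
        dx = self.cand_x[P] - self.x[P][:, None]  # (m, K)
        Snew = S0[:, None, :] + dx[:, :, None]  # (m, K, R)
        if self.mode == "geomean":
            vnew = np.exp(Snew / self.win_len)
        else:
            sa = Snew / self.win_len
            sx = (self.sx[Jc] / self.win_len)[:, None, :]
            sn = (self.sn[Jc] / self.win_len)[:, None, :]
            sm = (self.sm[Jc] / self.win_len)[:, None, :]
            up = sa >= sm
            num = np.where(up, sa - sm, sm - sa)
            den = np.where(up, sx - sm, sm - sn)
            with np.errstate(divide="ignore", invalid="ignore"):
                vals = 100.0 * num / den
            vals = np.where(den <= 0, 0.0, vals)
            vnew = np.clip(np.where(up, vals, -vals), -100.0, 100.0)
        delta = ((np.abs(vnew - t0[:, None, :]) - base[:, None, :]) * mask[:, None, :]).sum(axis=2)
        delta[~self.cand_valid[P]] = np.inf
        # a candidate equal to the current codon is a no-op, never a move
        same = self.cand_idx[P] == self.cur[P][:, None]
        delta[same] = np.inf
        self.D[P] = delta

    def step(self) -> float | None:
        """Apply the steepest single-codon substitution; None at a local optimum."""
        flat = int(np.argmin(self.D))
        p, k = divmod(flat, self.K)
        best = self.D[p, k]
        if not best < -_DESCENT_TOL:
            return None
        new_idx = self.cand_idx[p, k]
        dx = self.cand_x[p, k] - self.x[p]
        self.cur[p] = new_idx
        self.x[p] = self.cand_x[p, k]
        lo, hi = self.lo[p], self.hi[p]
        self.S[lo:hi + 1] += dx
        self.V[lo:hi + 1] = self._values(self.S[lo:hi + 1], np.arange(lo, hi + 1))
        qlo = max(0, int(lo))
        qhi = min(self.L - 1, int(hi) + self.window - 1)
        self._recompute_rows(np.arange(qlo, qhi + 1))
        return float(best)

    def codon_list(self) -> list[str]:
        return [ALL_CODONS[i] for i in self.cur]


def _descend(codons, recode, target_arrays, target_profile, window, mode, code,
             max_iter: int | None = None):
    state = _DescentState(codons, recode, target_arrays, target_profile,
                          window, mode, code)
    trace = [state.objective]
    limit = max_iter if max_iter is not None else 60 * state.L + 1000
    for _ in range(limit):
        if state.step() is None:
            break
        trace.append(state.objective)
    return state.codon_list(), trace


def _random_synonymous(codons, recode, rng, code: GeneticCode) -> list[str]:
    out = list(codons)
    for p, c in enumerate(codons):
        if recode[p]:
            fam = code.family_of(c)
            out[p] = fam[rng.integers(len(fam))]
    return out


def harmonize_charming(task: HarmonizationTask,
                       code: GeneticCode = STANDARD_CODE) -> HarmonizationResult:
    """Sliding-window net-deviation descent toward the wild-type profile.

    The target is the original gene's windowed profile under the source
    table; the candidate is scored under the target table.  Descent starts
    from the Rodriguez initialization and applies, per iteration, the single
    synonymous substitution with the largest net-deviation decrease, stopping
    at a local optimum.  With ``n_solutions > 1``, additional descents start
    from seeded random synonymous sequences and distinct local optima are
    collected; the best (lowest net deviation) is returned.
    """
    codons, recode = _prepare(task, code)
    target_profile = minmax_profile(codons, task.source_cut, task.window,
                                    task.mode, code=code).values
    target_arrays = CutArrays(task.target_cut, code)

    init = rodriguez_initialize(codons, task.source_cut, task.target_cut, code)
    for p in np.nonzero(~recode)[0]:
        init[p] = codons[p]
    best_codons, best_trace = _descend(init, recode, target_arrays,
                                       target_profile, task.window, task.mode, code)
    solutions = {tuple(best_codons): best_trace[-1]}

    if task.n_solutions > 1:
        rng = np.random.default_rng(task.seed)
        for _ in range(task.n_solutions - 1):
            start = _random_synonymous(codons, recode, rng, code)
            sol, trace = _descend(start, recode, target_arrays, target_profile,
                                  task.window, task.mode, code)
            key = tuple(sol)
            if key not in solutions:
                solutions[key] = trace[-1]
            if trace[-1] < best_trace[-1] - _DESCENT_TOL:
                best_codons, best_trace = sol, trace

    n_sub = sum(1 for a, b in zip(codons, best_codons) if a != b)
    ordered = sorted(solutions.items(), key=lambda kv: (kv[1], kv[0]))
    return HarmonizationResult(
        codons=best_codons, task=task, substitutions=n_sub,
        objective_trace=best_trace, solutions=ordered,
    )


def harmonize(task: HarmonizationTask,
              code: GeneticCode = STANDARD_CODE) -> HarmonizationResult:
    """Dispatch a task to its algorithm."""
    if task.algorithm == "pointwise":
        return harmonize_pointwise(task, code)
    return harmonize_charming(task, code)


# ---------------------------------------------------------------------------
# named tool configurations
# ---------------------------------------------------------------------------

#: Emulated tool name → task template (algorithm + measure/mode settings).
TOOL_CONFIGS: dict[str, dict] = {
    "eugene": {"algorithm": "pointwise", "measure": "rscu"},
    "galaxy": {"algorithm": "pointwise", "measure": "adaptiveness"},
    "codonwizard": {"algorithm": "pointwise", "measure": "family_fraction"},
    "charming-mm": {"algorithm": "charming", "mode": "minmax"},
    "charming-geo": {"algorithm": "charming", "mode": "geomean"},
}


def run_tool(tool: str, gene: str, source_cut: CodonUsageTable,
             target_cut: CodonUsageTable, *, seed: int = 0, tolerance: float = 0.0,
             window: int = 17, n_solutions: int = 1,
             include_terminal_stop: bool = False,
             code: GeneticCode = STANDARD_CODE) -> HarmonizationResult:
    """Harmonize a gene with one of the named tool emulations."""
    if tool not in TOOL_CONFIGS:
        raise ValueError(f"unknown tool {tool!r}; known: {sorted(TOOL_CONFIGS)}")
    cfg = TOOL_CONFIGS[tool]
    task = HarmonizationTask(
        gene=gene, source_cut=source_cut, target_cut=target_cut,
        seed=seed, tolerance=tolerance if cfg["algorithm"] == "pointwise" else 0.0,
        window=window, n_solutions=n_solutions,
        include_terminal_stop=include_terminal_stop, **cfg,
    )
    return harmonize(task, code)
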