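"""mRNA secondary-structure covariate: base pairing and %mRNA.

%mRNA is the fraction of a sliding window's nucleotides involved in
secondary structure, operationalized here as "base-paired" in a nested
pairing.  The default predictor is Nussinov-style base-pair maximization
(Watson–Crick plus GU wobble, minimum hairpin loop of 3 nt) with a
deterministic traceback; externally computed structures (e.g. RNAfold
output) can be supplied as dot-bracket strings and flow through the same
%mRNA computation.  Folding is always performed on the original gene, never
on a harmonized variant: the covariate describes the input, not the design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .usage_metrics import codon_windows

__all__ = [
    "PairingMask",
    "fold_max_pairing",
    "parse_dotbracket",
    "to_dotbracket",
    "percent_mrna",
]

MIN_LOOP_DEFAULT = 3

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
# allowed pairs: AU/AT, GC, GU/GT
_CAN_PAIR = np.zeros((4, 4), dtype=np.bool_)
for _a, _b in ((0, 3), (1, 2), (2, 3)):
    _CAN_PAIR[_a, _b] = _CAN_PAIR[_b, _a] = True


@dataclass
class PairingMask:
    """Per-nucleotide pairing state of one sequence.

    ``partner[i]`` is the 0-based partner index, or −1 when unpaired;
    ``provenance`` records whether the mask came from the internal fold or
    an external dot-bracket string.
    """

    partner: np.ndarray
    provenance: str = "internal_fold"
    min_loop: int = MIN_LOOP_DEFAULT

    def __post_init__(self) -> None:
        self.partner = np.asarray(self.partner, dtype=np.int64)
        p = self.partner
        paired = np.nonzero(p >= 0)[0]
        if np.any(p[paired] >= len(p)) or np.any(p[p[paired]] != paired):
            raise ValueError("pairing is not an involution")
        if np.any(np.abs(p[paired] - paired) <= self.min_loop):
            raise ValueError(f"a pair violates the minimum loop length {self.min_loop}")

    @property
    def paired(self) -> np.ndarray:
        return self.partner >= 0

    @property
    def n_pairs(self) -> int:
        return int((self.partner >= 0).sum()) // 2

    def __len__(self) -> int:
        return len(self.partner)


@njit(cache=True)
def _nussinov_fill(enc: np.ndarray, can_pair: np.ndarray, min_loop: int) -> np.ndarray:
    n = enc.shape[0]
    dp = np.zeros((n, n), dtype=np.int32)
    for d in range(min_loop + 1, n):
        for i in range(n - d):
            j = i + d
            best = dp[i, j - 1]  # j unpaired
            for k in range(i, j - min_loop):
                if can_pair[enc[k], enc[j]]:
                    left = dp[i, k - 1] if k > i else 0
                    cand = left + dp[k + 1, j - 1] + 1
                    if cand > best:
                        best = cand
            dp[i, j] = best
    return dp


def _encode(sequence: str) -> np.ndarray:
    seq = sequence.upper()
    try:
        return np.array([_ENC[b] for b in seq], dtype=np.int64)
    except KeyError:
        bad = sorted({b for b in seq if b not in _ENC})
        raise ValueError(f"sequence contains invalid symbols: {bad}") from None


def fold_max_pairing(sequence: str, min_loop: int = MIN_LOOP_DEFAULT) -> PairingMask:
    """Maximum-cardinality nested pairing via the classic dynamic program.

    Traceback is deterministic: the rightmost base of an interval pairs
    whenever pairing attains the optimum, taking the smallest-index partner.
    """
    if min_loop < 0:
        raise ValueError("min_loop must be >= 0")
    enc = _encode(sequence)
    n = len(enc)
    partner = np.full(n, -1, dtype=np.int64)
    if n > min_loop + 1:
        dp = _nussinov_fill(enc, _CAN_PAIR, min_loop)
        stack = [(0, n - 1)]
        while stack:
            i, j = stack.pop()
            if j - i <= min_loop:
                continue
            paired_here = False
            for k in range(i, j - min_loop):
                if _CAN_PAIR[enc[k], enc[j]]:
                    left = dp[i, k - 1] if k > i else 0
                    if left + dp[k + 1, j - 1] + 1 == dp[i, j]:
                        partner[k], partner[j] = j, k
                        if k > i:
                            stack.append((i, k - 1))
                        stack.append((k + 1, j - 1))
                        paired_here = True
                        break
            if not paired_here:
                stack.append((i, j - 1))
    return PairingMask(partner=partner, provenance="internal_fold", min_loop=min_loop)


def parse_dotbracket(structure: str, min_loop: int = 0) -> PairingMask:
    """Build a pairing mask from a dot-bracket string (``()`` and ``.`` only)."""
    bad = sorted(set(structure) - set("()."))
    if bad:
        raise ValueError(
            f"unsupported characters {bad} in dot-bracket string "
            "(pseudoknot brackets are not accepted)"
        )
    partner = np.full(len(structure), -1, dtype=np.int64)
    stack: list[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            k = stack.pop()
            partner[k], partner[i] = i, k
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return PairingMask(partner=partner, provenance="external_dotbracket",
                       min_loop=min_loop)


def to_dotbracket(mask: PairingMask) -> str:
    out = []
    for i, p in enumerate(mask.partner):
        out.append("." if p < 0 else ("(" if p > i else ")"))
    return "".join(out)


def percent_mrna(gene: str, mask: PairingMask, window: int = 18):
    """Per-window and mean fraction of base-paired nucleotides.

    Windows are ``window`` codons (3×window nt) at one-codon steps, as for
    the other covariates.  Returns ``(per_window, mean)``.
    """
    if len(mask) != len(gene):
        raise ValueError(
            f"mask length {len(mask)} does not match gene length {len(gene)}"
        )
    if len(gene) % 3 != 0:
        raise ValueError("gene must be in frame (length divisible by 3)")
    paired = mask.paired.astype(float)
    n_codons = len(gene) // 3
    frames = codon_windows(n_codons, window)
    per_window = np.array([
        paired[3 * fr.start: 3 * (fr.start + fr.length)].mean() for fr in frames
    ])
    return per_window, float(per_window.mean())
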