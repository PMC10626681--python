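"""Codon usage tables and per-codon usage measures.

A codon usage table (CUT) records, for one organism, how often each of the
64 codons occurs — as raw counts and/or as frequency per 1000 codons (the
Kazusa convention, which is the canonical internal scale here).  From a CUT
we derive the three family-relative measures every harmonization algorithm
consumes:

* ``family_fraction`` — a codon's share of its synonymous family, in [0, 1];
* ``rscu``            — relative synonymous codon usage, frequency divided by
  the family mean;
* ``adaptiveness_w``  — relative adaptiveness, frequency divided by the
  family maximum (the per-codon ingredient of CAI).

Two text dialects are supported: the Kazusa style (``UUU 17.6 (714298)``
records, whitespace separated, U or T accepted) and a CSV dialect with
header ``codon,amino_acid,fraction,frequency_per_thousand,count``.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field

from Bio.Data import CodonTable as _BioCodonTable
from Bio.Seq import Seq

__all__ = [
    "GeneticCode",
    "STANDARD_CODE",
    "CodonUsageTable",
    "CodonMeasures",
    "CutParseError",
    "parse_cut",
    "serialize_cut",
    "cut_from_cds",
    "codon_measures",
    "codons_of",
    "translate",
]

_BASES = "ACGT"
ALL_CODONS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)


class CutParseError(ValueError):
    """Raised when a codon usage table cannot be parsed."""


@dataclass(frozen=True)
class GeneticCode:
    """A codon → amino-acid mapping plus its synonymous families.

    ``mapping`` must cover all 64 DNA codons; stops map to ``'*'``.
    """

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        if set(self.mapping) != set(ALL_CODONS):
            missing = set(ALL_CODONS) - set(self.mapping)
            extra = set(self.mapping) - set(ALL_CODONS)
            raise ValueError(
                f"genetic code must cover exactly the 64 codons "
                f"(missing={sorted(missing)}, extra={sorted(extra)})"
            )

    @property
    def families(self) -> dict[str, tuple[str, ...]]:
        """Amino acid symbol → lexicographically sorted synonymous codons."""
        fams: dict[str, list[str]] = {}
        for codon in ALL_CODONS:
            fams.setdefault(self.mapping[codon], []).append(codon)
        return {aa: tuple(sorted(cods)) for aa, cods in fams.items()}

    def family_of(self, codon: str) -> tuple[str, ...]:
        return self.families[self.mapping[codon]]

    def amino_acid(self, codon: str) -> str:
        return self.mapping[codon]


def _standard_code() -> GeneticCode:
    table = _BioCodonTable.unambiguous_dna_by_id[1]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return GeneticCode(mapping=mapping)


STANDARD_CODE = _standard_code()


@dataclass
class CodonUsageTable:
    """Per-codon usage statistics for one organism.

    ``frequency_per_thousand`` is the canonical scale; ``counts`` may be
    absent (``None``) when the source dialect carried no counts.
    """

    organism: str
    frequency_per_thousand: dict[str, float]
    counts: dict[str, int] | None = None
    dialect: str = "memory"
    parse_report: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if set(self.frequency_per_thousand) != set(ALL_CODONS):
            missing = set(ALL_CODONS) - set(self.frequency_per_thousand)
            raise ValueError(f"table must contain all 64 codons; missing {sorted(missing)}")
        for codon, f in self.frequency_per_thousand.items():
            if f < 0:
                raise ValueError(f"negative frequency for {codon}: {f}")
        total = sum(self.frequency_per_thousand.values())
        if total > 0 and abs(total - 1000.0) > 0.5:
            raise ValueError(
                f"frequencies must sum to 1000 ± 0.5 (dialect rounding); got {total:.3f}"
            )
        if self.counts is not None:
            if set(self.counts) != set(ALL_CODONS):
                raise ValueError("counts, when present, must cover all 64 codons")
            n_total = sum(self.counts.values())
            if n_total > 0:
                for codon in ALL_CODONS:
                    implied = 1000.0 * self.counts[codon] / n_total
                    # one unit in the last printed decimal, plus float slack
                    if abs(implied - self.frequency_per_thousand[codon]) > 0.05 + 1e-9:
                        raise ValueError(
                            f"count/frequency mismatch for {codon}: "
                            f"count implies {implied:.4f}, table says "
                            f"{self.frequency_per_thousand[codon]}"
                        )

    def frequency(self, codon: str) -> float:
        return self.frequency_per_thousand[codon]


@dataclass
class CodonMeasures:
    """Family-relative usage measures derived from one CUT.

    ``rank`` is a competition rank within the family (1 = most used, ties
    share the lower rank); ``ordinal`` is the tie-broken position in the
    family's (descending frequency, lexicographic) order, 0-based — the
    deterministic rank used for rank-matching recoders.
    """

    cut_label: str
    family_fraction: dict[str, float]
    rscu: dict[str, float]
    adaptiveness_w: dict[str, float]
    rank: dict[str, int]
    ordinal: dict[str, int]
    zero_families: tuple[str, ...] = ()

    def measure(self, name: str) -> dict[str, float]:
        if name == "family_fraction":
            return self.family_fraction
        if name == "rscu":
            return self.rscu
        if name in ("adaptiveness", "adaptiveness_w"):
            return self.adaptiveness_w
        raise KeyError(f"unknown measure {name!r}")


# ---------------------------------------------------------------------------
# parsing / serialization
# ---------------------------------------------------------------------------

_KAZUSA_TRIPLE = re.compile(r"^([A-Za-z]{1,})$")

_CSV_HEADER = "codon,amino_acid,fraction,frequency_per_thousand,count"


def _normalize_codon(token: str, where: str) -> str:
    codon = token.upper().replace("U", "T")
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise CutParseError(f"non-triplet or invalid codon token {token!r} at {where}")
    return codon


def parse_cut(text: str, dialect: str = "kazusa", organism: str = "unknown") -> CodonUsageTable:
    """Parse a codon usage table from text in the named dialect.

    Kazusa dialect: whitespace-separated records ``CODON freq (count)``;
    codons may use U or T.  CSV dialect: header
    ``codon,amino_acid,fraction,frequency_per_thousand,count``; missing
    codons are filled with zero usage and flagged in the parse report.
    """
    if dialect == "kazusa":
        return _parse_kazusa(text, organism)
    if dialect == "csv":
        return _parse_csv(text, organism)
    raise CutParseError(f"unknown dialect {dialect!r}")


def _parse_kazusa(text: str, organism: str) -> CodonUsageTable:
    freqs: dict[str, float] = {}
    counts: dict[str, int] = {}
    # tolerate "(count)" glued to the frequency and arbitrary whitespace
    tokens = re.findall(r"[A-Za-z]{3}|\(\s*\d+\s*\)|[-+]?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?", text)
    i = 0
    n_rec = 0
    while i < len(tokens):
        tok = tokens[i]
        if not re.fullmatch(r"[A-Za-z]{3}", tok):
            raise CutParseError(f"expected a codon, found {tok!r} (record {n_rec + 1})")
        codon = _normalize_codon(tok, f"record {n_rec + 1}")
        if i + 1 >= len(tokens):
            raise CutParseError(f"truncated record for codon {codon}")
        try:
            freq = float(tokens[i + 1])
        except ValueError as exc:
            raise CutParseError(f"bad frequency for codon {codon}: {tokens[i + 1]!r}") from exc
        if freq < 0:
            raise CutParseError(f"negative frequency for codon {codon}: {freq}")
        i += 2
        count = None
        if i < len(tokens) and tokens[i].startswith("("):
            count = int(tokens[i].strip("() \t"))
            i += 1
        if codon in freqs:
            raise CutParseError(f"duplicate codon {codon}")
        freqs[codon] = freq
        counts[codon] = count if count is not None else 0
        n_rec += 1
    if set(freqs) != set(ALL_CODONS):
        missing = sorted(set(ALL_CODONS) - set(freqs))
        raise CutParseError(f"kazusa table incomplete; missing {missing}")
    has_counts = any(c > 0 for c in counts.values())
    return CodonUsageTable(
        organism=organism,
        frequency_per_thousand=freqs,
        counts=counts if has_counts else None,
        dialect="kazusa",
    )


def _parse_csv(text: str, organism: str) -> CodonUsageTable:
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise CutParseError("empty CSV table")
    header = lines[0].strip()
    if header != _CSV_HEADER:
        raise CutParseError(f"CSV header must be {_CSV_HEADER!r}; got {header!r}")
    freqs: dict[str, float] = {}
    counts: dict[str, int] = {}
    report: list[str] = []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = [p.strip() for p in line.split(",")]
        if len(parts) != 5:
            raise CutParseError(f"line {lineno}: expected 5 fields, got {len(parts)}")
        codon = _normalize_codon(parts[0], f"line {lineno}")
        if codon in freqs:
            raise CutParseError(f"duplicate codon {codon} (line {lineno})")
        freq = float(parts[3])
        if freq < 0:
            raise CutParseError(f"line {lineno}: negative value {freq}")
        count = int(parts[4]) if parts[4] else 0
        if count < 0:
            raise CutParseError(f"line {lineno}: negative count {count}")
        freqs[codon] = freq
        counts[codon] = count
    for codon in ALL_CODONS:
        if codon not in freqs:
            freqs[codon] = 0.0
            counts[codon] = 0
            report.append(f"missing codon {codon} filled with zero usage")
    has_counts = any(c > 0 for c in counts.values())
    table = CodonUsageTable(
        organism=organism,
        frequency_per_thousand=freqs,
        counts=counts if has_counts else None,
        dialect="csv",
    )
    table.parse_report = report
    return table


def serialize_cut(table: CodonUsageTable, dialect: str = "kazusa",
                  code: GeneticCode = STANDARD_CODE) -> str:
    """Serialize a table to the named dialect; round-trips through parse_cut."""
    if dialect == "kazusa":
        out = io.StringIO()
        for idx, codon in enumerate(ALL_CODONS):
            count = table.counts[codon] if table.counts is not None else 0
            out.write(f"{codon} {table.frequency_per_thousand[codon]!r} ({count})")
            out.write("\n" if idx % 4 == 3 else "  ")
        return out.getvalue()
    if dialect == "csv":
        measures = codon_measures(table, code)
        rows = [_CSV_HEADER]
        for codon in ALL_CODONS:
            count = table.counts[codon] if table.counts is not None else 0
            rows.append(
                f"{codon},{code.amino_acid(codon)},{measures.family_fraction[codon]!r},"
                f"{table.frequency_per_thousand[codon]!r},{count}"
            )
        return "\n".join(rows) + "\n"
    raise CutParseError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# building tables from coding sequences
# ---------------------------------------------------------------------------

def codons_of(sequence: str) -> list[str]:
    """Split an in-frame DNA sequence into its codons (validates frame/alphabet)."""
    seq = sequence.upper()
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} is not divisible by 3")
    if any(b not in _BASES for b in seq):
        bad = sorted({b for b in seq if b not in _BASES})
        raise ValueError(f"sequence contains non-ACGT symbols: {bad}")
    return [seq[i:i + 3] for i in range(0, len(seq), 3)]


def translate(sequence: str, code: GeneticCode = STANDARD_CODE) -> str:
    """Translate an in-frame DNA sequence (stops rendered as '*')."""
    if code is STANDARD_CODE:
        if len(sequence) % 3 != 0:
            raise ValueError(f"sequence length {len(sequence)} is not divisible by 3")
        return str(Seq(sequence).translate())
    return "".join(code.amino_acid(c) for c in codons_of(sequence))


def cut_from_cds(records: list[str], organism: str = "pooled-CDS") -> CodonUsageTable:
    """Pool codon counts over in-frame coding sequences into a usage table."""
    if not records:
        raise ValueError("cannot build a codon usage table from an empty record list")
    counts = {codon: 0 for codon in ALL_CODONS}
    for idx, rec in enumerate(records):
        try:
            for codon in codons_of(rec):
                counts[codon] += 1
        except ValueError as exc:
            raise ValueError(f"record {idx}: {exc}") from exc
    total = sum(counts.values())
    freqs = {codon: 1000.0 * n / total for codon, n in counts.items()}
    return CodonUsageTable(
        organism=organism, frequency_per_thousand=freqs, counts=counts, dialect="cds"
    )


# ---------------------------------------------------------------------------
# derived measures
# ---------------------------------------------------------------------------

def codon_measures(cut: CodonUsageTable, code: GeneticCode = STANDARD_CODE) -> CodonMeasures:
    """Derive family fraction, RSCU, relative adaptiveness and ranks from a CUT.

    All-zero synonymous families degrade to uniform measures (fraction 1/n,
    RSCU 1, w 1) with a recorded warning rather than an error: sparse tables
    for poorly sequenced organisms are legal inputs.
    """
    fraction: dict[str, float] = {}
    rscu: dict[str, float] = {}
    w: dict[str, float] = {}
    rank: dict[str, int] = {}
    ordinal: dict[str, int] = {}
    zero_families: list[str] = []

    for aa, family in code.families.items():
        freqs = [cut.frequency_per_thousand[c] for c in family]
        total = sum(freqs)
        n = len(family)
        if total <= 0.0:
            zero_families.append(aa)
            warnings.warn(
                f"synonymous family {aa!r} has zero total usage in CUT "
                f"{cut.organism!r}; using uniform measures",
                stacklevel=2,
            )
            for c in family:
                fraction[c] = 1.0 / n
                rscu[c] = 1.0
                w[c] = 1.0
        else:
            fmax = max(freqs)
            mean = total / n
            for c, f in zip(family, freqs):
                fraction[c] = f / total
                rscu[c] = f / mean
                w[c] = f / fmax
        # deterministic order: descending frequency, then lexicographic
        order = sorted(family, key=lambda c: (-cut.frequency_per_thousand[c], c))
        for pos, c in enumerate(order):
            ordinal[c] = pos
            if pos > 0 and (
                cut.frequency_per_thousand[c]
                == cut.frequency_per_thousand[order[pos - 1]]
            ):
                rank[c] = rank[order[pos - 1]]
            else:
                rank[c] = pos + 1

    return CodonMeasures(
        cut_label=cut.organism,
        family_fraction=fraction,
        rscu=rscu,
        adaptiveness_w=w,
        rank=rank,
        ordinal=ordinal,
        zero_families=tuple(zero_families),
    )
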