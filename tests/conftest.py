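"""Shared fixtures: small deterministic usage tables and gene builders."""

from __future__ import annotations

import numpy as np
import pytest

from harmobench.codon_tables import (
    ALL_CODONS,
    STANDARD_CODE,
    CodonUsageTable,
)

SENSE_CODONS = tuple(c for c in ALL_CODONS if STANDARD_CODE.amino_acid(c) != "*")


def make_cut(fraction_overrides: dict[str, float] | None = None,
             label: str = "toy") -> CodonUsageTable:
    """A complete table with equal weight per synonymous family.

    ``fraction_overrides`` sets within-family fractions for chosen codons
    (families must be fully specified when overridden); all other families
    are uniform.  Frequencies sum to exactly 1000.
    """
    overrides = fraction_overrides or {}
    families = STANDARD_CODE.families
    fam_weight = 1000.0 / len(families)
    freqs = {}
    for family in families.values():
        fracs = [overrides.get(c, None) for c in family]
        if any(f is not None for f in fracs):
            assert all(f is not None for f in fracs), (
                f"override the whole family {family}"
            )
            total = sum(fracs)
            fracs = [f / total for f in fracs]
        else:
            fracs = [1.0 / len(family)] * len(family)
        for c, f in zip(family, fracs):
            freqs[c] = f * fam_weight
    return CodonUsageTable(organism=label, frequency_per_thousand=freqs)


def random_cut(seed: int, label: str = "rand") -> CodonUsageTable:
    """A random complete table: uniform-Dirichlet fractions, equal family weight."""
    rng = np.random.default_rng(seed)
    families = STANDARD_CODE.families
    fam_weight = 1000.0 / len(families)
    freqs = {}
    for family in families.values():
        fracs = rng.dirichlet(np.ones(len(family)))
        for c, f in zip(family, fracs):
            freqs[c] = float(f * fam_weight)
    return CodonUsageTable(organism=label, frequency_per_thousand=freqs)


def random_gene(seed: int, n_codons: int, with_stop: bool = False) -> str:
    """Random in-frame gene of sense codons (optionally with a terminal stop)."""
    rng = np.random.default_rng(seed)
    codons = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons)]
    if with_stop:
        codons.append(("TAA", "TAG", "TGA")[rng.integers(3)])
    return "".join(codons)


@pytest.fixture
def uniform_cut() -> CodonUsageTable:
    return make_cut()
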