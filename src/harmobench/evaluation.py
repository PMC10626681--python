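"""Quantitative assessment of harmonization output.

The unit measures:

* **ΔMinMax** — per-window difference between the harmonized gene's %MinMax
  under the target-host table and the original gene's %MinMax under the
  source-host table.  Ideal harmonization drives every window to 0.
* **Per-gene RMSE** — root mean square of ΔMinMax over a gene's windows
  against a zero target: sqrt(Σ (0 − y_i)² / n) with n the number of
  sliding windows in the gene.
* **RMSE_codons** — per codon, over the gene set: with ORI%/HARM% the
  codon's family-relative occurrence in the original/harmonized gene and
  CUT% the family fraction in the corresponding host table,
  sqrt(Σ_genes (|ORI% − CUT_orig%| − |HARM% − CUT_het%|)² / n).
  Genes whose family is absent are skipped for that codon (n reduced).
  Single-codon families (ATG, TGG) are structurally zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codon_tables import (
    ALL_CODONS,
    STANDARD_CODE,
    CodonUsageTable,
    GeneticCode,
    codon_measures,
    codons_of,
)
from .usage_metrics import MinMaxProfile

__all__ = [
    "EvaluationRecord",
    "delta_minmax",
    "gene_rmse",
    "occurrence_percent",
    "rmse_codons",
    "build_codon_rmse_matrix",
    "build_heatmap",
]


@dataclass
class EvaluationRecord:
    """One gene × tool × host row — the unit of the downstream GEE analysis."""

    gene_id: str
    tool: str
    host: str
    rmse: float
    n_windows: int
    mean_gc: float
    mean_mrna: float
    enzyme_class: str

    def __post_init__(self) -> None:
        if self.rmse < 0 or not np.isfinite(self.rmse):
            raise ValueError(f"rmse must be finite and >= 0; got {self.rmse}")
        if self.n_windows < 1:
            raise ValueError("n_windows must be >= 1")


def delta_minmax(harmonized_profile: MinMaxProfile,
                 original_profile: MinMaxProfile) -> np.ndarray:
    """Elementwise harmonized − original profile values (ΔMinMax)."""
    h, o = harmonized_profile, original_profile
    if len(h.values) != len(o.values) or h.window != o.window:
        raise ValueError(
            f"profile mismatch: {len(h.values)} windows @ {h.window} vs "
            f"{len(o.values)} windows @ {o.window}"
        )
    return h.values - o.values


def gene_rmse(delta: np.ndarray) -> float:
    """Root mean square of per-window ΔMinMax against a zero target."""
    d = np.asarray(delta, dtype=float)
    if d.size == 0:
        raise ValueError("cannot compute RMSE of an empty delta vector")
    return float(np.sqrt(np.mean(d ** 2)))


def occurrence_percent(gene, code: GeneticCode = STANDARD_CODE) -> dict[str, float | None]:
    """Family-relative occurrence of each codon within one gene.

    Count of the codon divided by the total count of its synonymous family;
    codons whose family does not occur in the gene map to ``None``
    (undefined), never 0.
    """
    codons = codons_of(gene) if isinstance(gene, str) else list(gene)
    counts = {c: 0 for c in ALL_CODONS}
    for c in codons:
        counts[c] += 1
    out: dict[str, float | None] = {}
    for family in code.families.values():
        fam_total = sum(counts[c] for c in family)
        for c in family:
            out[c] = counts[c] / fam_total if fam_total > 0 else None
    return out


def rmse_codons(pairs: list[tuple], target_cut: CodonUsageTable,
                code: GeneticCode = STANDARD_CODE):
    """One RMSE_codons column for a (tool, host) combination.

    ``pairs`` holds ``(original_gene, harmonized_gene, source_cut)`` per
    gene; the target (heterologous) table is shared.  Returns
    ``(values, n_used)`` dicts over the 64 codons; codons whose family never
    occurs get value 0.0 with ``n_used`` 0.
    """
    if not pairs:
        raise ValueError("rmse_codons needs at least one (original, harmonized) pair")
    m_tgt = codon_measures(target_cut, code).family_fraction
    sq_sum = {c: 0.0 for c in ALL_CODONS}
    n_used = {c: 0 for c in ALL_CODONS}
    src_measures_cache: dict[int, dict[str, float]] = {}
    for orig, harm, source_cut in pairs:
        key = id(source_cut)
        if key not in src_measures_cache:
            src_measures_cache[key] = codon_measures(source_cut, code).family_fraction
        m_src = src_measures_cache[key]
        ori_pct = occurrence_percent(orig, code)
        harm_pct = occurrence_percent(harm, code)
        for c in ALL_CODONS:
            if ori_pct[c] is None or harm_pct[c] is None:
                continue  # family absent from this gene: skip, n reduced
            term = abs(ori_pct[c] - m_src[c]) - abs(harm_pct[c] - m_tgt[c])
            sq_sum[c] += term * term
            n_used[c] += 1
    values = {
        c: (np.sqrt(sq_sum[c] / n_used[c]) if n_used[c] > 0 else 0.0)
        for c in ALL_CODONS
    }
    return values, n_used


def build_codon_rmse_matrix(columns: dict[tuple[str, str], dict[str, float]],
                            code: GeneticCode = STANDARD_CODE) -> pd.DataFrame:
    """Assemble per-combination RMSE_codons columns into the 64×(tool,host) matrix.

    Rows are codons grouped by amino acid (then lexicographic); columns a
    (tool, host) MultiIndex.
    """
    order = sorted(ALL_CODONS, key=lambda c: (code.amino_acid(c), c))
    df = pd.DataFrame(
        {pair: [vals[c] for c in order] for pair, vals in sorted(columns.items())},
        index=pd.Index(order, name="codon"),
    )
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["tool", "host"])
    aa = [code.amino_acid(c) for c in order]
    df.insert(0, ("amino_acid", ""), aa)
    return df


def build_heatmap(matrix: pd.DataFrame, csv_path=None, image_path=None,
                  code: GeneticCode = STANDARD_CODE):
    """Summarize (and optionally render) an RMSE_codons matrix.

    Returns a per-combination means table with two rows per statistic: the
    mean over all 64 codons (single-codon families included as their
    structural zeros) and the mean excluding ATG/TGG.  ``image_path`` renders
    a single-hue heatmap where 0 is lightest.
    """
    value_cols = [c for c in matrix.columns if c[0] != "amino_acid"]
    values = matrix[value_cols].astype(float)
    means = pd.DataFrame({
        "mean_rmse_codons_all64": values.mean(axis=0),
        "mean_rmse_codons_excl_single": values.drop(index=["ATG", "TGG"]).mean(axis=0),
    })
    means.index.names = ["tool", "host"]
    if csv_path is not None:
        flat = matrix.copy()
        flat.columns = [
            "amino_acid" if c[0] == "amino_acid" else f"{c[0]}|{c[1]}"
            for c in flat.columns
        ]
        flat.to_csv(csv_path)
    if image_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(1.2 * len(value_cols) + 2, 12))
        im = ax.imshow(values.to_numpy(), aspect="auto", cmap="Blues",
                       vmin=0.0)
        ax.set_yticks(range(len(values.index)))
        ax.set_yticklabels(
            [f"{c} ({code.amino_acid(c)})" for c in values.index], fontsize=6
        )
        ax.set_xticks(range(len(value_cols)))
        ax.set_xticklabels([f"{t}\n{h}" for t, h in value_cols], fontsize=7)
        fig.colorbar(im, ax=ax, label="RMSE_codons")
        fig.tight_layout()
        fig.savefig(image_path, dpi=150)
        plt.close(fig)
    return means
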