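"""Marginal regression comparison of harmonization tools.

Evaluation records are repeated measures: each gene contributes one RMSE per
tool × host combination, so rows are correlated within genes.  Generalized
estimating equations (GEE) with a Gaussian family, identity link and an
exchangeable working correlation, clustered by gene, give marginal
coefficient estimates with robust (sandwich) standard errors.  Factors and
interaction blocks are compared with joint Wald chi-square tests on the
robust covariance; significance convention is p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.genmod.cov_struct import Exchangeable
from statsmodels.genmod.families import Gaussian

__all__ = [
    "TOOL_LEVELS",
    "WaldResult",
    "build_long_table",
    "fit_gee",
    "wald_factor_test",
    "rank_tools",
    "simulate_records",
    "DEFAULT_FORMULA",
]

TOOL_LEVELS = ("charming-mm", "charming-geo", "codonwizard", "eugene", "galaxy")

DEFAULT_FORMULA = (
    "rmse ~ C(tool) + C(host) + mean_gc + mean_mrna + C(enzyme_class)"
)

_REQUIRED = ["gene_id", "tool", "host", "rmse", "mean_gc", "mean_mrna",
             "enzyme_class"]


@dataclass
class WaldResult:
    """Joint Wald test on a block of coefficients.

    ``reference`` records the null distribution used: ``"chi2"`` for the
    classical sandwich test, ``"f"`` for the small-sample scaled-F version
    (``df_denom`` then holds the denominator degrees of freedom).
    """

    statistic: float
    df: int
    p_value: float
    terms: tuple[str, ...]
    reference: str = "chi2"
    df_denom: int | None = None

    def __post_init__(self) -> None:
        if self.statistic < 0 or self.df < 1:
            raise ValueError("invalid Wald result")


def build_long_table(records) -> pd.DataFrame:
    """Validate evaluation records into a long-format analysis table.

    Accepts a DataFrame or an iterable of objects with the record fields.
    Rejects duplicate gene × tool × host rows and missing responses; factor
    levels are ordered deterministically (sorted).
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        rows = list(records)
        if not rows:
            raise ValueError("no evaluation records")
        df = pd.DataFrame([vars(r) for r in rows])
    if df.empty:
        raise ValueError("no evaluation records")
    missing_cols = [c for c in _REQUIRED if c not in df.columns]
    if missing_cols:
        raise ValueError(f"records lack required fields {missing_cols}")
    if df["rmse"].isna().any():
        bad = df.loc[df["rmse"].isna(), ["gene_id", "tool", "host"]]
        raise ValueError(f"missing rmse for rows:\n{bad}")
    dup = df.duplicated(subset=["gene_id", "tool", "host"])
    if dup.any():
        raise ValueError(
            f"duplicate gene×tool×host rows: "
            f"{df.loc[dup, ['gene_id', 'tool', 'host']].to_records(index=False)}"
        )
    for col in ("gene_id", "tool", "host", "enzyme_class"):
        df[col] = df[col].astype(str)
    df = df.sort_values(["gene_id", "tool", "host"]).reset_index(drop=True)
    return df


def cluster_sizes(table: pd.DataFrame) -> pd.Series:
    return table.groupby("gene_id").size()


def fit_gee(table: pd.DataFrame, formula: str = DEFAULT_FORMULA,
            allow_overparameterized: bool = False):
    """Fit a Gaussian identity-link GEE clustered by gene.

    Working correlation is exchangeable; the returned fit carries robust
    sandwich covariance (the statsmodels GEE default).  Interaction formulas
    are refused when the number of clusters is below five times the number
    of coefficients (override with ``allow_overparameterized``) — too few
    genes cannot support interaction estimates without overfitting.
    """
    table = build_long_table(table)
    if np.isclose(float(np.var(table["rmse"])), 0.0):
        # a constant response has zero scale and no estimable correlation:
        # ordinary least squares gives the same (intercept-only) solution
        return smf.ols(formula, data=table).fit()
    model = smf.gee(formula, groups="gene_id", data=table,
                    family=Gaussian(), cov_struct=Exchangeable())
    n_coef = model.exog.shape[1]
    n_clusters = table["gene_id"].nunique()
    if ":" in formula and n_clusters < 5 * n_coef and not allow_overparameterized:
        raise ValueError(
            f"interaction fit refused: {n_clusters} clusters < 5 × {n_coef} "
            "coefficients (pass allow_overparameterized=True to override)"
        )
    rank = np.linalg.matrix_rank(model.exog)
    if rank < n_coef:
        # identify aliased columns via pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(model.exog, mode="economic", pivoting=True)
        aliased = [model.exog_names[i] for i in sorted(piv[rank:])]
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
    # bias_reduced populates both the plain and the Mancl–DeRouen sandwich
    result = model.fit(cov_type="bias_reduced")
    if not getattr(result, "converged", True):
        raise RuntimeError("GEE did not converge; inspect the input table")
    return result


def wald_factor_test(fit, terms, small_sample: bool = True) -> WaldResult:
    """Joint Wald test on named coefficients using the robust covariance.

    ``terms`` may be a single coefficient name, a list of names, or a factor
    prefix such as ``"C(tool)"`` which selects every coefficient of that
    factor (mirroring the model-with/without-factor comparison).

    With tens of gene clusters the plain sandwich chi-square test is
    anti-conservative, so by default the bias-reduced (Mancl–DeRouen)
    sandwich is used together with a scaled F reference with K − p
    denominator degrees of freedom (K clusters, p coefficients); both
    corrections vanish asymptotically.  ``small_sample=False`` gives the
    classical chi-square sandwich test.
    """
    names = list(fit.params.index)
    if isinstance(terms, str):
        terms = [terms]
    selected: list[str] = []
    for term in terms:
        if term in names:
            selected.append(term)
        else:
            hits = [n for n in names if n.startswith(term)]
            if not hits:
                raise KeyError(f"term {term!r} not found among {names}")
            selected.extend(hits)
    seen = dict.fromkeys(selected)
    selected = list(seen)
    idx = [names.index(n) for n in selected]
    beta = fit.params.to_numpy()[idx]
    use_small = small_sample and getattr(fit, "cov_robust_bc", None) is not None
    if use_small:
        cov_full = np.asarray(fit.cov_robust_bc)
    elif getattr(fit, "cov_robust", None) is not None:
        cov_full = np.asarray(fit.cov_robust)
    else:
        cov_full = np.asarray(fit.cov_params())
    cov = cov_full[np.ix_(idx, idx)]
    # with few clusters the sandwich block can be rank-deficient: use the
    # pseudo-inverse and test on the supported subspace
    rank = int(np.linalg.matrix_rank(cov))
    if rank == 0:
        raise ValueError(f"robust covariance of {selected} has rank 0")
    stat = float(max(beta @ np.linalg.pinv(cov) @ beta, 0.0))
    if use_small:
        n_clusters = int(fit.model.num_group)
        p_coef = len(names)
        df_denom = n_clusters - p_coef
        if df_denom > 0:
            f_stat = stat / rank * df_denom / (n_clusters - 1)
            return WaldResult(statistic=stat, df=rank,
                              p_value=float(sps.f.sf(f_stat, rank, df_denom)),
                              terms=tuple(selected), reference="f",
                              df_denom=df_denom)
    return WaldResult(statistic=stat, df=rank,
                      p_value=float(sps.chi2.sf(stat, rank)),
                      terms=tuple(selected))


def rank_tools(records, n_bootstrap: int = 0, seed: int = 0,
               expected_tools=None):
    """Order tools from lowest (best) to highest mean RMSE.

    Returns ``(overall, per_host)`` DataFrames; ``overall`` carries the mean
    RMSE, the rank (ties share a rank and are flagged), and — when
    ``n_bootstrap`` > 0 — the fraction of gene-level bootstrap resamples in
    which each tool keeps its observed rank.  ``expected_tools`` makes a
    tool with no records an error instead of a silent omission.
    """
    df = build_long_table(records)
    if expected_tools is not None:
        missing = sorted(set(expected_tools) - set(df["tool"].unique()))
        if missing:
            raise ValueError(f"tools without records: {missing}")

    def _ranking(frame: pd.DataFrame) -> pd.DataFrame:
        means = frame.groupby("tool")["rmse"].mean().sort_values(kind="stable")
        out = means.to_frame("mean_rmse")
        out["rank"] = means.rank(method="min").astype(int)
        out["tied"] = means.duplicated(keep=False)
        return out

    overall = _ranking(df)
    per_host = {host: _ranking(g) for host, g in df.groupby("host")}

    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        genes = np.array(sorted(df["gene_id"].unique()))
        observed = overall["rank"]
        hold = {t: 0 for t in overall.index}
        grouped = {g: frame for g, frame in df.groupby("gene_id")}
        for _ in range(n_bootstrap):
            draw = rng.choice(genes, size=len(genes), replace=True)
            boot = pd.concat([grouped[g] for g in draw], ignore_index=True)
            ranks = _ranking(boot)["rank"]
            for t in hold:
                if ranks.get(t) == observed[t]:
                    hold[t] += 1
        overall["rank_stability"] = pd.Series(hold) / n_bootstrap
    return overall, per_host


def simulate_records(n_genes: int = 30, tools=TOOL_LEVELS,
                     hosts=("hostA", "hostB"), tool_effects=None,
                     host_effect: float = 0.0, baseline: float = 20.0,
                     gene_sd: float = 3.0, resid_sd: float = 2.0,
                     seed: int = 0) -> pd.DataFrame:
    """Simulate evaluation records with gene-level clustering.

    The response is ``baseline + gene effect + tool effect + host effect +
    noise``; used for calibrating the Wald machinery (type-I error, power)
    under a known truth.
    """
    rng = np.random.default_rng(seed)
    tools = list(tools)
    hosts = list(hosts)
    if tool_effects is None:
        tool_effects = {t: 0.0 for t in tools}
    gene_eff = rng.normal(0.0, gene_sd, size=n_genes)
    gc = rng.uniform(0.30, 0.80, size=n_genes)
    mrna = rng.normal(0.63, 0.025, size=n_genes)
    rows = []
    for g in range(n_genes):
        gid = f"g{g:03d}"
        for t in tools:
            for h_i, h in enumerate(hosts):
                y = (baseline + gene_eff[g] + tool_effects.get(t, 0.0)
                     + host_effect * h_i + rng.normal(0.0, resid_sd))
                rows.append(dict(
                    gene_id=gid, tool=t, host=h, rmse=y, n_windows=100,
                    mean_gc=gc[g], mean_mrna=float(np.clip(mrna[g], 0, 1)),
                    enzyme_class="EC1" if g % 2 == 0 else "EC2",
                ))
    return pd.DataFrame(rows)
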