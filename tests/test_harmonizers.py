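"""Harmonization algorithms: rank matching, pointwise matching, descent."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from harmobench.codon_tables import STANDARD_CODE, codon_measures, translate
from harmobench.harmonizers import (
    HarmonizationTask,
    harmonize,
    harmonize_charming,
    harmonize_pointwise,
    rodriguez_initialize,
    run_tool,
)
from harmobench.usage_metrics import minmax_profile

from conftest import make_cut, random_cut, random_gene


class TestRodriguezInitialize:
    def test_identical_cuts_identity(self):
        cut = random_cut(1)
        gene = random_gene(2, 30)
        assert rodriguez_initialize(gene, cut, cut) == [
            gene[i:i + 3] for i in range(0, len(gene), 3)]

    def test_rank_lookup(self):
        src = make_cut({"GAA": 0.8, "GAG": 0.2})  # GAA rank 1 in source
        tgt = make_cut({"GAA": 0.2, "GAG": 0.8})  # GAG rank 1 in target
        assert rodriguez_initialize("GAA", src, tgt) == ["GAG"]
        assert rodriguez_initialize("GAG", src, tgt) == ["GAA"]

    def test_single_codon_family_unchanged(self):
        out = rodriguez_initialize("ATGTGG", random_cut(3), random_cut(4))
        assert out == ["ATG", "TGG"]


class TestPointwise:
    def test_family_fraction_argmin_example(self):
        src = make_cut({"GAA": 0.7, "GAG": 0.3})
        tgt = make_cut({"GAA": 0.2, "GAG": 0.8})
        res = harmonize_pointwise(HarmonizationTask(
            gene="GAA", source_cut=src, target_cut=tgt,
            measure="family_fraction"))
        assert res.codons == ["GAG"]  # |0.8-0.7| = 0.1 beats |0.2-0.7|

    @pytest.mark.parametrize("measure", ["family_fraction", "rscu", "adaptiveness"])
    def test_self_harmonization_is_identity(self, measure):
        cut = random_cut(5)
        gene = random_gene(6, 40, with_stop=True)
        res = harmonize_pointwise(HarmonizationTask(
            gene=gene, source_cut=cut, target_cut=cut, measure=measure))
        assert res.sequence == gene and res.substitutions == 0

    def test_full_tolerance_pool_is_whole_family(self):
        # at t=1 every synonymous codon can be drawn
        src = make_cut({"TTA": 0.9, "TTG": 0.02, "CTA": 0.02, "CTC": 0.02,
                        "CTG": 0.02, "CTT": 0.02})
        tgt = random_cut(7)
        seen = set()
        for seed in range(300):
            res = harmonize_pointwise(HarmonizationTask(
                gene="TTA", source_cut=src, target_cut=tgt,
                measure="family_fraction", tolerance=1.0, seed=seed))
            seen.add(res.codons[0])
        assert seen == set(STANDARD_CODE.families["L"])

    def test_tolerance_determinism_under_seed(self):
        src, tgt = random_cut(8), random_cut(9)
        gene = random_gene(10, 25)
        task = dict(gene=gene, source_cut=src, target_cut=tgt,
                    measure="family_fraction", tolerance=0.5, seed=42)
        a = harmonize_pointwise(HarmonizationTask(**task))
        b = harmonize_pointwise(HarmonizationTask(**task))
        assert a.sequence == b.sequence

    def test_zero_tolerance_seed_independent(self):
        src, tgt = random_cut(11), random_cut(12)
        gene = random_gene(13, 25)
        seqs = {
            harmonize_pointwise(HarmonizationTask(
                gene=gene, source_cut=src, target_cut=tgt, seed=s)).sequence
            for s in (0, 1, 999)
        }
        assert len(seqs) == 1

    @pytest.mark.parametrize("measure", ["family_fraction", "rscu", "adaptiveness"])
    def test_matches_exhaustive_argmin_oracle(self, measure):
        """t=0 output equals a from-scratch per-position argmin on short genes."""
        for case in range(30):
            src, tgt = random_cut(100 + case), random_cut(200 + case)
            gene = random_gene(300 + case, 8)
            res = harmonize_pointwise(HarmonizationTask(
                gene=gene, source_cut=src, target_cut=tgt, measure=measure))
            m_src = codon_measures(src).measure(measure)
            m_tgt = codon_measures(tgt).measure(measure)
            for p in range(8):
                orig = gene[3 * p: 3 * p + 3]
                got = res.codons[p]
                family = STANDARD_CODE.family_of(orig)
                best = min(abs(m_tgt[c] - m_src[orig]) for c in family)
                if abs(m_tgt[orig] - m_src[orig]) <= best + 1e-15:
                    assert got == orig
                else:
                    winners = [c for c in family
                               if abs(m_tgt[c] - m_src[orig]) <= best + 1e-15]
                    assert got == sorted(winners)[0]

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="internal stop"):
            harmonize_pointwise(HarmonizationTask(
                gene="ATGTAAGAA", source_cut=random_cut(1), target_cut=random_cut(2)))

    def test_terminal_stop_kept_by_default(self):
        src = make_cut({"TAA": 0.1, "TAG": 0.1, "TGA": 0.8})
        tgt = make_cut({"TAA": 0.8, "TAG": 0.1, "TGA": 0.1})
        res = harmonize_pointwise(HarmonizationTask(
            gene="GAATAA", source_cut=src, target_cut=tgt))
        assert res.codons[-1] == "TAA"
        res2 = harmonize_pointwise(HarmonizationTask(
            gene="GAATAA", source_cut=src, target_cut=tgt,
            include_terminal_stop=True))
        assert translate(res2.sequence)[-1] == "*"


class TestCharming:
    def test_self_harmonization_identity(self):
        cut = random_cut(21)
        gene = random_gene(22, 30, with_stop=True)
        for mode in ("minmax", "geomean"):
            res = harmonize_charming(HarmonizationTask(
                gene=gene, source_cut=cut, target_cut=cut,
                algorithm="charming", mode=mode))
            assert res.sequence == gene
            assert res.objective_trace[0] == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("mode", ["minmax", "geomean"])
    def test_trace_strictly_decreasing(self, mode):
        src, tgt = random_cut(23), random_cut(24)
        gene = random_gene(25, 60)
        res = harmonize_charming(HarmonizationTask(
            gene=gene, source_cut=src, target_cut=tgt,
            algorithm="charming", mode=mode))
        trace = np.array(res.objective_trace)
        assert np.all(np.diff(trace) < 0)
        assert trace[-1] <= trace[0]

    @pytest.mark.parametrize("mode", ["minmax", "geomean"])
    def test_local_optimum_by_exhaustive_neighbors(self, mode):
        """No single synonymous substitution improves the final objective."""
        src, tgt = random_cut(31), random_cut(32)
        gene = random_gene(33, 6)
        window = 3
        res = harmonize_charming(HarmonizationTask(
            gene=gene, source_cut=src, target_cut=tgt,
            algorithm="charming", mode=mode, window=window))
        target = minmax_profile(gene, src, window, mode).values

        def objective(codon_list):
            vals = minmax_profile(codon_list, tgt, window, mode).values
            return np.abs(vals - target).sum()

        final = objective(res.codons)
        assert final == pytest.approx(res.objective_trace[-1], abs=1e-6)
        for p, c in enumerate(res.codons):
            for alt in STANDARD_CODE.family_of(c):
                if alt == c:
                    continue
                neighbor = list(res.codons)
                neighbor[p] = alt
                assert objective(neighbor) >= final - 1e-6

    def test_final_objective_not_worse_than_rodriguez(self):
        src, tgt = random_cut(35), random_cut(36)
        gene = random_gene(37, 50)
        init = "".join(rodriguez_initialize(gene, src, tgt))
        res = harmonize_charming(HarmonizationTask(
            gene=gene, source_cut=src, target_cut=tgt, algorithm="charming"))
        target = minmax_profile(gene, src, 17, "minmax").values
        init_obj = np.abs(minmax_profile(init, tgt, 17, "minmax").values - target).sum()
        assert res.objective_trace[-1] <= init_obj + 1e-9
        assert res.objective_trace[0] == pytest.approx(init_obj)

    def test_multiple_solutions_are_distinct_local_optima(self):
        src, tgt = random_cut(41), random_cut(42)
        gene = random_gene(43, 20)
        res = harmonize_charming(HarmonizationTask(
            gene=gene, source_cut=src, target_cut=tgt, algorithm="charming",
            n_solutions=4, seed=5))
        assert len(res.solutions) >= 1
        assert len({s for s, _ in res.solutions}) == len(res.solutions)
        for sol, _ in res.solutions:
            assert translate("".join(sol)) == translate(gene)
        objs = [o for _, o in res.solutions]
        assert res.objective_trace[-1] == pytest.approx(min(objs))


class TestProperties:
    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 5_000), st.integers(0, 5_000), st.integers(5, 40),
           st.sampled_from(["eugene", "galaxy", "codonwizard", "charming-mm",
                            "charming-geo"]))
    def test_protein_identity(self, cut_seed, gene_seed, length, tool):
        src = random_cut(cut_seed)
        tgt = random_cut(cut_seed + 77)
        gene = random_gene(gene_seed, length, with_stop=True)
        res = run_tool(tool, gene, src, tgt, seed=1)
        assert translate(res.sequence) == translate(gene)
        assert len(res.sequence) == len(gene)

    def test_dispatch_and_determinism(self):
        src, tgt = random_cut(51), random_cut(52)
        gene = random_gene(53, 30)
        for tool in ("eugene", "galaxy", "codonwizard", "charming-mm", "charming-geo"):
            a = run_tool(tool, gene, src, tgt, seed=3)
            b = run_tool(tool, gene, src, tgt, seed=3)
            assert a.sequence == b.sequence

    def test_unknown_tool_rejected(self):
        with pytest.raises(ValueError, match="unknown tool"):
            run_tool("optimizer9000", "ATG", random_cut(1), random_cut(2))

    def test_invalid_task_parameters(self):
        with pytest.raises(ValueError):
            HarmonizationTask(gene="ATG", source_cut=None, target_cut=None,
                              tolerance=1.5)
        with pytest.raises(ValueError):
            HarmonizationTask(gene="ATG", source_cut=None, target_cut=None,
                              window=0)
        with pytest.raises(ValueError):
            HarmonizationTask(gene="ATG", source_cut=None, target_cut=None,
                              algorithm="annealing")
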