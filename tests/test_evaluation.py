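"""ΔMinMax, per-gene RMSE, RMSE_codons and the heatmap matrix."""

import numpy as np
import pandas as pd
import pytest

from harmobench.evaluation import (
    EvaluationRecord,
    build_codon_rmse_matrix,
    build_heatmap,
    delta_minmax,
    gene_rmse,
    occurrence_percent,
    rmse_codons,
)
from harmobench.usage_metrics import MinMaxProfile, minmax_profile

from conftest import make_cut, random_cut, random_gene


def profile(values, window=18):
    return MinMaxProfile(gene_id="g", cut_label="c", window=window,
                         mode="minmax", values=np.asarray(values, dtype=float))


class TestDeltaMinMax:
    def test_identical_profiles_zero(self):
        p = profile([10.0, -5.0, 3.0])
        assert np.all(delta_minmax(p, p) == 0.0)

    def test_elementwise_subtraction(self):
        d = delta_minmax(profile([10.0, -5.0]), profile([7.0, -1.0]))
        assert np.allclose(d, [3.0, -4.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            delta_minmax(profile([1.0]), profile([1.0, 2.0]))

    def test_self_harmonized_pipeline_zero(self):
        cut = random_cut(61)
        gene = random_gene(62, 30)
        p = minmax_profile(gene, cut, 18)
        assert np.allclose(delta_minmax(p, p), 0.0)


class TestGeneRmse:
    def test_zero_deltas(self):
        assert gene_rmse(np.zeros(7)) == 0.0

    def test_hand_arithmetic(self):
        assert gene_rmse([3.0, -4.0]) == pytest.approx(np.sqrt(12.5))

    def test_matches_naive_accumulation(self):
        rng = np.random.default_rng(4)
        deltas = rng.normal(0, 20, size=57)
        acc = 0.0
        for d in deltas:
            acc += (0.0 - d) ** 2
        assert gene_rmse(deltas) == pytest.approx(np.sqrt(acc / 57))

    def test_window_order_invariance_and_scaling(self):
        rng = np.random.default_rng(5)
        deltas = rng.normal(0, 10, size=20)
        assert gene_rmse(deltas) == pytest.approx(gene_rmse(deltas[::-1]))
        assert gene_rmse(3.0 * deltas) == pytest.approx(3.0 * gene_rmse(deltas))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gene_rmse(np.array([]))


class TestOccurrencePercent:
    def test_hand_count(self):
        occ = occurrence_percent("GAAGAGGAA")
        assert occ["GAA"] == pytest.approx(2 / 3)
        assert occ["GAG"] == pytest.approx(1 / 3)

    def test_single_codon_family(self):
        occ = occurrence_percent("ATG")
        assert occ["ATG"] == 1.0

    def test_absent_family_undefined(self):
        occ = occurrence_percent("ATG")
        assert occ["GAA"] is None  # undefined, not 0


class TestRmseCodons:
    def test_single_codon_families_structurally_zero(self):
        src, tgt = random_cut(71), random_cut(72)
        pairs = []
        for s in range(5):
            gene = "ATGTGG" + random_gene(s, 20, with_stop=True)
            harm = "ATGTGG" + random_gene(s + 100, 20)  # same aa not needed here
            pairs.append((gene, gene, src))
        vals, n = rmse_codons(pairs, tgt)
        assert vals["ATG"] == 0.0 and vals["TGG"] == 0.0
        assert n["ATG"] == 5

    def test_identity_with_matched_cut_is_zero(self):
        src = random_cut(73)
        genes = [random_gene(s, 40, with_stop=True) for s in range(4)]
        vals, _ = rmse_codons([(g, g, src) for g in genes], src)
        assert all(v == 0.0 for v in vals.values())

    def test_two_gene_hand_tabulation(self):
        """Spreadsheet-style recomputation on a 2-gene toy set."""
        src = make_cut({"GAA": 0.6, "GAG": 0.4})
        tgt = make_cut({"GAA": 0.3, "GAG": 0.7})
        # gene 1: ORI% GAA=2/3; HARM% GAA=1/3
        g1, h1 = "ATGGAAGAAGAGTAA", "ATGGAGGAGGAATAA"
        # gene 2: ORI% GAA=0; HARM% GAA=1
        g2, h2 = "ATGGAGTAA", "ATGGAATAA"
        vals, n = rmse_codons([(g1, h1, src), (g2, h2, src)], tgt)
        t1 = abs(2 / 3 - 0.6) - abs(1 / 3 - 0.3)
        t2 = abs(0.0 - 0.6) - abs(1.0 - 0.3)
        assert vals["GAA"] == pytest.approx(np.sqrt((t1 ** 2 + t2 ** 2) / 2))
        u1 = abs(1 / 3 - 0.4) - abs(2 / 3 - 0.7)
        u2 = abs(1.0 - 0.4) - abs(0.0 - 0.7)
        assert vals["GAG"] == pytest.approx(np.sqrt((u1 ** 2 + u2 ** 2) / 2))
        assert n["GAA"] == 2

    def test_absent_family_skipped_not_imputed(self):
        src, tgt = random_cut(74), random_cut(75)
        # TGG (Trp) absent from gene 1, present in gene 2
        g1 = "ATGGAAGAATAA"
        g2 = "ATGTGGTGGTAA"
        vals, n = rmse_codons([(g1, g1, src), (g2, g2, src)], tgt)
        assert n["TGG"] == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rmse_codons([], random_cut(1))


class TestHeatmap:
    def _matrix(self):
        src, tgt = random_cut(81), random_cut(82)
        pairs = [(random_gene(s, 30, with_stop=True),) * 2 + (src,)
                 for s in range(3)]
        cols = {}
        for tool in ("toolA", "toolB"):
            for host in ("h1", "h2"):
                vals, _ = rmse_codons(pairs, tgt if tool == "toolA" else src)
                cols[(tool, host)] = vals
        return build_codon_rmse_matrix(cols)

    def test_column_mean_recomputed(self, tmp_path):
        matrix = self._matrix()
        means = build_heatmap(matrix, csv_path=tmp_path / "m.csv")
        col = ("toolA", "h1")
        expected = matrix[col].astype(float).mean()
        assert means.loc[col, "mean_rmse_codons_all64"] == pytest.approx(expected)
        # excluding the structurally-zero single-codon families
        excl = matrix[col].drop(index=["ATG", "TGG"]).astype(float).mean()
        assert means.loc[col, "mean_rmse_codons_excl_single"] == pytest.approx(excl)

    def test_all_zero_matrix(self):
        zero = {("t", "h"): {c: 0.0 for c in occurrence_percent("ATG")}}
        matrix = build_codon_rmse_matrix(zero)
        means = build_heatmap(matrix)
        assert (means == 0).all().all()

    def test_csv_roundtrip(self, tmp_path):
        matrix = self._matrix()
        build_heatmap(matrix, csv_path=tmp_path / "m.csv")
        back = pd.read_csv(tmp_path / "m.csv").set_index("codon")
        for tool, host in (("toolA", "h1"), ("toolB", "h2")):
            col = back[f"{tool}|{host}"]
            assert np.allclose(col.to_numpy(),
                               matrix[(tool, host)].to_numpy(dtype=float))


class TestMonotoneSanity:
    def test_one_codon_strategy_shifts_delta_positive(self):
        """'One amino acid-one codon' recoding inflates usage everywhere,
        so its ΔMinMax distribution sits above a harmonizing recoder's."""
        from harmobench.codon_tables import STANDARD_CODE
        from harmobench.harmonizers import run_tool

        src, tgt = random_cut(91), random_cut(92)
        f = tgt.frequency_per_thousand
        deltas_one, deltas_harm = [], []
        for s in range(3):
            gene = random_gene(93 + s, 60)
            codons = [gene[i:i + 3] for i in range(0, len(gene), 3)]
            one = [max(STANDARD_CODE.family_of(c), key=lambda x: (f[x], x))
                   for c in codons]
            harm = run_tool("charming-mm", gene, src, tgt, seed=s).codons
            orig = minmax_profile(gene, src, 18)
            deltas_one.extend(delta_minmax(minmax_profile(one, tgt, 18), orig))
            deltas_harm.extend(delta_minmax(minmax_profile(harm, tgt, 18), orig))
        assert np.mean(deltas_one) > np.mean(deltas_harm)
        assert np.median(deltas_one) > np.median(deltas_harm)


class TestEvaluationRecord:
    def test_invalid_rmse_rejected(self):
        with pytest.raises(ValueError):
            EvaluationRecord(gene_id="g", tool="t", host="h", rmse=-1.0,
                             n_windows=3, mean_gc=0.5, mean_mrna=0.5,
                             enzyme_class="EC1")
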