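"""nCounter pipeline: background, geNorm, normalization, calls."""

import numpy as np
import pandas as pd
import pytest

from krabkit import simulate
from krabkit.ncounter import (
    AssayDesign,
    CountMatrix,
    background_correct,
    differential_groups,
    genorm_iterative_ranking,
    genorm_stability,
    normalize_counts,
    sample_correlation,
    summarize_expression,
    _pairwise_m,
)


def make_matrix(counts: dict, classes: dict, assays=None) -> CountMatrix:
    df = pd.DataFrame(counts, index=assays).T if assays else pd.DataFrame(counts).T
    info = pd.DataFrame(
        {"gene_id": list(counts), "probe_class": [classes[p] for p in counts]},
        index=df.index,
    )
    return CountMatrix(df.astype(float), info)


def brute_force_m(counts: pd.DataFrame) -> dict:
    """Direct pairwise-variation formula, independent of the implementation."""
    out = {}
    genes = list(counts.index)
    for j in genes:
        vs = []
        for k in genes:
            if k == j:
                continue
            ratios = np.log2(counts.loc[j].to_numpy() / counts.loc[k].to_numpy())
            vs.append(np.std(ratios, ddof=1))
        out[j] = float(np.mean(vs))
    return out


class TestBackgroundCorrect:
    def setup_method(self):
        self.m = make_matrix(
            {
                "neg1": [8, 2],
                "neg2": [2, 8],
                "probe1": [100, 103],
                "probe2": [3, 2],
            },
            {"neg1": "negative", "neg2": "negative",
             "probe1": "target", "probe2": "target"},
            assays=["a1", "a2"],
        )

    def test_geometric_mean_subtracted(self):
        out = background_correct(self.m)  # geomean(8,2) = 4 per assay
        assert out.counts.loc["probe1", "a1"] == pytest.approx(96.0)
        assert out.counts.loc["probe1", "a2"] == pytest.approx(99.0)

    def test_negative_values_floored(self):
        out = background_correct(self.m)
        assert out.counts.loc["probe2", "a1"] == pytest.approx(0.1)
        assert out.counts.loc["probe2", "a2"] == pytest.approx(0.1)

    def test_negative_probes_dropped(self):
        out = background_correct(self.m)
        assert set(out.counts.index) == {"probe1", "probe2"}

    def test_all_zero_negatives_leave_probes_unchanged(self):
        m = make_matrix(
            {"neg1": [0, 0], "probe1": [50, 60]},
            {"neg1": "negative", "probe1": "target"},
            assays=["a1", "a2"],
        )
        out = background_correct(m)  # zeros → 1 before geomean; bg = 1
        assert out.counts.loc["probe1", "a1"] == pytest.approx(49.0)

    def test_missing_negatives_error(self):
        m = make_matrix({"p": [1, 2]}, {"p": "target"}, assays=["a1", "a2"])
        with pytest.raises(ValueError, match="negative"):
            background_correct(m)

    def test_floor_is_global_minimum(self, counts_run):
        m, _, _ = counts_run
        out = background_correct(m)
        assert (out.counts.to_numpy() >= 0.1).all()

    def test_rank_order_preserved_within_assay(self, counts_run):
        m, _, _ = counts_run
        out = background_correct(m)
        common = out.counts.index
        for assay in m.assays[:3]:
            raw = m.counts.loc[common, assay]
            cor = out.counts.loc[common, assay]
            above = cor > 0.1  # floored values collapse ties by design
            assert (
                raw[above].rank(method="average")
                == cor[above].rank(method="average")
            ).all()


class TestGeNorm:
    def test_proportional_genes_have_zero_m(self):
        counts = pd.DataFrame(
            {"a1": [2, 4], "a2": [4, 8], "a3": [8, 16]},
            index=["g1", "g2"],
        ).astype(float)
        m = _pairwise_m(np.log2(counts))
        assert m["g1"] == pytest.approx(0.0)
        assert m["g2"] == pytest.approx(0.0)

    def test_m_matches_brute_force_formula(self):
        rng = np.random.default_rng(42)
        counts = pd.DataFrame(
            rng.integers(50, 5000, size=(4, 4)).astype(float),
            index=[f"g{i}" for i in range(4)],
            columns=[f"a{i}" for i in range(4)],
        )
        info = pd.DataFrame(
            {"gene_id": counts.index, "probe_class": "housekeeping"},
            index=counts.index,
        )
        res = genorm_stability(CountMatrix(counts, info), m_cutoff=10.0)
        expected = brute_force_m(counts)
        for g, want in expected.items():
            assert res.m_values[g] == pytest.approx(want)

    def test_m_invariant_under_per_assay_scaling(self):
        rng = np.random.default_rng(7)
        counts = pd.DataFrame(
            rng.uniform(100, 1000, size=(5, 6)),
            index=[f"g{i}" for i in range(5)],
        )
        base = _pairwise_m(np.log2(counts))
        scaled = counts.copy()
        scaled.iloc[:, 2] *= 37.5  # multiply one assay by a constant
        after = _pairwise_m(np.log2(scaled))
        assert np.allclose(base.to_numpy(), after.to_numpy())

    def test_planted_stability_order_recovered(self):
        rng = np.random.default_rng(0)
        sigmas = [0.05, 0.15, 0.30, 0.50, 0.80]
        counts = pd.DataFrame(
            [1000 * np.exp(rng.normal(0, s, size=30)) for s in sigmas],
            index=[f"hk{i}" for i in range(5)],
        )
        m = _pairwise_m(np.log2(counts))
        assert list(m.sort_values().index) == [f"hk{i}" for i in range(5)]

    def test_nf_geometric_mean_is_one(self, counts_run):
        m, _, _ = counts_run
        res = genorm_stability(background_correct(m))
        nf = res.normalization_factors.to_numpy()
        assert np.exp(np.mean(np.log(nf))) == pytest.approx(1.0, abs=1e-9)

    def test_fallback_when_too_few_selected(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            [500 * np.exp(rng.normal(0, 1.5, size=10)) for _ in range(4)],
            index=[f"g{i}" for i in range(4)],
        )
        info = pd.DataFrame(
            {"gene_id": counts.index, "probe_class": "housekeeping"},
            index=counts.index,
        )
        with pytest.warns(UserWarning, match="falling back"):
            res = genorm_stability(CountMatrix(counts, info))
        assert len(res.selected) == 2

    def test_too_few_genes_error(self):
        counts = pd.DataFrame({"a1": [1, 2], "a2": [2, 4]}, index=["g1", "g2"])
        info = pd.DataFrame(
            {"gene_id": ["g1", "g2"], "probe_class": "housekeeping"},
            index=counts.index,
        )
        with pytest.raises(ValueError, match="≥3"):
            genorm_stability(CountMatrix(counts.astype(float), info))

    def test_iterative_ranking_finds_noisiest_first(self):
        rng = np.random.default_rng(1)
        sigmas = {"stable1": 0.05, "stable2": 0.06, "mid": 0.3, "noisy": 1.0}
        counts = pd.DataFrame(
            {g: 800 * np.exp(rng.normal(0, s, size=40)) for g, s in sigmas.items()}
        ).T
        ranking = genorm_iterative_ranking(counts)
        assert ranking[0] == "noisy"
        assert set(ranking[-2:]) == {"stable1", "stable2"}


class TestNormalize:
    def test_raw_nf_rescaling(self):
        # reference genes with per-assay geomeans 2 and 8 → NFs 0.5 and 2
        counts = pd.DataFrame(
            {"a1": [2, 2, 2, 100], "a2": [8, 8, 8, 100]},
            index=["hk1", "hk2", "hk3", "t1"],
        ).astype(float)
        info = pd.DataFrame(
            {"gene_id": counts.index,
             "probe_class": ["housekeeping"] * 3 + ["target"]},
            index=counts.index,
        )
        m = CountMatrix(counts, info)
        g = genorm_stability(pd.DataFrame(counts.loc[["hk1", "hk2", "hk3"]]))
        assert g.normalization_factors["a1"] == pytest.approx(0.5)
        assert g.normalization_factors["a2"] == pytest.approx(2.0)
        out = normalize_counts(m, g)
        assert out.counts.loc["t1", "a1"] == pytest.approx(200.0)
        assert out.counts.loc["t1", "a2"] == pytest.approx(50.0)

    def test_unit_nf_is_identity(self, counts_run):
        m, _, _ = counts_run
        from krabkit.ncounter import GeNormResult

        nf = pd.Series(1.0, index=m.assays)
        g = GeNormResult(pd.Series(dtype=float), [], nf, 0.5)
        out = normalize_counts(m, g)
        assert np.allclose(out.counts.to_numpy(), m.counts.to_numpy())

    def test_reference_geomean_constant_after_normalization(self, counts_run):
        m, _, _ = counts_run
        corrected = background_correct(m)
        g = genorm_stability(corrected)
        out = normalize_counts(corrected, g)
        ref = out.counts.loc[g.selected]
        geomeans = np.exp(np.log(ref.to_numpy()).mean(axis=0))
        assert np.allclose(geomeans, geomeans[0], rtol=1e-6)

    def test_nonpositive_nf_errors(self, counts_run):
        m, _, _ = counts_run
        from krabkit.ncounter import GeNormResult

        nf = pd.Series(1.0, index=m.assays)
        nf.iloc[0] = -1.0
        g = GeNormResult(pd.Series(dtype=float), [], nf, 0.5)
        with pytest.raises(ValueError, match="positive"):
            normalize_counts(m, g)


class TestSummarizeExpression:
    def make_simple(self, values):
        """One gene over 4 cell types, 1 replicate each is disallowed, use 2."""
        assays, design_rows = [], []
        cols = {}
        for ct, (g1, g2) in values.items():
            for r in (1, 2):
                aid = f"{ct}_r{r}"
                assays.append(aid)
                design_rows.append(
                    {"assay_id": aid, "cell_type": ct, "replicate": r,
                     "group": "G1"}
                )
                cols[aid] = [g1 if r == 1 else g2]
        counts = pd.DataFrame(cols, index=["gene"]).astype(float)
        info = pd.DataFrame(
            {"gene_id": ["gene"], "probe_class": ["target"]}, index=["gene"]
        )
        design = AssayDesign(pd.DataFrame(design_rows).set_index("assay_id"))
        return CountMatrix(counts, info), design

    def test_relative_log2_of_known_means(self):
        m, d = self.make_simple(
            {"c1": (2, 2), "c2": (2, 2), "c3": (8, 8), "c4": (8, 8)}
        )
        t = summarize_expression(m, d)
        assert np.allclose(
            t.relative_log2.loc["gene"].to_numpy(), [-1, -1, 1, 1]
        )
        assert t.relative_log2.loc["gene"].sum() == pytest.approx(0.0, abs=1e-9)

    def test_threshold_is_strict(self):
        m, d = self.make_simple(
            {"c1": (100, 100), "c2": (1, 1), "c3": (1, 1), "c4": (1, 1)}
        )
        assert summarize_expression(m, d, threshold=99).expressed["gene"]
        m2, d2 = self.make_simple(
            {"c1": (99, 99), "c2": (1, 1), "c3": (1, 1), "c4": (1, 1)}
        )
        assert not summarize_expression(m2, d2, threshold=99).expressed["gene"]

    def test_replicate_averaging(self):
        m, d = self.make_simple(
            {"c1": (10, 30), "c2": (10, 10), "c3": (10, 10), "c4": (10, 10)}
        )
        t = summarize_expression(m, d)
        assert t.means.loc["gene", "c1"] == pytest.approx(20.0)

    def test_row_sums_zero_on_synthetic_run(self, normalized_run):
        m, design, _ = normalized_run
        t = summarize_expression(m, design)
        assert np.allclose(t.relative_log2.sum(axis=1).to_numpy(), 0.0, atol=1e-9)


class TestSampleCorrelation:
    def test_duplicated_profiles_correlate_perfectly_and_merge_first(
        self, normalized_run
    ):
        m, design, _ = normalized_run
        t = summarize_expression(m, design)
        rel = t.relative_log2.copy()
        rel["dup"] = rel[rel.columns[0]]
        t.relative_log2 = rel
        t.gene_info = t.gene_info
        corr, order = sample_correlation(t)
        first = rel.columns[0]
        assert corr.loc[first, "dup"] == pytest.approx(1.0)
        assert abs(order.index(first) - order.index("dup")) == 1

    def test_affine_profiles_cluster_together(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=30)
        rel = pd.DataFrame(
            {
                "s1": base,
                "s2": 2.0 * base + 1.0,  # affine transform of s1
                "s3": rng.normal(size=30),
            }
        )
        from krabkit.ncounter import ExpressionTable

        t = ExpressionTable(
            means=rel, relative_log2=rel, expressed=pd.Series(True, index=rel.index),
            threshold=99.0, gene_info=None,
        )
        corr, order = sample_correlation(t, probe_class=None)
        assert corr.loc["s1", "s2"] == pytest.approx(1.0)
        assert abs(order.index("s1") - order.index("s2")) == 1

    def test_matrix_is_symmetric_unit_diagonal_bounded(self, normalized_run):
        m, design, _ = normalized_run
        corr, _ = sample_correlation(summarize_expression(m, design))
        arr = corr.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 1.0)
        assert (arr >= -1 - 1e-12).all() and (arr <= 1 + 1e-12).all()

    def test_zero_variance_sample_errors_with_name(self):
        rel = pd.DataFrame({"flat": [1.0, 1.0, 1.0], "ok": [1.0, 2.0, 3.0]})
        from krabkit.ncounter import ExpressionTable

        t = ExpressionTable(
            means=rel, relative_log2=rel,
            expressed=pd.Series(True, index=rel.index), threshold=99.0,
            gene_info=None,
        )
        with pytest.raises(ValueError, match="flat"):
            sample_correlation(t, probe_class=None)


class TestDifferentialGroups:
    def test_identical_values_are_housekeeping_like(self, counts_run):
        m, design, _ = counts_run
        counts = m.counts.copy()
        counts.iloc[0, :] = 500.0  # flatten one target gene
        flat = CountMatrix(counts, m.probe_info)
        calls = differential_groups(flat, design)
        call = next(c for c in calls if c.gene_id == counts.index[0])
        assert call.category == "housekeeping-like"

    def test_planted_fourfold_called_pluripotent(self, normalized_run):
        m, design, truth = normalized_run
        calls = differential_groups(m, design)
        probe_to_gene = m.probe_info["gene_id"].to_dict()
        called = {
            probe_to_gene[c.gene_id]
            for c in calls
            if c.category == "pluripotency-associated"
        }
        effect_genes = set(truth.per_item["effects"])
        sensitivity = len(called & effect_genes) / len(effect_genes)
        assert sensitivity >= 0.9

    def test_planted_inverse_fold_called_non_pluripotent(self):
        counts, info, design, _ = simulate.gen_counts(
            n_targets=30, effects={"SYNG0000": 0.25, "SYNG0001": 0.25}, seed=4
        )
        m = CountMatrix(counts, info)
        calls = differential_groups(m, AssayDesign(design))
        probe_to_gene = info["gene_id"].to_dict()
        cats = {
            probe_to_gene[c.gene_id]: c.category
            for c in calls
            if probe_to_gene[c.gene_id] in ("SYNG0000", "SYNG0001")
        }
        assert set(cats.values()) == {"non-pluripotent-associated"}

    def test_small_fold_never_differential(self):
        # planted 1.5-fold: significance is irrelevant, fold filter blocks it
        counts, info, design, _ = simulate.gen_counts(
            n_targets=20, effects={"SYNG0000": 1.5}, cv=0.01, seed=9
        )
        calls = differential_groups(CountMatrix(counts, info), AssayDesign(design))
        probe = info.index[info["gene_id"] == "SYNG0000"][0]
        call = next(c for c in calls if c.gene_id == probe)
        assert call.category not in (
            "pluripotency-associated", "non-pluripotent-associated",
        )

    def test_null_simulation_false_positive_rate(self):
        counts, info, design, _ = simulate.gen_counts(
            n_targets=1000, effects={}, seed=21
        )
        calls = differential_groups(CountMatrix(counts, info), AssayDesign(design))
        fp = sum(
            c.category in ("pluripotency-associated", "non-pluripotent-associated")
            for c in calls
        )
        # ≤ α plus 3-sigma binomial slack at n=1000, p=0.05
        assert fp / len(calls) <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 1000)
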