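"""SNP filtering, the genotype-mixture EM and doublet/origin calling."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from scorigin import (
    ConfigError,
    DataError,
    DemuxSpec,
    GenotypeModel,
    call_doublets,
    cell_loglik,
    filter_snps,
    fit_mixture,
    label_origins,
    simulate_allele_counts,
)
from conftest import make_allele_counts


class TestFilterSnps:
    def test_boundary_inclusive_at_default_threshold(self):
        a = make_allele_counts(
            np.ones((2, 4)), np.zeros((2, 4)), maf=[0.01, 0.09, 0.10, 0.25]
        )
        kept = filter_snps(a)
        assert kept.n_variants == 3
        assert kept.variants["maf"].tolist() == [0.01, 0.09, 0.10]

    def test_permissive_threshold_keeps_all_covered(self):
        a = make_allele_counts(
            np.ones((2, 4)), np.zeros((2, 4)), maf=[0.01, 0.09, 0.10, 0.25]
        )
        assert filter_snps(a, max_maf=50).n_variants == 4

    def test_zero_coverage_variant_dropped(self):
        ref = np.array([[1, 0], [2, 0]])
        a = make_allele_counts(ref, np.zeros_like(ref), maf=[0.05, 0.05])
        kept = filter_snps(a)
        assert kept.n_variants == 1
        assert kept.variants["pos"].tolist() == [1]

    def test_nothing_survives_is_actionable_error(self):
        a = make_allele_counts(np.ones((2, 2)), np.zeros((2, 2)), maf=[0.3, 0.4])
        with pytest.raises(DataError, match="max-maf"):
            filter_snps(a)


class TestCellLoglik:
    def test_hom_alt_single_read(self):
        ll = cell_loglik([0], [1], [1.0], eps=0.01)
        assert ll == pytest.approx(math.log(0.99))

    def test_het_symmetry(self):
        for eps in (0.01, 0.1, 0.3):
            ll = cell_loglik([1], [1], [0.5], eps=eps)
            assert ll == pytest.approx(2 * math.log(0.5))

    def test_invalid_error_rate(self):
        with pytest.raises(ConfigError):
            cell_loglik([1], [1], [0.5], eps=0.7)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_read_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.integers(1, 8)
        ref = rng.integers(0, 6, v)
        alt = rng.integers(0, 6, v)
        while ref.sum() + alt.sum() > 50:
            alt = alt // 2
        dosage = rng.choice([0.0, 0.5, 1.0], v)
        eps = 0.01
        expected = 0.0
        for j in range(v):
            p = dosage[j] * (1 - eps) + (1 - dosage[j]) * eps
            for _ in range(int(alt[j])):
                expected += math.log(p)
            for _ in range(int(ref[j])):
                expected += math.log(1 - p)
        assert cell_loglik(ref, alt, dosage, eps) == pytest.approx(expected, rel=1e-12)


class TestFitMixture:
    def test_single_origin_is_pooled_argmax(self):
        ref = np.array([[5, 0, 1], [4, 0, 1]])
        alt = np.array([[0, 5, 1], [0, 6, 1]])
        a = make_allele_counts(ref, alt)
        model, resp = fit_mixture(a, n_origins=1, seed=0)
        np.testing.assert_array_equal(resp, np.ones((2, 1)))
        # pooled: v0 ref-only -> 0; v1 alt-only -> 1; v2 balanced -> 0.5
        np.testing.assert_array_equal(model.dosages[0], [0.0, 1.0, 0.5])

    def test_loglik_nondecreasing_and_recovery(self):
        sim = simulate_allele_counts(DemuxSpec(n_cells=100, n_snps=200, seed=3))
        a = filter_snps(sim.counts)
        model, resp = fit_mixture(a, n_origins=2, seed=3)
        trace = np.array(model.loglik_trace)
        assert (np.diff(trace) >= -1e-9).all()
        assert model.converged
        labels = resp.argmax(axis=1).astype(str)
        truth = sim.truth.set_index("barcode")
        singlets = ~truth.loc[a.barcodes, "doublet"].to_numpy()
        true_origin = truth.loc[a.barcodes, "origin"].to_numpy()
        accs = [
            (np.array([str(p[int(l)]) for l in labels])[singlets]
             == true_origin[singlets]).mean()
            for p in itertools.permutations(range(2))
        ]
        assert max(accs) >= 0.98

    def test_duplicated_cells_leave_dosages_unchanged(self):
        sim = simulate_allele_counts(
            DemuxSpec(n_cells=60, n_snps=100, doublet_rate=0.0, seed=5)
        )
        a = filter_snps(sim.counts)
        doubled = make_allele_counts(
            np.vstack([a.ref_counts.toarray()] * 2),
            np.vstack([a.alt_counts.toarray()] * 2),
            maf=a.variants["maf"].to_numpy(),
            barcodes=[f"d{i}" for i in range(2 * a.n_cells)],
        )
        m1, _ = fit_mixture(a, n_origins=2, seed=5)
        m2, _ = fit_mixture(doubled, n_origins=2, seed=5)
        match = [
            (m1.dosages == m2.dosages[list(p)]).mean()
            for p in itertools.permutations(range(2))
        ]
        assert max(match) == 1.0

    def test_origin_permutation_equivariance(self):
        sim = simulate_allele_counts(DemuxSpec(n_cells=50, n_snps=80, seed=7))
        a = filter_snps(sim.counts)
        model, resp = fit_mixture(a, n_origins=2, seed=7)
        swapped = GenotypeModel(
            model.dosages[::-1], model.mix_weights[::-1],
            model.error_rate, model.doublet_rate,
        )
        r1 = call_doublets(a, model)
        r2 = call_doublets(a, swapped)
        np.testing.assert_allclose(
            r1["posterior_origin_0"], r2["posterior_origin_1"], atol=1e-12
        )
        np.testing.assert_allclose(
            r1["posterior_doublet"], r2["posterior_doublet"], atol=1e-12
        )

    def test_invalid_n_origins(self):
        a = make_allele_counts(np.ones((3, 2)), np.zeros((3, 2)))
        with pytest.raises(ConfigError):
            fit_mixture(a, n_origins=0)


class TestCallDoublets:
    @pytest.fixture()
    def two_origin_model(self):
        # 40 discriminating variants: origin 0 hom-ref, origin 1 hom-alt
        v = 40
        dosages = np.vstack([np.zeros(v), np.ones(v)])
        return GenotypeModel(dosages, np.array([0.5, 0.5]))

    def test_pure_cell_called_confidently(self, two_origin_model):
        v = two_origin_model.dosages.shape[1]
        a = make_allele_counts(
            np.full((1, v), 3), np.zeros((1, v)), maf=np.full(v, 0.05)
        )
        res = call_doublets(a, two_origin_model)
        assert res.loc[0, "call"] == "0"
        assert res.loc[0, "posterior_origin_0"] > 0.99

    def test_mixed_cell_called_doublet(self, two_origin_model):
        v = two_origin_model.dosages.shape[1]
        rng = np.random.default_rng(0)
        depth = rng.poisson(4.0, v)
        alt = rng.binomial(depth, 0.5)  # 50/50 genetic mixture
        a = make_allele_counts((depth - alt)[None, :], alt[None, :],
                               maf=np.full(v, 0.05))
        res = call_doublets(a, two_origin_model)
        assert res.loc[0, "call"] == "doublet"

    def test_zero_coverage_posterior_equals_prior(self, two_origin_model):
        v = two_origin_model.dosages.shape[1]
        a = make_allele_counts(np.zeros((1, v)), np.zeros((1, v)),
                               maf=np.full(v, 0.05))
        res = call_doublets(a, two_origin_model)
        assert res.loc[0, "call"] == "ambiguous"
        assert res.loc[0, "posterior_origin_0"] == pytest.approx(0.95 * 0.5)
        assert res.loc[0, "posterior_doublet"] == pytest.approx(0.05)

    def test_posteriors_sum_to_one(self):
        sim = simulate_allele_counts(DemuxSpec(n_cells=40, n_snps=60, seed=9))
        a = filter_snps(sim.counts)
        model, _ = fit_mixture(a, n_origins=2, seed=9)
        res = call_doublets(a, model)
        total = (
            res[["posterior_origin_0", "posterior_origin_1", "posterior_doublet"]]
            .sum(axis=1)
            .to_numpy()
        )
        np.testing.assert_allclose(total, 1.0, atol=1e-9)

    def test_single_origin_model_rejected(self):
        a = make_allele_counts(np.ones((2, 3)), np.zeros((2, 3)))
        model = GenotypeModel(np.zeros((1, 3)), np.array([1.0]))
        with pytest.raises(ConfigError):
            call_doublets(a, model)


class TestLabelOrigins:
    def _results(self, calls):
        return pd.DataFrame(
            {"barcode": [f"c{i}" for i in range(len(calls))], "call": calls}
        )

    def _ann(self, types):
        return pd.DataFrame(
            {"barcode": [f"c{i}" for i in range(len(types))], "cell_type": types}
        )

    def test_majority_anchor_assigns_labels(self):
        calls = ["1"] * 19 + ["0"] + ["0"] * 10 + ["doublet"]
        types = ["trophoblast"] * 20 + ["T-cells"] * 11
        out = label_origins(self._results(calls), self._ann(types),
                            "trophoblast", "fetal", "maternal")
        assert out.loc[out["call"] == "1", "origin_label"].unique().tolist() == ["fetal"]
        assert out.loc[out["call"] == "0", "origin_label"].unique().tolist() == ["maternal"]
        assert out.loc[out["call"] == "doublet", "origin_label"].tolist() == ["doublet"]

    def test_absent_anchor_type_is_error(self):
        with pytest.raises(DataError, match="absent"):
            label_origins(self._results(["0", "1"]), self._ann(["T-cells"] * 2),
                          "trophoblast", "fetal")

    def test_even_split_is_error(self):
        calls = ["0"] * 5 + ["1"] * 5
        types = ["trophoblast"] * 10
        with pytest.raises(DataError, match="manual"):
            label_origins(self._results(calls), self._ann(types),
                          "trophoblast", "fetal")
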