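"""Bag-of-alleles aggregation: coverage filtering, the weighted-average
equation against brute-force oracles, and its convexity/permutation
invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ricegxw.alleles import (
    CVGDefinition,
    GenotypeMatrix,
    bag_of_alleles,
    coverage_filter,
    cvg_frequencies,
)
from ricegxw.io import read_genotypes_tsv, read_genotypes_vcf, write_genotypes_tsv


def make_genotypes(calls: np.ndarray, missing=None) -> GenotypeMatrix:
    calls = np.asarray(calls, float)
    if missing is not None:
        calls[missing] = np.nan
    n_v, n_m = calls.shape
    idx = pd.Index([f"V{i}" for i in range(n_v)], name="variety")
    meta = pd.DataFrame({"release_year": 2000 + np.arange(n_v)}, index=idx)
    return GenotypeMatrix(
        calls=pd.DataFrame(calls, index=idx, columns=[f"M{j}" for j in range(n_m)]),
        meta=meta,
    )


def acreage_rows(*rows):
    return pd.DataFrame(rows, columns=["county", "year", "variety", "acres"])


class TestGenotypeMatrix:
    def test_rejects_heterozygous_coding(self):
        with pytest.raises(ValueError, match="0, 1 or missing"):
            make_genotypes([[0.0, 0.5], [1.0, 1.0]])

    def test_rejects_duplicate_variety_ids(self):
        g = make_genotypes([[0, 1], [1, 0]])
        dup = g.calls.copy()
        dup.index = pd.Index(["V0", "V0"], name="variety")
        with pytest.raises(ValueError, match="unique"):
            GenotypeMatrix(calls=dup, meta=g.meta.set_index(dup.index))

    def test_strict_policy_raises_on_missing(self):
        g = make_genotypes([[0, 1], [1, 0]], missing=(0, 0))
        with pytest.raises(ValueError, match="missing"):
            g.imputed_calls("strict")

    def test_mean_imputation_uses_marker_mean(self):
        g = make_genotypes([[0, 1], [1, 0], [1, 1]], missing=(0, 0))
        filled = g.imputed_calls("mean")
        assert filled.iloc[0, 0] == pytest.approx(1.0)  # mean of the other two


class TestCoverageFilter:
    def test_exactly_at_threshold_retained(self):
        # 5 varieties, 4 genotyped: coverage 0.8 is inclusive
        g = make_genotypes(np.ones((4, 3)))
        acr = acreage_rows(*[("A", 2000, f"V{i}", 100.0) for i in range(4)],
                           ("A", 2000, "UNG", 100.0))
        filtered, report = coverage_filter(acr, g, threshold=0.8, mode="count")
        assert report["retained"].all()
        assert set(filtered["variety"]) == {f"V{i}" for i in range(4)}

    def test_no_genotyped_varieties_dropped(self):
        g = make_genotypes(np.ones((2, 3)))
        acr = acreage_rows(("A", 2000, "X1", 50.0), ("A", 2000, "X2", 50.0))
        filtered, report = coverage_filter(acr, g)
        assert not report["retained"].any()
        assert filtered.empty

    def test_acreage_vs_count_mode_disagree(self):
        # acres 60/25/15 with the 15-acre variety ungenotyped:
        # acreage coverage 0.85 (retained), count coverage 2/3 (dropped)
        g = make_genotypes(np.ones((2, 3)))
        acr = acreage_rows(
            ("A", 2000, "V0", 60.0), ("A", 2000, "V1", 25.0), ("A", 2000, "UNG", 15.0)
        )
        _, rep_acreage = coverage_filter(acr, g, mode="acreage")
        assert rep_acreage["coverage"].iloc[0] == pytest.approx(0.85)
        assert rep_acreage["retained"].iloc[0]
        _, rep_count = coverage_filter(acr, g, mode="count")
        assert rep_count["coverage"].iloc[0] == pytest.approx(2 / 3)
        assert not rep_count["retained"].iloc[0]

    def test_validation(self):
        g = make_genotypes(np.ones((2, 2)))
        with pytest.raises(ValueError):
            coverage_filter(acreage_rows(), g)
        with pytest.raises(ValueError):
            coverage_filter(acreage_rows(("A", 2000, "V0", 1.0)), g, threshold=1.5)
        with pytest.raises(ValueError):
            coverage_filter(acreage_rows(("A", 2000, "V0", 1.0)), g, mode="area")


class TestBagOfAlleles:
    def test_single_variety_identity(self):
        g = make_genotypes([[1, 0, 1]])
        acr = acreage_rows(("A", 2000, "V0", 500.0))
        out = bag_of_alleles(acr, g)
        assert np.allclose(out.freqs.iloc[0], [1.0, 0.0, 1.0])

    def test_two_varieties_weighted(self):
        g = make_genotypes([[1], [0]])
        acr = acreage_rows(("A", 2000, "V0", 300.0), ("A", 2000, "V1", 100.0))
        out = bag_of_alleles(acr, g)
        assert out.freqs.iloc[0, 0] == pytest.approx(0.75)

    def test_ungenotyped_variety_raises(self):
        g = make_genotypes([[1, 0]])
        acr = acreage_rows(("A", 2000, "V0", 1.0), ("A", 2000, "GHOST", 1.0))
        with pytest.raises(KeyError, match="GHOST"):
            bag_of_alleles(acr, g)

    def test_totals_mode_leaves_share_unnormalized(self):
        g = make_genotypes([[1]])
        acr = acreage_rows(("A", 2000, "V0", 80.0))
        totals = pd.Series([100.0], index=pd.MultiIndex.from_tuples(
            [("A", 2000)], names=["county", "year"]))
        out = bag_of_alleles(acr, g, totals=totals)
        assert out.freqs.iloc[0, 0] == pytest.approx(0.8)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_double_loop_oracle(self, seed):
        """Vectorized aggregation equals the explicit summation over
        varieties and markers on random small instances."""
        rng = np.random.default_rng(seed)
        n_v, n_m = rng.integers(2, 11), rng.integers(1, 21)
        g = make_genotypes(rng.integers(0, 2, size=(n_v, n_m)))
        rows = [("A", 2001, f"V{i}", float(rng.uniform(1, 1000))) for i in range(n_v)]
        acr = acreage_rows(*rows)
        out = bag_of_alleles(acr, g).freqs.iloc[0]

        acres = np.array([r[3] for r in rows])
        props = acres / acres.sum()
        for j in range(n_m):
            expected = sum(props[i] * g.calls.iloc[i, j] for i in range(n_v))
            assert out.iloc[j] == pytest.approx(expected)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_convexity_and_permutation_invariance(self, seed):
        """Frequencies stay within the convex hull of contributing calls and
        are unchanged by reordering varieties or markers."""
        rng = np.random.default_rng(seed)
        n_v, n_m = int(rng.integers(2, 8)), int(rng.integers(1, 12))
        calls = rng.integers(0, 2, size=(n_v, n_m)).astype(float)
        g = make_genotypes(calls)
        acr = acreage_rows(
            *[("A", 2000, f"V{i}", float(rng.uniform(1, 100))) for i in range(n_v)]
        )
        out = bag_of_alleles(acr, g).freqs.iloc[0]
        assert (out >= calls.min(axis=0) - 1e-12).all()
        assert (out <= calls.max(axis=0) + 1e-12).all()

        perm_v = rng.permutation(n_v)
        perm_m = rng.permutation(n_m)
        g2 = GenotypeMatrix(
            calls=g.calls.iloc[perm_v, perm_m], meta=g.meta.iloc[perm_v]
        )
        out2 = bag_of_alleles(acr, g2).freqs.iloc[0]
        pd.testing.assert_series_equal(out2[out.index], out, check_names=False)

    def test_identical_genotypes_dominate_acreage(self):
        calls = np.tile([1.0, 0.0, 1.0], (4, 1))
        g = make_genotypes(calls)
        acr = acreage_rows(*[("A", 2000, f"V{i}", float(10 ** i)) for i in range(4)])
        out = bag_of_alleles(acr, g).freqs.iloc[0]
        assert np.allclose(out, [1.0, 0.0, 1.0])


class TestCVGFrequencies:
    def test_single_member_is_call_vector(self):
        g = make_genotypes([[1, 0], [0, 1]])
        f = cvg_frequencies(CVGDefinition("one", ["V0"]), g)
        assert np.allclose(f, [1.0, 0.0])

    def test_two_members_average(self):
        g = make_genotypes([[1], [0]])
        f = cvg_frequencies(CVGDefinition("two", ["V0", "V1"]), g)
        assert f.iloc[0] == pytest.approx(0.5)

    def test_matches_column_means(self):
        rng = np.random.default_rng(0)
        g = make_genotypes(rng.integers(0, 2, size=(20, 15)))
        members = [f"V{i}" for i in range(20)]
        f = cvg_frequencies(CVGDefinition("all", members), g)
        assert np.allclose(f, g.calls.mean(axis=0))

    def test_empty_members_raise(self):
        g = make_genotypes([[1]])
        with pytest.raises(ValueError, match="no members"):
            cvg_frequencies(CVGDefinition("empty", []), g)

    def test_weights_validated(self):
        with pytest.raises(ValueError):
            CVGDefinition("bad", ["V0", "V1"], weights=np.array([0.7, 0.7]))
        with pytest.raises(ValueError):
            CVGDefinition("neg", ["V0", "V1"], weights=np.array([1.5, -0.5]))


class TestGenotypeIO:
    def test_tsv_roundtrip(self, tmp_path, tiny_system):
        g = tiny_system["observed"]
        write_genotypes_tsv(g, tmp_path / "calls.tsv", tmp_path / "meta.csv")
        back = read_genotypes_tsv(tmp_path / "calls.tsv", tmp_path / "meta.csv")
        pd.testing.assert_frame_equal(back.calls, g.calls)
        assert (back.meta["release_year"] == g.meta["release_year"]).all()

    def _write_vcf(self, path, body):
        header = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tV0\tV1\n"
        )
        path.write_text(header + body)

    def test_vcf_binary_collapse(self, tmp_path):
        vcf = tmp_path / "g.vcf"
        self._write_vcf(
            vcf,
            "1\t100\tM0\tA\tT\t.\tPASS\t.\tGT\t0/0\t1/1\n"
            "1\t200\tM1\tG\tC\t.\tPASS\t.\tGT\t1/1\t./.\n",
        )
        meta = tmp_path / "meta.csv"
        meta.write_text("variety,release_year\nV0,1990\nV1,2000\n")
        g = read_genotypes_vcf(vcf, meta)
        assert g.calls.loc["V0", "M0"] == 0.0
        assert g.calls.loc["V1", "M0"] == 1.0
        assert np.isnan(g.calls.loc["V1", "M1"])

    def test_vcf_heterozygous_rejected(self, tmp_path):
        vcf = tmp_path / "het.vcf"
        self._write_vcf(vcf, "1\t100\tM0\tA\tT\t.\tPASS\t.\tGT\t0/1\t1/1\n")
        meta = tmp_path / "meta.csv"
        meta.write_text("variety,release_year\nV0,1990\nV1,2000\n")
        with pytest.raises(ValueError, match="homozygous"):
            read_genotypes_vcf(vcf, meta)
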