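import math

import numpy as np
import pandas as pd
import pytest

from sweepscan.core import annotate_sites
from sweepscan.ihs import (
    EhhCurve,
    ehh,
    ihh,
    ihs_scan,
    select_cores,
    standardize,
)
from tests.conftest import ehh_bruteforce, make_hapset


class TestEhh:
    def test_core_only_is_one(self):
        haps = np.array([[0, 1, 0], [0, 1, 1], [1, 1, 0]], dtype=np.uint8)
        pos = np.array([0, 100, 200])
        curve = ehh(haps, pos, core_idx=1, core_allele=1)
        assert curve.left_ehh[0] == 1.0
        assert curve.right_ehh[0] == 1.0

    def test_four_carriers_two_pairs(self):
        # 4 carriers split 2+2 into distinct extended haplotypes:
        # EHH = (C(2,2)+C(2,2))/C(4,2) = 2/6 = 1/3
        haps = np.array(
            [[1, 0], [1, 0], [1, 1], [1, 1]], dtype=np.uint8
        )
        pos = np.array([0, 50])
        curve = ehh(haps, pos, core_idx=0, core_allele=1)
        assert curve.right_ehh == [1.0, pytest.approx(1 / 3)]

    def test_identical_carriers_edge_truncated(self):
        haps = np.tile([1, 0, 1, 0, 1], (6, 1)).astype(np.uint8)
        pos = np.arange(5) * 10
        curve = ehh(haps, pos, core_idx=2, core_allele=1)
        assert all(v == 1.0 for v in curve.left_ehh + curve.right_ehh)
        assert curve.left_truncation == "edge"
        assert curve.right_truncation == "edge"

    def test_fewer_than_two_carriers_rejected(self):
        haps = np.array([[1, 0], [0, 0], [0, 1]], dtype=np.uint8)
        with pytest.raises(ValueError, match="carriers"):
            ehh(haps, np.array([0, 10]), core_idx=0, core_allele=1)

    def test_monotone_nonincreasing_and_bounded(self, rng):
        haps = rng.integers(0, 2, size=(16, 60), dtype=np.uint8)
        haps[:, 30] = rng.permutation([1] * 8 + [0] * 8)
        pos = np.sort(rng.choice(10_000, size=60, replace=False))
        curve = ehh(haps, pos, core_idx=30, core_allele=1, cutoff=0.0)
        for vals in (curve.left_ehh, curve.right_ehh):
            assert all(0.0 <= v <= 1.0 for v in vals)
            assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_matches_pair_counting_oracle(self, rng):
        # exhaustive check on 20 haplotypes x 100 sites
        haps = rng.integers(0, 2, size=(20, 100), dtype=np.uint8)
        core = 50
        haps[:, core] = rng.permutation([1] * 9 + [0] * 11)
        pos = np.arange(100) * 37
        curve = ehh(haps, pos, core_idx=core, core_allele=1, cutoff=0.0)
        for k, val in enumerate(curve.right_ehh):
            if k == 0:
                continue
            expected = ehh_bruteforce(haps, core, 1, slice(core, core + k + 1))
            assert val == pytest.approx(expected)
        for k, val in enumerate(curve.left_ehh):
            if k == 0:
                continue
            expected = ehh_bruteforce(haps, core, 1, slice(core - k, core + 1))
            assert val == pytest.approx(expected)


class TestIhh:
    def test_rectangle(self):
        curve = EhhCurve(
            core_idx=0, core_allele="derived",
            left_offsets=[0.0], left_ehh=[1.0],
            right_offsets=[0.0, 1000.0], right_ehh=[1.0, 1.0],
        )
        assert ihh(curve) == pytest.approx(1000.0)

    def test_hand_trapezoid_with_crossing(self):
        # 1 at core, 0.5 at 100 bp, 0.04 at 200 bp on each flank.
        # Trapezoid to 100: 75. Crossing of 0.05 between (100, 0.5) and
        # (200, 0.04): at 100 + 0.45/0.46*100; tail trapezoid
        # (0.5+0.05)/2 * that distance.
        d = 0.45 / 0.46 * 100
        per_flank = 75.0 + (0.5 + 0.05) / 2 * d
        curve = EhhCurve(
            core_idx=0, core_allele="derived",
            left_offsets=[0.0, 100.0, 200.0], left_ehh=[1.0, 0.5, 0.04],
            right_offsets=[0.0, 100.0, 200.0], right_ehh=[1.0, 0.5, 0.04],
        )
        assert ihh(curve) == pytest.approx(2 * per_flank)

    def test_symmetric_curves_give_zero_raw_score(self):
        curve = EhhCurve(
            core_idx=0, core_allele="derived",
            left_offsets=[0.0, 500.0], left_ehh=[1.0, 0.5],
            right_offsets=[0.0, 500.0], right_ehh=[1.0, 0.5],
        )
        assert math.log(ihh(curve) / ihh(curve)) == 0.0

    def test_degenerate_curve_rejected(self):
        curve = EhhCurve(
            core_idx=0, core_allele="derived",
            left_offsets=[0.0], left_ehh=[1.0],
            right_offsets=[0.0], right_ehh=[1.0],
        )
        with pytest.raises(ValueError):
            ihh(curve)


class TestSelectCores:
    def _hapset(self):
        rng = np.random.default_rng(7)
        alleles = rng.integers(0, 2, size=(30, 40), dtype=np.uint8)
        # craft site 0: breed MAF exactly 0.2 (4/20); site 1: MAF 0.35
        alleles[:20, 0] = [1] * 4 + [0] * 16
        alleles[:20, 1] = [1] * 7 + [0] * 13
        alleles[20:, 0] = 0
        alleles[20:, 1] = 0
        # site 2: ambiguous in outgroup (5/10)
        alleles[:20, 2] = [1] * 8 + [0] * 12
        alleles[20:, 2] = [1] * 5 + [0] * 5
        alleles[0, 3:] = 1
        alleles[1, 3:] = 0
        alleles[20, 3:] = 1  # keep sites polymorphic overall
        pops = np.array(["b"] * 20 + ["outgroup"] * 10)
        return make_hapset(alleles, populations=pops)

    def test_maf_boundary_is_strict(self):
        haps = self._hapset()
        ann = annotate_sites(haps, "outgroup")
        cores = select_cores(haps, ann, "b", maf_min=0.2)
        assert 0 not in cores  # MAF exactly 0.2 excluded
        assert 1 in cores  # MAF 0.35 included

    def test_ambiguous_polarization_excluded(self):
        haps = self._hapset()
        ann = annotate_sites(haps, "outgroup")
        cores = select_cores(haps, ann, "b", maf_min=0.2)
        assert 2 not in cores


class TestStandardize:
    @staticmethod
    def _records(rng, n=400):
        return pd.DataFrame(
            {
                "chrom": "1",
                "site": np.arange(n),
                "pos": np.arange(n) * 100,
                "derived_freq": rng.uniform(0.21, 0.79, size=n),
                "ihh_a": 1.0,
                "ihh_d": 1.0,
                "raw_ihs": rng.normal(size=n),
                "edge_truncated": False,
            }
        )

    def test_class_mean_zero_variance_one(self, rng):
        out = standardize(self._records(rng))
        for c, grp in out.groupby("freq_class"):
            if c < 0:
                continue
            assert grp["ihs"].mean() == pytest.approx(0.0, abs=1e-12)
            assert grp["ihs"].std(ddof=0) == pytest.approx(1.0)

    def test_against_bruteforce_per_class_zscore(self, rng):
        df = self._records(rng)
        out = standardize(df, n_bins=20, min_class_size=1)
        bins = np.clip((df["derived_freq"] * 20).astype(int), 0, 19)
        for c in bins.unique():
            sel = bins == c
            raw = df.loc[sel, "raw_ihs"]
            expected = (raw - raw.mean()) / raw.std(ddof=0)
            got = out.loc[sel.to_numpy(), "ihs"]
            np.testing.assert_allclose(got.to_numpy(), expected.to_numpy())

    def test_disjoint_classes_standardized_independently(self, rng):
        df = self._records(rng, n=200)
        df.loc[df["derived_freq"] < 0.5, "raw_ihs"] += 100.0
        out = standardize(df, min_class_size=1)
        # the +100 offset must vanish within classes
        assert abs(out["ihs"].mean()) < 0.2

    def test_small_classes_merged(self, rng):
        df = self._records(rng, n=30)
        out = standardize(df, n_bins=20, min_class_size=10)
        sizes = out[out["freq_class"] >= 0]["freq_class"].value_counts()
        assert (sizes >= 10).all() or len(sizes) == 1

    def test_zero_variance_class_flagged(self, rng):
        df = self._records(rng, n=40)
        df["raw_ihs"] = 1.5
        df["derived_freq"] = 0.4
        out = standardize(df)
        assert out["zero_variance"].all()
        assert out["ihs"].isna().all()

    def test_truncated_excluded_by_default(self, rng):
        df = self._records(rng)
        df.loc[: len(df) // 2, "edge_truncated"] = True
        out = standardize(df)
        assert out.loc[out["edge_truncated"], "ihs"].isna().all()
        out_keep = standardize(df, keep_truncated=True)
        assert out_keep["ihs"].notna().all()


class TestIhsScanInvariants:
    def test_allele_flip_invariance(self, rng):
        alleles = rng.integers(0, 2, size=(40, 120), dtype=np.uint8)
        alleles[0], alleles[1] = 0, 1
        pops = np.array(["b"] * 28 + ["outgroup"] * 12)
        haps = make_hapset(alleles, populations=pops)
        flipped = make_hapset(1 - alleles, populations=pops)
        a = ihs_scan(haps, "b", "outgroup")
        b = ihs_scan(flipped, "b", "outgroup")
        # flipping 0/1 together with polarization leaves |iHS| unchanged
        merged = a.merge(b, on="site", suffixes=("_a", "_b"))
        assert len(merged) == len(a)
        np.testing.assert_allclose(
            merged["raw_ihs_a"].abs(), merged["raw_ihs_b"].abs(), atol=1e-12
        )
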