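"""PET quantification: SUV/SUVR identities, % change, method comparison."""

import numpy as np
import pytest

from ivoiseg.core import CEREBELLUM, ImageVolume, LabelVolume, REGION_CODES, REGION_NAMES
from ivoiseg import quant
from ivoiseg.quant import QuantRecord, compare_methods, mean_count, pct_change, quantify, suv, suvr

SP = (0.8, 0.15625, 0.15625)


def _labels_volume():
    lab = np.zeros((6, 8, 8), np.uint8)
    for code in range(1, 6):
        lab[code, 1:4, 1:4] = code
    return LabelVolume(lab, SP)


def _pet_from_values(labels, values):
    pet = np.zeros(labels.shape, np.float32)
    for code, v in values.items():
        pet[labels.data == code] = v
    return ImageVolume(pet, SP)


class TestMeanCount:
    def test_uniform_volume(self):
        lab = _labels_volume()
        pet = ImageVolume(np.full(lab.shape, 7.5, np.float32), SP)
        for code in range(1, 6):
            assert mean_count(pet, lab, code) == pytest.approx(7.5)

    def test_two_voxel_average(self):
        lab = LabelVolume(np.zeros((1, 1, 2), np.uint8) + 5, SP)
        pet = ImageVolume(np.array([[[1.0, 3.0]]], np.float32), SP)
        assert mean_count(pet, lab, 5) == pytest.approx(2.0)

    def test_matches_masked_sum_oracle(self, rng):
        lab = LabelVolume(rng.integers(0, 6, (5, 5, 5)).astype(np.uint8), SP)
        pet = ImageVolume(rng.random((5, 5, 5)).astype(np.float32), SP)
        for code in range(6):
            sel = lab.data == code
            if not sel.any():
                continue
            total = sum(pet.data[idx] for idx in zip(*np.nonzero(sel)))
            assert mean_count(pet, lab, code) == pytest.approx(total / sel.sum(), rel=1e-6)

    def test_empty_region_names_it(self):
        lab = LabelVolume(np.zeros((3, 3, 3), np.uint8), SP)
        pet = ImageVolume(np.ones((3, 3, 3), np.float32), SP)
        with pytest.raises(ValueError, match="cortex"):
            mean_count(pet, lab, REGION_CODES["cortex"])


class TestSuv:
    def test_definition_unity(self):
        assert suv(5.0, injected_dose_kbq=100.0, body_weight_g=20.0) == pytest.approx(1.0)

    def test_doubling_weight_doubles_suv(self):
        a = suv(3.0, 100.0, 20.0)
        assert suv(3.0, 100.0, 40.0) == pytest.approx(2 * a)

    def test_nonpositive_inputs_raise(self):
        with pytest.raises(ValueError):
            suv(1.0, 0.0, 20.0)
        with pytest.raises(ValueError):
            suv(1.0, 100.0, -1.0)


class TestSuvr:
    def test_reference_region_is_exactly_one(self):
        lab = _labels_volume()
        pet = _pet_from_values(lab, {c: 100.0 + c for c in range(1, 6)})
        assert suvr(pet, lab, CEREBELLUM) == 1.0

    def test_direct_ratio(self):
        lab = _labels_volume()
        pet = _pet_from_values(lab, {1: 2.4, 2: 1, 3: 1, 4: 1, 5: 1.2})
        assert suvr(pet, lab, REGION_CODES["cortex"]) == pytest.approx(2.0)

    def test_suv_route_equals_count_route(self):
        lab = _labels_volume()
        pet = _pet_from_values(lab, {1: 180.0, 2: 170, 3: 190, 4: 175, 5: 150})
        ratio_counts = mean_count(pet, lab, 1) / mean_count(pet, lab, 5)
        id_kbq, bw = 5000.0, 24.0
        ratio_suv = suv(mean_count(pet, lab, 1), id_kbq, bw) / suv(
            mean_count(pet, lab, 5), id_kbq, bw
        )
        assert ratio_suv == pytest.approx(ratio_counts, abs=1e-12)

    def test_invariant_to_global_rescaling(self):
        lab = _labels_volume()
        pet = _pet_from_values(lab, {1: 180.0, 2: 170, 3: 190, 4: 175, 5: 150})
        scaled = ImageVolume(pet.data * 3.7, SP)
        for code in range(1, 5):
            assert suvr(scaled, lab, code) == pytest.approx(suvr(pet, lab, code), rel=1e-6)


class TestPctChange:
    @pytest.mark.parametrize(
        "bl, fu, expected", [(2.0, 2.0, 0.0), (2.0, 2.2, 10.0), (2.0, 1.8, -10.0)]
    )
    def test_direct_substitution(self, bl, fu, expected):
        assert pct_change(bl, fu) == pytest.approx(expected)

    def test_nonpositive_baseline_raises(self):
        with pytest.raises(ValueError):
            pct_change(0.0, 1.0)


def _records_for(methods, n_mice=5, jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    records = []
    base = {1: 180.0, 2: 170.0, 3: 190.0, 4: 175.0, 5: 150.0}
    effect = {1: 1.10, 2: 1.08, 3: 0.90, 4: 1.08, 5: 1.0}
    for m in range(n_mice):
        for session in ("BL", "FU"):
            for method in methods:
                ref = base[5] + jitter * rng.standard_normal()
                for code, region in REGION_NAMES.items():
                    c = base[code] * (effect[code] if session == "FU" else 1.0)
                    c += jitter * rng.standard_normal()
                    records.append(
                        QuantRecord(
                            mouse_id=f"m{m}",
                            session=session,
                            method=method,
                            region=region,
                            mean_count=c,
                            suv=c / 222.0,
                            suvr=c / ref,
                        )
                    )
    return records


class TestCompareMethods:
    def test_identical_methods_agree_perfectly(self):
        recs = _records_for(["DL"], jitter=1.0) + _records_for(["iGT"], jitter=1.0)
        # make iGT an exact copy of DL values
        recs = _records_for(["DL"], jitter=1.0, seed=3)
        copies = [
            QuantRecord(r.mouse_id, r.session, "iGT", r.region, r.mean_count, r.suv, r.suvr)
            for r in recs
        ]
        cmp = compare_methods(recs + copies)
        assert np.allclose(cmp.agreement["ccc_count"], 1.0)
        tests = cmp.effect_tests
        assert np.allclose(tests["t_paired"], 0.0)
        assert np.allclose(tests["p_paired"], 1.0)

    def test_constant_nonzero_differences_are_degenerate(self):
        recs = _records_for(["DL"], jitter=0.0)
        shifted = [
            QuantRecord(r.mouse_id, r.session, "iGT", r.region, r.mean_count, r.suv,
                        r.suvr * (1.02 if r.session == "FU" else 1.0))
            for r in recs
        ]
        cmp = compare_methods(recs + shifted)
        # % change differences are constant and nonzero -> zero-variance t
        assert cmp.effect_tests["t_paired"].isna().all()

    def test_welch_t_matches_closed_form(self):
        x = np.array([10.0, 12.0, 9.0, 11.0])
        y = np.array([8.0, 9.5, 7.5])
        recs = []
        for i, v in enumerate(x):
            recs.append(QuantRecord(f"m{i}", "BL", "DL", "cortex", 100.0, 1.0, 1.0))
            recs.append(QuantRecord(f"m{i}", "FU", "DL", "cortex", 100.0, 1.0, 1.0 + v / 100))
        for i, v in enumerate(y):
            recs.append(QuantRecord(f"m{i}", "BL", "iGT", "cortex", 100.0, 1.0, 1.0))
            recs.append(QuantRecord(f"m{i}", "FU", "iGT", "cortex", 100.0, 1.0, 1.0 + v / 100))
        # reference region rows so pct_change_table has the full region set
        for i in range(4):
            for meth in ("DL", "iGT"):
                if meth == "iGT" and i == 3:
                    continue
                recs.append(QuantRecord(f"m{i}", "BL", meth, "cerebellum", 150.0, 1.0, 1.0))
                recs.append(QuantRecord(f"m{i}", "FU", meth, "cerebellum", 150.0, 1.0, 1.0))
        cmp = compare_methods(recs)
        row = cmp.effect_tests.iloc[0]
        sx2, sy2 = x.var(ddof=1), y.var(ddof=1)
        t_hand = (x.mean() - y.mean()) / np.sqrt(sx2 / len(x) + sy2 / len(y))
        assert row["t_welch"] == pytest.approx(t_hand, rel=1e-12)

    def test_single_method_raises(self):
        with pytest.raises(ValueError):
            compare_methods(_records_for(["DL"]))


class TestQuantify:
    def test_records_cover_all_regions_with_unit_reference(self):
        lab = _labels_volume()
        pet = _pet_from_values(lab, {1: 180.0, 2: 170, 3: 190, 4: 175, 5: 150})
        recs = quantify(pet, lab, 5000.0, 25.0, "m01", "BL", "iGT")
        by_region = {r.region: r for r in recs}
        assert set(by_region) == set(REGION_NAMES.values())
        assert by_region["cerebellum"].suvr == 1.0
        assert by_region["cortex"].suvr == pytest.approx(180 / 150)
        assert by_region["cortex"].suv == pytest.approx(180.0 / (5000.0 / 25.0))
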