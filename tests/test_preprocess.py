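import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vfarch.fields import ABSOLUTE, CHANGE, SAP_III, SMP, TDField, VisualField, align_to_common
from vfarch.grids import COMMON_42, GridMismatchError, P24_2, build_grid
from vfarch.preprocess import (
    NormativeReference,
    PreprocessConfig,
    age_standardize,
    average_same_day,
    build_avfa_matrix,
    build_change_fields,
    build_vfca_matrix,
    censor,
    change_map,
    preprocess_fields,
    read_normative_csv,
    to_total_deviation,
    write_normative_csv,
)
from vfarch.synth import generating_reference


def sap_field(values, visit=0, age=60.0, eye="e1"):
    grid = build_grid(P24_2)
    full = np.full(54, 25.0)
    full[: len(values)] = values
    return VisualField(eye, visit, age, SAP_III, grid, full)


def td_common(values, visit=0, eye="e1", kind=ABSOLUTE, modality=SAP_III):
    grid = build_grid(COMMON_42)
    return TDField(eye, visit, 45.0, modality, grid, np.asarray(values, dtype=float),
                   kind=kind)


class TestCensor:
    def test_values_below_floor_mapped_to_floor(self):
        f = sap_field([15.0, 25.0, 20.0])
        c = censor(f, 20.0)
        assert list(c.values_db[:3]) == [20.0, 25.0, 20.0]

    def test_idempotent(self, rng):
        f = sap_field(rng.uniform(0, 35, 54))
        once = censor(f, 20.0)
        twice = censor(once, 20.0)
        np.testing.assert_array_equal(once.values_db, twice.values_db)

    def test_all_zero_field_fully_censored(self):
        grid = build_grid(P24_2)
        f = VisualField("e", 0, 60.0, SAP_III, grid, np.zeros(54))
        c = censor(f, 20.0)
        np.testing.assert_array_equal(c.values_db, np.full(54, 20.0))
        assert c.meta["censored_fraction"] == 1.0

    @settings(max_examples=25, deadline=None)
    @given(
        values=st.lists(st.floats(0, 40), min_size=54, max_size=54),
        floor=st.floats(0, 40),
    )
    def test_never_decreases_and_preserves_above_floor(self, values, floor):
        f = sap_field(np.array(values))
        c = censor(f, floor)
        assert np.all(c.values_db >= f.values_db)
        above = f.values_db >= floor
        np.testing.assert_array_equal(c.values_db[above], f.values_db[above])


class TestAgeStandardize:
    def test_reference_age_is_identity(self, gen_refs):
        ref = gen_refs[SAP_III]
        f = sap_field(np.full(54, 25.0), age=45.0)
        out = age_standardize(f, ref, 45.0)
        np.testing.assert_array_equal(out.values_db, f.values_db)

    def test_formula(self):
        grid = build_grid(P24_2)
        ref = NormativeReference(SAP_III, grid, np.full(54, 30.0), np.full(54, 0.05))
        f = VisualField("e", 0, 65.0, SAP_III, grid, np.full(54, 20.0))
        out = age_standardize(f, ref, 45.0)
        np.testing.assert_allclose(out.values_db, 21.0)
        assert out.age_years == 45.0

    def test_zero_slope_identity_any_age(self):
        grid = build_grid(P24_2)
        ref = NormativeReference(SAP_III, grid, np.full(54, 30.0), np.zeros(54))
        f = VisualField("e", 0, 82.0, SAP_III, grid, np.full(54, 17.0))
        np.testing.assert_array_equal(age_standardize(f, ref).values_db, f.values_db)

    def test_grid_mismatch_rejected(self, gen_refs):
        ref = gen_refs[SMP]  # SMP_44 reference vs P24_2 field
        f = sap_field(np.full(54, 25.0))
        with pytest.raises(GridMismatchError):
            age_standardize(f, ref)


class TestTotalDeviation:
    def test_definition(self):
        grid = build_grid(P24_2)
        ref = NormativeReference(SAP_III, grid, np.full(54, 30.0), np.zeros(54))
        f = VisualField("e", 0, 45.0, SAP_III, grid, np.full(54, 28.0))
        td = to_total_deviation(f, ref)
        np.testing.assert_allclose(td.values_db, -2.0)
        assert td.kind == ABSOLUTE

    def test_field_at_mean_gives_zero(self, gen_refs):
        ref = gen_refs[SAP_III]
        f = VisualField("e", 0, 45.0, SAP_III, ref.grid, ref.mean45_db.copy())
        np.testing.assert_allclose(to_total_deviation(f, ref).values_db, 0.0, atol=1e-12)

    def test_censored_field_td_lower_bound(self, gen_refs):
        # brute-force bound: TD of a censored-at-20 field is >= 20 - max(mean45)
        ref = gen_refs[SAP_III]
        rng = np.random.default_rng(3)
        for _ in range(20):
            f = VisualField("e", 0, 45.0, SAP_III, ref.grid, rng.uniform(0, 35, 54))
            td = to_total_deviation(censor(f, 20.0), ref)
            assert td.values_db.min() >= 20.0 - ref.mean45_db.max() - 1e-12


class TestAverageSameDay:
    def test_single_field_identity(self):
        f = sap_field(np.full(54, 20.0))
        np.testing.assert_array_equal(average_same_day([f]).values_db, f.values_db)

    def test_pointwise_mean(self):
        a = sap_field([28.0])
        b = sap_field([30.0])
        assert average_same_day([a, b]).values_db[0] == 29.0

    def test_replicate_idempotence(self, rng):
        f = sap_field(rng.uniform(0, 35, 54))
        avg = average_same_day([f, f, f])
        np.testing.assert_allclose(avg.values_db, f.values_db)

    def test_empty_and_mixed_rejected(self):
        with pytest.raises(ValueError):
            average_same_day([])
        with pytest.raises(ValueError):
            average_same_day([sap_field([1.0], eye="a"), sap_field([1.0], eye="b")])


class TestChangeMap:
    def test_self_subtraction_zero(self):
        base = td_common(np.full(42, -4.0), visit=0)
        follow = td_common(np.full(42, -4.0), visit=1)
        np.testing.assert_array_equal(change_map(base, follow).values_db, 0.0)

    def test_deterioration_sign(self):
        base = td_common(np.full(42, -4.0), visit=0)
        follow = td_common(np.full(42, -6.0), visit=2)
        out = change_map(base, follow)
        np.testing.assert_array_equal(out.values_db, -2.0)
        assert out.kind == CHANGE

    def test_antisymmetric_values(self, rng):
        v0, v1 = rng.normal(-5, 3, 42), rng.normal(-5, 3, 42)
        fwd = change_map(td_common(v0, 0), td_common(v1, 1)).values_db
        rev = change_map(td_common(v1, 0), td_common(v0, 1)).values_db
        np.testing.assert_allclose(fwd, -rev)

    def test_visit_ordering_enforced(self):
        with pytest.raises(ValueError):
            change_map(td_common(np.zeros(42), 1), td_common(np.zeros(42), 2))
        with pytest.raises(ValueError):
            change_map(td_common(np.zeros(42), 0), td_common(np.zeros(42), 0))


class TestMatrices:
    def test_avfa_shape_and_rows(self, rng):
        fields = [td_common(rng.normal(-5, 2, 42), visit=i) for i in range(2)]
        X, index = build_avfa_matrix(fields)
        assert X.shape == (2, 42)
        for i, f in enumerate(fields):
            np.testing.assert_array_equal(X[i], f.values_db)
        assert list(index["visit_index"]) == [0, 1]

    def test_mixed_modality_rejected(self):
        with pytest.raises(ValueError):
            build_avfa_matrix([td_common(np.zeros(42)), td_common(np.zeros(42), visit=1,
                                                                  modality=SMP)])

    def test_change_kind_required_for_vfca(self):
        with pytest.raises(ValueError):
            build_vfca_matrix([td_common(np.zeros(42))])

    def test_change_field_counting(self, rng):
        fields = [td_common(rng.normal(-5, 1, 42), visit=v, eye="a") for v in range(4)]
        changes = build_change_fields(fields)
        assert len(changes) == 3
        X, _ = build_vfca_matrix(changes)
        assert X.shape == (3, 42)

    def test_baseline_only_eye_contributes_nothing(self):
        assert build_change_fields([td_common(np.zeros(42))]) == []

    def test_missing_baseline_excluded_with_warning(self, caplog):
        fields = [td_common(np.full(42, -1.0), visit=v, eye="nob") for v in (1, 2)]
        with caplog.at_level("WARNING"):
            out = build_change_fields(fields)
        assert out == []
        assert "no baseline" in caplog.text

    def test_identical_visits_give_zero_matrix(self):
        fields = [td_common(np.full(42, -3.0), visit=v) for v in range(3)]
        X, _ = build_vfca_matrix(build_change_fields(fields))
        np.testing.assert_array_equal(X, 0.0)


class TestPipeline:
    def test_noiseless_round_trip(self, noiseless_cohort, gen_refs):
        # with zero noise and the generating normative, the pipeline returns
        # the planted TD surface exactly (no censoring triggered at 5 dB depth)
        fields, truth = noiseless_cohort
        td = preprocess_fields(fields, gen_refs)
        for modality in (SAP_III, SMP):
            for f in td[modality]:
                eye = int(f.eye_id.replace("eye", ""))
                planted = truth.planted_td(eye, f.visit_index)
                np.testing.assert_allclose(f.values_db, planted, atol=1e-9)

    def test_change_fields_equal_progression(self, noiseless_cohort, gen_refs):
        fields, truth = noiseless_cohort
        td = preprocess_fields(fields, gen_refs)
        for f in build_change_fields(td[SMP]):
            eye = int(f.eye_id.replace("eye", ""))
            expected = truth.planted_td(eye, f.visit_index) - truth.planted_td(eye, 0)
            np.testing.assert_allclose(f.values_db, expected, atol=1e-9)

    def test_output_on_common_grid(self, small_cohort, gen_refs):
        fields, _ = small_cohort
        td = preprocess_fields(fields, gen_refs)
        assert set(td) == {SAP_III, SMP}
        for fs in td.values():
            assert all(f.grid.name == COMMON_42 for f in fs)

    def test_smp_never_censored(self, small_cohort, gen_refs):
        fields, _ = small_cohort
        td = preprocess_fields(fields, gen_refs)
        assert all("censored_fraction" not in f.meta for f in td[SMP])
        assert all("censored_fraction" in f.meta for f in td[SAP_III])

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PreprocessConfig(censor_floor_db=50.0)


class TestNormativeCsv:
    def test_round_trip(self, tmp_path, gen_refs):
        path = tmp_path / "normative.csv"
        write_normative_csv(gen_refs, path, header_comment="seed=0")
        back = read_normative_csv(path)
        for modality, ref in gen_refs.items():
            np.testing.assert_allclose(back[modality].mean45_db, ref.mean45_db, atol=1e-6)
            np.testing.assert_allclose(
                back[modality].slope_db_per_year, ref.slope_db_per_year, atol=1e-6
            )
            assert back[modality].grid.name == ref.grid.name
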