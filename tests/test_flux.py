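"""Bioenergetic profile: parsing, section summaries, parameter algebra,
subject pooling and group statistics."""

import numpy as np
import pandas as pd
import pytest

from mecfs_omics import CohortSpec, flux, synthetic
from mecfs_omics.flux import (
    FluxPlate,
    FluxValidationError,
    ParameterContractError,
    SummaryPolicy,
    aggregate_subject,
    compare_groups,
    compute_well_parameters,
    read_flux_plate,
    summarise_sections,
    well_parameters,
)


def _one_well_plate(cycles: dict, scheme: str = "A") -> FluxPlate:
    """Plate with a single well; cycles maps section -> [(ocr, ecar) x3]."""
    rows = []
    for section, triple in cycles.items():
        for i, (ocr, ecar) in enumerate(triple, 1):
            rows.append(("W1", scheme, section, i, ocr, ecar))
    traces = pd.DataFrame(rows, columns=["well", "scheme", "section", "cycle", "ocr", "ecar"])
    layout = pd.DataFrame(
        [("W1", "S1", "patient", scheme)], columns=["well", "subject", "group", "scheme"]
    )
    return FluxPlate.from_frames(traces, layout)


class TestReadAndValidate:
    def test_generator_output_round_trips(self, tmp_path, small_cohort):
        small_cohort.flux_traces.to_csv(tmp_path / "t.csv", index=False)
        small_cohort.flux_layout.to_csv(tmp_path / "l.csv", index=False)
        plate = read_flux_plate(tmp_path / "t.csv", tmp_path / "l.csv")
        assert len(plate.layout) == len(small_cohort.flux_layout)
        assert plate.n_cycles == 3

    def test_layout_referencing_absent_well_errors_with_name(self, small_cohort):
        layout = pd.concat(
            [
                small_cohort.flux_layout,
                pd.DataFrame(
                    [{"well": "W99X", "subject": "S9", "group": "control", "scheme": "A"}]
                ),
            ],
            ignore_index=True,
        )
        with pytest.raises(FluxValidationError, match="W99X"):
            FluxPlate.from_frames(small_cohort.flux_traces, layout)

    def test_missing_section_errors_with_name(self, small_cohort):
        traces = small_cohort.flux_traces
        broken = traces[~((traces.well == "W0001") & (traces.section == "inj2"))]
        with pytest.raises(FluxValidationError, match="inj2"):
            FluxPlate.from_frames(broken, small_cohort.flux_layout)

    def test_ragged_cycles_rejected(self, small_cohort):
        traces = small_cohort.flux_traces
        broken = traces.drop(traces[(traces.well == "W0001")].index[:1])
        with pytest.raises(FluxValidationError, match="ragged"):
            FluxPlate.from_frames(broken, small_cohort.flux_layout)

    def test_unknown_scheme_rejected(self, small_cohort):
        traces = small_cohort.flux_traces.copy()
        traces.loc[0, "scheme"] = "D"
        with pytest.raises(FluxValidationError, match="scheme"):
            FluxPlate.from_frames(traces, small_cohort.flux_layout)

    def test_negative_ocr_needs_tolerance_flag(self, small_cohort):
        traces = small_cohort.flux_traces.copy()
        traces.loc[0, "ocr"] = -0.5
        with pytest.raises(FluxValidationError, match="negative"):
            FluxPlate.from_frames(traces, small_cohort.flux_layout)
        plate = FluxPlate.from_frames(traces, small_cohort.flux_layout, allow_negative=True)
        assert plate.n_cycles == 3


class TestSectionSummaries:
    def test_basal_mean_and_fccp_max_rules(self):
        plate = _one_well_plate(
            {
                "basal": [(100, 10), (100, 10), (100, 10)],
                "inj1": [(150, 10), (180, 10), (170, 10)],
                "inj2": [(20, 10), (25, 10), (22, 10)],
            },
            scheme="B",
        )
        s = summarise_sections(plate).set_index("section")
        assert s.loc["basal", "ocr"] == 100
        assert s.loc["inj1", "ocr"] == 180  # max after FCCP
        assert s.loc["inj2", "ocr"] == 20  # min after rotenone/antimycin

    def test_mean_everywhere_equals_default_on_constant_traces(self):
        cycles = {
            "basal": [(100, 30)] * 3,
            "inj1": [(40, 35)] * 3,
            "inj2": [(20, 33)] * 3,
        }
        plate = _one_well_plate(cycles)
        default = summarise_sections(plate)
        mean = summarise_sections(plate, SummaryPolicy.mean_everywhere())
        pd.testing.assert_frame_equal(
            default.sort_values("section").reset_index(drop=True),
            mean.sort_values("section").reset_index(drop=True),
        )


class TestWellParameters:
    def test_scheme_a_hand_arithmetic(self):
        v = well_parameters("A", 100, 40, 20, 30, 35, 33)
        assert v["basal_respiration"] == 80
        assert v["atp_linked_respiration"] == 60
        assert v["proton_leak"] == 20
        assert v["coupling_efficiency"] == pytest.approx(75.0)
        assert v["nonmito_respiration"] == 20

    def test_scheme_b_hand_arithmetic(self):
        v = well_parameters("B", 100, 180, 20, 30, 35, 33)
        assert v["maximal_respiration"] == 160
        assert v["spare_respiratory_capacity"] == pytest.approx(2.0)

    def test_scheme_c_hand_arithmetic(self):
        v = well_parameters("C", 100, 90, 85, 30, 44, 8)
        assert v["basal_ecar"] == 30
        assert v["nonglycolytic_acidification"] == 8
        assert v["glycolysis"] == 22
        assert v["glycolytic_capacity"] == 36
        assert v["glycolytic_reserve"] == pytest.approx(36 / 22)

    def test_oligomycin_equal_to_basal_boundary(self):
        v = well_parameters("A", 100, 100, 20, 30, 35, 33)
        assert v["atp_linked_respiration"] == 0
        assert v["coupling_efficiency"] == pytest.approx(0.0)

    def test_nonpositive_denominator_flagged_not_silent(self):
        v = well_parameters("A", 20, 10, 20, 30, 35, 33)  # basal == nonmito
        assert np.isnan(v["coupling_efficiency"])

    def test_foreign_parameter_raises_contract_error(self):
        with pytest.raises(ParameterContractError, match="maximal_respiration"):
            well_parameters("A", 100, 40, 20, 30, 35, 33, parameters=("maximal_respiration",))

    def test_decomposition_basal_equals_atp_plus_leak(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            basal, oligo, nonmito = sorted(rng.uniform(5, 200, 3))[::-1]
            v = well_parameters("A", basal, oligo, nonmito, 30, 35, 33)
            assert v["basal_respiration"] == pytest.approx(
                v["atp_linked_respiration"] + v["proton_leak"], abs=1e-12
            )

    def test_scale_invariance_of_ratio_parameters(self):
        base = well_parameters("A", 100, 40, 20, 30, 35, 33)
        scaled = well_parameters("A", 300, 120, 60, 30, 35, 33)
        assert scaled["coupling_efficiency"] == pytest.approx(base["coupling_efficiency"])
        assert scaled["basal_respiration"] == pytest.approx(3 * base["basal_respiration"])
        b = well_parameters("B", 100, 180, 20, 30, 35, 33)
        bs = well_parameters("B", 500, 900, 100, 30, 35, 33)
        assert bs["spare_respiratory_capacity"] == pytest.approx(
            b["spare_respiratory_capacity"]
        )

    def test_oracle_equivalence_on_one_well_plate(self):
        """Pipeline result matches a brute-force recomputation from cycles."""
        rng = np.random.default_rng(42)
        cycles = {
            sec: [(o, e) for o, e in zip(rng.uniform(50, 150, 3), rng.uniform(10, 40, 3))]
            for sec in ("basal", "inj1", "inj2")
        }
        plate = _one_well_plate(cycles, scheme="A")
        params = compute_well_parameters(summarise_sections(plate))
        got = params.set_index("parameter")["value"]

        basal = np.mean([o for o, _ in cycles["basal"]])
        oligo = np.min([o for o, _ in cycles["inj1"]])
        nonmito = np.min([o for o, _ in cycles["inj2"]])
        assert got["basal_respiration"] == pytest.approx(basal - nonmito, abs=1e-12)
        assert got["atp_linked_respiration"] == pytest.approx(basal - oligo, abs=1e-12)
        assert got["proton_leak"] == pytest.approx(oligo - nonmito, abs=1e-12)
        assert got["coupling_efficiency"] == pytest.approx(
            100 * (basal - oligo) / (basal - nonmito), abs=1e-12
        )


class TestAggregateSubject:
    def _params(self, values, parameter="basal_respiration", scheme="A"):
        return pd.DataFrame(
            {
                "well": [f"W{i}" for i in range(len(values))],
                "subject": "S1",
                "group": "patient",
                "scheme": scheme,
                "parameter": parameter,
                "value": values,
            }
        )

    def test_mean_and_sample_sd(self):
        prof = aggregate_subject(self._params([70, 80, 90]))
        row = prof[prof.parameter == "basal_respiration"].iloc[0]
        assert row["mean"] == 80
        assert row["sd"] == pytest.approx(10.0)
        assert row["n_wells"] == 3

    def test_single_well_sd_undefined(self):
        prof = aggregate_subject(self._params([55.0]))
        row = prof[prof.parameter == "basal_respiration"].iloc[0]
        assert row["mean"] == 55
        assert np.isnan(row["sd"])

    def test_cross_scheme_ratio_from_subject_means(self):
        params = pd.concat(
            [
                self._params([50, 70], parameter="atp_linked_respiration"),
                self._params([150, 170], parameter="maximal_respiration", scheme="B"),
            ],
            ignore_index=True,
        )
        prof = aggregate_subject(params)
        row = prof[prof.parameter == "atp_linked_to_maximal"].iloc[0]
        assert row["mean"] == pytest.approx(60 / 160)  # 0.375

    def test_missing_scheme_logged_not_fatal(self, caplog):
        with caplog.at_level("WARNING", logger="mecfs_omics"):
            prof = aggregate_subject(self._params([70, 80]))
        assert "lacks wells" in caplog.text
        assert set(prof.parameter) >= {"basal_respiration"}


class TestCompareGroups:
    def _profiles(self, pat, con, parameter="coupling_efficiency"):
        rows = []
        for i, v in enumerate(pat):
            rows.append((f"P{i}", "patient", parameter, v, 1.0, 3))
        for i, v in enumerate(con):
            rows.append((f"C{i}", "control", parameter, v, 1.0, 3))
        return pd.DataFrame(
            rows, columns=["subject", "group", "parameter", "mean", "sd", "n_wells"]
        )

    def test_identical_groups_fc_one_p_one(self):
        comp = compare_groups(self._profiles([70, 75, 80], [70, 75, 80]))
        row = comp.iloc[0]
        assert row["fold_change"] == pytest.approx(1.0)
        assert row["p_raw"] == pytest.approx(1.0)

    def test_bonferroni_adjustment_properties(self):
        comp = compare_groups(self._profiles([70, 75, 80, 85], [71, 74, 81, 86]))
        row = comp.iloc[0]
        assert row["p_bonferroni"] >= row["p_raw"]
        assert row["p_bonferroni"] == pytest.approx(min(1.0, row["p_raw"] * 14))
        # raw p >= 1/14 saturates the adjusted value
        assert row["p_raw"] >= 1 / 14 and row["p_bonferroni"] == 1.0

    def test_group_with_one_subject_skipped_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="mecfs_omics"):
            comp = compare_groups(self._profiles([70, 75], [70]))
        assert comp.empty
        assert "skipped" in caplog.text

    def test_calibrator_group_excluded(self):
        prof = self._profiles([70, 75, 80], [72, 77, 79])
        prof = pd.concat(
            [
                prof,
                pd.DataFrame(
                    [("CAL", "calibrator", "coupling_efficiency", 999.0, 1.0, 3)],
                    columns=prof.columns,
                ),
            ],
            ignore_index=True,
        )
        comp = compare_groups(prof)
        assert comp.iloc[0]["n_patient"] == 3 and comp.iloc[0]["n_control"] == 3
        assert comp.iloc[0]["patient_mean"] == pytest.approx(75.0)

    def test_welch_flag_changes_dof_not_direction(self):
        prof = self._profiles([70, 75, 80, 90], [60, 61, 62, 63])
        student = compare_groups(prof, welch=False).iloc[0]
        welch = compare_groups(prof, welch=True).iloc[0]
        assert np.sign(student["t"]) == np.sign(welch["t"])
        assert student["p_raw"] != welch["p_raw"]


def test_full_plate_scale_invariance(small_cohort):
    """Scaling every OCR by c leaves ratio parameters unchanged and scales
    pmol-unit parameters by c."""
    plate = FluxPlate.from_frames(small_cohort.flux_traces, small_cohort.flux_layout)
    scaled_traces = small_cohort.flux_traces.assign(ocr=small_cohort.flux_traces.ocr * 3.0)
    plate3 = FluxPlate.from_frames(scaled_traces, small_cohort.flux_layout)
    p1 = aggregate_subject(compute_well_parameters(summarise_sections(plate)))
    p3 = aggregate_subject(compute_well_parameters(summarise_sections(plate3)))
    m1 = p1.pivot_table(index="subject", columns="parameter", values="mean", observed=True)
    m3 = p3.pivot_table(index="subject", columns="parameter", values="mean", observed=True)
    for ratio_param in ("coupling_efficiency", "spare_respiratory_capacity",
                        "atp_linked_to_maximal"):
        assert np.allclose(m1[ratio_param], m3[ratio_param])
    for unit_param in ("basal_respiration", "maximal_respiration", "proton_leak"):
        assert np.allclose(3.0 * m1[unit_param], m3[unit_param])
    assert np.allclose(3.0 * m1["ocr_ecar_ratio"], m3["ocr_ecar_ratio"])
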