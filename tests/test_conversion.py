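"""The conversion estimator: control subtraction, stoichiometry, aggregates."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rumenferm.conversion import (
    AlignmentError,
    BcvfaPanel,
    ConfigurationError,
    bcvfa_increase,
    conversion_table,
    mM_to_mmol,
    percent_conversion,
    replicate_conversions,
    rup_percent,
)
from rumenferm.design import BCAAS, BCVFA_PARTNER


def panel(tid, t, total=None, **acids):
    return BcvfaPanel(treatment_id=tid, time_h=t, reported_total=total, **acids)


class TestBcvfaIncrease:
    def test_total_subtraction_matches_published_cells(self):
        # high-dose 24-h totals minus control total
        d = bcvfa_increase(panel("SBM High", 24, total=3.76), panel("Control", 24, total=1.25))
        assert d["total"] == pytest.approx(2.51)
        d = bcvfa_increase(panel("WHEY High", 24, total=6.05), panel("Control", 24, total=1.25))
        assert d["total"] == pytest.approx(4.80)

    def test_control_minus_itself_is_zero(self):
        c = panel("Control", 24, isobutyric=0.5, methylbutyric2=0.3, isovaleric=0.45)
        d = bcvfa_increase(c, c)
        assert all(v == 0.0 for v in d.values())

    def test_mismatched_timepoints_rejected(self):
        with pytest.raises(AlignmentError):
            bcvfa_increase(panel("A", 24, total=2.0), panel("Control", 10, total=1.0))

    def test_negative_differences_pass_through(self):
        d = bcvfa_increase(panel("A", 10, total=0.34), panel("Control", 10, total=0.35))
        assert d["total"] == pytest.approx(-0.01)


@pytest.mark.parametrize(
    "conc, vol, expected",
    [(2.51, 40.0, 0.1004), (0.0, 40.0, 0.0), (5.05, 40.0, 0.202)],
)
def test_mM_to_mmol(conc, vol, expected):
    assert mM_to_mmol(conc, vol) == pytest.approx(expected)


def test_mM_to_mmol_requires_positive_volume():
    with pytest.raises(ValueError):
        mM_to_mmol(1.0, 0.0)


class TestPercentConversion:
    def test_total_basis_high_dose_examples(self):
        # published total increments x 40 mL vs dosed BCAA
        cases = [
            ("WHEY High", 4.80, {"Val": 0.088, "Ile": 0.085, "Leu": 0.139}, 61.5),
            ("SBM High", 2.51, {"Val": 0.062, "Ile": 0.052, "Leu": 0.088}, 49.7),
            ("YMP High", 0.61, {"Val": 0.065, "Ile": 0.047, "Leu": 0.074}, 13.1),
        ]
        for tid, d_mM, bcaa, expected in cases:
            res = percent_conversion({"total": mM_to_mmol(d_mM, 40.0)}, bcaa, treatment_id=tid)
            assert res.total_pct_molar == pytest.approx(expected, abs=0.05)
            assert res.rup_pct == pytest.approx(100.0 - expected, abs=0.05)

    def test_zero_delta_is_zero_conversion_full_rup(self):
        res = percent_conversion({"total": 0.0}, {"Val": 0.1, "Ile": 0.1, "Leu": 0.1})
        assert res.total_pct_molar == 0.0
        assert res.rup_pct == 100.0
        assert not res.flags

    def test_per_acid_and_aggregate_identity(self):
        """Molar-sum aggregate equals the BCAA-mole-weighted mean of per-acid values."""
        bcaa = {"Val": 0.06, "Ile": 0.05, "Leu": 0.09}
        delta = {"isobutyric": 0.03, "methylbutyric2": 0.02, "isovaleric": 0.05}
        res = percent_conversion(delta, bcaa)
        weighted = sum(res.per_acid_pct[aa] * bcaa[aa] for aa in BCAAS) / sum(bcaa.values())
        assert res.total_pct_molar == pytest.approx(weighted, rel=1e-12)
        assert res.mean_of_acids_pct == pytest.approx(
            np.mean([res.per_acid_pct[aa] for aa in BCAAS]), rel=1e-12
        )

    def test_volume_cancels(self):
        """Same result whether amounts come from a 40 or a 100 mL vessel."""
        bcaa_mM = {"Val": 1.5, "Ile": 1.2, "Leu": 2.0}
        delta_mM = {"isobutyric": 0.6, "methylbutyric2": 0.5, "isovaleric": 0.9}
        results = []
        for vol in (40.0, 100.0):
            res = percent_conversion(
                {k: mM_to_mmol(v, vol) for k, v in delta_mM.items()},
                {k: mM_to_mmol(v, vol) for k, v in bcaa_mM.items()},
            )
            results.append(res.total_pct_molar)
        assert results[0] == pytest.approx(results[1], rel=1e-12)

    def test_missing_bcaa_gives_missing_per_acid(self):
        res = percent_conversion(
            {"isobutyric": 0.01, "methylbutyric2": 0.01, "isovaleric": 0.01, "total": 0.03},
            {"Val": 0.1, "Ile": 0.0, "Leu": 0.1},
        )
        assert math.isnan(res.per_acid_pct["Ile"])
        assert not math.isnan(res.per_acid_pct["Val"])

    def test_negative_conversion_flagged_not_clipped(self):
        res = percent_conversion({"total": -0.01}, {"Val": 0.1})
        assert res.total_pct_molar < 0
        assert res.rup_pct > 100
        assert any("negative" in f for f in res.flags)

    def test_all_zero_bcaa_rejected(self):
        with pytest.raises(ValueError):
            percent_conversion({"total": 0.1}, {"Val": 0.0})

    @given(d1=st.floats(-0.05, 0.3), d2=st.floats(-0.05, 0.3))
    @settings(max_examples=60, derandomize=True)
    def test_monotone_in_delta(self, d1, d2):
        bcaa = {"Val": 0.1, "Ile": 0.1, "Leu": 0.1}
        c1 = percent_conversion({"total": d1}, bcaa).total_pct_molar
        c2 = percent_conversion({"total": d2}, bcaa).total_pct_molar
        if d1 < d2:
            assert c1 < c2
        elif d1 == d2:
            assert c1 == c2


def test_rup_complement_roundtrip():
    for pct in (62.0, 13.0, 100.0, -5.0):
        assert rup_percent(pct) + pct == pytest.approx(100.0)


class TestConversionTable:
    def test_published_means_give_headline_conversions(self, fixture_means, design):
        table = conversion_table(fixture_means, design, 24.0).set_index("treatment_id")
        assert table.loc["WHEY High", "total_pct_molar"] == pytest.approx(61.5, abs=0.05)
        assert table.loc["SBM High", "total_pct_molar"] == pytest.approx(49.7, abs=0.05)
        assert table.loc["YMP High", "total_pct_molar"] == pytest.approx(13.1, abs=0.05)

    def test_control_only_records_give_empty_table(self, fixture_means, design):
        ctrl = fixture_means[fixture_means.treatment_id == "Control"]
        assert conversion_table(ctrl, design, 24.0).empty

    def test_missing_control_is_configuration_error(self, fixture_means, design):
        no_ctrl = fixture_means[fixture_means.treatment_id != "Control"]
        with pytest.raises(ConfigurationError):
            conversion_table(no_ctrl, design, 24.0)

    def test_replicate_level_se_attached(self, default_simulation, design):
        _, records, _ = default_simulation
        table = conversion_table(records, design, 24.0)
        assert (table["n"] == 6).all()
        assert table["total_pct_molar"].notna().all()
        assert table["total_pct_se"].gt(0).all()
        reps = replicate_conversions(records, design, 24.0)
        assert len(reps) == 9 * 6

    def test_unknown_treatment_rejected(self, design):
        df = pd.DataFrame(
            {"treatment_id": ["Control", "Mystery"], "replicate": [1, 1],
             "time_h": [24.0, 24.0], "total_bcvfa_mM": [1.0, 2.0]}
        )
        with pytest.raises(ConfigurationError):
            conversion_table(df, design, 24.0)
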