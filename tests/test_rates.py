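"""Residence-time arithmetic, cytometry and leucine conversions, EcoPlate scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taunich.rates import (
    ChemostatGeometry,
    CytometryReading,
    EcoPlateReading,
    InfiniteResidenceTimeError,
    InvalidReadingError,
    LeucineAssayConfig,
    ResidenceTime,
    absolute_count,
    canonical_ecoplate_substrates,
    dilution_rate,
    ecoplate_score,
    leucine_to_carbon,
    max_generation_time,
    residence_time,
)


class TestResidenceTime:
    def test_tau_is_volume_over_flow(self):
        assert residence_time(ChemostatGeometry(40, 80)).tau == pytest.approx(0.5)
        assert residence_time(ChemostatGeometry(40, 40)).tau == pytest.approx(1.0)

    def test_zero_flow_signals_infinite_residence(self):
        with pytest.raises(InfiniteResidenceTimeError):
            residence_time(ChemostatGeometry(40, 0.0))

    def test_longest_chemostat_dilution_rounds_to_published_value(self):
        # 330-year vessel: 1/tau = 0.00303/y, printed as 0.003/y
        rt = ResidenceTime.from_years(330)
        per_year = dilution_rate(rt) * 24 * 365
        assert round(per_year, 3) == 0.003

    def test_fastest_dilution_rate_implies_half_hour_tau(self):
        # 1.9/h corresponds to tau ~= 32 min, reported as ~30 min
        rt = ResidenceTime.from_rate(1.9)
        assert rt.minutes == pytest.approx(31.58, abs=0.01)
        assert abs(rt.minutes - 30) < 5

    def test_dilution_rate_inverts_residence_time(self):
        g = ChemostatGeometry(40, 13.0)
        assert dilution_rate(residence_time(g)) * (g.volume / g.flow_rate) == (
            pytest.approx(1.0, abs=1e-12)
        )

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=1e-6, max_value=1e9, allow_nan=False))
    def test_unit_views_round_trip(self, hours):
        rt = ResidenceTime(hours)
        for view, back in [
            (rt.minutes, ResidenceTime.from_minutes),
            (rt.days, ResidenceTime.from_days),
            (rt.years, ResidenceTime.from_years),
        ]:
            assert back(view).tau == pytest.approx(hours, rel=1e-9)

    def test_invalid_geometry(self):
        with pytest.raises(ValueError):
            ChemostatGeometry(-1, 10)
        with pytest.raises(ValueError):
            ResidenceTime(0.0)


class TestMaxGenerationTime:
    def test_equals_tau_by_default(self):
        assert max_generation_time(ResidenceTime(1.0)) == pytest.approx(1.0)
        # rate 1.9/h -> ~30 min limiting generation time
        g = max_generation_time(ResidenceTime.from_rate(1.9))
        assert g * 60 == pytest.approx(31.58, abs=0.01)

    def test_monotone_in_tau(self):
        taus = np.geomspace(0.1, 1e6, 20)
        gens = [max_generation_time(float(t)) for t in taus]
        assert np.all(np.diff(gens) > 0)

    def test_ln2_variant_is_shorter_by_log_two(self):
        assert max_generation_time(2.0, ln2_corrected=True) == pytest.approx(
            2.0 * np.log(2)
        )


class TestAbsoluteCount:
    def test_worked_example(self):
        r = CytometryReading(events_in_gate=500, dilution_factor=100,
                             acquisition_volume=0.025)
        assert absolute_count(r) == pytest.approx(2.0e6)

    def test_zero_events_and_identity(self):
        assert absolute_count(CytometryReading(0, 100, 0.025)) == 0
        assert absolute_count(CytometryReading(137, 1, 1.0)) == 137

    @settings(derandomize=True, max_examples=50)
    @given(
        st.integers(min_value=0, max_value=10**6),
        st.floats(min_value=0.1, max_value=1e4, allow_nan=False),
    )
    def test_linear_in_events_and_dilution(self, events, dilution):
        base = absolute_count(CytometryReading(events, dilution, 0.05))
        assert absolute_count(
            CytometryReading(2 * events, dilution, 0.05)
        ) == pytest.approx(2 * base)
        assert absolute_count(
            CytometryReading(events, 2 * dilution, 0.05)
        ) == pytest.approx(2 * base)

    def test_invalid_volume(self):
        with pytest.raises(InvalidReadingError):
            CytometryReading(10, 1, 0.0)


class TestLeucineConversion:
    def test_no_net_incorporation_gives_zero(self):
        assert leucine_to_carbon(500.0, 500.0, 1.0) == 0.0

    def test_kill_above_live_warns_and_clamps(self):
        with pytest.warns(UserWarning):
            assert leucine_to_carbon(400.0, 500.0, 1.0) == 0.0

    def test_linearity_in_net_cpm(self):
        one = leucine_to_carbon(1400.0, 400.0, 1.0)
        two = leucine_to_carbon(2400.0, 400.0, 1.0)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_golden_fixture(self):
        # frozen from an independent unit-analysis chain:
        # (10000-400) cpm / 0.639 -> dpm; / 2.22e12 -> Ci; / 161 Ci/mmol;
        # * 131.2 g/mol / 0.073 -> g protein; * 0.86 -> g C; / 12.011 -> umol
        got = leucine_to_carbon(10000.0, 400.0, 1.0, LeucineAssayConfig())
        assert got == pytest.approx(5.40905980957603e-06, rel=1e-9)

    def test_incubation_normalises(self):
        assert leucine_to_carbon(10000.0, 400.0, 2.0) == pytest.approx(
            leucine_to_carbon(10000.0, 400.0, 1.0) / 2
        )


def _plate(od_values: np.ndarray, blank: float = 0.05) -> EcoPlateReading:
    subs = canonical_ecoplate_substrates().index
    return EcoPlateReading(
        od_by_substrate=pd.DataFrame(
            od_values, index=subs, columns=["r1", "r2", "r3"]
        ),
        blank_od=blank,
    )


class TestEcoPlate:
    def test_all_wells_at_blank(self):
        score = ecoplate_score(_plate(np.full((31, 3), 0.05)))
        assert score.n_positive == 0
        assert score.community_mean_consumption == 0.0

    def test_threshold_is_strict(self):
        od = np.full((31, 3), 0.05)
        od[0, :] = 0.05 + 0.125  # exactly at blank + threshold
        score = ecoplate_score(_plate(od))
        assert not score.positive.iloc[0]
        od[0, :] = 0.05 + 0.125 + 1e-9
        assert ecoplate_score(_plate(od)).positive.iloc[0]

    def test_mean_matches_brute_force(self):
        rng = np.random.default_rng(42)
        od = rng.uniform(0.0, 1.0, size=(31, 3))
        score = ecoplate_score(_plate(od, blank=0.1))
        brute = np.clip(od - 0.1, 0, None).mean()
        assert score.community_mean_consumption == pytest.approx(brute, rel=1e-12)

    def test_positive_count_monotone_in_threshold(self):
        rng = np.random.default_rng(7)
        od = rng.uniform(0.0, 0.6, size=(31, 3))
        plate = _plate(od)
        counts = [
            ecoplate_score(plate, threshold=t).n_positive
            for t in (0.05, 0.125, 0.25, 0.5)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_missing_substrate_named(self):
        subs = canonical_ecoplate_substrates().index
        df = pd.DataFrame(np.full((30, 3), 0.2), index=subs[:-1],
                          columns=["r1", "r2", "r3"])
        with pytest.raises(InvalidReadingError, match="Putrescine"):
            EcoPlateReading(od_by_substrate=df, blank_od=0.05)

    def test_category_means_cover_seven_groups(self):
        score = ecoplate_score(_plate(np.full((31, 3), 0.3)))
        assert len(score.category_means) == 7
        assert score.category_means.max() == pytest.approx(0.25)

    def test_tsv_round_trip(self, tmp_path):
        from taunich.io import read_ecoplate

        rng = np.random.default_rng(1)
        od = rng.uniform(0.1, 0.8, size=(31, 3))
        df = pd.DataFrame(od, index=canonical_ecoplate_substrates().index,
                          columns=["r1", "r2", "r3"])
        df["blank"] = 0.07
        p = tmp_path / "plate.tsv"
        df.to_csv(p, sep="\t", index_label="substrate")
        reading = read_ecoplate(p)
        assert reading.blank_od == pytest.approx(0.07)
        score = ecoplate_score(reading)
        brute = np.clip(od - 0.07, 0, None).mean()
        assert score.community_mean_consumption == pytest.approx(brute)
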