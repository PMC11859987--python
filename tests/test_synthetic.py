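"""Synthetic soundscapes and coupled-pair benchmarks."""

import numpy as np
import pytest

from soundflow import transfer_entropy as te
from soundflow.sites import river_park_sites, urban_park_sites
from soundflow.synthetic import (
    CouplingSpec,
    SoundscapeSpec,
    SurveyThresholds,
    gen_audio_segment,
    gen_coupled_pair,
    gen_index_series,
    gen_soundscape,
    gen_survey_labels,
    make_timeline,
)

INDEX_COLS = ["H", "ACI", "ADI", "AEI", "NDSI", "BI", "DSC", "ZCR"]


# ---------------------------------------------------------------------------
# coupled pair
# ---------------------------------------------------------------------------

class TestCoupledPair:
    def test_same_seed_is_bit_identical(self):
        for map_type in ("linear_var", "logistic"):
            spec = CouplingSpec(map_type=map_type, seed=3)
            x1, y1 = gen_coupled_pair(spec)
            x2, y2 = gen_coupled_pair(spec)
            np.testing.assert_array_equal(x1, x2)
            np.testing.assert_array_equal(y1, y2)

    def test_linear_var_coupling_orders_ste_in_true_direction(self):
        x, y = gen_coupled_pair(CouplingSpec(seed=42))
        sx, sy = te.discretize(x), te.discretize(y)
        assert te.shannon_te(sx, sy).value > te.shannon_te(sy, sx).value

    def test_logistic_coupling_orders_ste_in_true_direction(self):
        # moderate coupling (strong coupling synchronizes the two maps and
        # the direction becomes unidentifiable); equiprobable terciles suit
        # the edge-peaked invariant density of the logistic map
        scheme = te.DiscretizationScheme(boundaries=(33.3, 66.7))
        hits = 0
        for seed in range(20):
            x, y = gen_coupled_pair(
                CouplingSpec(
                    map_type="logistic",
                    coupling_strength=0.3,
                    noise_sd=0.05,
                    seed=seed,
                )
            )
            sx, sy = te.discretize(x, scheme), te.discretize(y, scheme)
            hits += te.shannon_te(sx, sy).value > te.shannon_te(sy, sx).value
        assert hits >= 18

    def test_zero_coupling_gives_null_level_te(self):
        """With no coupling, mean STE over replicates sits within 3 null
        standard deviations of a shuffle-null mean."""
        values = []
        for seed in range(200):
            x, y = gen_coupled_pair(
                CouplingSpec(coupling_strength=0.0, n_steps=500, seed=seed)
            )
            sx, sy = te.discretize(x), te.discretize(y)
            values.append(te.shannon_te(sx, sy).value)
        x, y = gen_coupled_pair(
            CouplingSpec(coupling_strength=0.0, n_steps=500, seed=999)
        )
        null = te.shuffle_null(
            te.discretize(x), te.discretize(y), reps=199, seed=0
        )
        assert abs(np.mean(values) - null["mean"]) < 3 * null["sd"]

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_steps": 10},
            {"lag": 0},
            {"lag": 5000},
            {"noise_sd": 0.0},
            {"coupling_strength": 1.5},
            {"map_type": "nonsense"},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CouplingSpec(**kwargs)


# ---------------------------------------------------------------------------
# timelines
# ---------------------------------------------------------------------------

class TestTimeline:
    def test_continuous_3p5h_gives_210_windows(self):
        spec = SoundscapeSpec(
            protocol="continuous", duration_h=3.5, start="2015-05-25 06:30"
        )
        assert len(make_timeline(spec)) == 210

    def test_duty_cycle_14_days_gives_3360_windows(self):
        assert len(make_timeline(SoundscapeSpec())) == 3360

    def test_windows_follow_the_duty_cycle_step(self):
        tl = make_timeline(SoundscapeSpec(days=1))
        steps = np.diff(tl.asi8) / 1e9
        assert (steps == 360.0).all()


# ---------------------------------------------------------------------------
# index-series fast path
# ---------------------------------------------------------------------------

class TestIndexSeries:
    def test_rows_per_site_match_protocol(self):
        trp = gen_index_series(SoundscapeSpec(days=14, seed=0))
        assert (trp.groupby("site_id").size() == 3360).all()
        pnm = gen_index_series(
            SoundscapeSpec(
                site_map=urban_park_sites(),
                protocol="continuous",
                duration_h=3.5,
                start="2015-05-25 06:30",
                seed=0,
            )
        )
        assert (pnm.groupby("site_id").size() == 210).all()
        assert pnm["site_id"].nunique() == 16

    def test_index_columns_respect_ranges(self, small_soundscape):
        m = small_soundscape.index_matrix
        assert m["H"].between(0, 1).all()
        assert m["AEI"].between(0, 1).all()
        assert m["NDSI"].between(-1, 1).all()
        assert (m["BI"] >= 0).all() and (m["ACI"] >= 0).all()
        assert m["ZCR"].between(0, 1).all()

    def test_biophony_peaks_at_dawn(self, small_soundscape):
        bio = small_soundscape.biophony
        hours = bio.index.hour
        dawn = bio[(hours >= 5) & (hours < 8)].mean().mean()
        night = bio[(hours >= 22) | (hours < 3)].mean().mean()
        assert dawn > 2 * night

    def test_traffic_decays_with_distance_from_road(self, small_soundscape):
        tra = small_soundscape.traffic.mean()
        site_map = small_soundscape.spec.site_map
        dists = {s: site_map.road_distance(s) for s in tra.index}
        near = min(dists, key=dists.get)
        far = max(dists, key=dists.get)
        assert tra[near] > tra[far]

    def test_interior_sites_lead_exterior_by_the_configured_lag(self):
        real = gen_soundscape(SoundscapeSpec(seed=1, days=3, inter_site_lag=2))
        bio = real.biophony
        internal = bio[1].to_numpy()
        external = bio[7].to_numpy()
        lags = range(-4, 5)
        cors = [
            np.corrcoef(internal[4 + k : len(internal) - 4 + k],
                        external[4 : len(external) - 4])[0, 1]
            for k in lags
        ]
        assert list(lags)[int(np.argmax(cors))] == -2

    def test_symmetric_generator_shows_no_group_contrast(self):
        """No road noise + uniform chorus -> internal/external group means
        statistically indistinguishable across seeds."""
        diffs = []
        for seed in range(50):
            real = gen_soundscape(
                SoundscapeSpec(
                    seed=seed, days=1, road_noise_amp=0.0, uniform_chorus=True
                )
            )
            m = real.index_matrix
            groups = real.spec.site_map.active["group"]
            m = m.assign(group=m["site_id"].map(groups))
            gm = m.groupby("group")["BI"].mean()
            diffs.append(gm["internal"] - gm["external"])
        t_stat = np.mean(diffs) / (np.std(diffs, ddof=1) / np.sqrt(len(diffs)))
        assert abs(t_stat) < 3.0

    def test_empty_site_map_rejected(self):
        site_map = river_park_sites()
        for sid in site_map.table["site_id"]:
            site_map.excluded[sid] = "all broken"
        with pytest.raises(ValueError, match="no active sites"):
            SoundscapeSpec(site_map=site_map)

    def test_same_seed_reproduces_bitwise(self):
        a = gen_index_series(SoundscapeSpec(seed=5, days=1))
        b = gen_index_series(SoundscapeSpec(seed=5, days=1))
        assert a.equals(b)


# ---------------------------------------------------------------------------
# audio path
# ---------------------------------------------------------------------------

class TestAudioSegment:
    def test_zero_drivers_give_exact_silence(self):
        w = gen_audio_segment(0.0, 0.0, duration_s=2, seed=0)
        assert not np.any(w)

    def test_peak_never_exceeds_full_scale(self):
        for seed in range(5):
            w = gen_audio_segment(3.0, 3.0, duration_s=2, seed=seed)
            assert np.max(np.abs(w)) <= 1.0

    def test_fixed_seed_is_reproducible(self):
        a = gen_audio_segment(1.0, 1.0, duration_s=1, seed=9)
        b = gen_audio_segment(1.0, 1.0, duration_s=1, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_biophony_only_audio_has_positive_ndsi(self):
        from soundflow.index_engine import AudioSegment, compute_NDSI

        w = gen_audio_segment(1.5, 0.0, duration_s=5, seed=2)
        assert compute_NDSI(AudioSegment(w, 48000)) > 0

    def test_traffic_only_audio_has_negative_ndsi(self):
        from soundflow.index_engine import AudioSegment, compute_NDSI

        w = gen_audio_segment(0.0, 1.5, duration_s=5, seed=2)
        assert compute_NDSI(AudioSegment(w, 48000)) < 0

    def test_negative_drivers_rejected(self):
        with pytest.raises(ValueError):
            gen_audio_segment(-1.0, 0.0)


# ---------------------------------------------------------------------------
# survey labels
# ---------------------------------------------------------------------------

class TestSurveyLabels:
    def test_fractions_match_brute_force_recount(self, small_soundscape):
        th = SurveyThresholds()
        labels = gen_survey_labels(small_soundscape, th, seed=0)
        for sid in small_soundscape.biophony.columns:
            b = small_soundscape.biophony[sid].to_numpy()
            t = small_soundscape.traffic[sid].to_numpy()
            grp = labels[labels["site_id"] == sid]
            assert (grp["birds_singing"] == "many").sum() == int(
                (b >= th.birds_many).sum()
            )
            assert (grp["traffic_intensity"] == "high").sum() == int(
                (t >= th.traffic_high).sum()
            )

    def test_saturated_drivers_give_unit_fractions(self, small_soundscape):
        th = SurveyThresholds(birds_many=0.0, traffic_high=1e9)
        labels = gen_survey_labels(small_soundscape, th, seed=0)
        assert (labels["birds_singing"] == "many").all()
        assert not (labels["traffic_intensity"] == "high").any()

    def test_vocabulary_is_closed(self, small_soundscape):
        from soundflow.reporting import SURVEY_VOCABULARY, validate_survey

        labels = gen_survey_labels(small_soundscape, seed=1)
        validate_survey(labels)  # raises on any out-of-vocabulary label
        for col, vocab in SURVEY_VOCABULARY.items():
            assert set(labels[col].unique()) <= vocab
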