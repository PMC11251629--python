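"""Motor-unit pool initialisation and spike-train generation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from emgforge import (twitch_distribution, allocate_sizes, init_pool,
                      fuglevand_spikes, lif_spikes, lif_isi_closed_form,
                      drive_profile, MuscleModel, PoolConfig)
from emgforge.pool import write_spikes, read_spikes


# Independent scalar evaluation of the linear-exponential twitch law,
# written before the implementation and kept separate from it.
def _twitch_oracle(j: int, N: int) -> float:
    x = j / N
    return 0.81 * (18.51 * x + 104.10 * x ** 4.83)


class TestTwitchDistribution:
    def test_classical_single_unit_equals_rp(self):
        assert twitch_distribution("classical", 1)[0] == pytest.approx(100.0)
        assert twitch_distribution("classical", 1, rp=50.0)[0] == \
            pytest.approx(50.0)

    def test_lif_last_unit_value(self):
        tw = twitch_distribution("lif", 5)
        assert tw[-1] == pytest.approx(0.81 * (18.51 + 104.10), abs=1e-12)

    @pytest.mark.parametrize("N", [1, 10, 100])
    def test_lif_matches_scalar_oracle(self, N):
        tw = twitch_distribution("lif", N)
        expected = np.array([_twitch_oracle(j, N) for j in range(1, N + 1)])
        assert np.max(np.abs(tw - expected)) < 1e-12

    def test_midpoint_ratio_against_oracle(self):
        tw = twitch_distribution("lif", 100)
        assert tw[49] / tw[99] == pytest.approx(
            _twitch_oracle(50, 100) / _twitch_oracle(100, 100), abs=1e-12)

    @pytest.mark.parametrize("kind", ["classical", "lif"])
    def test_strictly_increasing(self, kind):
        tw = twitch_distribution(kind, 50)
        assert np.all(np.diff(tw) > 0)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            twitch_distribution("classical", 0)


# Independent largest-remainder allocation, coded separately as the oracle.
def _largest_remainder_oracle(tw, n_f):
    quota = [t / sum(tw) * n_f for t in tw]
    sizes = [int(np.floor(q)) for q in quota]
    fracs = sorted(range(len(tw)), key=lambda i: (-(quota[i] - sizes[i]), i))
    for i in fracs[:n_f - sum(sizes)]:
        sizes[i] += 1
    return sizes


class TestAllocateSizes:
    def test_single_unit_gets_all(self):
        assert allocate_sizes(np.array([3.7]), 250).tolist() == [250]

    def test_equal_twitches_split_equally(self):
        assert allocate_sizes(np.ones(4), 100).tolist() == [25, 25, 25, 25]

    def test_matches_hand_computed_largest_remainder(self):
        tw = twitch_distribution("lif", 10)
        assert allocate_sizes(tw, 1000).tolist() == \
            _largest_remainder_oracle(tw.tolist(), 1000)

    def test_too_few_fibres_raises(self):
        with pytest.raises(ValueError):
            allocate_sizes(np.ones(5), 4)

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(min_value=1, max_value=120),
           st.integers(min_value=0, max_value=100000))
    def test_conservation_property(self, n, extra):
        """Sizes always sum to the requested fibre count, each >= 1."""
        n_f = n + extra
        for kind in ("classical", "lif"):
            sizes = allocate_sizes(twitch_distribution(kind, n), n_f)
            assert sizes.sum() == n_f
            assert sizes.min() >= 1


class TestInitPool:
    def test_deterministic_given_seed(self, small_muscle):
        p1 = init_pool(small_muscle, "classical", seed=5)
        p2 = init_pool(small_muscle, "classical", seed=5)
        for u1, u2 in zip(p1.units, p2.units):
            assert u1 == u2

    def test_last_threshold_is_one(self, small_muscle):
        for kind in ("classical", "lif"):
            pool = init_pool(small_muscle, kind, seed=2)
            assert pool.units[-1].recruitment_threshold == 1.0
            assert np.all(np.diff(pool.thresholds()) > 0)

    def test_depths_within_territory(self, small_muscle):
        pool = init_pool(small_muscle, "classical", seed=9)
        lo = small_muscle.territory_centre_depth - small_muscle.territory_radius
        hi = small_muscle.territory_centre_depth + small_muscle.territory_radius
        for u in pool.units:
            assert lo <= u.depth <= hi
            assert abs(u.ml_pos) <= small_muscle.territory_radius

    def test_sizes_conserved_and_cv_sorted(self, small_muscle):
        for kind in ("classical", "lif"):
            pool = init_pool(small_muscle, kind, seed=11)
            assert sum(u.size for u in pool.units) == small_muscle.total_fibres
            cvs = [u.cv for u in pool.units]
            assert np.all(np.diff(cvs) >= 0)

    def test_iz_within_range(self, small_muscle, pool_config):
        pool = init_pool(small_muscle, "classical", pool_config, seed=4)
        for u in pool.units:
            assert pool_config.iz_range[0] <= u.iz_pos <= pool_config.iz_range[1]

    def test_added_unit_does_not_perturb_others(self, small_muscle):
        import dataclasses
        bigger = dataclasses.replace(small_muscle, n_units=11,
                                     total_fibres=2000)
        p_small = init_pool(small_muscle, "classical", seed=7)
        p_big = init_pool(bigger, "classical", seed=7)
        # per-unit streams: positional draws of shared ranks are identical
        for u1, u2 in zip(p_small.units, p_big.units):
            assert u1.iz_pos == u2.iz_pos
            assert u1.ml_pos == u2.ml_pos


class TestFuglevandSpikes:
    def test_zero_drive_no_spikes(self, small_muscle):
        pool = init_pool(small_muscle, "classical", seed=0)
        st_ = fuglevand_spikes(pool, np.zeros(2001), 2000.0, seed=0)
        assert st_.total_spikes == 0

    def test_drive_at_first_threshold_periodic_mfr(self, small_muscle):
        cfg = PoolConfig(isi_cv=0.0)
        pool = init_pool(small_muscle, "classical", cfg, seed=0)
        theta1 = pool.units[0].recruitment_threshold
        drive = np.full(10 * 2000 + 1, theta1)
        st_ = fuglevand_spikes(pool, drive, 2000.0, seed=0)
        isis = np.diff(st_.trains[0])
        assert np.allclose(isis, 1.0 / cfg.MFR, atol=1e-9)
        assert all(t.size == 0 for t in st_.trains[1:])

    def test_spike_counts_match_rate_formula(self, small_muscle):
        """At constant drive with no ISI jitter the empirical count equals
        the analytic rate, evaluated by an independent scalar oracle."""
        cfg = PoolConfig(isi_cv=0.0)
        pool = init_pool(small_muscle, "classical", cfg, seed=0)
        drive = np.full(10 * 2000 + 1, 0.5)
        st_ = fuglevand_spikes(pool, drive, 2000.0, seed=0)
        for u, train in zip(pool.units, st_.trains):
            theta = u.recruitment_threshold
            if 0.5 < theta:
                assert train.size == 0
                continue
            fr = min(max(cfg.MFR + cfg.gain * (0.5 - theta), cfg.MFR),
                     u.peak_rate)
            assert abs(train.size - round(10 * fr)) <= 1

    def test_unit_stops_below_threshold(self, small_muscle):
        cfg = PoolConfig(isi_cv=0.0)
        pool = init_pool(small_muscle, "classical", cfg, seed=0)
        fs = 2000.0
        drive = drive_profile("triangle", 1.0, 4.0, fs)
        st_ = fuglevand_spikes(pool, drive, fs, seed=0)
        for u, train in zip(pool.units, st_.trains):
            for t in train:
                assert drive[int(round(t * fs))] >= u.recruitment_threshold

    def test_out_of_range_drive_raises(self, small_muscle):
        pool = init_pool(small_muscle, "classical", seed=0)
        with pytest.raises(ValueError):
            fuglevand_spikes(pool, np.array([0.0, 1.5]), 2000.0)


class TestLIFSpikes:
    def test_subthreshold_silent(self, small_muscle):
        pool = init_pool(small_muscle, "lif", seed=1)
        fs = 10000.0
        # drive below the first unit's recruitment threshold
        level = 0.5 * pool.units[0].recruitment_threshold
        st_ = lif_spikes(pool, np.full(int(fs) + 1, level), fs)
        assert st_.total_spikes == 0

    def test_closed_form_isi(self, small_muscle):
        pool = init_pool(small_muscle, "lif", seed=1)
        fs = 10000.0
        drive = np.full(2 * int(fs) + 1, 0.4)
        st_ = lif_spikes(pool, drive, fs)
        checked = 0
        for u, train in zip(pool.units, st_.trains):
            if train.size < 3:
                continue
            expected = lif_isi_closed_form(u.R, u.tau, u.v_th, u.t_ref,
                                           0.4 * u.i_max)
            assert np.mean(np.diff(train)) == pytest.approx(expected,
                                                            rel=0.01)
            checked += 1
        assert checked >= 3

    def test_ramp_recruits_in_rank_order(self, small_muscle):
        pool = init_pool(small_muscle, "lif", seed=1)
        fs = 10000.0
        ramp = np.linspace(0, 1, 3 * int(fs) + 1)
        drive = np.concatenate([ramp, np.ones(int(fs))])  # hold to let the
        st_ = lif_spikes(pool, drive, fs)                  # last unit charge
        firsts = [t[0] for t in st_.trains if t.size]
        assert len(firsts) == pool.n_units
        assert np.all(np.diff(firsts) >= 0)


@pytest.mark.parametrize("kind", ["classical", "lif"])
class TestPoolPrinciples:
    FS = {"classical": 2000.0, "lif": 10000.0}

    def _spikes(self, pool, drive, fs, seed):
        fn = fuglevand_spikes if pool.model_kind == "classical" else lif_spikes
        return fn(pool, drive, fs, seed=seed)

    def test_size_principle_on_ramp(self, kind, small_muscle):
        """First-spike times are non-decreasing in recruitment rank."""
        cfg = PoolConfig(isi_cv=0.0)
        fs = self.FS[kind]
        drive = np.linspace(0, 1, 3 * int(fs) + 1)
        for seed in range(3):
            pool = init_pool(small_muscle, kind, cfg, seed=seed)
            st_ = self._spikes(pool, drive, fs, seed)
            firsts = [t[0] for t in st_.trains if t.size]
            assert np.all(np.diff(firsts) >= 0)

    def test_onion_skin_at_constant_drive(self, kind, small_muscle):
        """Earlier-recruited units fire at least as fast as later ones."""
        cfg = PoolConfig(isi_cv=0.0)
        fs = self.FS[kind]
        drive = np.full(4 * int(fs) + 1, 0.6)
        for seed in range(3):
            pool = init_pool(small_muscle, kind, cfg, seed=seed)
            st_ = self._spikes(pool, drive, fs, seed)
            rates = [t.size / 4.0 for t in st_.trains if t.size > 1]
            assert np.all(np.diff(rates) <= 1e-9)


class TestDriveProfiles:
    def test_shapes_and_bounds(self):
        fs = 1000.0
        for kind in ("constant", "trapezoid", "triangle", "sinusoid"):
            d = drive_profile(kind, 0.7, 2.0, fs, offset=0.3)
            assert d.size == 2001
            assert d.min() >= 0.0 and d.max() <= 1.0

    def test_triangle_peaks_at_midpoint(self):
        d = drive_profile("triangle", 0.9, 2.0, 1000.0)
        assert d[1000] == pytest.approx(0.9)
        assert d[0] == pytest.approx(0.0) and d[-1] == pytest.approx(0.0)

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            drive_profile("sawtooth", 1.0, 1.0, 1000.0)


def test_spike_train_text_roundtrip(tmp_path, small_muscle):
    pool = init_pool(small_muscle, "classical", seed=0)
    drive = np.full(2 * 2000 + 1, 0.5)
    st_ = fuglevand_spikes(pool, drive, 2000.0, seed=3)
    path = tmp_path / "spikes.tsv"
    write_spikes(st_, path, pool)
    back = read_spikes(path)
    assert back.n_units == st_.n_units
    for a, b in zip(st_.trains, back.trains):
        assert np.allclose(a, b, atol=1e-9)
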