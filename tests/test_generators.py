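"""Simulators: exact iterates, reproducibility, spectral and ordinal properties."""

import warnings

import numpy as np
import pytest

import renyispace as rs


def test_white_noise_reproducible_and_centered():
    a = rs.white_noise(10_000, seed=5)
    b = rs.white_noise(10_000, seed=5)
    np.testing.assert_array_equal(a.values, b.values)
    assert abs(a.values.mean()) < 3 / np.sqrt(10_000)
    with pytest.raises(ValueError):
        rs.white_noise(0)


def test_white_noise_is_nearly_pattern_uniform():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        d = rs.ordinal_distribution(rs.white_noise(100_000, seed=1), 3, 1)
    assert rs.normalized_renyi_entropy(d, 1.0) > 0.99


def test_knoise_zero_mean_and_reproducible():
    spec = rs.NoiseSpec(k=2.0, M=4096, seed=3)
    a, b = rs.knoise(spec), rs.knoise(spec)
    np.testing.assert_array_equal(a.values, b.values)
    assert abs(a.values.mean()) < 1e-10  # DC removed exactly
    assert len(a) == 4096


def test_knoise_rejects_invalid_spec():
    with pytest.raises(ValueError):
        rs.NoiseSpec(k=-1.0, M=100)
    with pytest.raises(ValueError):
        rs.NoiseSpec(k=1.0, M=1)


def test_knoise_k0_is_flat():
    """Degenerate exponent: PSD slope of k = 0 noise is near zero."""
    ks = []
    for seed in range(10):
        ts = rs.knoise(rs.NoiseSpec(k=0.0, M=10_000, seed=seed))
        f, p, _ = rs.welch_psd(ts.values, 200.0)
        ks.append(rs.powerlaw_fit(f, p).k)
    assert abs(np.median(ks)) < 0.1


def test_knoise_entropy_decreases_with_k():
    """H_1 at D=6 falls strictly as the spectral exponent grows."""
    ks = np.exp(np.linspace(np.log(1), np.log(5), 5))
    hs = []
    for k in ks:
        ts = rs.knoise(rs.NoiseSpec(k=float(k), M=10_000, seed=11))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d = rs.ordinal_distribution(ts, 6, 1)
        hs.append(rs.normalized_renyi_entropy(d, 1.0))
    assert np.all(np.diff(hs) < 0)


def test_logistic_hand_iteration_and_interval():
    ts = rs.logistic_map(rs.MapParams(M=5, x0=0.5, burn_in=0))
    np.testing.assert_allclose(ts.values, [0.5, 1.0, 0.0, 0.0, 0.0])
    long = rs.logistic_map(rs.MapParams(M=10_000, seed=2))
    assert np.all((long.values >= 0) & (long.values <= 1))
    with pytest.raises(ValueError):
        rs.logistic_map(rs.MapParams(M=10, x0=1.5, burn_in=0))
    with pytest.raises(ValueError):
        rs.logistic_map(rs.MapParams(M=10, r=5.0))


def test_logistic_has_forbidden_patterns():
    """Deterministic chaos leaves some D=6 ordinal patterns unobserved."""
    ts = rs.logistic_map(rs.MapParams(M=10_000, seed=4))
    d = rs.ordinal_distribution(ts, 6, 1)
    assert (d.probabilities == 0).sum() > 0


def test_henon_hand_iteration_bounded_and_reproducible():
    ts = rs.henon_map(rs.MapParams(M=3, x0=0.0, y0=0.0, burn_in=0))
    np.testing.assert_allclose(ts.values, [0.0, 1.0, -0.4])
    long = rs.henon_map(rs.MapParams(M=10_000, seed=8))
    assert np.max(np.abs(long.values)) < 2.0
    again = rs.henon_map(rs.MapParams(M=10_000, seed=8))
    np.testing.assert_array_equal(long.values, again.values)


def test_henon_divergence_raises():
    with pytest.raises(RuntimeError, match="diverged"):
        rs.henon_map(rs.MapParams(M=100, a=6.0, x0=2.0, y0=0.0, burn_in=0))


def test_schuster_hand_arithmetic_and_range():
    ts = rs.schuster_map(rs.MapParams(M=2, x0=0.25, z=2.0, burn_in=0))
    np.testing.assert_allclose(ts.values, [0.25, 0.3125])
    long = rs.schuster_map(rs.MapParams(M=10_000, z=1.5, seed=3))
    assert np.all((long.values >= 0) & (long.values < 1))
    with pytest.raises(ValueError):
        rs.schuster_map(rs.MapParams(M=10, x0=-0.5, burn_in=0))


def test_schuster_exponents_occupy_distinct_locations():
    """z = 3/2 and z = 5/2 sit apart in the q=1 plane beyond seed noise."""
    pts = {z: [] for z in (1.5, 2.5)}
    for z in pts:
        for seed in range(8):
            ts = rs.schuster_map(rs.MapParams(M=10_000, z=z, seed=seed))
            d = rs.ordinal_distribution(ts, 6, 1)
            pts[z].append((rs.normalized_renyi_entropy(d, 1.0),
                           rs.renyi_complexity(d, 1.0)))
    a, b = (np.array(pts[z]) for z in (1.5, 2.5))
    gap = np.hypot(*(a.mean(axis=0) - b.mean(axis=0)))
    se = np.sqrt(a.var(axis=0).sum() / len(a) + b.var(axis=0).sum() / len(b))
    assert gap > se


def test_atlas_structure_and_determinism(small_atlas):
    records, truth, cfg = small_atlas
    assert len(records) == 2 * 2 * cfg.patients_per_sex * cfg.channels_per_patient
    for r in records:
        assert len(r.signal) == 13_600
        assert r.signal.sampling_rate == 200.0
    again, _ = rs.synthetic_atlas(cfg)
    np.testing.assert_array_equal(records[0].signal.values, again[0].signal.values)
    assert truth["planted"] == {"RegB|W": 1.0}
    assert truth["groups"]["RegB|W|M"] == pytest.approx(
        truth["groups"]["RegB|W|F"] + 1.0
    )


def test_atlas_rejects_thin_cohorts():
    with pytest.raises(ValueError, match="patients_per_sex"):
        rs.SyntheticAtlasConfig(patients_per_sex=3)


def test_atlas_write_and_reload_roundtrip(tmp_path, small_atlas):
    records, truth, _ = small_atlas
    manifest = rs.write_atlas(records[:6], truth, tmp_path)
    loaded, report = rs.load_channels(manifest)
    assert len(loaded) == 6
    assert all(r["status"] == "ok" for r in report)
    # trailing zero-padding trimmed on load
    assert all(len(r.signal) <= 13_600 for r in loaded)
    orig = np.trim_zeros(records[0].signal.values, trim="b")
    np.testing.assert_allclose(loaded[0].signal.values, orig, atol=1e-6)
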