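"""Simulators: scale-free (f^-k) noise, white noise, classical chaotic maps,
and a synthetic multichannel atlas with the structure of open iEEG
repositories (200 Hz channels zero-padded to 13,600 samples, grouped by
region x state x sex).

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ordinal import TimeSeries

__all__ = [
    "NoiseSpec",
    "MapParams",
    "SyntheticAtlasConfig",
    "knoise",
    "white_noise",
    "logistic_map",
    "henon_map",
    "schuster_map",
    "synthetic_atlas",
    "write_atlas",
]

STATES = ("W", "N2", "N3", "R")


@dataclass
class NoiseSpec:
    """Parameters of a power-law (PSD ~ f^-k) noise series.

    ``sampling_rate``/``highpass`` are optional: with both set, spectral
    content below the high-pass corner (Hz) is removed, emulating the
    hardware filtering of physiological recordings.  Without them the
    power law spans the full normalized frequency axis.
    """

    k: float
    M: int
    seed: int | None = None
    normalize: bool = True
    sampling_rate: float | None = None
    highpass: float | None = None

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("power-law exponent k must be >= 0")
        if self.M < 2:
            raise ValueError("series length M must be >= 2")


def knoise(spec: NoiseSpec | None = None, *, k: float | None = None,
           M: int | None = None, seed: int | None = None,
           rng: np.random.Generator | None = None) -> TimeSeries:
    """Correlated noise with expected power spectral density ~ f^-k.

    White Gaussian noise is Fourier transformed, each positive-frequency
    amplitude is scaled by f^(-k/2) (so *power* follows f^-k), the DC
    component is zeroed (zero-mean output) and the inverse transform returns
    a real series of length M.
    """
    if spec is None:
        spec = NoiseSpec(k=float(k), M=int(M), seed=seed)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    x = rng.standard_normal(spec.M)
    X = np.fft.rfft(x)
    d = 1.0 / spec.sampling_rate if spec.sampling_rate else 1.0
    f = np.fft.rfftfreq(spec.M, d=d)  # f[0] = 0
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-spec.k / 2.0)
    if spec.highpass:
        shape[f < spec.highpass] = 0.0
    y = np.fft.irfft(X * shape, n=spec.M)
    if spec.normalize:
        sd = y.std()
        if sd > 0:
            y = y / sd
    return TimeSeries(y, meta={"generator": "knoise", "k": spec.k, "seed": spec.seed})


def white_noise(M: int, seed: int | None = None,
                rng: np.random.Generator | None = None) -> TimeSeries:
    """Standard-normal i.i.d. noise."""
    if M < 1:
        raise ValueError("M must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    return TimeSeries(rng.standard_normal(M),
                      meta={"generator": "white", "seed": seed})


@dataclass
class MapParams:
    """Iteration parameters for the chaotic maps."""

    M: int = 10_000
    burn_in: int = 1000
    x0: float | None = None
    y0: float | None = None
    seed: int | None = None
    r: float = 4.0        # logistic
    a: float = 1.4        # Henon
    b: float = 0.3        # Henon
    z: float = 2.0        # Schuster

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")


def _init_x0(params: MapParams, low: float, high: float) -> float:
    if params.x0 is not None:
        return float(params.x0)
    rng = np.random.default_rng(params.seed)
    return float(rng.uniform(low, high))


def logistic_map(params: MapParams | None = None, **kw) -> TimeSeries:
    """Logistic map x_{t+1} = r x_t (1 - x_t); fully chaotic at r = 4."""
    params = params or MapParams(**kw)
    if not (0 < params.r <= 4):
        raise ValueError("logistic r must be in (0, 4]")
    x = _init_x0(params, 1e-6, 1 - 1e-6)
    if not (0 < x < 1):
        raise ValueError("logistic x0 must be in (0, 1)")
    out = np.empty(params.M)
    for t in range(params.burn_in):
        x = params.r * x * (1.0 - x)
    for t in range(params.M):
        out[t] = x
        x = params.r * x * (1.0 - x)
    return TimeSeries(out, meta={"generator": "logistic", "r": params.r})


def henon_map(params: MapParams | None = None, **kw) -> TimeSeries:
    """Henon map x_{t+1} = 1 - a x_t^2 + y_t, y_{t+1} = b x_t; returns x."""
    params = params or MapParams(**kw)
    x = params.x0 if params.x0 is not None else 0.0
    y = params.y0 if params.y0 is not None else 0.0
    if params.x0 is None and params.seed is not None:
        rng = np.random.default_rng(params.seed)
        x, y = rng.uniform(-0.1, 0.1, size=2)
    out = np.empty(params.M)
    for t in range(params.burn_in + params.M):
        if t >= params.burn_in:
            out[t - params.burn_in] = x
        x, y = 1.0 - params.a * x * x + y, params.b * x
        if abs(x) > 1e6:
            raise RuntimeError(
                f"Henon orbit diverged at iteration {t} "
                f"(a={params.a}, b={params.b}); try other initial conditions"
            )
    return TimeSeries(out, meta={"generator": "henon", "a": params.a, "b": params.b})


def schuster_map(params: MapParams | None = None, **kw) -> TimeSeries:
    """Schuster map x_{t+1} = (x_t + x_t^z) mod 1 (intermittent dynamics)."""
    params = params or MapParams(**kw)
    x = _init_x0(params, 1e-6, 1 - 1e-6)
    if x <= 0:
        raise ValueError("Schuster x0 must be positive")
    out = np.empty(params.M)
    for t in range(params.burn_in):
        x = (x + x**params.z) % 1.0
    for t in range(params.M):
        out[t] = x
        x = (x + x**params.z) % 1.0
    return TimeSeries(out, meta={"generator": "schuster", "z": params.z})


# ---------------------------------------------------------------------------
# synthetic atlas
# ---------------------------------------------------------------------------

#: state-specific oscillatory components (center freq Hz, SD rel. to background);
#: realized as ~1 Hz-wide narrowband noise, not pure sinusoids
_STATE_OSC = {
    "W": [(8.5, 0.30)],           # posterior alpha
    "N2": [(13.0, 0.15), (1.2, 0.30)],   # spindle band + slow activity
    "N3": [(0.8, 0.50)],          # slow waves
    "R": [(6.0, 0.25)],           # theta-range activity
}

#: baseline spectral exponent per state (aperiodic slope in the 10-40 Hz band)
_STATE_K = {"W": 2.0, "N2": 2.5, "N3": 3.0, "R": 2.2}


@dataclass
class SyntheticAtlasConfig:
    """Structure and ground truth of the synthetic multichannel dataset.

    Each channel is group-specific f^-k background + state oscillations +
    white measurement noise, 60 s at 200 Hz, zero-padded to 13,600 samples.
    ``delta_k`` plants sex differences: for (region, state) keys present,
    male channels use k + delta_k.
    """

    regions: tuple = ("RegA", "RegB", "RegC")
    states: tuple = STATES
    patients_per_sex: int = 6
    channels_per_patient: int = 2
    sampling_rate: float = 200.0
    padded_length: int = 13_600
    valid_seconds: float = 60.0
    state_k: dict = field(default_factory=lambda: dict(_STATE_K))
    k_sigma: float = 0.1  # per-channel spread of the exponent (patient heterogeneity)
    oscillations: dict = field(default_factory=lambda: {s: list(v) for s, v in _STATE_OSC.items()})
    noise_floor: float = 0.02
    highpass: float = 0.5  # Hz, hardware-style high-pass on the background
    delta_k: dict = field(default_factory=dict)  # {(region, state): dk}
    age_range: tuple = (20, 55)
    hemisphere: str = "L"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patients_per_sex < 5:
            raise ValueError(
                "patients_per_sex must be >= 5 for a region to be analyzable"
            )


def _narrowband(n: int, fs: float, f0: float, rng: np.random.Generator,
                sigma: float = 0.5) -> np.ndarray:
    """Unit-SD narrowband noise at f0 (waxing/waning oscillation).

    Shaped in the frequency domain by a Gaussian bump (SD ``sigma`` Hz), so
    the component is effectively band-limited and does not leak across the
    spectral-fit band edges the way IIR filter skirts do.
    """
    X = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    X *= np.exp(-0.5 * ((f - f0) / sigma) ** 2)
    y = np.fft.irfft(X, n=n)
    sd = y.std()
    return y / sd if sd > 0 else y


def synthetic_atlas(config: SyntheticAtlasConfig):
    """Generate channel records and the ground-truth manifest.

    Returns ``(records, truth)`` where records is a list of
    :class:`renyispace.pipeline.ChannelRecord` and truth maps each
    region x state x sex group to its true spectral exponent plus the
    planted-difference bookkeeping.
    """
    from .pipeline import ChannelRecord  # local import to avoid a cycle

    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    n_valid = int(round(config.valid_seconds * fs))
    if n_valid > config.padded_length:
        raise ValueError("valid_seconds exceeds padded_length")
    t = np.arange(n_valid) / fs

    records = []
    truth = {"groups": {}, "planted": {f"{r}|{s}": dk for (r, s), dk in config.delta_k.items()},
             "seed": config.seed}
    pid = 0
    for region in config.regions:
        for sex in ("F", "M"):
            ages = rng.integers(*config.age_range, size=config.patients_per_sex)
            for j in range(config.patients_per_sex):
                pid += 1
                patient = f"P{pid:03d}"
                for state in config.states:
                    k_true = config.state_k[state]
                    if sex == "M":
                        k_true += config.delta_k.get((region, state), 0.0)
                    truth["groups"][f"{region}|{state}|{sex}"] = k_true
                    for ch in range(config.channels_per_patient):
                        k_ch = max(0.0, k_true + config.k_sigma * rng.standard_normal())
                        bg = knoise(NoiseSpec(k=k_ch, M=n_valid,
                                              sampling_rate=fs,
                                              highpass=config.highpass),
                                    rng=rng).values
                        sig = bg.copy()
                        for freq, amp in config.oscillations.get(state, []):
                            sig = sig + amp * _narrowband(n_valid, fs, freq, rng)
                        sig = sig + config.noise_floor * rng.standard_normal(n_valid)
                        padded = np.zeros(config.padded_length)
                        padded[:n_valid] = sig
                        ts = TimeSeries(padded, sampling_rate=fs,
                                        meta={"true_k": k_true, "valid_samples": n_valid})
                        records.append(ChannelRecord(
                            signal=ts, patient_id=patient, sex=sex,
                            hemisphere=config.hemisphere, region=region,
                            state=state, age=float(ages[j]),
                            channel=f"{patient}-{state}-ch{ch}",
                        ))
    return records, truth


def write_atlas(records, truth: dict, outdir: str | Path) -> Path:
    """Write an atlas to disk: one CSV per channel, manifest.tsv, truth JSON."""
    outdir = Path(outdir)
    (outdir / "signals").mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        fname = f"signals/{rec.channel}.csv"
        np.savetxt(outdir / fname, rec.signal.values, delimiter=",",
                   header="value", comments="")
        rows.append({
            "file": fname, "column": "value", "patient_id": rec.patient_id,
            "sex": rec.sex, "hemisphere": rec.hemisphere, "region": rec.region,
            "state": rec.state, "age": rec.age, "channel": rec.channel,
            "sampling_rate": rec.signal.sampling_rate,
        })
    import pandas as pd

    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return manifest
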