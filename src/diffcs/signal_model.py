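"""Core data types for 2D NMR data and the synthetic series generator.

The time-domain model is the standard sum of exponentially damped
complex sinusoids.  The indirect dimension is represented as a single
complex value per t1 increment (States-equivalent), so one "NUS point"
is one complex increment, matching how NUS grids are counted here.
Synthetic data is generated with zero phase, so the real part of the
complex 2D transform is the displayed spectrum.

The synthetic series generator emulates a variable-temperature HSQC
study of an intrinsically disordered protein titrated with liposomes:
a reference series (protein alone) whose peak amplitudes are flat in
temperature, and a target series (protein + liposomes) whose per-peak
amplitudes follow a hyperbolic-tangent melting profile, with a small
direct-dimension frequency shift, extra Gaussian line broadening and a
dilution amplitude factor relative to the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._fft import (
    cos2_window,
    freq_axis,
    gaussian_envelope,
    spectrum_from_time,
)
from .sampling import SamplingSchedule

__all__ = [
    "AxisMeta",
    "TimeDomain2D",
    "Spectrum2D",
    "Peak",
    "SyntheticSeriesSpec",
    "generate_fid",
    "generate_series",
    "series_assignments",
    "ft2d",
    "ft2d_complex",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class AxisMeta:
    """Metadata for one spectral axis.

    ``max_evolution_time`` is derived as (n_points - 1) / spectral_width
    when not given explicitly, and validated against it when it is.
    """

    n_points: int
    spectral_width: float  # Hz
    carrier_ppm: float = 0.0
    base_frequency: float = 500.0  # MHz
    max_evolution_time: float | None = None  # s

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        if self.spectral_width <= 0:
            raise ValueError("spectral_width must be positive")
        derived = (self.n_points - 1) / self.spectral_width
        if self.max_evolution_time is None:
            object.__setattr__(self, "max_evolution_time", derived)
        elif not np.isclose(self.max_evolution_time, derived, rtol=1e-9, atol=0.0):
            raise ValueError(
                f"max_evolution_time {self.max_evolution_time!r} inconsistent with "
                f"(n_points - 1)/spectral_width = {derived!r}"
            )

    @property
    def dwell(self) -> float:
        return 1.0 / self.spectral_width

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_points) / self.spectral_width

    def freqs(self, n_out: int | None = None) -> np.ndarray:
        return freq_axis(n_out or self.n_points, self.spectral_width)

    def ppm(self, n_out: int | None = None) -> np.ndarray:
        return self.carrier_ppm + self.freqs(n_out) / self.base_frequency

    def hz_to_ppm(self, f: float | np.ndarray):
        return self.carrier_ppm + np.asarray(f) / self.base_frequency

    def with_points(self, n: int) -> "AxisMeta":
        return AxisMeta(
            n_points=n,
            spectral_width=self.spectral_width,
            carrier_ppm=self.carrier_ppm,
            base_frequency=self.base_frequency,
        )


@dataclass
class TimeDomain2D:
    """A 2D FID: complex matrix indexed [t1 increment, t2 sample]."""

    data: np.ndarray
    axis1: AxisMeta  # indirect
    axis2: AxisMeta  # direct
    schedule: SamplingSchedule | None = None
    temperature: float | None = None  # degC
    label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim != 2:
            raise ValueError("FID data must be a 2D matrix")
        expected = self.schedule.m if self.schedule is not None else self.axis1.n_points
        if self.data.shape[0] != expected:
            raise ValueError(
                f"FID has {self.data.shape[0]} rows, expected {expected} "
                "(schedule length or full indirect grid)"
            )
        if self.data.shape[1] != self.axis2.n_points:
            raise ValueError("direct dimension length does not match axis2 metadata")

    def is_fully_sampled(self) -> bool:
        if self.schedule is None:
            return True
        return self.schedule.is_full()

    def copy(self) -> "TimeDomain2D":
        return replace(self, data=self.data.copy())


@dataclass
class Spectrum2D:
    """Frequency-domain real 2D matrix; axes carry the transform sizes."""

    data: np.ndarray
    axis1: AxisMeta
    axis2: AxisMeta
    temperature: float | None = None
    provenance: str = "full_ft"  # full_ft | cs_rec | dcs_rec | difference

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.shape != (self.axis1.n_points, self.axis2.n_points):
            raise ValueError("spectrum shape does not match axis metadata")


@dataclass(frozen=True)
class Peak:
    """One resonance: frequency offsets from carrier (Hz) and decay rates (1/s)."""

    f1: float
    f2: float
    r2_1: float = 0.0
    r2_2: float = 0.0
    amplitude: float = 1.0
    label: str = ""


def generate_fid(
    peaks: Sequence[Peak],
    axis1: AxisMeta,
    axis2: AxisMeta,
    noise_sigma: float = 0.0,
    seed: int = 0,
    temperature: float | None = None,
    label: str = "",
) -> TimeDomain2D:
    """Sum of damped complex sinusoids plus complex Gaussian noise.

    ``noise_sigma`` is the standard deviation of each noise component
    (real and imaginary, independently).  Deterministic in ``seed``.
    """
    for p in peaks:
        if abs(p.f1) > axis1.spectral_width / 2 or abs(p.f2) > axis2.spectral_width / 2:
            raise ValueError(
                f"peak {p.label or p} frequency outside +-SW/2 of the carrier"
            )
    t1 = axis1.times
    t2 = axis2.times
    data = np.zeros((axis1.n_points, axis2.n_points), dtype=np.complex128)
    for p in peaks:
        e1 = np.exp((2j * np.pi * p.f1 - p.r2_1) * t1)
        e2 = np.exp((2j * np.pi * p.f2 - p.r2_2) * t2)
        data += p.amplitude * np.outer(e1, e2)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        data = data + noise_sigma * (
            rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape)
        )
    return TimeDomain2D(data=data, axis1=axis1, axis2=axis2, temperature=temperature, label=label)


def _apodize(data: np.ndarray, apodization: str | None) -> np.ndarray:
    if apodization is None:
        return data
    if apodization != "cos2":
        raise ValueError(f"unknown apodization {apodization!r}")
    n1, n2 = data.shape
    return data * cos2_window(n1)[:, None] * cos2_window(n2)[None, :]


def ft2d_complex(
    fid: TimeDomain2D,
    zero_fill: tuple[int, int] | None = None,
    apodization: str | None = "cos2",
) -> np.ndarray:
    """Complex 2D transform of a fully sampled FID (unitary convention)."""
    if not fid.is_fully_sampled():
        raise ValueError(
            "FID is non-uniformly sampled; reconstruct it with "
            "diffcs.cs_recon.cs_reconstruct_2d instead of ft2d"
        )
    n1, n2 = fid.data.shape
    z1, z2 = zero_fill or (2 * n1, 2 * n2)
    x = _apodize(fid.data, apodization)
    X = spectrum_from_time(x, n_out=z2, axis=1)
    X = spectrum_from_time(X, n_out=z1, axis=0)
    return X


def ft2d(
    fid: TimeDomain2D,
    zero_fill: tuple[int, int] | None = None,
    apodization: str | None = "cos2",
) -> Spectrum2D:
    """Conventional processing: apodize, zero-fill, 2D FT, real part."""
    X = ft2d_complex(fid, zero_fill=zero_fill, apodization=apodization)
    z1, z2 = X.shape
    return Spectrum2D(
        data=X.real,
        axis1=fid.axis1.with_points(z1),
        axis2=fid.axis2.with_points(z2),
        temperature=fid.temperature,
        provenance="full_ft",
    )


@dataclass
class SyntheticSeriesSpec:
    """Conditions for a synthetic variable-temperature HSQC-like series.

    Defaults emulate the study design this package targets: ~100 amide
    peaks on a 256-point indirect grid (15N, 2.7 kHz width, ~94 ms
    maximum evolution), a 15-step series from 15 to 43 degC, a
    reference/target mismatch of 2 spectral points shift and 1 Hz extra
    Gaussian broadening in the direct dimension, and a 0.9 amplitude
    dilution of the target sample.  The direct dimension covers the
    amide 1H region (1.5 kHz) with 128 complex points, giving ~85 ms of
    acquisition, i.e. the resolution at which a 1 Hz broadening is a
    measurable effect.  ``shift_points`` is counted on the default
    2x zero-filled spectral grid.
    """

    n_peaks: int = 100
    n_indirect: int = 256
    n_direct: int = 128
    sw_indirect: float = 2700.0  # Hz
    sw_direct: float = 1500.0  # Hz
    carrier1_ppm: float = 118.0
    base1_mhz: float = 70.94
    carrier2_ppm: float = 8.2
    base2_mhz: float = 700.0
    temperatures: tuple = tuple(range(15, 44, 2))
    snr: float = 100.0
    noise_sigma: float | None = None  # overrides snr when set
    shift_points: float = 2.0
    broadening_hz: float = 1.0
    amplitude_scale: float = 0.9  # target dilution (585/650 volume ratio)
    reference_decline_per_degc: float = 0.0
    zero_fill_factor: int = 2
    seed: int = 0
    # optional per-peak parameter overrides: {column -> scalar or length-n_peaks
    # array}, applied to the columns of peak_table() (e.g. {"y_scale": 0.0})
    overrides: dict | None = None

    def __post_init__(self) -> None:
        temps = np.asarray(self.temperatures, dtype=float)
        if temps.size == 0:
            raise ValueError("temperature list must not be empty")
        if temps.size > 1 and np.any(np.diff(temps) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if self.n_peaks < 1:
            raise ValueError("n_peaks must be >= 1")
        if self.noise_sigma is not None and self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def axis1(self) -> AxisMeta:
        return AxisMeta(self.n_indirect, self.sw_indirect, self.carrier1_ppm, self.base1_mhz)

    @property
    def axis2(self) -> AxisMeta:
        return AxisMeta(self.n_direct, self.sw_direct, self.carrier2_ppm, self.base2_mhz)

    def peak_table(self) -> pd.DataFrame:
        """Per-peak parameters, deterministic in ``seed``.

        Transition temperatures rise linearly along the sequence from 24
        to 30 degC, mimicking an N-terminus that binds (melts) earlier
        than the rest of the membrane-binding region.
        """
        rng = np.random.default_rng(np.random.SeedSequence([int(self.seed), 101]))
        n = self.n_peaks
        residue = np.arange(1, n + 1)
        frac = (residue - 1) / max(n - 1, 1)
        table = pd.DataFrame(
            {
                "label": [f"{_AA[(r - 1) % len(_AA)]}{r:03d}N-H" for r in residue],
                "residue": residue,
                "f1_hz": rng.uniform(-0.45, 0.45, n) * self.sw_indirect,
                "f2_hz": rng.uniform(-0.45, 0.45, n) * self.sw_direct,
                "r2_1": rng.uniform(8.0, 20.0, n),
                "r2_2": rng.uniform(15.0, 30.0, n),
                "amplitude": rng.uniform(0.6, 1.4, n),
                # unbound baseline y_scale + y_shift = 1: at the lowest
                # temperatures every residue is (nearly) free in solution
                "x_scale": np.full(n, 0.3),
                "x_shift": 24.0 + 6.0 * frac,
                "y_scale": np.full(n, 0.8),
                "y_shift": np.full(n, 0.2),
            }
        )
        if self.overrides:
            for column, value in self.overrides.items():
                if column not in table.columns:
                    raise ValueError(f"unknown peak-table column {column!r}")
                table[column] = value
        table["omega1_ppm"] = self.axis1.hz_to_ppm(table["f1_hz"].to_numpy())
        table["omega2_ppm"] = self.axis2.hz_to_ppm(table["f2_hz"].to_numpy())
        return table


def series_assignments(spec: SyntheticSeriesSpec) -> pd.DataFrame:
    """Assigned peak list (label, omega1_ppm, omega2_ppm) for the series."""
    return spec.peak_table()[["label", "omega1_ppm", "omega2_ppm"]].copy()


def _resolve_noise_sigma(spec: SyntheticSeriesSpec, table: pd.DataFrame) -> float:
    """Time-domain noise level realizing the requested spectral SNR.

    SNR is defined on the processed spectrum: the median noiseless
    reference peak height divided by the spectral noise standard
    deviation.  Apodization and zero-filling attenuate white noise, so
    the attenuation factor of the processing chain is measured on a
    noise-only data set and divided out.
    """
    if spec.noise_sigma is not None:
        return float(spec.noise_sigma)
    if not np.isfinite(spec.snr) or spec.snr <= 0:
        return 0.0
    peaks = [
        Peak(r.f1_hz, r.f2_hz, r.r2_1, r.r2_2, r.amplitude, r.label)
        for r in table.itertuples()
    ]
    fid = generate_fid(peaks, spec.axis1, spec.axis2)
    spectrum = ft2d(fid)
    from ._fft import hz_to_index

    z1, z2 = spectrum.data.shape
    heights = [
        spectrum.data[
            hz_to_index(f1, z1, spec.sw_indirect), hz_to_index(f2, z2, spec.sw_direct)
        ]
        for f1, f2 in zip(table["f1_hz"], table["f2_hz"])
    ]
    noise_only = generate_fid([], spec.axis1, spec.axis2, noise_sigma=1.0, seed=2**20 + 7)
    gain = float(np.std(ft2d(noise_only).data))
    return float(np.median(heights) / (spec.snr * gain))


def generate_series(
    spec: SyntheticSeriesSpec,
) -> tuple[list[TimeDomain2D], list[TimeDomain2D]]:
    """Generate the (reference, target) FID series for a spec.

    The reference series has temperature-independent amplitudes (up to
    an optional linear decline); the target series follows the per-peak
    sigmoid profiles and carries the configured direct-dimension shift,
    broadening and dilution.  Bit-reproducible for a fixed spec.
    """
    from .series_analysis import sigmoid

    table = spec.peak_table()
    sigma = _resolve_noise_sigma(spec, table)
    temps = np.asarray(spec.temperatures, dtype=float)
    axis1, axis2 = spec.axis1, spec.axis2
    z2 = spec.zero_fill_factor * spec.n_direct
    delta_f2 = spec.shift_points * spec.sw_direct / z2
    seeds = np.random.SeedSequence([int(spec.seed), 202]).generate_state(2 * temps.size)

    reference, target = [], []
    broad_env = (
        gaussian_envelope(spec.n_direct, spec.sw_direct, spec.broadening_hz)
        if spec.broadening_hz > 0
        else None
    )
    for i, temp in enumerate(temps):
        decline = 1.0 - spec.reference_decline_per_degc * (temp - temps[0])
        ref_peaks = [
            Peak(r.f1_hz, r.f2_hz, r.r2_1, r.r2_2, r.amplitude * decline, r.label)
            for r in table.itertuples()
        ]
        ref = generate_fid(
            ref_peaks, axis1, axis2, noise_sigma=sigma, seed=int(seeds[2 * i]),
            temperature=float(temp), label=f"reference T={temp:g}C",
        )
        reference.append(ref)

        tgt_peaks = [
            Peak(
                r.f1_hz,
                r.f2_hz - delta_f2,
                r.r2_1,
                r.r2_2,
                r.amplitude
                * spec.amplitude_scale
                * sigmoid(temp, r.x_scale, r.x_shift, r.y_scale, r.y_shift),
                r.label,
            )
            for r in table.itertuples()
        ]
        tgt = generate_fid(
            tgt_peaks, axis1, axis2, noise_sigma=0.0, seed=0,
            temperature=float(temp), label=f"target T={temp:g}C",
        )
        if broad_env is not None:
            tgt.data *= broad_env[None, :]
        if sigma > 0:
            rng = np.random.default_rng(int(seeds[2 * i + 1]))
            tgt.data += sigma * (
                rng.standard_normal(tgt.data.shape)
                + 1j * rng.standard_normal(tgt.data.shape)
            )
        target.append(tgt)
    return reference, target
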