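"""Serial (variable-temperature) peak-intensity analysis.

Peak heights are grid maxima inside a small window around the assigned
position.  The per-residue relative intensity I_rel is the height in
the perturbed (target) spectrum over the height in the reference
spectrum at the same temperature; for slowly exchanging binding
equilibria 1 - I_rel tracks the bound (NMR-invisible) fraction.

I_rel(T) profiles are fitted with a scaled/shifted hyperbolic tangent,

    y = y_scale * (1 - tanh(x_scale * (x - x_shift))) / 2 + y_shift,

whose x_shift is the transition ("melting") temperature.  Fits are
bounded (0.05 < x_scale < 0.8, 20 < x_shift < 40 degC, y_scale within
half to twice the observed y range, y_shift within min(y) +- 0.1) and
profiles that are not sigmoidal enough are rejected by four filters:
too few visible points (< 6), a quasi-linear profile (x_scale <= 0.08),
a too-small transition (the last-but-one visible points on the two
sides differ by less than a factor of two), and a poor fit (relative
residual > 0.1).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

__all__ = [
    "PeakAssignment",
    "PeakSeries",
    "SigmoidFit",
    "sigmoid",
    "peak_height",
    "noise_std",
    "relative_intensity",
    "fit_sigmoid",
    "filter_fits",
    "normalized_residual",
    "transition_table",
    "read_peak_list",
    "write_peak_list",
]


def sigmoid(x, x_scale, x_shift, y_scale, y_shift):
    """Scaled/shifted falling tanh used for melting profiles."""
    return y_scale * (1.0 - np.tanh(x_scale * (np.asarray(x, float) - x_shift))) / 2.0 + y_shift


@dataclass(frozen=True)
class PeakAssignment:
    label: str
    omega1_ppm: float
    omega2_ppm: float


@dataclass
class PeakSeries:
    """Per-peak heights and relative intensities across a series."""

    label: str
    temperatures: np.ndarray
    heights_ref: np.ndarray
    heights_target: np.ndarray
    i_rel: np.ndarray  # NaN where not visible
    visible: np.ndarray  # bool per temperature

    def visible_points(self) -> tuple[np.ndarray, np.ndarray]:
        return self.temperatures[self.visible], self.i_rel[self.visible]


@dataclass
class SigmoidFit:
    """Fitted tanh parameters plus acceptance status.

    status is one of accepted / too_few_points / linear /
    small_transition / poor_fit.
    """

    label: str = ""
    x_scale: float = float("nan")
    x_shift: float = float("nan")  # transition temperature, degC
    y_scale: float = float("nan")
    y_shift: float = float("nan")
    relative_residual: float = float("nan")
    n_points: int = 0
    status: str = "accepted"
    message: str = ""

    def predict(self, x):
        return sigmoid(x, self.x_scale, self.x_shift, self.y_scale, self.y_shift)


def _nearest_index(ppm_axis: np.ndarray, ppm: float) -> int:
    lo, hi = float(ppm_axis.min()), float(ppm_axis.max())
    if not lo <= ppm <= hi:
        raise ValueError(f"position {ppm} ppm outside the spectral window [{lo:.3f}, {hi:.3f}]")
    return int(np.argmin(np.abs(ppm_axis - ppm)))


def peak_height(spectrum, peak: PeakAssignment, window: int = 1) -> float:
    """Maximum of the real spectrum within +-window points of the assignment."""
    i1 = _nearest_index(spectrum.axis1.ppm(), peak.omega1_ppm)
    i2 = _nearest_index(spectrum.axis2.ppm(), peak.omega2_ppm)
    n1, n2 = spectrum.data.shape
    box = spectrum.data[
        max(i1 - window, 0) : min(i1 + window + 1, n1),
        max(i2 - window, 0) : min(i2 + window + 1, n2),
    ]
    return float(box.max())


def noise_std(spectrum, corner_fraction: float = 1.0 / 16.0) -> float:
    """Noise level from a signal-free corner of the spectrum.

    The synthetic generator keeps peaks within +-45% of both spectral
    widths, so the outermost corner box is signal-free by construction;
    for real data pass an explicit region instead.
    """
    n1, n2 = spectrum.data.shape
    k1, k2 = max(int(n1 * corner_fraction), 2), max(int(n2 * corner_fraction), 2)
    return float(np.std(spectrum.data[:k1, :k2]))


def height_matrix(spectra, assignments, window: int = 1) -> pd.DataFrame:
    """Heights of every assigned peak in every spectrum of a series.

    Rows are peak labels, columns the spectrum temperatures.
    """
    temps = [s.temperature for s in spectra]
    rows = {
        a.label: [peak_height(s, a, window=window) for s in spectra] for a in assignments
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=temps)


def relative_intensity(
    series_target: pd.Series,
    series_ref: pd.Series,
    noise_threshold: float,
    label: str = "",
) -> PeakSeries:
    """I_rel = h_target / h_ref per temperature.

    Inputs are pandas Series of heights indexed by temperature; the two
    indexes must match.  I_rel is defined (and the point marked visible)
    only where both heights are above the noise threshold.
    """
    if len(series_target) != len(series_ref) or not np.allclose(
        np.asarray(series_target.index, float), np.asarray(series_ref.index, float)
    ):
        raise ValueError("target and reference series have mismatched temperature lists")
    ht = series_target.to_numpy(dtype=float)
    hr = series_ref.to_numpy(dtype=float)
    visible = (ht >= noise_threshold) & (hr >= noise_threshold)
    i_rel = np.where(visible, ht / np.where(hr != 0, hr, np.nan), np.nan)
    return PeakSeries(
        label=label,
        temperatures=np.asarray(series_target.index, dtype=float),
        heights_ref=hr,
        heights_target=ht,
        i_rel=i_rel,
        visible=visible,
    )


def fit_sigmoid(temps: np.ndarray, i_rel: np.ndarray, label: str = "") -> SigmoidFit:
    """Bounded trust-region-reflective least squares fit of the tanh profile."""
    temps = np.asarray(temps, dtype=float)
    y = np.asarray(i_rel, dtype=float)
    keep = np.isfinite(y) & np.isfinite(temps)
    x, y = temps[keep], y[keep]
    if x.size < 2:
        return SigmoidFit(label=label, n_points=int(x.size), status="too_few_points")
    y_range = max(float(y.max() - y.min()), 1e-9)
    y_min = float(y.min())
    lower = [0.05, 20.0, y_range / 2.0, y_min - 0.1]
    upper = [0.8, 40.0, 2.0 * y_range, y_min + 0.1]
    p0 = [
        0.3,
        float(np.clip(np.median(x), 20.0 + 1e-6, 40.0 - 1e-6)),
        float(np.clip(y_range, lower[2] + 1e-12, upper[2] - 1e-12)),
        y_min,
    ]
    try:
        popt, _ = curve_fit(
            sigmoid, x, y, p0=p0, bounds=(lower, upper), method="trf", maxfev=5000
        )
    except Exception as err:  # optimizer failure
        return SigmoidFit(label=label, n_points=int(x.size), status="poor_fit", message=str(err))
    resid = float(np.linalg.norm(sigmoid(x, *popt) - y) / max(np.linalg.norm(y), 1e-300))
    return SigmoidFit(
        label=label,
        x_scale=float(popt[0]),
        x_shift=float(popt[1]),
        y_scale=float(popt[2]),
        y_shift=float(popt[3]),
        relative_residual=resid,
        n_points=int(x.size),
        status="accepted",
    )


def filter_fits(
    fits: list[SigmoidFit], profiles: list[PeakSeries]
) -> tuple[list[SigmoidFit], dict[str, str]]:
    """Apply the four rejection rules; returns accepted fits and reasons.

    Rules, in order: fewer than six visible points; quasi-linear profile
    (x_scale <= 0.08); transition too small (second and penultimate
    visible points differ by less than a factor of two); relative
    residual above 0.1.  Fit statuses are updated in place.
    """
    accepted: list[SigmoidFit] = []
    reasons: dict[str, str] = {}
    for fit, prof in zip(fits, profiles):
        _, y = prof.visible_points()
        if y.size < 6 or fit.status == "too_few_points":
            fit.status = "too_few_points"
        elif fit.status == "poor_fit":
            pass
        elif fit.x_scale <= 0.08:
            fit.status = "linear"
        else:
            lo, hi = sorted((y[1], y[-2]))
            if lo <= 0 or hi / lo < 2.0:
                fit.status = "small_transition"
            elif fit.relative_residual > 0.1:
                fit.status = "poor_fit"
            else:
                fit.status = "accepted"
        if fit.status == "accepted":
            accepted.append(fit)
        else:
            reasons[fit.label] = fit.status
    return accepted, reasons


def normalized_residual(heights_rec: np.ndarray, heights_full: np.ndarray) -> float:
    """||h_rec - h_full||_2 / ||h_full||_2 over a peak-height vector."""
    h_rec = np.asarray(heights_rec, dtype=float)
    h_full = np.asarray(heights_full, dtype=float)
    if h_rec.shape != h_full.shape:
        raise ValueError("height vectors must have equal length")
    denom = np.linalg.norm(h_full)
    if denom == 0:
        raise ValueError("reference height vector has zero norm")
    return float(np.linalg.norm(h_rec - h_full) / denom)


_RESIDUE_RE = re.compile(r"(\d+)")


def transition_table(fits: list[SigmoidFit]) -> pd.DataFrame:
    """Transition temperatures per residue, sorted by residue number."""
    rows = []
    for fit in fits:
        match = _RESIDUE_RE.search(fit.label)
        if match is None:
            logger.warning("could not parse a residue number from label %r", fit.label)
            residue = np.nan
        else:
            residue = int(match.group(1))
        rows.append(
            {
                "label": fit.label,
                "residue": residue,
                "transition_temp_c": fit.x_shift,
                "x_scale": fit.x_scale,
                "relative_residual": fit.relative_residual,
                "status": fit.status,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["label", "residue", "transition_temp_c", "x_scale", "relative_residual", "status"],
    )
    if len(table):
        table = table.sort_values("residue", na_position="last").reset_index(drop=True)
    return table


def read_peak_list(path) -> list[PeakAssignment]:
    """Whitespace/comma-delimited table with header label, omega1_ppm, omega2_ppm."""
    table = pd.read_csv(path, sep=None, engine="python")
    required = {"label", "omega1_ppm", "omega2_ppm"}
    if not required.issubset(table.columns):
        raise ValueError(f"peak list must have columns {sorted(required)}")
    return [
        PeakAssignment(str(r.label), float(r.omega1_ppm), float(r.omega2_ppm))
        for r in table.itertuples()
    ]


def write_peak_list(assignments, path) -> None:
    pd.DataFrame(
        [(a.label, a.omega1_ppm, a.omega2_ppm) for a in assignments],
        columns=["label", "omega1_ppm", "omega2_ppm"],
    ).to_csv(path, sep="\t", index=False)


def plot_intensity_profiles(profiles, fits, path, max_panels: int = 12) -> None:
    """Small-multiple I_rel(T) panels with fitted curves."""
    import matplotlib.pyplot as plt

    chosen = list(zip(profiles, fits))[:max_panels]
    ncol = 4
    nrow = max((len(chosen) + ncol - 1) // ncol, 1)
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.2 * nrow), squeeze=False)
    for ax, (prof, fit) in zip(axes.ravel(), chosen):
        x, y = prof.visible_points()
        ax.plot(x, y, "o", ms=3)
        if np.isfinite(fit.x_shift):
            grid = np.linspace(prof.temperatures.min(), prof.temperatures.max(), 200)
            ax.plot(grid, fit.predict(grid), "-", lw=1)
        ax.set_title(f"{prof.label} [{fit.status}]", fontsize=8)
    for ax in axes.ravel()[len(chosen):]:
        ax.axis("off")
    fig.supxlabel("temperature (degC)")
    fig.supylabel("I_rel")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_transition_map(table: pd.DataFrame, path) -> None:
    """Transition temperature vs residue number for accepted fits."""
    import matplotlib.pyplot as plt

    accepted = table[table["status"] == "accepted"]
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.plot(accepted["residue"], accepted["transition_temp_c"], "o", ms=4)
    ax.set_xlabel("residue number")
    ax.set_ylabel("transition temperature (degC)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
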