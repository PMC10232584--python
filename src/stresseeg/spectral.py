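"""Relative band power with 1/f correction.

Power spectral densities are estimated with Welch's method (2-s Hann
windows, 50 % overlap), averaged over epochs, multiplied by ``f**exponent``
to compensate the 1/f background, and integrated per band by the
trapezoidal rule.  Relative power is the band integral divided by the
integral over the total band (1–40 Hz), so disjoint bands tiling the total
band sum exactly to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps


__all__ = [
    "BandScheme",
    "FRONTAL_CHANNELS",
    "psd_welch",
    "one_over_f_correct",
    "band_power",
    "relative_band_power",
    "power_table_from_epochs",
    "frontal_average",
]

#: Frontal electrode group used for the sensor-level average.
FRONTAL_CHANNELS = ("F7", "F3", "Fz", "FPz", "F4", "F8")


@dataclass(frozen=True)
class BandScheme:
    """Frequency bands (Hz) and the total band used for normalization."""

    theta: tuple[float, float] = (4.0, 8.0)
    alpha: tuple[float, float] = (8.0, 13.0)
    beta: tuple[float, float] = (13.0, 30.0)
    total: tuple[float, float] = (1.0, 40.0)

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bands.items():
            if not lo < hi:
                raise ValueError(f"band {name}: edges must increase, got ({lo}, {hi})")
            if lo < self.total[0] or hi > self.total[1]:
                raise ValueError(f"band {name} ({lo}, {hi}) outside total {self.total}")
        if not self.total[0] < self.total[1]:
            raise ValueError("total band edges must increase")

    @property
    def bands(self) -> dict[str, tuple[float, float]]:
        return {"theta": self.theta, "alpha": self.alpha, "beta": self.beta}


def psd_welch(
    data: np.ndarray,
    fs: float,
    window_s: float = 2.0,
    overlap: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD, averaged over epochs when a 3-d stack is given.

    Parameters
    ----------
    data : ndarray
        ``(n_samples,)``, ``(n_channels, n_samples)`` or
        ``(n_epochs, n_channels, n_samples)``.  Epoch axes are averaged
        after the per-epoch PSD (epoch-mean spectrum).
    fs : float
        Sampling rate (Hz).
    window_s : float
        Hann window length in seconds (default 2 s → 0.5 Hz resolution).

    Returns
    -------
    freqs, psd : ndarray
        ``psd`` has the channel axes of the input minus the sample axis,
        plus a trailing frequency axis.
    """
    x = np.asarray(data, dtype=float)
    nperseg = int(round(window_s * fs))
    if x.shape[-1] < nperseg:
        raise ValueError(
            f"epoch of {x.shape[-1]} samples shorter than one {nperseg}-sample window"
        )
    noverlap = int(round(nperseg * overlap))
    freqs, pxx = sps.welch(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap, axis=-1
    )
    if x.ndim == 3:
        pxx = pxx.mean(axis=0)
    return freqs, pxx


def one_over_f_correct(psd: np.ndarray, freqs: np.ndarray, exponent: float = 1.0) -> np.ndarray:
    """Multiply the density by ``f**exponent`` (exponent 0 is the identity)."""
    return np.asarray(psd, dtype=float) * np.asarray(freqs, dtype=float) ** exponent


def band_power(psd: np.ndarray, freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    """Trapezoidal integral of the density over ``band`` (edges inclusive).

    Trapezoid integrals are additive over adjacent bands sharing an edge,
    so a partition of the total band sums exactly to the total integral
    provided the edges fall on grid points.
    """
    lo, hi = band
    freqs = np.asarray(freqs, dtype=float)
    m = (freqs >= lo) & (freqs <= hi)
    if m.sum() < 2:
        raise ValueError(f"fewer than two frequency bins inside band ({lo}, {hi})")
    return np.trapezoid(np.asarray(psd, dtype=float)[..., m], freqs[m], axis=-1)


def relative_band_power(
    psd: np.ndarray,
    freqs: np.ndarray,
    band: tuple[float, float],
    total_band: tuple[float, float] = (1.0, 40.0),
) -> np.ndarray:
    """Band integral divided by the total-band integral, in [0, 1].

    Both numerator and denominator are taken on the same (already
    corrected) density.
    """
    if band[0] < total_band[0] or band[1] > total_band[1]:
        raise ValueError(f"band {band} not contained in total band {total_band}")
    total = band_power(psd, freqs, total_band)
    if np.any(total <= 0):
        raise ValueError("total power is zero; relative power undefined")
    return band_power(psd, freqs, band) / total


def power_table_from_epochs(
    epoch_sets,
    bands: BandScheme | None = None,
    exponent: float = 1.0,
    window_s: float = 2.0,
) -> pd.DataFrame:
    """Relative band power per participant × condition × channel × band.

    One row per key; the single relative power per cell is computed from
    the epoch-mean Welch spectrum after 1/f correction.
    """
    if bands is None:
        bands = BandScheme()
    rows = []
    for es in epoch_sets:
        if es.n_epochs == 0:
            continue
        freqs, pxx = psd_welch(es.data, es.fs, window_s=window_s)
        pxx = one_over_f_correct(pxx, freqs, exponent)
        for name, band in bands.bands.items():
            rp = relative_band_power(pxx, freqs, band, bands.total)
            for ch, value in zip(es.channel_labels, np.atleast_1d(rp)):
                rows.append(
                    {
                        "participant": es.participant,
                        "condition": es.condition,
                        "region": ch,
                        "band": name,
                        "relative_power": float(value),
                    }
                )
    return pd.DataFrame(rows, columns=["participant", "condition", "region", "band", "relative_power"])


def frontal_average(
    power_table: pd.DataFrame,
    channels=FRONTAL_CHANNELS,
    label: str = "frontal",
) -> pd.DataFrame:
    """Average per-channel relative power over the frontal electrode group.

    Raises if any requested channel is missing from the table.
    """
    channels = list(channels)
    present = set(power_table["region"].unique())
    missing = [c for c in channels if c not in present]
    if missing:
        raise ValueError(f"missing channels for frontal average: {missing}")
    sub = power_table[power_table["region"].isin(channels)]
    out = (
        sub.groupby(["participant", "condition", "band"], as_index=False)["relative_power"]
        .mean()
    )
    out.insert(2, "region", label)
    return out[["participant", "condition", "region", "band", "relative_power"]]
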