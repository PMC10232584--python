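"""Ground-truth-known synthetic two-condition recordings.

Every region signal is a sum of band-limited carriers (theta, alpha,
beta) modulated by slow log-normal amplitude envelopes, plus a white
background.  Requested region pairs share a common slow component on the
latent Gaussian scale (``√ρ·common + √(1−ρ)·private``), which gives
analytic control of the pairwise envelope correlation; the latent
correlation is adjusted for the exponentiation so the *log-normal*
envelopes hit the requested Pearson correlation in expectation.
Condition effects scale band amplitudes so that the realized
relative-power contrast matches the requested standardized effect size in
expectation (internally calibrated against the package's own spectral
estimator).  Channel data are an instantaneous linear mixture of the
region signals plus sensor noise, emulating spatial leakage.

All randomness derives from one root seed expanded into per-participant,
per-purpose substreams via ``numpy`` seed sequences with fixed spawn
keys, so any participant subset is reproducible in isolation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .connectivity import DEFAULT_SCOUT_MAP, canonical_pair
from .epochs import EpochSet

__all__ = [
    "BAND_EDGES",
    "SimulationConfig",
    "generate_epochs",
    "generate_study",
    "generate_rpeaks",
    "generate_scores",
    "default_event_times",
    "participant_id",
]

logger = logging.getLogger(__name__)

BAND_EDGES: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

# spawn-key namespaces for the substream scheme
_KEY_PARTICIPANT = 1
_KEY_EPOCHS = 2
_KEY_RPEAKS = 3
_KEY_SCORES = 4
_KEY_CALIBRATION = 5

_COND_INDEX = {"control": 0, "negative": 1}


def participant_id(index: int) -> str:
    return f"P{index:03d}"


@dataclass
class SimulationConfig:
    """Parameters of the synthetic two-condition study."""

    n_participants: int = 73
    n_epochs_per_condition: int = 30
    epoch_duration_s: float = 6.2
    fs: float = 512.0
    regions: tuple[str, ...] = tuple(DEFAULT_SCOUT_MAP)
    #: (region, band) → standardized condition effect on relative power
    band_effects: dict = field(default_factory=dict)
    #: (region pair, band) → condition difference in envelope correlation
    coupling_effects: dict = field(default_factory=dict)
    #: (region pair, band) → baseline envelope correlation (both conditions)
    baseline_coupling: dict = field(default_factory=dict)
    #: channels × regions mixing weights; None means identity (no leakage)
    mixing_matrix: np.ndarray | None = None
    channel_labels: tuple[str, ...] | None = None
    sensor_noise: float = 0.0
    band_amplitudes: dict = field(
        default_factory=lambda: {"theta": 0.7, "alpha": 1.0, "beta": 0.5}
    )
    background_amplitude: float = 0.8
    envelope_sigma: float = 0.5
    envelope_cutoff_hz: float = 1.0
    amplitude_sd: float = 0.2          # per participant × region × band, log scale
    # cardiac
    ibi_mean_ms: float = 850.0
    ibi_sd_ms: float = 50.0
    ibi_effect_ms: float = 0.0         # shortening of IBI_2..IBI_7, negative condition
    # questionnaire scores
    score_mean: float = 5.0
    score_shift: float = 0.0           # additive condition effect on the mean
    score_shape: float = 8.0
    score_participant_sd: float = 1.0
    likert: bool = False
    random_seed: int = 0

    _multipliers: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.n_samples_per_epoch <= 0:
            raise ValueError("epoch_duration_s * fs rounds to zero samples")
        for key in self.band_effects:
            region, band = key
            if region not in self.regions or band not in BAND_EDGES:
                raise ValueError(f"band_effects key {key} not in regions × bands")
        self.baseline_coupling = {
            (canonical_pair(*pair), band): rho
            for (pair, band), rho in self.baseline_coupling.items()
        }
        self.coupling_effects = {
            (canonical_pair(*pair), band): d
            for (pair, band), d in self.coupling_effects.items()
        }
        for (pair, band), rho in self.baseline_coupling.items():
            self._check_pair(pair, band)
            if not 0 <= rho < 1:
                raise ValueError(f"baseline coupling for {pair}/{band} must be in [0, 1)")
        for (pair, band), d in self.coupling_effects.items():
            self._check_pair(pair, band)
            rho = self.baseline_coupling.get((pair, band), 0.0) + d
            if not 0 <= rho < 1:
                raise ValueError(
                    f"coupling for {pair}/{band} leaves [0, 1) in the negative condition"
                )
        if self.mixing_matrix is not None:
            m = np.asarray(self.mixing_matrix, dtype=float)
            if m.ndim != 2 or m.shape[1] != len(self.regions):
                raise ValueError("mixing_matrix must be (n_channels, n_regions)")
            if np.linalg.matrix_rank(m) < m.shape[1]:
                raise ValueError("mixing_matrix must have full column rank")
            self.mixing_matrix = m
            if self.channel_labels is None:
                self.channel_labels = tuple(f"ch{i:02d}" for i in range(m.shape[0]))
            elif len(self.channel_labels) != m.shape[0]:
                raise ValueError("channel_labels length must match mixing rows")
        elif self.channel_labels is None:
            self.channel_labels = tuple(self.regions)

    def _check_pair(self, pair, band) -> None:
        a, b = pair
        if a not in self.regions or b not in self.regions or band not in BAND_EDGES:
            raise ValueError(f"coupling key ({pair}, {band}) not in regions × bands")

    @property
    def n_samples_per_epoch(self) -> int:
        # floor: never read past the recording
        return int(np.floor(self.epoch_duration_s * self.fs))

    def rng(self, *spawn_key: int) -> np.random.Generator:
        """Substream generator for a fixed purpose/participant key."""
        ss = np.random.SeedSequence(self.random_seed, spawn_key=tuple(spawn_key))
        return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# envelope / carrier machinery


def _slow_latent(rng: np.random.Generator, shape: tuple[int, int], fs: float, cutoff: float) -> np.ndarray:
    """Standardized slow Gaussian signals (band-limited white noise).

    The passband is [cutoff/6.5, cutoff] Hz: modulation stays at or below
    ``cutoff`` while power at periods longer than one epoch is excluded,
    so within-epoch envelope correlations match the full-series value.
    Synthesis happens at a low internal rate with generous padding (the
    normalized band edges at the target rate would be numerically
    degenerate and leak filter transients into the series), then the
    result is upsampled to ``fs``.
    """
    n_reg, total = shape
    lo = cutoff / 6.5
    up = max(1, int(fs // 16))
    fs_env = fs / up
    n_env = int(np.ceil(total / up))
    pad = int(np.ceil(10.0 / lo * fs_env))  # ~10 time constants of the low edge
    z = rng.standard_normal((n_reg, n_env + 2 * pad))
    sos = sps.butter(
        2, [lo / (fs_env / 2.0), cutoff / (fs_env / 2.0)], btype="bandpass", output="sos"
    )
    z = sps.sosfiltfilt(sos, z, axis=-1)[:, pad : pad + n_env]
    if up > 1:
        z = sps.resample_poly(z, up, 1, axis=-1)
    z = z[:, :total]
    z -= z.mean(axis=-1, keepdims=True)
    sd = z.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return z / sd


def _carrier_freqs(rng: np.random.Generator, n_reg: int, band: tuple[float, float]) -> np.ndarray:
    """Random carrier frequencies, stratified across the band interior."""
    lo, hi = band
    bw = hi - lo
    slots = rng.permutation(n_reg)
    jitter = rng.uniform(0.15, 0.85, size=n_reg)
    return lo + 0.1 * bw + 0.8 * bw * (slots + jitter) / n_reg


def _carrier(
    rng: np.random.Generator,
    shape: tuple[int, int],
    fs: float,
    band: tuple[float, float],
    freqs: np.ndarray | None = None,
) -> np.ndarray:
    """Unit-RMS constant-envelope carriers: one random-phase sinusoid per
    region.

    Constant carrier envelopes make the Hilbert envelope of the product
    track the generating slow envelope (noise carriers would add Rayleigh
    envelope fluctuations of their own); distinct frequencies keep the
    carriers mutually near-orthogonal over an epoch.
    """
    n_reg, total = shape
    if freqs is None:
        freqs = _carrier_freqs(rng, n_reg, band)
    phases = rng.uniform(0.0, 2 * np.pi, size=n_reg)
    t = np.arange(total) / fs
    return np.sqrt(2.0) * np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])


def _latent_corr_for_lognormal(rho: float, sigma: float) -> float:
    """Latent Gaussian correlation giving Pearson correlation ``rho``
    between the exponentiated (log-normal) envelopes."""
    if rho == 0:
        return 0.0
    return float(np.log1p(rho * np.expm1(sigma**2)) / sigma**2)


def _whiten(z: np.ndarray) -> np.ndarray:
    """Transform rows so the sample covariance is exactly the identity."""
    cov = z @ z.T / z.shape[-1]
    w = np.linalg.inv(np.linalg.cholesky(cov))
    return w @ z


def _epoch_mean_corr(a: np.ndarray, b: np.ndarray, epoch_len: int) -> float:
    """Mean over epochs of the within-epoch Pearson correlation."""
    n_ep = a.shape[-1] // epoch_len
    x = a[: n_ep * epoch_len].reshape(n_ep, epoch_len)
    y = b[: n_ep * epoch_len].reshape(n_ep, epoch_len)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    ok = den > 0
    return float(np.mean(num[ok] / den[ok]))


def _calibrated_envelopes(
    z: np.ndarray,
    latent_corr: np.ndarray,
    targets: dict[tuple[int, int], float],
    sigma: float,
    epoch_len: int,
    tol: float = 5e-4,
    max_iter: int = 40,
) -> np.ndarray:
    """Log-normal envelopes whose realized pair correlations hit ``targets``.

    ``z`` holds whitened slow latents (sample covariance exactly I), so
    the latent sample correlation equals ``latent_corr`` exactly; the
    residual mismatch introduced by the exponentiation is removed by a
    secant adjustment of the requested latent entries.  Realized
    correlations are evaluated as the epoch-mean within-epoch Pearson
    correlation — the scale on which the envelope-correlation estimator
    operates.
    """
    C = latent_corr.copy()
    env = None
    prev: dict[tuple[int, int], tuple[float, float]] = {}
    for _ in range(max_iter):
        lat = _cholesky_psd(C) @ z
        env = np.exp(sigma * lat - sigma**2 / 2)
        if not targets:
            break
        realized = {
            key: _epoch_mean_corr(env[key[0]], env[key[1]], epoch_len) for key in targets
        }
        if max(abs(targets[k] - realized[k]) for k in targets) < tol:
            break
        for key, tgt in targets.items():
            c, r = C[key], realized[key]
            slope = 1.0
            if key in prev:
                c0, r0 = prev[key]
                if abs(c - c0) > 1e-9 and (r - r0) * (c - c0) > 0:
                    slope = np.clip((r - r0) / (c - c0), 0.3, 10.0)
            prev[key] = (c, r)
            step = float(np.clip((tgt - r) / slope, -0.2, 0.2))
            v = float(np.clip(c + step, -0.999, 0.999))
            C[key] = C[key[::-1]] = v
        w, V = np.linalg.eigh(C)
        if w.min() < 1e-8:  # keep the working matrix positive definite
            C = V @ np.diag(np.clip(w, 1e-8, None)) @ V.T
            d = np.sqrt(np.diag(C))
            C = C / np.outer(d, d)
    return env


def _coupling_targets(
    config: SimulationConfig, band: str, condition: str
) -> dict[tuple[int, int], float]:
    """Requested envelope correlations (region-index pairs) for one band."""
    idx = {r: i for i, r in enumerate(config.regions)}
    targets: dict[tuple[int, int], float] = {}
    for (pair, b), rho in config.baseline_coupling.items():
        if b != band:
            continue
        tgt = rho
        if condition == "negative":
            tgt += config.coupling_effects.get((pair, b), 0.0)
        targets[(idx[pair[0]], idx[pair[1]])] = tgt
    for (pair, b), d in config.coupling_effects.items():
        if b != band or (pair, b) in config.baseline_coupling:
            continue
        targets[(idx[pair[0]], idx[pair[1]])] = d if condition == "negative" else 0.0
    return targets


def _coupling_matrix(config: SimulationConfig, band: str, condition: str) -> np.ndarray:
    """Initial latent correlation matrix across regions for one band."""
    n = len(config.regions)
    C = np.eye(n)
    targets = _coupling_targets(config, band, condition)
    for (i, j), target in targets.items():
        lat = _latent_corr_for_lognormal(target, config.envelope_sigma)
        C[i, j] = C[j, i] = lat
    w = np.linalg.eigvalsh(C)
    if w.min() < -1e-10:
        regions = list(config.regions)
        pairs = [(regions[i], regions[j]) for i, j in targets]
        raise ValueError(
            f"requested envelope correlations for band {band!r} are jointly "
            f"unsatisfiable (non-positive-semidefinite); offending pairs: {pairs}"
        )
    return C


def _cholesky_psd(C: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        return np.linalg.cholesky(C + 1e-10 * np.eye(len(C)))


# ---------------------------------------------------------------------------
# condition-effect calibration


def _estimate_relative_power(config: SimulationConfig, data: np.ndarray, band: str) -> float:
    from .spectral import one_over_f_correct, psd_welch, relative_band_power

    window_s = min(2.0, config.epoch_duration_s / 2.0)
    freqs, pxx = psd_welch(data, config.fs, window_s=window_s)
    pxx = one_over_f_correct(pxx, freqs, 1.0)
    return float(relative_band_power(pxx, freqs, BAND_EDGES[band], (1.0, 40.0)))


def _calibrate_band_effect(config: SimulationConfig, band: str) -> tuple[float, float]:
    """Null-condition mean and between-participant SD of relative power.

    Estimated from a small dedicated simulation substream using the same
    generator and the package's own spectral estimator, so the injected
    standardized effects refer to the scale on which they are estimated.
    """
    n_cal = 12
    values = []
    for i in range(n_cal):
        rng = config.rng(_KEY_CALIBRATION, i)
        sig = _single_region_signal(config, rng, band_multipliers={})
        values.append(_estimate_relative_power(config, sig, band))
    values = np.asarray(values)
    return float(values.mean()), float(values.std(ddof=1))


def _single_region_signal(config: SimulationConfig, rng: np.random.Generator, band_multipliers: dict) -> np.ndarray:
    """One region's signal for calibration (one long pseudo-epoch)."""
    n = config.n_samples_per_epoch * max(4, min(config.n_epochs_per_condition, 8))
    total = np.zeros(n)
    for band, edges in BAND_EDGES.items():
        lat = _slow_latent(rng, (1, n), config.fs, config.envelope_cutoff_hz)[0]
        env = np.exp(config.envelope_sigma * lat - config.envelope_sigma**2 / 2)
        car = _carrier(rng, (1, n), config.fs, edges)[0]
        amp = config.band_amplitudes[band] * np.exp(rng.normal(0.0, config.amplitude_sd))
        amp *= band_multipliers.get(band, 1.0)
        total += amp * env * car
    total += config.background_amplitude * rng.standard_normal(n)
    return total


def _effect_multipliers(config: SimulationConfig) -> dict:
    """Amplitude multipliers realizing the requested standardized effects."""
    if config._multipliers is not None:
        return config._multipliers
    mult: dict = {}
    cal_cache: dict[str, tuple[float, float]] = {}
    for (region, band), effect in config.band_effects.items():
        if effect == 0.0:
            continue
        if band not in cal_cache:
            cal_cache[band] = _calibrate_band_effect(config, band)
        r0, sd = cal_cache[band]
        r1 = float(np.clip(r0 + effect * sd, 1e-4, 1 - 1e-4))
        # amplitude scale m with relative power r(m) = m²·p/(T − p + m²·p)
        m2 = (r1 * (1 - r0)) / (r0 * (1 - r1))
        mult[(region, band)] = float(np.sqrt(m2))
    config._multipliers = mult
    return mult


# ---------------------------------------------------------------------------
# public generators


def generate_epochs(
    config: SimulationConfig,
    participant: int = 0,
    condition: str = "control",
    keep_envelopes: bool = False,
) -> EpochSet:
    """Generate the epochs of one participant in one condition.

    The returned :class:`EpochSet` carries ground truth in
    ``ground_truth``: realized envelope correlations for every requested
    pair and the per-region band amplitudes; with ``keep_envelopes`` the
    generating envelopes themselves are retained (large).
    """
    if condition not in _COND_INDEX:
        raise ValueError(f"condition must be one of {list(_COND_INDEX)}")
    n_reg = len(config.regions)
    n_ep = config.n_epochs_per_condition
    n_samp = config.n_samples_per_epoch
    total = n_ep * n_samp
    mult = _effect_multipliers(config)

    # participant-level randomness shared across conditions: amplitude
    # intercepts and carrier frequencies (a per-condition frequency draw
    # would masquerade as a condition effect after the 1/f weighting)
    prng = config.rng(_KEY_PARTICIPANT, participant)
    intercepts = {
        (r, b): np.exp(prng.normal(0.0, config.amplitude_sd))
        for r in config.regions
        for b in BAND_EDGES
    }
    carrier_freqs = {
        b: _carrier_freqs(prng, n_reg, edges) for b, edges in BAND_EDGES.items()
    }

    rng = config.rng(_KEY_EPOCHS, participant, _COND_INDEX[condition])
    roi = np.zeros((n_reg, total))
    envelopes: dict[str, np.ndarray] = {}
    amplitudes: dict[str, float] = {}
    for band, edges in BAND_EDGES.items():
        C = _coupling_matrix(config, band, condition)
        targets = _coupling_targets(config, band, condition)
        z = _whiten(_slow_latent(rng, (n_reg, total), config.fs, config.envelope_cutoff_hz))
        env = _calibrated_envelopes(z, C, targets, config.envelope_sigma, n_samp)
        car = _carrier(rng, (n_reg, total), config.fs, edges, freqs=carrier_freqs[band])
        for i, region in enumerate(config.regions):
            amp = config.band_amplitudes[band] * intercepts[(region, band)]
            if condition == "negative":
                amp *= mult.get((region, band), 1.0)
            roi[i] += amp * env[i] * car[i]
            amplitudes[f"{region}|{band}"] = amp
        envelopes[band] = env
    roi += config.background_amplitude * rng.standard_normal((n_reg, total))

    # realized envelope correlations for the requested pairs
    idx = {r: i for i, r in enumerate(config.regions)}
    env_corr: dict[str, float] = {}
    keys = set(config.baseline_coupling) | set(config.coupling_effects)
    for (a, b), band in keys:
        e = envelopes[band]
        r = _epoch_mean_corr(e[idx[a]], e[idx[b]], n_samp)
        env_corr[f"{a}|{b}|{band}"] = r

    ground_truth: dict = {
        "envelope_corr": env_corr,
        "band_amplitude": amplitudes,
        "effect_multipliers": {f"{r}|{b}": m for (r, b), m in mult.items()},
    }
    if keep_envelopes:
        ground_truth["envelopes"] = {
            band: env.reshape(n_reg, n_ep, n_samp) for band, env in envelopes.items()
        }

    if config.mixing_matrix is not None:
        data = config.mixing_matrix @ roi
    else:
        data = roi
    if config.sensor_noise > 0:
        data = data + config.sensor_noise * rng.standard_normal(data.shape)

    data = data.reshape(data.shape[0], n_ep, n_samp).transpose(1, 0, 2)
    return EpochSet(
        data=data,
        fs=config.fs,
        channel_labels=list(config.channel_labels),
        participant=participant_id(participant),
        condition=condition,
        epoch_onset_s=-0.2,
        ground_truth=ground_truth,
    )


def generate_study(config: SimulationConfig, conditions=("control", "negative")):
    """Yield ``(participant_index, {condition: EpochSet})`` for the cohort."""
    for p in range(config.n_participants):
        yield p, {c: generate_epochs(config, p, c) for c in conditions}


def default_event_times(n_events: int, spacing_s: float = 15.0, start_s: float = 20.0) -> np.ndarray:
    """Evenly spaced event onsets in seconds."""
    return start_s + spacing_s * np.arange(n_events)


def generate_rpeaks(
    config: SimulationConfig,
    event_times_s,
    condition: str = "control",
    participant: int = 0,
    pad_beats: int = 15,
) -> np.ndarray:
    """R-peak timestamps (s) with condition-dependent post-event shortening.

    Baseline inter-beat intervals are Gaussian around ``ibi_mean_ms``; in
    the negative condition the six intervals mapping to IBI_2..IBI_7
    after each event are shortened by ``ibi_effect_ms``.  Events too
    close to the series edge are left unmodified with a warning.
    """
    events = np.sort(np.atleast_1d(np.asarray(event_times_s, dtype=float)))
    mean_s = config.ibi_mean_ms / 1000.0
    if len(events) > 1 and np.min(np.diff(events)) <= 12 * mean_s:
        raise ValueError("event spacing must exceed 12 mean inter-beat intervals")
    rng = config.rng(_KEY_RPEAKS, participant, _COND_INDEX[condition])
    t0 = events[0] - pad_beats * mean_s
    t1 = events[-1] + pad_beats * mean_s
    n_beats = int(np.ceil((t1 - t0) / mean_s * 1.5)) + 20
    ibis = rng.normal(mean_s, config.ibi_sd_ms / 1000.0, size=n_beats)
    ibis = np.clip(ibis, 0.3 * mean_s, None)

    if condition == "negative" and config.ibi_effect_ms != 0.0:
        for ev in events:
            t = t0 + np.concatenate([[0.0], np.cumsum(ibis)])
            anchor = int(np.argmin(np.abs(t - ev)))
            lo, hi = anchor + 1, anchor + 7  # intervals of IBI_2 .. IBI_7
            if anchor - 4 < 0 or hi > len(ibis) - 1:
                warnings.warn(
                    f"event at {ev:.1f}s too close to the series edge; left unmodified",
                    stacklevel=2,
                )
                continue
            ibis[lo:hi] = np.clip(
                ibis[lo:hi] - config.ibi_effect_ms / 1000.0, 0.25 * mean_s, None
            )
    t = t0 + np.concatenate([[0.0], np.cumsum(ibis)])
    return t


def generate_scores(
    config: SimulationConfig,
    scale: str = "valence",
) -> pd.DataFrame:
    """Gamma-distributed per-participant, per-condition outcome scores.

    Participant random intercepts act on the mean; the negative condition
    adds ``score_shift``.  With ``likert`` the draws are rounded and
    clipped to the 1–9 range.
    """
    for cond, shift in (("control", 0.0), ("negative", config.score_shift)):
        if config.score_mean + shift <= 0:
            raise ValueError(
                f"requested mean for condition {cond!r} is non-positive "
                "(outside gamma support)"
            )
    rng = config.rng(_KEY_SCORES, hash(scale) % (2**31))
    rows = []
    for p in range(config.n_participants):
        b = config.rng(_KEY_PARTICIPANT, p, _KEY_SCORES).normal(0.0, config.score_participant_sd)
        sex = "F" if p % 2 == 0 else "M"
        for cond in ("control", "negative"):
            mean = config.score_mean + b + (config.score_shift if cond == "negative" else 0.0)
            mean = max(mean, 0.05 * config.score_mean)
            value = rng.gamma(config.score_shape, mean / config.score_shape)
            if config.likert:
                value = float(np.clip(np.round(value), 1, 9))
            rows.append(
                {
                    "participant": participant_id(p),
                    "condition": cond,
                    "sex": sex,
                    "scale": scale,
                    "value": float(value),
                }
            )
    return pd.DataFrame(rows)
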