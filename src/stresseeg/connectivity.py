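"""Orthogonalized amplitude-envelope-correlation functional connectivity.

For each epoch and band, two region series are band-passed, pairwise
orthogonalized in both orders (least-squares projection, the stabilized
Gram–Schmidt step), their Hilbert envelopes correlated, and the two
orientation values averaged; epoch values are then averaged into a single
AEC per region pair.  Orthogonalization removes zero-lag shared components
so instantaneous linear mixing (spatial leakage) cannot inflate the
estimate.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.signal import hilbert

from .preprocess import bandpass

__all__ = [
    "ROICatalog",
    "DEFAULT_SCOUT_MAP",
    "combine_scouts_pca",
    "orthogonalize",
    "envelope",
    "envelope_correlation",
    "aec_pair",
    "enumerate_connections",
    "connectivity_table_from_epochs",
    "canonical_pair",
]

logger = logging.getLogger(__name__)

#: Mapping of the ten cortical regions of interest to their constituent
#: atlas scouts (left/right anterior insula, posterior and anterior
#: cingulate, precuneus, orbitofrontal cortex).
DEFAULT_SCOUT_MAP: dict[str, list[str]] = {
    "anterior insula L": [
        "Insula - anterior L",
        "Pars Opercularis - Inferior L",
        "Pars Opercularis - Superior L",
        "Pars Triangularis - Middle L",
        "Pars Triangularis - Posterior L",
    ],
    "anterior insula R": [
        "Insula - anterior R",
        "Pars Opercularis - Inferior R",
        "Pars Opercularis - Superior R",
        "Pars Triangularis - Middle R",
        "Pars Triangularis - Posterior R",
    ],
    "PCC L": ["Cingulate Gyrus - Posterior L"],
    "PCC R": ["Cingulate Gyrus - Posterior R"],
    "precuneus L": ["Precuneus - Inferior L"],
    "precuneus R": ["Precuneus - Inferior R"],
    "ACC L": ["Cingulate Gyrus - Anterior L"],
    "ACC R": ["Cingulate Gyrus - Anterior R"],
    "orbitofrontal L": [
        "Anterior Orbito-frontal Gyrus L",
        "Gyrus Rectus L",
        "Middle Orbito-frontal Gyrus L",
    ],
    "orbitofrontal R": [
        "Anterior Orbito-frontal Gyrus R",
        "Gyrus Rectus R",
        "Middle Orbito-frontal Gyrus R",
    ],
}

PRECUNEUS_REGIONS = ("precuneus L", "precuneus R")


@dataclass(frozen=True)
class ROICatalog:
    """Region-of-interest catalog: region label → constituent scout labels."""

    scout_map: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_SCOUT_MAP.items()}
    )

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for region, scouts in self.scout_map.items():
            if not scouts:
                raise ValueError(f"region {region!r} has an empty scout list")
            overlap = seen.intersection(scouts)
            if overlap:
                raise ValueError(f"scouts {sorted(overlap)} assigned to more than one region")
            seen.update(scouts)

    @property
    def regions(self) -> list[str]:
        return list(self.scout_map)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.scout_map, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ROICatalog":
        raw = yaml.safe_load(Path(path).read_text())
        return cls({str(k): [str(s) for s in v] for k, v in raw.items()})


def combine_scouts_pca(series_list) -> np.ndarray:
    """Collapse several scout series into their first principal component.

    A single input series is returned unchanged.  The component sign is
    fixed so its correlation with the scout mean is non-negative; the
    returned series keeps the PC score scale.
    """
    series = [np.asarray(s, dtype=float) for s in series_list]
    if not series:
        raise ValueError("need at least one scout series")
    lengths = {s.shape[-1] for s in series}
    if len(lengths) != 1:
        raise ValueError(f"scout series lengths differ: {sorted(lengths)}")
    if len(series) == 1:
        return series[0]
    x = np.stack(series)                      # (n_scouts, n_samples)
    xc = x - x.mean(axis=1, keepdims=True)
    # first right-singular vector of the scout × time matrix = PC scores
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    pc = s[0] * vt[0]
    mean_series = xc.mean(axis=0)
    if np.dot(pc, mean_series) < 0:
        pc = -pc
    return pc


def orthogonalize(x: np.ndarray, y: np.ndarray, rel_tol: float = 1e-8) -> np.ndarray:
    """Return the component of ``y`` orthogonal to ``x`` (zero inner product).

    The projection coefficient is computed against the renormalized ``x``
    (the stabilized Gram–Schmidt step).  Asymmetric in its arguments.
    A near-zero residual (``y`` collinear with ``x``) is flagged with a
    warning because envelope correlation of the residual is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    nx = np.linalg.norm(x)
    if nx == 0:
        raise ValueError("cannot orthogonalize against an identically zero signal")
    q = x / nx
    resid = y - np.dot(q, y) * q
    if np.linalg.norm(resid) < rel_tol * max(np.linalg.norm(y), 1e-300):
        warnings.warn(
            "orthogonalization residual is near zero (collinear inputs); "
            "downstream envelope correlation is undefined",
            stacklevel=2,
        )
    return resid


def envelope(x: np.ndarray) -> np.ndarray:
    """Amplitude envelope: magnitude of the analytic signal (last axis)."""
    return np.abs(hilbert(np.asarray(x, dtype=float), axis=-1))


def _trim(n_samples: int, fs: float, edge_s: float) -> slice:
    k = int(round(edge_s * fs))
    if 2 * k >= n_samples:
        return slice(None)
    return slice(k, n_samples - k)


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def envelope_correlation(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    band: tuple[float, float] | None = None,
    edge_s: float = 0.25,
) -> float:
    """Plain (non-orthogonalized) envelope correlation, averaged over epochs.

    Reference value for leakage demonstrations; inputs are (n_epochs,
    n_samples) or 1-d.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    vals = []
    for xe, ye in zip(x, y):
        if band is not None:
            xe = bandpass(xe, fs, *band)
            ye = bandpass(ye, fs, *band)
        sl = _trim(xe.shape[-1], fs, edge_s)
        r = _corr(envelope(xe)[sl], envelope(ye)[sl])
        if not np.isnan(r):
            vals.append(r)
    return float(np.mean(vals)) if vals else np.nan


def aec_pair(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    band: tuple[float, float],
    edge_s: float = 0.25,
    prefiltered: bool = False,
) -> float:
    """Orthogonalized amplitude envelope correlation for one region pair.

    Per epoch: band-pass both series, orthogonalize in both orders,
    correlate the Hilbert envelopes (first and last ``edge_s`` seconds
    discarded) and average the two orientations; epoch values are then
    averaged.  Symmetric in (x, y) by construction; lies in [−1, 1].

    Epochs where either envelope has zero variance are skipped with a
    warning; if every epoch is skipped the result is NaN.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape != y.shape:
        raise ValueError(f"epoch stacks differ in shape: {x.shape} vs {y.shape}")
    vals = []
    n_skipped = 0
    for xe, ye in zip(x, y):
        if not prefiltered:
            xe = bandpass(xe, fs, *band)
            ye = bandpass(ye, fs, *band)
        sl = _trim(xe.shape[-1], fs, edge_s)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # collinear flag handled via NaN below
                r1 = _corr(envelope(xe)[sl], envelope(orthogonalize(xe, ye))[sl])
                r2 = _corr(envelope(ye)[sl], envelope(orthogonalize(ye, xe))[sl])
        except ValueError:  # identically zero epoch
            r1 = r2 = np.nan
        if np.isnan(r1) or np.isnan(r2):
            n_skipped += 1
            continue
        vals.append(0.5 * (r1 + r2))
    if n_skipped:
        warnings.warn(f"{n_skipped} epoch(s) skipped (zero-variance envelope)", stacklevel=2)
    if not vals:
        logger.warning("all epochs skipped; AEC undefined for this pair")
        return np.nan
    return float(np.mean(vals))


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Stable unordered-pair key: sorted region labels."""
    if a == b:
        raise ValueError(f"self-pair {a!r} is not a connection")
    return (a, b) if a <= b else (b, a)


def enumerate_connections(
    catalog: ROICatalog | list[str],
    bands,
    anchor=None,
) -> list[tuple[tuple[str, str], str]]:
    """List (unordered region pair, band) items, canonically ordered.

    Without ``anchor``: all unordered pairs × bands.  With ``anchor`` (a
    region set): only pairs containing at least one anchor region.
    """
    regions = catalog.regions if isinstance(catalog, ROICatalog) else list(catalog)
    bands = list(bands)
    anchor = set(anchor) if anchor is not None else None
    if anchor is not None:
        unknown = anchor.difference(regions)
        if unknown:
            raise ValueError(f"anchor regions not in catalog: {sorted(unknown)}")
    pairs = [
        canonical_pair(a, b)
        for a, b in itertools.combinations(regions, 2)
        if anchor is None or a in anchor or b in anchor
    ]
    pairs = sorted(set(pairs))
    return [(pair, band) for pair in pairs for band in bands]


def connectivity_table_from_epochs(
    epoch_sets,
    connections,
    band_edges: dict[str, tuple[float, float]],
    edge_s: float = 0.25,
) -> pd.DataFrame:
    """AEC per participant × condition × region pair × band (tidy table).

    ``connections`` is the output of :func:`enumerate_connections`; region
    labels must be channel labels of the epoch sets.
    """
    rows = []
    for es in epoch_sets:
        if es.n_epochs == 0:
            continue
        for (r1, r2), band in connections:
            a = es.channel(r1)
            b = es.channel(r2)
            val = aec_pair(a, b, es.fs, band_edges[band], edge_s=edge_s)
            rows.append(
                {
                    "participant": es.participant,
                    "condition": es.condition,
                    "region_a": r1,
                    "region_b": r2,
                    "band": band,
                    "aec": val,
                }
            )
    return pd.DataFrame(
        rows, columns=["participant", "condition", "region_a", "region_b", "band", "aec"]
    )
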