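"""Synthetic BOLD-like data with known ground truth.

The generator emulates the statistical structure that the event-triggered
estimators assume: z-scored signals with realistic temporal
autocorrelation (empirical lag-1 autocorrelation of resting-state BOLD
lies around 0.6-0.85), transient hemodynamic-response-shaped events of
roughly 10-15 s duration, and optional directed coupling in which a
receiver region reproduces a fraction of a driver's events after a
configurable — possibly sub-sample — lag.

Sub-sample lags are produced by shifting the *continuous* HRF before
sampling, so the imposed lag is exact ground truth rather than an
interpolation artefact.  All randomness flows through one
``numpy.random.default_rng(seed)`` (PCG64), so outputs are bit-identical
for a fixed seed across platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal as _sig
from scipy.special import gammaln

from .signal_io import RoiTimeSeries, zscore


@dataclass(frozen=True)
class HrfParams:
    """Double-gamma hemodynamic response: positive peak plus undershoot.

    ``peak_s`` and ``undershoot_s`` are the modes of the two gamma lobes
    in seconds; ``undershoot_ratio`` scales the negative lobe;
    ``support_s`` truncates the kernel (the response timescale is
    ~10-15 s).  The sampled kernel is normalised to unit peak amplitude.
    """

    peak_s: float = 5.0
    undershoot_s: float = 12.0
    undershoot_ratio: float = 1.0 / 6.0
    support_s: float = 15.0
    shape1: float = 6.0
    shape2: float = 16.0


@dataclass(frozen=True)
class Coupling:
    """Directed link: *receiver* copies a fraction of *driver*'s events.

    ``lag_tr`` may be fractional (sub-sample); ``share`` is the fraction
    of driver events reproduced in the receiver; ``amplitude`` scales the
    copied response relative to the driver's.
    """

    driver: str
    receiver: str
    lag_tr: float = 0.0
    share: float = 1.0
    amplitude: float = 1.0


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one synthetic scan.

    Defaults mirror a typical resting-state acquisition: TR 2.3 s, a
    4-minute scan of 104 samples, AR(1) noise with lag-1 autocorrelation
    0.725 (midpoint of the empirical 0.6-0.85 range), and roughly 8
    events per scan — the empirical order of threshold-crossing counts.
    """

    n_regions: int = 2
    n_timepoints: int = 104
    tr: float = 2.3
    noise_model: str = "ar1"     # "ar1" | "spectral"
    rho: float = 0.725           # AR(1) lag-1 autocorrelation
    alpha: float = 1.0           # 1/f^alpha exponent for "spectral"
    hrf: HrfParams = field(default_factory=HrfParams)
    couplings: tuple[Coupling, ...] = ()
    event_rate: float = 8.0      # expected events per scan
    event_amplitude: float = 3.0  # in noise-SD units, before z-scoring
    noise_scale: float = 1.0
    refractory_tr: float | None = None  # default: one search-window span (15 TR)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_model not in ("ar1", "spectral"):
            raise ValueError("noise_model must be 'ar1' or 'spectral'")
        if not 0 < self.rho < 1:
            raise ValueError("rho must lie in (0, 1)")
        if not self.alpha > 0:
            raise ValueError("alpha must be > 0")
        for c in self.couplings:
            if not 0 <= c.share <= 1:
                raise ValueError("coupling share must lie in [0, 1]")
            if abs(c.lag_tr) > 8:
                raise ValueError("coupling lag outside the delay search window")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(f"r{i}" for i in range(self.n_regions))

    def to_json(self) -> str:
        d = asdict(self)
        d["couplings"] = [asdict(c) for c in self.couplings]
        d["hrf"] = asdict(self.hrf)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimulationSpec":
        d = json.loads(text)
        d["hrf"] = HrfParams(**d.get("hrf", {}))
        d["couplings"] = tuple(Coupling(**c) for c in d.get("couplings", ()))
        return cls(**d)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually put into the data."""

    event_times: dict[str, np.ndarray]        # continuous sample indices
    lags: dict[tuple[str, str], float]        # (driver, receiver) -> lag in TR
    shares: dict[tuple[str, str], float]

    def to_json(self) -> str:
        return json.dumps({
            "event_times": {k: list(map(float, v))
                            for k, v in self.event_times.items()},
            "lags": {f"{a}->{b}": v for (a, b), v in self.lags.items()},
            "shares": {f"{a}->{b}": v for (a, b), v in self.shares.items()},
        }, indent=2)


def double_gamma_hrf(t_seconds: np.ndarray, params: HrfParams = HrfParams()) -> np.ndarray:
    """Evaluate the double-gamma HRF at (possibly fractional) times in seconds.

    Zero for t < 0 and t > support; unit peak amplitude.
    """
    t = np.asarray(t_seconds, dtype=float)
    a1, a2 = params.shape1, params.shape2
    b1 = (a1 - 1) / params.peak_s
    b2 = (a2 - 1) / params.undershoot_s

    def gpdf(x, a, b):
        out = np.zeros_like(x)
        pos = x > 0
        out[pos] = np.exp((a - 1) * np.log(x[pos]) + a * np.log(b)
                          - b * x[pos] - gammaln(a))
        return out

    h = gpdf(t, a1, b1) - params.undershoot_ratio * gpdf(t, a2, b2)
    h[(t < 0) | (t > params.support_s)] = 0.0
    # unit peak: the positive lobe's mode value
    peak = np.exp((a1 - 1) * np.log(params.peak_s) + a1 * np.log(b1)
                  - b1 * params.peak_s - gammaln(a1))
    return h / peak


def _ar1(rng: np.random.Generator, T: int, n: int, rho: float) -> np.ndarray:
    """Stationary unit-variance AR(1): x_t = rho x_{t-1} + sqrt(1-rho^2) e_t."""
    e = rng.standard_normal((T, n))
    # driving term: full-variance innovation at t=0 gives a stationary start
    u = np.vstack([e[:1], np.sqrt(1 - rho ** 2) * e[1:]])
    return _sig.lfilter([1.0], [1.0, -rho], u, axis=0)


def _spectral_noise(rng: np.random.Generator, T: int, n: int, alpha: float) -> np.ndarray:
    """Gaussian noise with a 1/f^alpha amplitude spectrum, random phases."""
    freqs = np.fft.rfftfreq(T, d=1.0)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-alpha / 2.0)
    spec = amp[:, None] * np.exp(2j * np.pi * rng.random((len(freqs), n)))
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=T, axis=0)
    return x / x.std(axis=0)


def gen_noise(spec: SimulationSpec) -> RoiTimeSeries:
    """Per-region independent autocorrelated noise, z-scored, seed-deterministic."""
    rng = np.random.default_rng(spec.seed)
    if spec.noise_model == "ar1":
        x = _ar1(rng, spec.n_timepoints, spec.n_regions, spec.rho)
    else:
        x = _spectral_noise(rng, spec.n_timepoints, spec.n_regions, spec.alpha)
    return zscore(RoiTimeSeries(x, tr=spec.tr, labels=spec.labels))


def _poisson_times(rng: np.random.Generator, T: int, rate_per_scan: float,
                   refractory: float) -> np.ndarray:
    """Event onsets (continuous sample units) with a refractory gap."""
    if rate_per_scan <= 0:
        return np.empty(0)
    mean_gap = T / rate_per_scan
    times = []
    t = float(rng.exponential(mean_gap))
    while t < T:
        times.append(t)
        t += refractory + float(rng.exponential(max(mean_gap - refractory, 1e-6)))
    return np.asarray(times)


def gen_coupled(spec: SimulationSpec) -> tuple[RoiTimeSeries, GroundTruth]:
    """Coupled event trains plus noise, with the imposed structure returned.

    Driver regions (and regions outside any coupling) receive their own
    HRF-shaped events at Poisson onsets with a refractory gap of one
    event-window length; pure receivers carry only the events copied from
    their drivers, shifted by the coupling lag via the continuous HRF.
    Output is z-scored; the returned :class:`GroundTruth` lists each
    region's own event onsets and every imposed (lag, share).
    """
    rng = np.random.default_rng(spec.seed)
    T, N = spec.n_timepoints, spec.n_regions
    labels = spec.labels
    label_set = set(labels)
    for c in spec.couplings:
        if c.driver not in label_set or c.receiver not in label_set:
            raise ValueError(f"coupling references unknown region "
                             f"{c.driver!r} or {c.receiver!r}")

    receivers_only = ({c.receiver for c in spec.couplings}
                      - {c.driver for c in spec.couplings})
    refractory = spec.refractory_tr if spec.refractory_tr is not None else 15.0

    data = np.zeros((T, N))
    t_grid = np.arange(T, dtype=float)
    own_times: dict[str, np.ndarray] = {}
    for i, lab in enumerate(labels):
        if lab in receivers_only:
            own_times[lab] = np.empty(0)
            continue
        onsets = _poisson_times(rng, T, spec.event_rate, refractory)
        own_times[lab] = onsets
        for t0 in onsets:
            data[:, i] += spec.event_amplitude * double_gamma_hrf(
                (t_grid - t0) * spec.tr, spec.hrf)

    lags: dict[tuple[str, str], float] = {}
    shares: dict[tuple[str, str], float] = {}
    for c in spec.couplings:
        i = labels.index(c.receiver)
        onsets = own_times[c.driver]
        n_copy = int(round(c.share * len(onsets)))
        copied = rng.choice(len(onsets), size=n_copy, replace=False) \
            if n_copy < len(onsets) else np.arange(len(onsets))
        for k in sorted(copied):
            t0 = onsets[k] + c.lag_tr
            data[:, i] += spec.event_amplitude * c.amplitude * double_gamma_hrf(
                (t_grid - t0) * spec.tr, spec.hrf)
        lags[(c.driver, c.receiver)] = c.lag_tr
        shares[(c.driver, c.receiver)] = c.share

    if spec.noise_scale > 0:
        if spec.noise_model == "ar1":
            noise = _ar1(rng, T, N, spec.rho)
        else:
            noise = _spectral_noise(rng, T, N, spec.alpha)
        data = data + spec.noise_scale * noise

    series = zscore(RoiTimeSeries(data, tr=spec.tr, labels=labels))
    return series, GroundTruth(event_times=own_times, lags=lags, shares=shares)
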