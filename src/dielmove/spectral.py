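"""Spectral detection of circadian structure in hourly displacement.

Movement predictability (MP) is the daily proportion of hours whose wavelet
power at 1, 2 or 3 cycles/day significantly exceeds a white-noise null.  The
chain is:

1. min-max normalize the hourly net displacements within each day, so the
   statistic tracks changes in periodicity rather than changes in variance;
2. continuous Morlet wavelet transform of the full multi-day series;
3. per-scale significance thresholds from a bootstrap of white-noise
   surrogates with variance matched to the analyzed series;
4. classify each hour as periodic if power at any diel scale (24, 12 or 8 h
   period) exceeds its threshold; MP(day) = significant hours / 24.

The Morlet wavelet uses the standard center frequency ``omega0 = 6``; with
the normalization adopted here the expected wavelet power of a white-noise
input equals its variance at every scale, so bootstrap thresholds scale
exactly linearly with variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import get_window
from sklearn.base import BaseEstimator

from .trajectory import HOURS_PER_DAY, DisplacementSeries, day_dates

#: wavelet periods (hours) corresponding to 1, 2 and 3 cycles/day
DIEL_PERIODS_H = (24.0, 12.0, 8.0)
DEFAULT_OMEGA0 = 6.0
DEFAULT_ALPHA = 0.05
DEFAULT_N_SURROGATES = 1000


@dataclass
class NormalizedSeries:
    """Per-day min-max rescaled hourly displacement values."""

    values: np.ndarray
    day_index: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class FourierSpectrum:
    """Smoothed periodogram normalized so white noise has power one."""

    frequencies: np.ndarray  # cycles/day
    power: np.ndarray


@dataclass
class BootstrapNull:
    """Per-scale white-noise significance thresholds."""

    variance: float
    n_surrogates: int
    alpha: float
    periods_hours: np.ndarray
    thresholds: np.ndarray


@dataclass
class WaveletResult:
    """Wavelet power over time x scale with diel significance labels."""

    day_index: np.ndarray
    periods_hours: np.ndarray
    power: np.ndarray  # (n_scales, n_times)
    sig_mask: np.ndarray | None = None
    diel_hourly: np.ndarray | None = None


def normalize_daily(series: DisplacementSeries) -> NormalizedSeries:
    """Min-max rescale S^N to [0, 1] within each day; constant days map to 0.

    Days with missing values or fewer than 24 hours are dropped (they sit at
    the series edges and cannot enter a daily proportion anyway).
    """
    df = pd.DataFrame({"v": series.values, "day": series.day_index})
    keep_days = []
    for day, grp in df.groupby("day", sort=True):
        if len(grp) == HOURS_PER_DAY and np.isfinite(grp["v"]).all():
            keep_days.append(day)
    df = df[df["day"].isin(keep_days)]
    values = df["v"].to_numpy(dtype=float)
    days = df["day"].to_numpy()
    out = np.zeros_like(values)
    for day in keep_days:
        m = days == day
        v = values[m]
        lo, hi = v.min(), v.max()
        out[m] = 0.0 if hi == lo else (v - lo) / (hi - lo)
    return NormalizedSeries(out, days)


def _modified_daniell_kernel(spans: tuple[int, ...]) -> np.ndarray:
    """Convolution of modified Daniell kernels (half-weight endpoints)."""
    kernel = np.array([1.0])
    for width in spans:
        if width < 3 or width % 2 == 0:
            raise ValueError("smoother spans must be odd and >= 3")
        k = np.ones(width)
        k[0] = k[-1] = 0.5
        k /= k.sum()
        kernel = np.convolve(kernel, k)
    return kernel


def fourier_spectrum(
    series: NormalizedSeries,
    taper_fraction: float = 0.1,
    smoother_spans: tuple[int, ...] = (3, 3),
) -> FourierSpectrum:
    """Tukey-tapered, Daniell-smoothed periodogram in cycles/day.

    Power is divided by the white-noise expectation given the sample
    variance, so a white-noise input has mean power ~1 at all frequencies.
    """
    x = np.asarray(series.values, dtype=float)
    if len(x) < 2 * HOURS_PER_DAY:
        raise ValueError("need at least two days of data")
    x = x - x.mean()
    var = x.var()
    if var == 0:
        raise ValueError("constant series has no spectrum")
    w = get_window(("tukey", taper_fraction), len(x))
    X = np.fft.rfft(x * w)
    # E|X_k|^2 = var * sum(w^2) for white noise, uniformly over 0 < f < Nyquist
    pgram = np.abs(X) ** 2 / (w @ w)
    kernel = _modified_daniell_kernel(smoother_spans)
    half = len(kernel) // 2
    padded = np.concatenate([pgram[half:0:-1], pgram, pgram[-2 : -half - 2 : -1]])
    smooth = np.convolve(padded, kernel, mode="valid")
    freqs = np.fft.rfftfreq(len(x), d=1.0 / HOURS_PER_DAY)  # cycles/day
    return FourierSpectrum(freqs[1:], smooth[1:] / var)


def default_scale_grid(
    min_period_h: float = 2.0, max_period_h: float = 48.0, voices_per_octave: int = 12
) -> np.ndarray:
    """Log-spaced wavelet periods (hours), 12 voices per octave by default."""
    n_octaves = np.log2(max_period_h / min_period_h)
    k = np.arange(int(np.floor(n_octaves * voices_per_octave)) + 1)
    return min_period_h * 2.0 ** (k / voices_per_octave)


def morlet_fourier_factor(omega0: float = DEFAULT_OMEGA0) -> float:
    """Ratio of Fourier period to wavelet scale for the Morlet wavelet."""
    return 4.0 * np.pi / (omega0 + np.sqrt(2.0 + omega0**2))


def cwt_morlet(
    x: np.ndarray,
    periods_hours: np.ndarray,
    dt: float = 1.0,
    omega0: float = DEFAULT_OMEGA0,
) -> np.ndarray:
    """Continuous Morlet wavelet transform, FFT implementation.

    The series is mean-removed and zero-padded to the next power of two at
    least twice its length; the analytic Morlet is sampled in the frequency
    domain.  Normalized so that E|W|^2 equals the input variance for white
    noise at every scale.  Returns a complex (n_scales, n_times) array.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("series must be finite")
    periods = np.atleast_1d(np.asarray(periods_hours, dtype=float))
    n = len(x)
    if n < 2 * periods.max() / dt:
        raise ValueError("series shorter than twice the largest scale")
    scales = periods / (morlet_fourier_factor(omega0) * dt)  # in samples
    m = 1 << int(np.ceil(np.log2(2 * n)))
    xh = np.fft.fft(x - x.mean(), m)
    omega = 2.0 * np.pi * np.fft.fftfreq(m)  # rad/sample
    pos = omega > 0
    out = np.empty((len(scales), n), dtype=complex)
    for i, s in enumerate(scales):
        psi_hat = np.zeros(m)
        psi_hat[pos] = (
            np.pi**-0.25
            * np.sqrt(2.0 * np.pi * s)
            * np.exp(-0.5 * (s * omega[pos] - omega0) ** 2)
        )
        out[i] = np.fft.ifft(xh * psi_hat)[:n]
    return out


def wavelet_power(
    series: NormalizedSeries,
    periods_hours: np.ndarray | None = None,
    omega0: float = DEFAULT_OMEGA0,
) -> WaveletResult:
    """Wavelet power spectrum |CWT|^2 of the multi-day normalized series."""
    periods = (
        default_scale_grid() if periods_hours is None else np.atleast_1d(periods_hours)
    )
    w = cwt_morlet(series.values, periods, omega0=omega0)
    return WaveletResult(series.day_index, np.asarray(periods, float), np.abs(w) ** 2)


def coi_efolding_hours(periods_hours: np.ndarray, omega0: float = DEFAULT_OMEGA0) -> np.ndarray:
    """Cone-of-influence e-folding distance (hours) per period."""
    return np.sqrt(2.0) * np.asarray(periods_hours, float) / morlet_fourier_factor(omega0)


def _interior_mask(n: int, period_h: float, omega0: float) -> np.ndarray:
    coi = coi_efolding_hours(np.array([period_h]), omega0)[0]
    t = np.arange(n)
    return (t >= coi) & (t <= n - 1 - coi)


def bootstrap_thresholds(
    variance: float,
    n_times: int,
    periods_hours: np.ndarray = DIEL_PERIODS_H,
    n_surrogates: int = DEFAULT_N_SURROGATES,
    alpha: float = DEFAULT_ALPHA,
    seed: int | np.random.Generator = 0,
    omega0: float = DEFAULT_OMEGA0,
) -> BootstrapNull:
    """Pointwise (1-alpha) power quantiles under a white-noise null.

    Surrogates are Gaussian white noise of the analyzed series' length.  The
    quantile pools surrogate power over interior time points (outside the
    cone of influence at each scale).  Power is computed at unit variance and
    scaled by ``variance`` — exact, since wavelet power is linear in input
    variance.
    """
    if variance <= 0:
        raise ValueError("variance must be positive")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    periods = np.atleast_1d(np.asarray(periods_hours, dtype=float))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    interiors = [_interior_mask(n_times, p, omega0) for p in periods]
    pools: list[list[np.ndarray]] = [[] for _ in periods]
    chunk = max(1, int(2e6 // n_times))
    done = 0
    while done < n_surrogates:
        k = min(chunk, n_surrogates - done)
        noise = rng.standard_normal((k, n_times))
        for z in noise:
            w = cwt_morlet(z, periods, omega0=omega0)
            p = np.abs(w) ** 2
            for i in range(len(periods)):
                pools[i].append(p[i][interiors[i]].astype(np.float32))
        done += k
    thresholds = np.array(
        [np.quantile(np.concatenate(pool), 1.0 - alpha) for pool in pools]
    )
    return BootstrapNull(variance, n_surrogates, alpha, periods, thresholds * variance)


def classify_diel_hours(wps: WaveletResult, null: BootstrapNull) -> WaveletResult:
    """Mark each hour significant where power at any diel scale beats its
    threshold; fills ``sig_mask`` and ``diel_hourly`` in place."""
    idx = [int(np.argmin(np.abs(wps.periods_hours - p))) for p in null.periods_hours]
    sig = np.zeros_like(wps.power, dtype=bool)
    for row, thr in zip(idx, null.thresholds):
        sig[row] = wps.power[row] > thr
    wps.sig_mask = sig
    wps.diel_hourly = sig[idx].any(axis=0)
    return wps


def daily_mp(wps: WaveletResult) -> pd.DataFrame:
    """Daily MP: proportion of the day's 24 hours classified periodic."""
    if wps.diel_hourly is None:
        raise ValueError("classification has not been run")
    df = pd.DataFrame({"sig": wps.diel_hourly, "day": wps.day_index})
    grp = df.groupby("day")["sig"]
    counts, sizes = grp.sum(), grp.size()
    full = sizes == HOURS_PER_DAY
    out = pd.DataFrame(
        {
            "date": day_dates(counts.index[full].to_numpy()),
            "mp": counts[full].to_numpy() / HOURS_PER_DAY,
        }
    )
    return out.reset_index(drop=True)


class MovementPredictability(BaseEstimator):
    """Estimator computing daily MP from one individual's displacement series.

    ``fit`` normalizes the series and calibrates the white-noise bootstrap
    null; ``transform`` classifies hours at the diel scales and returns one
    MP value per complete day.  A constant (zero-variance) series yields
    MP = 0 for all its days.

    Parameters
    ----------
    alpha : pointwise significance level per scale (no multiplicity
        correction across the three diel scales; classification is a union).
    n_surrogates : number of white-noise surrogate series for the null.
    periods_hours : wavelet periods checked for diel structure.
    omega0 : Morlet center frequency.
    seed : seed for surrogate generation.
    """

    def __init__(
        self,
        alpha: float = DEFAULT_ALPHA,
        n_surrogates: int = DEFAULT_N_SURROGATES,
        periods_hours: tuple[float, ...] = DIEL_PERIODS_H,
        omega0: float = DEFAULT_OMEGA0,
        seed: int = 0,
    ) -> None:
        self.alpha = alpha
        self.n_surrogates = n_surrogates
        self.periods_hours = periods_hours
        self.omega0 = omega0
        self.seed = seed

    def fit(self, series: DisplacementSeries, y=None, null: BootstrapNull | None = None):
        normalized = normalize_daily(series)
        self.normalized_ = normalized
        self.variance_ = float(np.var(normalized.values))
        if self.variance_ == 0.0:
            self.null_ = None
        elif null is not None:
            if null.variance != self.variance_ or null.alpha != self.alpha:
                # rescale a unit-compatible null by the exact linearity of
                # wavelet power in input variance
                null = BootstrapNull(
                    self.variance_,
                    null.n_surrogates,
                    null.alpha,
                    null.periods_hours,
                    null.thresholds * (self.variance_ / null.variance),
                )
            self.null_ = null
        else:
            self.null_ = bootstrap_thresholds(
                self.variance_,
                len(normalized),
                np.asarray(self.periods_hours, float),
                self.n_surrogates,
                self.alpha,
                self.seed,
                self.omega0,
            )
        return self

    def transform(self, series: DisplacementSeries | None = None) -> pd.DataFrame:
        if not hasattr(self, "normalized_"):
            raise RuntimeError("call fit before transform")
        normalized = self.normalized_
        days = np.unique(normalized.day_index)
        if self.null_ is None:  # constant series: no detectable periodicity
            return pd.DataFrame({"date": day_dates(days), "mp": 0.0})
        wps = wavelet_power(
            normalized, np.asarray(self.periods_hours, float), self.omega0
        )
        classify_diel_hours(wps, self.null_)
        self.wavelet_result_ = wps
        return daily_mp(wps)

    def fit_transform(self, series: DisplacementSeries, y=None, **kwargs) -> pd.DataFrame:
        return self.fit(series, **kwargs).transform()


def fill_mp(
    records: pd.DataFrame,
    series_by_individual: dict[str, DisplacementSeries],
    alpha: float = DEFAULT_ALPHA,
    n_surrogates: int = DEFAULT_N_SURROGATES,
    seed: int = 0,
    shared_null: bool = True,
) -> pd.DataFrame:
    """Fill the ``mp`` column of diel records, one individual at a time.

    With ``shared_null=True`` the surrogate bootstrap is run once at unit
    variance for the common series length and rescaled per individual, which
    is exact (power is linear in variance); lengths that differ get their own
    bootstrap.
    """
    records = records.copy()
    null_cache: dict[int, BootstrapNull] = {}
    for ind, series in series_by_individual.items():
        est = MovementPredictability(alpha=alpha, n_surrogates=n_surrogates, seed=seed)
        normalized = normalize_daily(series)
        n = len(normalized)
        var = float(np.var(normalized.values))
        null = None
        if shared_null and var > 0:
            if n not in null_cache:
                null_cache[n] = bootstrap_thresholds(
                    1.0, n, np.asarray(DIEL_PERIODS_H), n_surrogates, alpha, seed
                )
            base = null_cache[n]
            null = BootstrapNull(
                var, base.n_surrogates, base.alpha, base.periods_hours,
                base.thresholds * var,
            )
        mp = est.fit(series, null=null).transform()
        m = records["individual_id"] == ind
        merged = records.loc[m, ["date"]].merge(mp, on="date", how="left")
        records.loc[m, "mp"] = merged["mp"].to_numpy()
    return records
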