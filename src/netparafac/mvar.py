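"""Multivariate autoregressive (MVAR) spectral connectivity estimation.

An MVAR model of order p describes K simultaneously recorded signals as

    Y(t) = sum_{q=1..p} lambda(q) Y(t-q) + eps(t)

with K x K coefficient matrices lambda(q) and white residuals eps. Its
frequency-domain representation Lambda(f) = I - sum_q lambda(q) e^{-i 2 pi
(f/fs) q} yields squared partial directed coherence (PDC)

    pi_ij(f) = |Lambda_ij(f)|^2 / sum_m |Lambda_mj(f)|^2,

a column-normalized measure of the direct (Granger-causal) influence of
channel j on channel i at frequency f: every column of every frequency
slice sums to one.

Models are fitted by ordinary least squares over lag-embedded rows pooled
across trials (no regression row spans a trial boundary), the standard
approach for segmented recordings. Connection-wise significance is assessed
against a phase-randomized surrogate null: surrogates preserve each
channel's amplitude spectrum while destroying cross-channel phase
relations, giving an empirical null distribution for each off-diagonal
connection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Epochs",
    "MVARModel",
    "PDCSpectrum",
    "BandNetwork",
    "fit_mvar",
    "select_order_aic",
    "transfer_matrix",
    "pdc",
    "band_average",
    "binarize_null",
    "default_freq_grid",
    "BANDS",
]

#: Standard EEG band definitions in Hz (closed intervals).
BANDS: dict[str, tuple[float, float]] = {
    "theta": (3.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
    "gamma": (31.0, 40.0),
}


@dataclass
class Epochs:
    """Multichannel epoched recording: K channels x T samples x N trials."""

    data: np.ndarray
    fs: float

    def __post_init__(self):
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim == 2:  # single trial
            arr = arr[:, :, None]
        if arr.ndim != 3:
            raise ValueError("epochs data must be K x T or K x T x N")
        if not np.all(np.isfinite(arr)):
            raise ValueError("epochs contain non-finite values")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.data = arr

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]


@dataclass
class MVARModel:
    """Fitted MVAR coefficients lambda(1..p) and residual covariance.

    ``coeffs[q-1][i, j]`` is the weight of channel j's sample at lag q in
    the prediction of channel i; lambda(0) = I is implicit. ``noise_cov``
    is the (symmetric PSD) covariance of the one-step prediction residuals.
    """

    order: int
    coeffs: np.ndarray          # p x K x K
    noise_cov: np.ndarray       # K x K
    fs: float

    def __post_init__(self):
        if not np.allclose(self.noise_cov, self.noise_cov.T, atol=1e-10):
            raise ValueError("noise covariance must be symmetric")

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]


@dataclass
class PDCSpectrum:
    """Squared PDC values: entry [i, j, f] is the influence j -> i."""

    values: np.ndarray          # K x K x F, entries in [0, 1]
    freqs: np.ndarray           # F frequencies in Hz


@dataclass
class BandNetwork:
    """Band-averaged squared-PDC connectivity matrix."""

    values: np.ndarray          # K x K
    band: tuple[float, float]
    name: str = ""


def _lag_embed(data: np.ndarray, p: int):
    """Regression design over all trials: predict Y(t) from p past samples.

    Returns (targets, regressors) with one row per usable time point; rows
    never straddle trial boundaries.
    """
    K, T, N = data.shape
    ys, zs = [], []
    for n in range(N):
        tr = data[:, :, n]
        Y = tr[:, p:].T                                   # (T-p) x K
        Z = np.hstack([tr[:, p - q:T - q].T for q in range(1, p + 1)])
        ys.append(Y)
        zs.append(Z)
    return np.vstack(ys), np.vstack(zs)


def fit_mvar(epochs: Epochs, order: int) -> MVARModel:
    """Fit an MVAR(p) model by pooled ordinary least squares.

    Minimizes the summed squared one-step prediction error over all trials
    (lag-embedded rows stacked across trials). The residual covariance uses
    the maximum-likelihood normalization (divide by the row count), which
    keeps it comparable across candidate orders for AIC.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    K, T, N = epochs.data.shape
    if T <= order:
        raise ValueError(f"need more than order={order} samples per trial, got {T}")
    n_rows = N * (T - order)
    if n_rows <= K * order:
        raise ValueError(
            f"underdetermined fit: {n_rows} usable rows for {K * order} "
            f"regressors per channel"
        )
    Y, Z = _lag_embed(epochs.data, order)
    rank = np.linalg.matrix_rank(Z)
    if rank < Z.shape[1]:
        raise np.linalg.LinAlgError(
            f"singular regressor matrix: rank {rank} < {Z.shape[1]} "
            f"({K} channels x {order} lags); channels may be collinear"
        )
    coef, *_ = np.linalg.lstsq(Z, Y, rcond=None)          # (K*p) x K
    resid = Y - Z @ coef
    noise_cov = resid.T @ resid / n_rows
    noise_cov = (noise_cov + noise_cov.T) / 2.0
    lam = coef.T.reshape(K, order, K).transpose(1, 0, 2)  # p x K x K
    return MVARModel(order=order, coeffs=lam, noise_cov=noise_cov, fs=epochs.fs)


def select_order_aic(epochs: Epochs, max_order: int) -> int:
    """Akaike-optimal model order over p = 1..max_order.

    AIC(p) = N_eff * ln det(noise_cov(p)) + 2 p K^2, with N_eff the number
    of regression rows available at max_order; every candidate is fitted on
    that same row set so the likelihood terms are comparable.
    """
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    K, T, N = epochs.data.shape
    if T <= max_order:
        raise ValueError(f"max_order={max_order} >= samples per trial {T}")
    # common sample: drop the first max_order samples of every trial
    n_eff = N * (T - max_order)
    aics = []
    for p in range(1, max_order + 1):
        try:
            Y, Z = _lag_embed(epochs.data, max_order)
            Zp = Z[:, : K * p]                            # lags 1..p only
            coef, *_ = np.linalg.lstsq(Zp, Y, rcond=None)
            resid = Y - Zp @ coef
            sigma = resid.T @ resid / n_eff
            sign, logdet = np.linalg.slogdet(sigma)
            if sign <= 0:
                raise np.linalg.LinAlgError("non-PD residual covariance")
            aics.append(n_eff * logdet + 2.0 * p * K * K)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(f"AIC fit failed at order {p}: {exc}") from exc
    return int(np.argmin(aics)) + 1


def transfer_matrix(model: MVARModel, freq: float) -> np.ndarray:
    """Spectral transfer matrix Lambda(f) at one frequency in Hz.

    Lambda_ij(f) = delta_ij - sum_q lambda_ij(q) exp(-i 2 pi (f/fs) q).
    """
    if not 0 <= freq <= model.fs / 2:
        raise ValueError(f"freq {freq} outside [0, fs/2]")
    K = model.n_channels
    q = np.arange(1, model.order + 1)
    phase = np.exp(-2j * np.pi * (freq / model.fs) * q)
    return np.eye(K, dtype=complex) - np.tensordot(phase, model.coeffs, axes=(0, 0))


def pdc(model: MVARModel, freqs) -> PDCSpectrum:
    """Squared partial directed coherence over a frequency grid.

    pi_ij(f) = |Lambda_ij|^2 / sum_m |Lambda_mj|^2 — already the squared,
    column-normalized form, so sum_i pi_ij(f) = 1 for every source j.
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if np.any(freqs < 0) or np.any(freqs > model.fs / 2):
        raise ValueError("frequencies must lie in [0, fs/2]")
    K = model.n_channels
    out = np.empty((K, K, len(freqs)))
    for k, f in enumerate(freqs):
        lam = transfer_matrix(model, f)
        mag = np.abs(lam) ** 2
        denom = mag.sum(axis=0)
        bad = np.flatnonzero(denom == 0)
        if bad.size:
            raise ZeroDivisionError(
                f"degenerate PDC column {bad[0]} at {f} Hz: all transfer "
                f"entries vanish"
            )
        out[:, :, k] = mag / denom
    return PDCSpectrum(values=out, freqs=freqs)


def default_freq_grid(fs: float, fmax: float = 40.0) -> np.ndarray:
    """Integer-Hz grid from 1 Hz to min(fs/2, fmax)."""
    return np.arange(1.0, min(fs / 2, fmax) + 0.5)


def band_average(spec: PDCSpectrum, band, name: str = "") -> BandNetwork:
    """Mean squared PDC over the frequencies inside a closed band [lo, hi]."""
    lo, hi = band
    sel = (spec.freqs >= lo) & (spec.freqs <= hi)
    if not np.any(sel):
        raise ValueError(f"band {band} contains no grid frequency")
    return BandNetwork(values=spec.values[:, :, sel].mean(axis=2),
                       band=(float(lo), float(hi)), name=name)


def _phase_randomize(data: np.ndarray, rng) -> np.ndarray:
    """Independent phase randomization of each channel and trial.

    Preserves each signal's amplitude spectrum (hence autocorrelation)
    while destroying cross-channel phase coupling.
    """
    K, T, N = data.shape
    out = np.empty_like(data)
    spec = np.fft.rfft(data, axis=1)
    nf = spec.shape[1]
    phases = rng.uniform(0, 2 * np.pi, size=(K, nf, N))
    phases[:, 0, :] = 0.0
    if T % 2 == 0:
        phases[:, -1, :] = 0.0  # Nyquist bin must stay real
    out = np.fft.irfft(spec * np.exp(1j * phases), n=T, axis=1)
    return out


def _band_statistic(epochs: Epochs, order: int, freqs, band) -> np.ndarray:
    model = fit_mvar(epochs, order)
    spec = pdc(model, freqs)
    if band is not None:
        return band_average(spec, band).values
    return spec.values.mean(axis=2)


def binarize_null(spec_or_band, epochs: Epochs, order: int | None = None,
                  alpha: float = 0.05, n_surrogates: int = 100,
                  rng_seed=None, freqs=None, threshold_fn=None) -> np.ndarray:
    """Binarize a connectivity estimate against a connection-wise null.

    The observed statistic per connection is the band-averaged squared PDC
    in ``spec_or_band`` (a :class:`BandNetwork`, or a :class:`PDCSpectrum`
    whose whole grid is treated as one band). By default the null is built
    from ``n_surrogates`` phase-randomized copies of ``epochs``, refitting
    the MVAR model on each; entry (i, j) is set to 1 when the observed
    statistic exceeds the connection's (1 - alpha) null quantile. The
    diagonal is forced to 0.

    A custom ``threshold_fn(epochs, order, freqs, band) -> K x K threshold
    matrix`` may be supplied to replace the surrogate construction (e.g.
    with an asymptotic-theory threshold).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if threshold_fn is None and n_surrogates < 20:
        raise ValueError("need at least 20 surrogates for a stable quantile")
    if epochs.n_channels < 2:
        raise ValueError("binarization needs at least 2 channels")

    if isinstance(spec_or_band, BandNetwork):
        observed = spec_or_band.values
        band = spec_or_band.band
    elif isinstance(spec_or_band, PDCSpectrum):
        observed = spec_or_band.values.mean(axis=2)
        band = (float(spec_or_band.freqs.min()), float(spec_or_band.freqs.max()))
    else:
        raise TypeError("expected a PDCSpectrum or BandNetwork")

    if freqs is None:
        freqs = default_freq_grid(epochs.fs)
    freqs = np.asarray(freqs, dtype=float)
    grid = freqs[(freqs >= band[0]) & (freqs <= band[1])]
    if grid.size == 0:
        grid = freqs
    if order is None:
        order = select_order_aic(epochs, max_order=min(10, epochs.n_samples // 4))

    if threshold_fn is not None:
        thresh = threshold_fn(epochs, order, grid, band)
    else:
        rng = np.random.default_rng(rng_seed)
        null = np.empty((n_surrogates,) + observed.shape)
        for s in range(n_surrogates):
            surr = Epochs(data=_phase_randomize(epochs.data, rng), fs=epochs.fs)
            null[s] = _band_statistic(surr, order, grid, band)
        thresh = np.quantile(null, 1.0 - alpha, axis=0)

    binary = (observed > thresh).astype(float)
    np.fill_diagonal(binary, 0.0)
    return binary
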