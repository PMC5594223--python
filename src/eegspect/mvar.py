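"""Multivariate autoregressive (MVAR) modelling of multichannel EEG.

The model is

    X(t) = sum_{k=1..p} A_k X(t-k) + E(t),      E(t) ~ (0, Sigma)

with m channels and order p.  Fitting uses the Vieira-Morf multichannel
Levinson recursion (geometric-mean partial-correlation lattice) with
unbiased covariance normalization: at lag stage k the forward, backward
and cross error covariances are normalized by n - k rather than n.

Frequency-domain transforms on a 1-Hz grid:

    Abar(f) = I - sum_k A_k exp(-i 2 pi f k / fs)      (AR polynomial)
    H(f)    = Abar(f)^{-1}                              (transfer function)
    S(f)    = H(f) Sigma H(f)^*                         (spectral matrix)

Usage follows the statsmodels convention::

    res = MVAR(signal, order=5, sfreq=200.0).fit()
    spec = res.spectral()          # SpectralMatrices on the 2..80 Hz grid
    sim = res.simulate(20000, rng) # draw a realization of the process
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray
from scipy.linalg import cholesky, solve_triangular

from .constants import FREQ_GRID_HZ

__all__ = [
    "MVAR",
    "MVARModel",
    "MVARResults",
    "SpectralMatrices",
    "fit_mvar",
    "spectral_transform",
]


class MVARFitError(RuntimeError):
    """Raised when the lattice recursion encounters a singular error covariance."""


@dataclass
class MVARModel:
    """An MVAR process: coefficient stack, residual covariance, metadata.

    Serves both as the generative template of the synthetic cohort and as
    the container behind a fitted model.

    Parameters
    ----------
    coefficients : (p, m, m) array
        A_1 .. A_p; ``coefficients[k-1][i, j]`` is the influence of channel
        j at lag k on channel i.
    resid_cov : (m, m) array
        Residual (innovation) covariance Sigma; symmetric PSD.
    sfreq : float
        Sampling rate in Hz.
    channel_labels : list of str, optional
    """

    coefficients: NDArray[np.float64]
    resid_cov: NDArray[np.float64]
    sfreq: float = 200.0
    channel_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.resid_cov = np.asarray(self.resid_cov, dtype=float)
        if self.coefficients.ndim != 3 or (
            self.coefficients.shape[1] != self.coefficients.shape[2]
        ):
            raise ValueError("coefficients must have shape (p, m, m)")
        m = self.coefficients.shape[1]
        if self.resid_cov.shape != (m, m):
            raise ValueError("resid_cov shape inconsistent with coefficients")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("non-finite coefficients")
        if not np.all(np.isfinite(self.resid_cov)):
            raise ValueError("non-finite residual covariance")
        if not np.allclose(self.resid_cov, self.resid_cov.T, atol=1e-10):
            raise ValueError("residual covariance must be symmetric")
        if self.channel_labels is not None and len(self.channel_labels) != m:
            raise ValueError("channel_labels length mismatch")

    @property
    def order(self) -> int:
        return self.coefficients.shape[0]

    @property
    def n_channels(self) -> int:
        return self.coefficients.shape[1]

    def companion(self) -> NDArray[np.float64]:
        """Companion matrix of the lag polynomial, shape (p*m, p*m)."""
        p, m = self.order, self.n_channels
        comp = np.zeros((p * m, p * m))
        comp[:m, :] = np.concatenate(list(self.coefficients), axis=1)
        if p > 1:
            comp[m:, : (p - 1) * m] = np.eye((p - 1) * m)
        return comp

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.companion()))))

    def is_stable(self, tol: float = 1.0) -> bool:
        return self.spectral_radius() < tol

    # ---- frequency domain -------------------------------------------------

    def spectral(self, frequencies=None) -> "SpectralMatrices":
        """Evaluate Abar(f), H(f), S(f) on a frequency grid (default 2..80 Hz)."""
        return spectral_transform(self, frequencies)

    # ---- simulation -------------------------------------------------------

    def simulate(
        self,
        n_samples: int,
        rng: np.random.Generator,
        burn_in: int | None = None,
    ) -> NDArray[np.float64]:
        """Draw a realization of the process, shape (m, n_samples).

        A burn-in of ``max(1000, 10*order)`` samples (by default) is
        discarded so the output is approximately stationary.  Gaussian
        innovations with covariance ``resid_cov``.
        """
        if not self.is_stable():
            raise ValueError(
                f"cannot simulate an unstable MVAR model "
                f"(spectral radius {self.spectral_radius():.4f} >= 1)"
            )
        p, m = self.order, self.n_channels
        if burn_in is None:
            burn_in = max(1000, 10 * p)
        total = n_samples + burn_in
        # innovations drawn in one block; Cholesky with PSD fallback
        try:
            L = np.linalg.cholesky(self.resid_cov)
        except np.linalg.LinAlgError:
            w, V = np.linalg.eigh(self.resid_cov)
            L = V * np.sqrt(np.clip(w, 0.0, None))
        noise = rng.standard_normal((total, m)) @ L.T
        x = np.zeros((total, m))
        for t in range(total):
            acc = noise[t]
            kmax = min(p, t)
            for k in range(1, kmax + 1):
                acc = acc + self.coefficients[k - 1] @ x[t - k]
            x[t] = acc
        return x[burn_in:].T.copy()

    # ---- serialization ----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "order": self.order,
                "coefficients": self.coefficients.tolist(),
                "resid_cov": self.resid_cov.tolist(),
                "sfreq": self.sfreq,
                "channel_labels": self.channel_labels,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "MVARModel":
        d = json.loads(text)
        return cls(
            coefficients=np.asarray(d["coefficients"], dtype=float),
            resid_cov=np.asarray(d["resid_cov"], dtype=float),
            sfreq=float(d["sfreq"]),
            channel_labels=d.get("channel_labels"),
        )


@dataclass
class SpectralMatrices:
    """AR polynomial, transfer function and spectral matrix on a grid.

    ``Af[fi]`` is Abar(f) = I - sum_k A_k e^{-i 2 pi f k / fs}; ``H`` its
    inverse; ``S = H Sigma H^*``.  Shapes are (F, m, m), complex.
    """

    frequencies: NDArray[np.float64]
    Af: NDArray[np.complex128]
    H: NDArray[np.complex128]
    S: NDArray[np.complex128]
    resid_cov: NDArray[np.float64] = field(repr=False, default=None)

    @property
    def n_channels(self) -> int:
        return self.Af.shape[1]


def spectral_transform(model: MVARModel, frequencies=None) -> SpectralMatrices:
    """Evaluate the frequency-domain transforms of an MVAR model.

    Parameters
    ----------
    model : MVARModel
    frequencies : array-like of Hz, optional
        Defaults to the integer grid 2..80 Hz.  Must lie in (0, fs/2].

    Raises
    ------
    ValueError
        If a frequency lies outside (0, fs/2] or Abar(f) is singular there.
    """
    if frequencies is None:
        frequencies = np.asarray(FREQ_GRID_HZ, dtype=float)
    freqs = np.asarray(frequencies, dtype=float)
    nyquist = model.sfreq / 2.0
    if np.any(freqs <= 0) or np.any(freqs > nyquist + 1e-9):
        raise ValueError(f"frequencies must lie in (0, {nyquist}] Hz")

    p, m = model.order, model.n_channels
    lags = np.arange(1, p + 1)
    # phase[fi, k] = exp(-i 2 pi f k / fs)
    phase = np.exp(-2j * np.pi * np.outer(freqs, lags) / model.sfreq)
    Af = np.eye(m, dtype=complex)[None, :, :] - np.einsum(
        "fk,kij->fij", phase, model.coefficients.astype(complex)
    )
    H = np.empty_like(Af)
    for fi, f in enumerate(freqs):
        try:
            H[fi] = np.linalg.inv(Af[fi])
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"AR polynomial singular at {f} Hz") from exc
    S = H @ model.resid_cov @ np.conj(np.swapaxes(H, 1, 2))
    return SpectralMatrices(
        frequencies=freqs, Af=Af, H=H, S=S, resid_cov=model.resid_cov.copy()
    )


class MVARResults(MVARModel):
    """Fitted MVAR model with fit diagnostics attached."""

    def __init__(self, coefficients, resid_cov, sfreq, channel_labels, nobs):
        super().__init__(coefficients, resid_cov, sfreq, channel_labels)
        self.nobs = nobs

    def summary(self) -> str:
        lines = [
            "MVAR fit (Vieira-Morf partial-correlation lattice)",
            f"  channels:        {self.n_channels}",
            f"  order:           {self.order}",
            f"  observations:    {self.nobs}",
            f"  sampling rate:   {self.sfreq:g} Hz",
            f"  spectral radius: {self.spectral_radius():.4f}",
            f"  resid var (per channel): "
            + np.array2string(np.diag(self.resid_cov), precision=4),
        ]
        return "\n".join(lines)


class MVAR:
    """MVAR model of a multichannel signal, statsmodels style.

    Parameters
    ----------
    endog : (m, n) array
        Channels x samples.  The per-channel mean is removed before fitting;
        no detrending or filtering is applied.
    order : int
        Number of lags p.
    sfreq : float
        Sampling rate in Hz (used by the spectral transforms).
    channel_labels : list of str, optional
    """

    def __init__(self, endog, order: int, sfreq: float = 200.0,
                 channel_labels: list[str] | None = None):
        endog = np.asarray(endog, dtype=float)
        if endog.ndim != 2:
            raise ValueError("endog must be a channels x samples matrix")
        if not np.all(np.isfinite(endog)):
            raise ValueError("endog contains non-finite values")
        if order < 1:
            raise ValueError("order must be >= 1")
        m, n = endog.shape
        if n <= order:
            raise ValueError("need more samples than lags")
        if n <= order * m:
            warnings.warn(
                f"sample count {n} below recommended order*channels={order * m}; "
                "estimates may be unreliable",
                stacklevel=2,
            )
        self.endog = endog
        self.order = order
        self.sfreq = sfreq
        self.channel_labels = channel_labels

    def fit(self) -> MVARResults:
        """Fit by the Vieira-Morf recursion with unbiased covariance estimates."""
        x = self.endog - self.endog.mean(axis=1, keepdims=True)
        A, sigma = _vieira_morf(x, self.order)
        return MVARResults(
            coefficients=A,
            resid_cov=sigma,
            sfreq=self.sfreq,
            channel_labels=self.channel_labels,
            nobs=x.shape[1],
        )


def _vieira_morf(x: NDArray[np.float64], p: int):
    """Geometric-mean (Vieira-Morf) multichannel Levinson recursion.

    Forward/backward prediction errors are updated through reflection
    matrices built from the Cholesky-normalized partial correlation; the
    error covariances at stage k use the unbiased divisor n - k.

    Returns (A, Sigma): A has shape (p, m, m) in the convention
    X(t) = sum A_k X(t-k) + E(t); Sigma is the final forward residual
    covariance.
    """
    m, n = x.shape
    ef = x.copy()
    eb = x.copy()
    # lattice predictor coefficients: f_k(t) = x(t) + sum_i Afp[i] x(t-i)
    Afp: list[NDArray[np.float64]] = []
    Abp: list[NDArray[np.float64]] = []

    for k in range(1, p + 1):
        # copies: both updates below must read the stage-(k-1) errors
        f_prev = ef[:, k:].copy()            # ef_{k-1}(t), t = k..n-1
        b_prev = eb[:, k - 1: n - 1].copy()  # eb_{k-1}(t-1)
        nk = n - k
        Pf = f_prev @ f_prev.T / nk
        Pb = b_prev @ b_prev.T / nk
        D = f_prev @ b_prev.T / nk
        try:
            Sf = cholesky(Pf, lower=True)
            Sb = cholesky(Pb, lower=True)
        except np.linalg.LinAlgError as exc:
            raise MVARFitError(
                f"singular prediction-error covariance at lattice stage {k}"
            ) from exc
        # rho = Sf^{-1} D Sb^{-T}; reflection matrices from rho
        rho = solve_triangular(Sf, D, lower=True)
        rho = solve_triangular(Sb, rho.T, lower=True).T
        if np.any(np.linalg.svd(rho, compute_uv=False) > 1.0 + 1e-8):
            # partial correlations should be contractions; beyond this the
            # recursion is numerically unreliable
            raise MVARFitError(
                f"partial-correlation magnitude exceeds 1 at stage {k}"
            )
        Sb_inv = solve_triangular(Sb, np.eye(m), lower=True)
        Sf_inv = solve_triangular(Sf, np.eye(m), lower=True)
        Kf = -Sf @ rho @ Sb_inv
        Kb = -Sb @ rho.T @ Sf_inv

        ef[:, k:] = f_prev + Kf @ b_prev
        eb[:, k:] = b_prev + Kb @ f_prev

        Af_new = [Afp[i] + Kf @ Abp[k - 2 - i] for i in range(k - 1)] + [Kf]
        Ab_new = [Abp[i] + Kb @ Afp[k - 2 - i] for i in range(k - 1)] + [Kb]
        Afp, Abp = Af_new, Ab_new

    A = np.stack([-a for a in Afp], axis=0)
    resid = ef[:, p:]
    sigma = resid @ resid.T / (n - p)
    sigma = 0.5 * (sigma + sigma.T)
    return A, sigma


def fit_mvar(signal, order: int, sfreq: float = 200.0,
             channel_labels: list[str] | None = None) -> MVARResults:
    """Functional wrapper: fit an MVAR model to a channels x samples matrix."""
    return MVAR(signal, order, sfreq=sfreq, channel_labels=channel_labels).fit()
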