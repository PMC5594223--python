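"""Frequency-domain interaction measures derived from a fitted MVAR model.

Fourteen channel-by-channel measures are computed from the spectral
matrices (Abar, H, S) of an MVAR model on the 2..80 Hz grid and then
averaged within the classical bands.  Orientation convention, fixed
repo-wide: entry ``values[f, i, j]`` quantifies the influence (or
association) of source channel j on sink channel i.

Complex quantities are reduced to real values before band averaging —
modulus everywhere except iCOH (imaginary part of coherency) and GGC
(already real) — because the downstream t-tests and SVM operate on real
features.

Measures
--------
S, h, Af      moduli of cross-spectrum, transfer function, AR polynomial
DC            direct causal gain |Abar_ij(f)| off the diagonal
COH, iCOH     modulus / imaginary part of coherency S_ij/sqrt(S_ii S_jj)
pCOH          partial coherence from P = S^{-1}
PDC, PDCF,    partial directed coherence family (column-normalized Abar),
GPDC          with inverse-noise (PDCF) or noise-variance (GPDC) weighting
DTF, ffDTF,   directed transfer function family (row-normalized H); dDTF
dDTF          multiplies the full-frequency DTF by partial coherence
GGC           Geweke's spectral Granger causality (log spectral ratio)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray

from .constants import BAND_ORDER, BANDS, FREQ_GRID_HZ, MEASURES
from .mvar import MVARModel, SpectralMatrices

__all__ = [
    "ConnectivityTensor",
    "BandedConnectivity",
    "coherency_family",
    "pdc_family",
    "dtf_family",
    "granger_family",
    "raw_family",
    "band_average",
    "compute_all",
]

logger = logging.getLogger(__name__)


@dataclass
class ConnectivityTensor:
    """One measure on the frequency grid; values[f, i, j] = source j -> sink i."""

    measure: str
    frequencies: NDArray[np.float64]
    values: NDArray[np.float64]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in {self.measure} tensor")


@dataclass
class BandedConnectivity:
    """Band-averaged measure: one m x m matrix per classical band."""

    measure: str
    bands: dict[str, NDArray[np.float64]]

    @property
    def n_channels(self) -> int:
        return next(iter(self.bands.values())).shape[0]


def _check_spectrum(spec: SpectralMatrices) -> None:
    diag = np.diagonal(spec.S, axis1=1, axis2=2)
    if np.any(diag.real <= 0):
        raise ValueError("spectral matrix has a non-positive diagonal entry")
    if np.max(np.abs(spec.S - np.conj(np.swapaxes(spec.S, 1, 2)))) > 1e-6 * max(
        1.0, float(np.max(np.abs(spec.S)))
    ):
        raise ValueError("spectral matrix is not Hermitian")


def coherency_family(spec: SpectralMatrices) -> dict[str, ConnectivityTensor]:
    """COH (|coherency|), iCOH (Im coherency) and pCOH (partial coherence)."""
    _check_spectrum(spec)
    S = spec.S
    diag = np.sqrt(np.diagonal(S, axis1=1, axis2=2).real)
    denom = diag[:, :, None] * diag[:, None, :]
    C = S / denom
    out = {
        "COH": np.abs(C),
        "iCOH": C.imag.copy(),
    }
    pcoh = np.empty_like(out["COH"])
    for fi, f in enumerate(spec.frequencies):
        try:
            P = np.linalg.inv(S[fi])
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"spectral matrix singular at {f} Hz (pCOH)") from exc
        pd = np.sqrt(np.abs(np.diagonal(P).real))
        pcoh[fi] = np.abs(P) / (pd[:, None] * pd[None, :])
    out["pCOH"] = pcoh
    return {
        k: ConnectivityTensor(k, spec.frequencies, v) for k, v in out.items()
    }


def pdc_family(
    spec: SpectralMatrices, resid_cov: NDArray[np.float64] | None = None
) -> dict[str, ConnectivityTensor]:
    """PDC, PDCF and GPDC from the AR polynomial Abar(f).

    PDC(i,j,f)  = |Abar_ij| / sqrt(sum_k |Abar_kj|^2)        (column norm)
    PDCF(i,j,f) = |Abar_ij| / sqrt(abar_j^* Sigma^{-1} abar_j)
    GPDC(i,j,f) = (|Abar_ij|/sqrt(Sigma_ii)) /
                  sqrt(sum_k |Abar_kj|^2 / Sigma_kk)
    """
    if resid_cov is None:
        resid_cov = spec.resid_cov
    A = spec.Af
    absA = np.abs(A)
    colnorm = np.sqrt(np.sum(absA**2, axis=1))  # (F, m), per source column j
    pdc = absA / colnorm[:, None, :]

    sig = np.asarray(resid_cov, dtype=float)
    sdiag = np.diag(sig)
    if np.any(sdiag <= 0):
        raise ValueError("residual covariance has non-positive diagonal (GPDC)")
    gnorm = np.sqrt(np.sum(absA**2 / sdiag[None, :, None], axis=1))
    gpdc = (absA / np.sqrt(sdiag)[None, :, None]) / gnorm[:, None, :]

    try:
        sig_inv = np.linalg.inv(sig)
    except np.linalg.LinAlgError as exc:
        raise ValueError("residual covariance singular (PDCF)") from exc
    # quadratic form abar_j^* Sigma^{-1} abar_j per frequency and column j
    qf = np.einsum("fij,ik,fkj->fj", np.conj(A), sig_inv.astype(complex), A).real
    pdcf = absA / np.sqrt(qf)[:, None, :]

    freqs = spec.frequencies
    return {
        "PDC": ConnectivityTensor("PDC", freqs, pdc),
        "PDCF": ConnectivityTensor("PDCF", freqs, pdcf),
        "GPDC": ConnectivityTensor("GPDC", freqs, gpdc),
    }


def dtf_family(
    spec: SpectralMatrices, pcoh: ConnectivityTensor | None = None
) -> dict[str, ConnectivityTensor]:
    """DTF, ffDTF and dDTF from the transfer function H(f).

    DTF(i,j,f)   = |H_ij| / sqrt(sum_k |H_ik|^2)              (row norm)
    ffDTF(i,j,f) = |H_ij| / sqrt(sum_{f'} sum_k |H_ik(f')|^2)
    dDTF         = ffDTF * pCOH (elementwise)
    """
    absH = np.abs(spec.H)
    rownorm = np.sqrt(np.sum(absH**2, axis=2))  # (F, m), per sink row i
    dtf = absH / rownorm[:, :, None]
    ffnorm = np.sqrt(np.sum(absH**2, axis=(0, 2)))  # (m,), over all freqs
    ffdtf = absH / ffnorm[None, :, None]
    if pcoh is None:
        pcoh = coherency_family(spec)["pCOH"]
    ddtf = ffdtf * pcoh.values
    freqs = spec.frequencies
    return {
        "DTF": ConnectivityTensor("DTF", freqs, dtf),
        "ffDTF": ConnectivityTensor("ffDTF", freqs, ffdtf),
        "dDTF": ConnectivityTensor("dDTF", freqs, ddtf),
    }


def granger_family(
    spec: SpectralMatrices, resid_cov: NDArray[np.float64] | None = None
) -> dict[str, ConnectivityTensor]:
    """Geweke's spectral Granger causality (GGC) and direct causality (DC).

    GGC(i,j,f) = ln( S_ii / (S_ii - (Sigma_jj - Sigma_ij^2/Sigma_ii) |H_ij|^2) )
    with the conditional innovation variance of j given i correcting for
    correlated residuals; non-positive log arguments are clipped to a GGC
    of 0 (and logged).  DC is |Abar_ij(f)| off the diagonal, 0 on it.
    """
    if resid_cov is None:
        resid_cov = spec.resid_cov
    sig = np.asarray(resid_cov, dtype=float)
    sdiag = np.diag(sig)
    if np.any(sdiag <= 0):
        raise ValueError("residual covariance has non-positive diagonal (GGC)")
    # conditional variance of innovation j given innovation i
    cond_var = sdiag[None, :] - sig**2 / sdiag[:, None]  # (i, j)
    Sii = np.diagonal(spec.S, axis1=1, axis2=2).real  # (F, m)
    absH2 = np.abs(spec.H) ** 2
    denom = Sii[:, :, None] - cond_var[None, :, :] * absH2
    ratio = Sii[:, :, None] / denom
    bad = ~(ratio > 0)
    if np.any(bad):
        logger.info("GGC: %d non-positive log arguments clipped to 0", bad.sum())
        ratio = np.where(bad, 1.0, ratio)
    ggc = np.clip(np.log(ratio), 0.0, None)

    dc = np.abs(spec.Af).copy()
    idx = np.arange(dc.shape[1])
    dc[:, idx, idx] = 0.0

    freqs = spec.frequencies
    return {
        "GGC": ConnectivityTensor("GGC", freqs, ggc),
        "DC": ConnectivityTensor("DC", freqs, dc),
    }


def raw_family(spec: SpectralMatrices) -> dict[str, ConnectivityTensor]:
    """Moduli of the spectral matrix, transfer function and AR polynomial."""
    freqs = spec.frequencies
    return {
        "S": ConnectivityTensor("S", freqs, np.abs(spec.S)),
        "h": ConnectivityTensor("h", freqs, np.abs(spec.H)),
        "Af": ConnectivityTensor("Af", freqs, np.abs(spec.Af)),
    }


def band_average(tensor: ConnectivityTensor) -> BandedConnectivity:
    """Arithmetic mean of a tensor within each classical band.

    Requires the full integer analysis grid 2..80 Hz.
    """
    freqs = np.asarray(tensor.frequencies)
    if freqs.shape != (len(FREQ_GRID_HZ),) or not np.array_equal(
        freqs, np.asarray(FREQ_GRID_HZ, dtype=float)
    ):
        raise ValueError("band averaging requires the integer 2..80 Hz grid")
    bands = {}
    for name in BAND_ORDER:
        lo, hi = BANDS[name]
        mask = (freqs >= lo) & (freqs <= hi)
        bands[name] = tensor.values[mask].mean(axis=0)
    return BandedConnectivity(tensor.measure, bands)


def compute_tensors(model: MVARModel) -> dict[str, ConnectivityTensor]:
    """All 14 tensors on the full grid from one spectral transform."""
    spec = model.spectral()
    out: dict[str, ConnectivityTensor] = {}
    families = (
        ("raw", lambda: raw_family(spec)),
        ("coherency", lambda: coherency_family(spec)),
        ("pdc", lambda: pdc_family(spec, model.resid_cov)),
        ("granger", lambda: granger_family(spec, model.resid_cov)),
    )
    for fam_name, fn in families:
        try:
            out.update(fn())
        except Exception as exc:
            raise RuntimeError(f"{fam_name} family failed: {exc}") from exc
    try:
        out.update(dtf_family(spec, pcoh=out["pCOH"]))
    except Exception as exc:
        raise RuntimeError(f"dtf family failed: {exc}") from exc
    assert set(out) == set(MEASURES)
    return out


def compute_all(model: MVARModel) -> dict[str, BandedConnectivity]:
    """All 14 measures, band-averaged: the EEG feature source for one subject."""
    return {name: band_average(t) for name, t in compute_tensors(model).items()}
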