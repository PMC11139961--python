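"""Subband decomposition of single-channel segments: VMD and multilevel DWT.

Variational mode decomposition (VMD) splits a signal into K narrowband modes
("VMFs") with learned center frequencies by solving, with an alternating
direction method of multipliers (ADMM) in the frequency domain, a
variational problem that penalizes each mode's bandwidth around its center
frequency.  The residual is defined by subtraction, so modes + residual
reconstruct the input exactly.  Modes are reported sorted by DESCENDING
center frequency: VMF1 is the highest-frequency mode, VMF5 (for K=5) the
slowest — matching the usual presentation for EEG where VMF1 sits in the
gamma range and VMF5 in the delta range.

The discrete wavelet transform (DWT) route uses a standard 5-level
decomposition (default ``db4``): detail level j occupies the dyadic band
(fs/2^(j+1), fs/2^j], the level-5 approximation the band [0, fs/2^6].  At
fs = 256 Hz this makes D1-D5 + A5 line up with 64-128, 32-64, 16-32, 8-16,
4-8 and 0-4 Hz — gamma down to delta.  Features are computed on the
coefficient vectors by default; a reconstruction-based variant (features on
band-limited time-domain signals) is available via ``use_reconstruction``.

Feature extraction consumes an ordered sub-signal list per channel segment:
VMD contributes 7 entries (5 VMFs, residual, original) and DWT 6 (A5,
D2-D5, original).  D1 (64-128 Hz) is dropped because the 0.5-64 Hz band-pass
of the preprocessing stage leaves it empty of physiological content.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt


@dataclass(frozen=True)
class VMDParams:
    """ADMM-VMD settings.

    alpha is the bandwidth penalty (larger -> narrower modes), tau the dual
    ascent step (0 disables strict reconstruction enforcement and tolerates
    noise), tol the convergence tolerance on the summed relative change of
    the modes between iterations.
    """

    K: int = 5
    alpha: float = 2000.0
    tau: float = 0.0
    tol: float = 1e-7
    max_iter: int = 500
    init: str = "uniform"  # 'uniform' or 'zero' center-frequency init

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.init not in ("uniform", "zero"):
            raise ValueError("init must be 'uniform' or 'zero'")


@dataclass(frozen=True)
class DWTParams:
    wavelet: str = "db4"
    levels: int = 5
    use_reconstruction: bool = False
    mode: str = "symmetric"  # mirror padding


@dataclass(frozen=True)
class BandSignal:
    """A named sub-signal with its nominal frequency localization.

    ``nominal_band`` is a (low, high) Hz interval for DWT subbands;
    ``center_frequency`` is the learned VMD center frequency in Hz.  Either
    may be None (e.g. for the untouched original segment).
    """

    name: str
    samples: np.ndarray
    nominal_band: "tuple[float, float] | None" = None
    center_frequency: "float | None" = None


@dataclass(frozen=True)
class VMDResult:
    modes: "tuple[BandSignal, ...]"
    residual: BandSignal
    converged: bool
    n_iter: int

    def __iter__(self):
        # allow `modes, residual = vmd(...)`
        return iter((list(self.modes), self.residual))


def vmd(x: np.ndarray, params: VMDParams = VMDParams(), fs: float = 1.0) -> VMDResult:
    """Decompose ``x`` into K narrowband modes plus a residual.

    Returns modes sorted by descending center frequency; the residual is
    ``x - sum(modes)`` so the decomposition is conservative by construction.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("vmd expects a 1-D signal")
    if len(x) < 8:
        raise ValueError("signal too short for VMD (need >= 8 samples)")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")
    if fs <= 0:
        raise ValueError("fs must be positive")

    N = len(x)
    # Full mirror extension on both sides: robust to odd lengths and
    # suppresses boundary discontinuities in the spectral updates.
    xm = np.concatenate([x[::-1], x, x[::-1]])
    T = len(xm)
    f_hat = np.fft.fftshift(np.fft.fft(xm))
    f_hat_plus = f_hat.copy()
    f_hat_plus[: T // 2] = 0.0  # keep non-negative frequencies only

    freqs = np.arange(T) / T - 0.5  # normalized frequency grid
    K = params.K
    omega = (0.5 * np.arange(K) / K if params.init == "uniform"
             else np.zeros(K))

    u_hat = np.zeros((K, T), dtype=complex)
    lam = np.zeros(T, dtype=complex)
    half = T // 2
    converged = False
    n_iter = 0
    for n_iter in range(1, params.max_iter + 1):
        u_prev = u_hat.copy()
        for k in range(K):
            others = u_hat.sum(axis=0) - u_hat[k]
            u_hat[k] = (f_hat_plus - others - lam / 2) / (
                1.0 + 2.0 * params.alpha * (freqs - omega[k]) ** 2)
            power = np.abs(u_hat[k, half:]) ** 2
            denom = power.sum()
            if denom > 0:
                omega[k] = float(freqs[half:] @ power / denom)
        if params.tau != 0.0:
            lam = lam + params.tau * (u_hat.sum(axis=0) - f_hat_plus)
        num = np.abs(u_hat - u_prev) ** 2
        den = np.abs(u_prev) ** 2
        change = sum(num[k].sum() / max(den[k].sum(), 1e-30) for k in range(K))
        if change < params.tol:
            converged = True
            break

    # Back to time domain: restore conjugate symmetry, invert, unmirror.
    modes_t = np.empty((K, N))
    for k in range(K):
        spec = np.zeros(T, dtype=complex)
        spec[half:] = u_hat[k, half:]
        spec[1:half + 1] = np.conj(u_hat[k, half:][::-1])
        spec[0] = np.conj(spec[-1])
        modes_t[k] = np.real(np.fft.ifft(np.fft.ifftshift(spec)))[N:2 * N]

    order = np.argsort(-omega)  # descending center frequency: VMF1 = fastest
    modes = tuple(
        BandSignal(name=f"VMF{i + 1}", samples=modes_t[k],
                   center_frequency=float(omega[k] * fs))
        for i, k in enumerate(order))
    residual = BandSignal(name="Residual",
                          samples=x - modes_t.sum(axis=0))
    return VMDResult(modes=modes, residual=residual,
                     converged=converged, n_iter=n_iter)


def dwt_band_map(fs: float, levels: int) -> "dict[str, tuple[float, float]]":
    """Nominal dyadic band of each DWT sub-signal (D1..Dlevels and A{levels})."""
    bands = {f"D{j}": (fs / 2 ** (j + 1), fs / 2 ** j) for j in range(1, levels + 1)}
    bands[f"A{levels}"] = (0.0, fs / 2 ** (levels + 1))
    return bands


def dwt_decompose(x: np.ndarray, params: DWTParams = DWTParams(),
                  fs: float = 1.0) -> "tuple[BandSignal, list[BandSignal]]":
    """Multilevel DWT of ``x``; returns (approximation, details D1..Dlevels).

    Sub-signals hold coefficient vectors, or reconstructed band-limited
    signals when ``params.use_reconstruction`` is set.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("dwt_decompose expects a 1-D signal")
    if len(x) < 2 ** params.levels:
        raise ValueError(
            f"signal of length {len(x)} too short for {params.levels} levels")
    if params.wavelet not in pywt.wavelist(kind="discrete"):
        raise ValueError(f"unknown wavelet {params.wavelet!r}")
    coeffs = pywt.wavedec(x, params.wavelet, level=params.levels, mode=params.mode)
    bands = dwt_band_map(fs, params.levels)

    def band_samples(idx: int) -> np.ndarray:
        if not params.use_reconstruction:
            return coeffs[idx]
        only = [c if i == idx else np.zeros_like(c) for i, c in enumerate(coeffs)]
        return pywt.waverec(only, params.wavelet, mode=params.mode)[: len(x)]

    approx_name = f"A{params.levels}"
    approx = BandSignal(name=approx_name, samples=band_samples(0),
                        nominal_band=bands[approx_name])
    details = [
        BandSignal(name=f"D{params.levels + 1 - i}", samples=band_samples(i),
                   nominal_band=bands[f"D{params.levels + 1 - i}"])
        for i in range(1, len(coeffs))
    ]
    details.sort(key=lambda b: int(b.name[1:]))  # D1 first
    return approx, details


def dwt_reconstruct(approx: BandSignal, details: "list[BandSignal]",
                    params: DWTParams = DWTParams(),
                    n_samples: "int | None" = None) -> np.ndarray:
    """Inverse of :func:`dwt_decompose` on coefficient vectors."""
    if params.use_reconstruction:
        raise ValueError("reconstruction-mode band signals are not coefficients")
    ordered = sorted(details, key=lambda b: -int(b.name[1:]))  # D(levels)..D1
    coeffs = [approx.samples] + [d.samples for d in ordered]
    out = pywt.waverec(coeffs, params.wavelet, mode=params.mode)
    return out[:n_samples] if n_samples is not None else out


def subsignals_for_features(x: np.ndarray, method: str,
                            params: "VMDParams | DWTParams | None" = None,
                            fs: float = 1.0) -> "list[BandSignal]":
    """Ordered sub-signal list feeding feature computation for one channel segment.

    VMD -> [VMF1..VMFK, Residual, Orig] (7 entries at K=5);
    DWT -> [A5, D2, D3, D4, D5, Orig] (6 entries; D1 excluded because the
    preprocessing band-pass empties the 64-128 Hz band).
    ``Orig`` is always the untouched input segment.
    """
    x = np.asarray(x, dtype=float)
    method = method.lower()
    orig = BandSignal(name="Orig", samples=x)
    if method == "vmd":
        p = params if params is not None else VMDParams()
        result = vmd(x, p, fs)
        return list(result.modes) + [result.residual, orig]
    if method == "dwt":
        p = params if params is not None else DWTParams()
        approx, details = dwt_decompose(x, p, fs)
        return [approx] + [d for d in details if d.name != "D1"] + [orig]
    raise ValueError(f"unknown decomposition method {method!r}")


def band_names(method: str, params: "VMDParams | DWTParams | None" = None) -> "list[str]":
    """Sub-signal names in feature-column order for a decomposition method."""
    method = method.lower()
    if method == "vmd":
        K = (params.K if isinstance(params, VMDParams) else VMDParams().K)
        return [f"VMF{i + 1}" for i in range(K)] + ["Residual", "Orig"]
    if method == "dwt":
        levels = (params.levels if isinstance(params, DWTParams) else DWTParams().levels)
        return [f"A{levels}"] + [f"D{j}" for j in range(2, levels + 1)] + ["Orig"]
    raise ValueError(f"unknown decomposition method {method!r}")
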