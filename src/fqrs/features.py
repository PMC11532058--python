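"""The ten per-lead fragmentation features.

Three features come from phase-rectified signal averaging (PRSA), which
averages signal windows aligned on "anchor" samples (here: increases) and
thereby isolates intra-QRS oscillations; six come from variational mode
decomposition (VMD), which splits the segment into narrow-band modes with
learned center frequencies -- fragmentation pushes energy and zero
crossings into the high-frequency modes; the tenth is the count of
prominent peaks inside the QRS.

Feature order is fixed and documented in :data:`FEATURE_NAMES`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import InvalidParameterError, NoAnchorError, ZeroEnergyError
from .qrs_segment import QrsSegment

FEATURE_NAMES: tuple[str, ...] = (
    "prsa_mean_derivative",
    "prsa_fit_slope",
    "prsa_fit_ycross",
    "vmd_e3",
    "vmd_e4",
    "vmd_e5",
    "vmd_z3",
    "vmd_z4",
    "vmd_z5",
    "peak_count",
)

DEFAULT_PRSA_L = 16
DEFAULT_VMD_K = 5
DEFAULT_VMD_ALPHA = 2000.0


def _as_waveform(segment: QrsSegment | np.ndarray) -> np.ndarray:
    x = segment.waveform if isinstance(segment, QrsSegment) else np.asarray(segment)
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise InvalidParameterError("segment must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise InvalidParameterError("segment must be finite")
    return x


# ---------------------------------------------------------------------------
# PRSA
# ---------------------------------------------------------------------------

@dataclass
class PrsaCurve:
    """Phase-rectified average: window of length 2L around increase anchors."""

    curve: np.ndarray
    anchor_count: int
    half_window: int
    source_id: str = ""

    def __post_init__(self) -> None:
        self.curve = np.asarray(self.curve, dtype=float)
        if self.anchor_count < 1:
            raise NoAnchorError("PRSA curve requires at least one anchor")
        if self.curve.shape != (2 * self.half_window,):
            raise ValueError("curve length must be exactly 2L")


def compute_prsa(
    segment: QrsSegment | np.ndarray, L: int = DEFAULT_PRSA_L
) -> PrsaCurve:
    """Anchored averaging: anchors are samples i with x[i] > x[i-1] and
    i in [L, M-L); curve[k] = mean over anchors of x[anchor - L + k].

    Raises
    ------
    NoAnchorError
        If the segment has no increase in the admissible range.
    InvalidParameterError
        If L is outside [2, M/4].
    """
    x = _as_waveform(segment)
    m = x.size
    if not (2 <= L <= m // 4):
        raise InvalidParameterError(f"L must be in [2, {m // 4}], got {L}")
    idx = np.arange(L, m - L)
    anchors = idx[x[idx] > x[idx - 1]]
    if anchors.size == 0:
        raise NoAnchorError("segment is monotone non-increasing: no anchors")
    offsets = np.arange(-L, L)
    windows = x[anchors[:, None] + offsets[None, :]]
    source = segment.lead if isinstance(segment, QrsSegment) else ""
    return PrsaCurve(
        curve=windows.mean(axis=0),
        anchor_count=int(anchors.size),
        half_window=L,
        source_id=source,
    )


def prsa_features(curve: PrsaCurve) -> tuple[float, float, float]:
    """(mean derivative, least-squares slope, y-crossing at k = 0)."""
    y = curve.curve
    mean_derivative = float(np.diff(y).mean())
    k = np.arange(y.size, dtype=float)
    # closed-form simple linear regression of y on k
    kc = k - k.mean()
    slope = float((kc @ (y - y.mean())) / (kc @ kc))
    ycross = float(y.mean() - slope * k.mean())
    return mean_derivative, slope, ycross


# ---------------------------------------------------------------------------
# VMD
# ---------------------------------------------------------------------------

@dataclass
class VmdModes:
    """K narrow-band modes with center frequencies sorted ascending."""

    modes: np.ndarray                 # (K, M)
    center_frequencies: np.ndarray    # Hz at the stated nominal rate
    converged: bool
    fs: float

    def __post_init__(self) -> None:
        self.modes = np.asarray(self.modes, dtype=float)
        self.center_frequencies = np.asarray(self.center_frequencies, dtype=float)
        if np.any(np.diff(self.center_frequencies) < 0):
            raise ValueError("center frequencies must be sorted ascending")

    @property
    def k(self) -> int:
        return self.modes.shape[0]

    def reconstruction(self) -> np.ndarray:
        return self.modes.sum(axis=0)


def vmd_decompose(
    segment: QrsSegment | np.ndarray,
    k: int = DEFAULT_VMD_K,
    alpha: float = DEFAULT_VMD_ALPHA,
    tau: float = 0.0,
    tol: float = 1e-7,
    max_iter: int = 500,
    fs: float = 1000.0,
) -> VmdModes:
    """Variational mode decomposition by ADMM.

    The signal is mirror-extended to halve edge effects, transformed to the
    half spectrum, and the modes are updated by Wiener filtering around
    their center frequencies, which are in turn updated as spectral
    centroids.  Center frequencies start at the K largest spectral peaks
    (uniformly spaced as a fallback), which breaks the degenerate fixed
    point where two modes share one tone.  ``alpha`` is the bandwidth
    penalty; ``tau`` the Lagrangian ascent step (0 = no
    exact-reconstruction constraint, tolerant to noise).  Non-convergence
    within ``max_iter`` returns the partial result with
    ``converged = False``.
    """
    x = _as_waveform(segment)
    n = x.size
    if n < 2 * k:
        raise InvalidParameterError("segment too short for the requested K")

    # mirror extension to length 2n
    half = n // 2
    f = np.concatenate([x[:half][::-1], x, x[n - half:][::-1]])
    t_len = f.size
    freqs = np.arange(t_len) / t_len - 0.5  # normalized, fftshifted order

    f_hat = np.fft.fftshift(np.fft.fft(f))
    f_hat_plus = f_hat.copy()
    f_hat_plus[: t_len // 2] = 0.0

    # initialise center frequencies at the K strongest spectral peaks
    half_mag = np.abs(f_hat_plus[t_len // 2:])
    pk, props = sps.find_peaks(half_mag, distance=max(2, t_len // (8 * k)))
    omega = 0.5 / k * np.arange(k)              # uniform fallback
    if pk.size:
        top = pk[np.argsort(half_mag[pk])[::-1][:k]]
        omega[: top.size] = np.sort(freqs[t_len // 2:][top])
    u_hat = np.zeros((k, t_len), dtype=complex)
    lam = np.zeros(t_len, dtype=complex)

    converged = False
    u_prev = u_hat.copy()
    for _ in range(max_iter):
        sum_u = u_hat.sum(axis=0)
        for i in range(k):
            sum_u = sum_u - u_hat[i]
            u_hat[i] = (f_hat_plus - sum_u - lam / 2.0) / (
                1.0 + 2.0 * alpha * (freqs - omega[i]) ** 2
            )
            power = np.abs(u_hat[i, t_len // 2:]) ** 2
            denom = power.sum()
            if denom > 1e-30:
                omega[i] = float(
                    (freqs[t_len // 2:] @ power) / denom
                )
            sum_u = sum_u + u_hat[i]
        if tau != 0.0:
            lam = lam + tau * (sum_u - f_hat_plus)
        diff = u_hat - u_prev
        denom = np.sum(np.abs(u_prev) ** 2, axis=1)
        denom[denom < 1e-30] = 1.0
        u_diff = float(np.sum(np.sum(np.abs(diff) ** 2, axis=1) / denom))
        u_prev = u_hat.copy()
        if u_diff < tol:
            converged = True
            break

    # back to time domain: hermitian-complete the half spectrum
    modes = np.empty((k, n))
    for i in range(k):
        full = np.zeros(t_len, dtype=complex)
        full[t_len // 2:] = u_hat[i, t_len // 2:]
        full[1: t_len // 2 + 1] = np.conj(u_hat[i, t_len // 2:][::-1])
        mode = np.real(np.fft.ifft(np.fft.ifftshift(full)))
        modes[i] = mode[half: half + n]

    order = np.argsort(omega)
    return VmdModes(
        modes=modes[order],
        center_frequencies=np.abs(omega[order]) * fs,
        converged=converged,
        fs=fs,
    )


def _sign_changes(u: np.ndarray) -> int:
    s = np.sign(u)
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.sum(s[:-1] * s[1:] < 0))


def vmd_features(modes: VmdModes) -> tuple[float, float, float, int, int, int]:
    """Relative energies and zero-crossing counts of the three
    highest-frequency modes: (e3, e4, e5, z3, z4, z5)."""
    if modes.k < 5:
        raise InvalidParameterError("vmd_features requires K >= 5 modes")
    energies = np.sum(modes.modes**2, axis=1)
    total = energies.sum()
    if total <= 0:
        raise ZeroEnergyError("all VMD modes carry zero energy")
    rel = energies / total
    e3, e4, e5 = (float(rel[i]) for i in (-3, -2, -1))
    z3, z4, z5 = (_sign_changes(modes.modes[i]) for i in (-3, -2, -1))
    return e3, e4, e5, z3, z4, z5


# ---------------------------------------------------------------------------
# Peak count and the assembled vector
# ---------------------------------------------------------------------------

def count_qrs_peaks(
    segment: QrsSegment | np.ndarray, prominence_fraction: float = 0.05
) -> int:
    """Number of prominent local extrema (maxima and minima) of the 5-point
    moving-average-smoothed segment; prominence threshold is a fraction of
    its peak-to-peak amplitude.  A flat segment counts zero peaks."""
    x = _as_waveform(segment)
    xs = np.convolve(x, np.ones(5) / 5.0, mode="same")
    p2p = float(xs.max() - xs.min())
    if p2p < 1e-12:
        return 0
    prom = prominence_fraction * p2p
    n_max, _ = sps.find_peaks(xs, prominence=prom)
    n_min, _ = sps.find_peaks(-xs, prominence=prom)
    return int(n_max.size + n_min.size)


@dataclass(frozen=True)
class FeatureVector:
    """The ten per-lead features, in :data:`FEATURE_NAMES` order."""

    prsa_mean_derivative: float
    prsa_fit_slope: float
    prsa_fit_ycross: float
    vmd_e3: float
    vmd_e4: float
    vmd_e5: float
    vmd_z3: int
    vmd_z4: int
    vmd_z5: int
    peak_count: int

    def __post_init__(self) -> None:
        arr = self.to_array()
        if arr.shape != (10,) or not np.all(np.isfinite(arr)):
            raise InvalidParameterError("feature vector must hold 10 finite values")
        if min(self.vmd_e3, self.vmd_e4, self.vmd_e5) < 0 or max(
            self.vmd_e3, self.vmd_e4, self.vmd_e5
        ) > 1:
            raise InvalidParameterError("relative energies must lie in [0, 1]")
        if min(self.vmd_z3, self.vmd_z4, self.vmd_z5, self.peak_count) < 0:
            raise InvalidParameterError("counts must be non-negative")

    def to_array(self) -> np.ndarray:
        return np.asarray(
            [getattr(self, name) for name in FEATURE_NAMES], dtype=float
        )


def extract_feature_vector(
    segment: QrsSegment | np.ndarray,
    prsa_l: int = DEFAULT_PRSA_L,
    vmd_k: int = DEFAULT_VMD_K,
    vmd_alpha: float = DEFAULT_VMD_ALPHA,
    prominence_fraction: float = 0.05,
) -> FeatureVector:
    """Compose the ten features for one segment.

    Propagates :class:`NoAnchorError` for degenerate (monotone
    non-increasing) segments so callers can flag the lead as skipped.
    """
    curve = compute_prsa(segment, L=prsa_l)
    d, slope, ycross = prsa_features(curve)
    modes = vmd_decompose(segment, k=vmd_k, alpha=vmd_alpha)
    e3, e4, e5, z3, z4, z5 = vmd_features(modes)
    peaks = count_qrs_peaks(segment, prominence_fraction=prominence_fraction)
    return FeatureVector(
        prsa_mean_derivative=d,
        prsa_fit_slope=slope,
        prsa_fit_ycross=ycross,
        vmd_e3=e3,
        vmd_e4=e4,
        vmd_e5=e5,
        vmd_z3=z3,
        vmd_z4=z4,
        vmd_z5=z5,
        peak_count=peaks,
    )
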