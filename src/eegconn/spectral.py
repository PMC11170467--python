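"""Frequency-domain connectivity: banded cross-spectra and the four metric
families (linear connectivity, coherence, nonlinear connectivity, phase
synchronization), each decomposed into instantaneous, lagged and total parts.

The decomposition follows the log-determinant framework for separating
zero-lag from time-lagged spectral dependence.  For two (possibly
multivariate) signals x, y with band cross-spectral matrix

    S = [[Sxx, Sxy],
         [Syx, Syy]]

the total linear dependence is F_total = ln(|Sxx| |Syy| / |S|) and the
instantaneous part is F_inst = ln(|Re Sxx| |Re Syy| / |Re S|); the lagged
part is the difference, F_lagged = F_total - F_inst.  All three are
non-negative.  The coherence-type measures map each F through
rho^2 = 1 - exp(-F), bounding them in [0, 1]; consequently the total does
not add but multiplies: (1 - rho2_total) = (1 - rho2_inst)(1 - rho2_lagged).
The nonlinear family (nLC) and phase synchronization (PS) apply the same two
forms to the cross-spectrum of amplitude-normalized Fourier coefficients, so
they carry phase information only.

The instantaneous parts absorb zero-lag dependence such as volume-conducted
source leakage; the lagged parts are blind to any purely instantaneous
mixing, which is the property that makes them usable on inverse-solution
source signals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import hann

from .core import RegionTimeSeries

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "BandedCrossSpectra",
    "DependenceTriple",
    "estimate_banded_cross_spectra",
    "linear_connectivity",
    "coherence",
    "nonlinear_connectivity",
    "phase_synchronization",
    "pairwise_triples",
]

DEFAULT_EPOCH_LEN = 2.0  # seconds; gives 0.5 Hz resolution, >= 3 bins/band


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band [f_lo, f_hi) in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError(f"invalid band edges for {self.name!r}: "
                             f"need 0 < f_lo < f_hi")


#: The canonical eight-band EEG taxonomy used throughout.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha1", 8.0, 10.0),
    BandDefinition("alpha2", 10.0, 13.0),
    BandDefinition("beta1", 13.0, 18.0),
    BandDefinition("beta2", 18.0, 21.0),
    BandDefinition("beta3", 21.0, 30.0),
    BandDefinition("gamma", 30.0, 40.0),
)


@dataclass
class BandedCrossSpectra:
    """Per-band Hermitian cross-spectral matrices.

    ``S`` holds the raw Fourier covariance averaged over epochs and over the
    frequency bins of each band; ``S_norm`` is computed identically after
    dividing each Fourier coefficient by its modulus (amplitude factored
    out), so its diagonal is ~1 and its off-diagonal entries carry phase
    consistency only.
    """

    S: dict[str, np.ndarray]
    S_norm: dict[str, np.ndarray]
    n_epochs: int
    bands: tuple[BandDefinition, ...]

    def band_names(self) -> list[str]:
        return [b.name for b in self.bands]


@dataclass(frozen=True)
class DependenceTriple:
    """(instantaneous, lagged, total) dependence for one metric family."""

    instantaneous: float
    lagged: float
    total: float
    family: str

    def as_dict(self) -> dict[str, float]:
        return {"instantaneous": self.instantaneous,
                "lagged": self.lagged, "total": self.total}


# ---------------------------------------------------------------------------
# Cross-spectral estimation
# ---------------------------------------------------------------------------

def estimate_banded_cross_spectra(
    ts: RegionTimeSeries,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    epoch_len: float = DEFAULT_EPOCH_LEN,
) -> BandedCrossSpectra:
    """Estimate per-band cross-spectral matrices from epoched, Hann-tapered
    Fourier transforms.

    The recording is cut into non-overlapping epochs of ``epoch_len``
    seconds.  For each epoch the discrete Fourier transform is taken per
    region and the complex covariance (outer product) is accumulated over
    every frequency bin whose center lies in ``[f_lo, f_hi)``, then averaged
    over epochs and bins.  ``S_norm`` repeats the estimate with each Fourier
    coefficient divided by its modulus.
    """
    fs = ts.fs
    nyquist = fs / 2.0
    for band in bands:
        if band.f_hi > nyquist:
            raise ValueError(
                f"band {band.name!r} upper edge {band.f_hi} Hz exceeds the "
                f"Nyquist frequency {nyquist} Hz")

    n_per_epoch = int(round(epoch_len * fs))
    n_epochs = ts.n_samples // n_per_epoch
    if n_epochs < 2:
        raise ValueError(
            f"recording too short: need at least {2 * n_per_epoch} samples "
            f"({2 * epoch_len:g} s) for 2 epochs of {epoch_len:g} s, "
            f"got {ts.n_samples}")

    window = hann(n_per_epoch, sym=False)
    data = ts.data[:, : n_epochs * n_per_epoch]
    # (n_epochs, n_regions, n_per_epoch)
    epochs = data.reshape(ts.n_regions, n_epochs, n_per_epoch).swapaxes(0, 1)
    coeffs = np.fft.rfft(epochs * window, axis=-1)
    freqs = np.fft.rfftfreq(n_per_epoch, d=1.0 / fs)

    with np.errstate(invalid="ignore", divide="ignore"):
        moduli = np.abs(coeffs)
        normed = np.where(moduli > 0, coeffs / np.where(moduli == 0, 1.0, moduli), 0.0)

    S: dict[str, np.ndarray] = {}
    S_norm: dict[str, np.ndarray] = {}
    for band in bands:
        sel = (freqs >= band.f_lo) & (freqs < band.f_hi)
        if not sel.any():
            raise ValueError(
                f"band {band.name!r} contains no frequency bin at "
                f"{1.0 / epoch_len:g} Hz resolution")
        c = coeffs[:, :, sel]
        cn = normed[:, :, sel]
        # average outer products over epochs and bins
        denom = c.shape[0] * c.shape[2]
        S[band.name] = np.einsum("eib,ejb->ij", c, np.conj(c)) / denom
        S_norm[band.name] = np.einsum("eib,ejb->ij", cn, np.conj(cn)) / denom

    return BandedCrossSpectra(S=S, S_norm=S_norm, n_epochs=n_epochs,
                              bands=tuple(bands))


# ---------------------------------------------------------------------------
# Determinant forms
# ---------------------------------------------------------------------------

def _check_pair(S_pair: np.ndarray, nx: int) -> None:
    S_pair = np.asarray(S_pair)
    n = S_pair.shape[0]
    if S_pair.shape != (n, n) or not (0 < nx < n):
        raise ValueError("S_pair must be square with 0 < nx < n")
    if not np.allclose(S_pair, S_pair.conj().T, atol=1e-8):
        raise ValueError("S_pair must be Hermitian")


def _logdet_hermitian(M: np.ndarray) -> float:
    sign, ld = np.linalg.slogdet(M)
    if sign <= 0 or not np.isfinite(ld):
        raise ValueError("degenerate spectrum")
    return float(ld)


def _f_components(S_pair: np.ndarray, nx: int) -> tuple[float, float, float]:
    """(F_inst, F_lagged, F_total) log-determinant dependences for a 2-block
    partition with x occupying the first ``nx`` rows."""
    S_pair = np.asarray(S_pair, dtype=complex)
    _check_pair(S_pair, nx)
    Sxx = S_pair[:nx, :nx]
    Syy = S_pair[nx:, nx:]
    ld_xx = _logdet_hermitian(Sxx)
    ld_yy = _logdet_hermitian(Syy)
    f_total = ld_xx + ld_yy - _logdet_hermitian(S_pair)
    ld_xx_re = _logdet_hermitian(Sxx.real)
    ld_yy_re = _logdet_hermitian(Syy.real)
    f_inst = ld_xx_re + ld_yy_re - _logdet_hermitian(S_pair.real)
    f_lagged = f_total - f_inst
    return _clamp(f_inst), _clamp(f_lagged), _clamp(f_total)


def _clamp(v: float) -> float:
    if v < -1e-8:
        raise ValueError(f"negative dependence component {v!r}; "
                         "input is not a valid cross-spectrum")
    return float(max(v, 0.0))


def linear_connectivity(S_pair: np.ndarray, nx: int = 1) -> DependenceTriple:
    """Linear connectivity (LC) triple from a raw band cross-spectrum block.

    Carries both amplitude and phase information; values are in nats,
    unbounded above, zero iff no linear dependence at the band.
    total = instantaneous + lagged.
    """
    f_inst, f_lagged, f_total = _f_components(S_pair, nx)
    return DependenceTriple(f_inst, f_lagged, f_total, family="LC")


def coherence(S_pair: np.ndarray, nx: int = 1) -> DependenceTriple:
    """Squared-coherence triple, each part ``1 - exp(-F)`` of the matching
    LC component, bounded in [0, 1].  The total is not additive:
    (1 - total) = (1 - inst) * (1 - lagged)."""
    f_inst, f_lagged, f_total = _f_components(S_pair, nx)
    return DependenceTriple(
        -np.expm1(-f_inst), -np.expm1(-f_lagged), -np.expm1(-f_total),
        family="Coh")


def nonlinear_connectivity(S_norm_pair: np.ndarray, nx: int = 1) -> DependenceTriple:
    """Nonlinear connectivity (nLC): the LC determinant forms applied to the
    amplitude-normalized cross-spectrum, hence phase-only."""
    f_inst, f_lagged, f_total = _f_components(S_norm_pair, nx)
    return DependenceTriple(f_inst, f_lagged, f_total, family="nLC")


def phase_synchronization(S_norm_pair: np.ndarray, nx: int = 1) -> DependenceTriple:
    """Phase synchronization (PS): coherence-type mapping of the
    amplitude-normalized forms; 0 = no synchronization, 1 = perfect phase
    locking."""
    f_inst, f_lagged, f_total = _f_components(S_norm_pair, nx)
    return DependenceTriple(
        -np.expm1(-f_inst), -np.expm1(-f_lagged), -np.expm1(-f_total),
        family="PS")


_FAMILY_FUNCS = {
    "LC": (linear_connectivity, "S"),
    "Coh": (coherence, "S"),
    "nLC": (nonlinear_connectivity, "S_norm"),
    "PS": (phase_synchronization, "S_norm"),
}


# ---------------------------------------------------------------------------
# Vectorized pairwise evaluation (univariate blocks, 2x2 spectra)
# ---------------------------------------------------------------------------

def pairwise_triples(S: np.ndarray, family: str) -> dict[str, np.ndarray]:
    """All-pairs dependence triples from a full region cross-spectral matrix.

    For univariate blocks the determinant forms reduce to scalar expressions
    of the complex coherency c = Sxy / sqrt(Sxx Syy):

        F_total = -ln(1 - |c|^2),  F_inst = -ln(1 - Re(c)^2)

    which this routine evaluates for every upper-triangle pair at once.
    Pass the raw ``S`` for LC/Coh and ``S_norm`` for nLC/PS.

    Returns a dict with keys ``instantaneous``, ``lagged``, ``total``, each a
    condensed-order vector.
    """
    if family not in _FAMILY_FUNCS:
        raise ValueError(f"unknown metric family {family!r}")
    S = np.asarray(S, dtype=complex)
    diag = S.diagonal().real
    if np.any(diag <= 0):
        raise ValueError("degenerate spectrum: non-positive diagonal power")
    iu, ju = np.triu_indices(S.shape[0], k=1)
    c = S[iu, ju] / np.sqrt(diag[iu] * diag[ju])
    mod2 = np.minimum(np.abs(c) ** 2, 1.0 - 1e-15)
    re2 = np.minimum(c.real ** 2, 1.0 - 1e-15)
    f_total = -np.log1p(-mod2)
    f_inst = -np.log1p(-re2)
    f_lagged = np.maximum(f_total - f_inst, 0.0)
    if family in ("LC", "nLC"):
        return {"instantaneous": f_inst, "lagged": f_lagged, "total": f_total}
    return {"instantaneous": -np.expm1(-f_inst),
            "lagged": -np.expm1(-f_lagged),
            "total": -np.expm1(-f_total)}
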