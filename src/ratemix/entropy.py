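"""Spectral entropy of unphased diploid local-ancestry signals.

With two parental populations, the diploid ancestry dosage p1(l) at marker l
takes values {0, 1/2, 1} (fraction of ancestry from parent population 1;
p2 = 1 - p1).  Each marker is mapped to a unit-modulus phasor

    z(l) = exp(i * theta(l)),   theta = arg(p1 + i * p2),

so the two pure ancestries sit at phases 0 and pi/2 and the heterozygous
state at pi/4.  Unit modulus means every marker carries equal power, so no
region or individual is up-weighted when the signal is decomposed into
spectral components, and swapping ancestry labels is the exact isometry
z -> i * conj(z), which leaves both entropies below invariant.

Two entropies summarize ancestry randomness:

* Sw (within-individual): Shannon entropy (nats) of the folded power
  spectrum of z along a chromosome interval - autocorrelated ancestry
  (long blocks) concentrates power at low frequency and lowers Sw.
* Sb (between-individual): Shannon entropy of the eigenvalue spectrum of
  the cohort cross-correlation matrix C, with c_{jj'} the genome-interval
  average of z_j * conj(z_j'); co-varying ancestry across individuals
  concentrates the eigenvalues and lowers Sb.  Sb lies in [0, ln J].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AncestrySignal",
    "SpectralEntropyResult",
    "CohortCorrelation",
    "snap_dosage",
    "to_signal",
    "within_entropy",
    "within_entropy_batch",
    "between_entropy",
]

_LEVELS = np.array([0.5, 0.0, 1.0])  # ordered so argmin ties resolve toward 1/2


@dataclass
class AncestrySignal:
    """Per-marker diploid ancestry as a unit-modulus complex signal."""

    positions: np.ndarray
    dosage: np.ndarray  # p1 per marker, in {0, 1/2, 1} after snapping
    z: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.z = np.asarray(self.z, dtype=complex)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("marker positions must be strictly increasing")
        if not (len(self.positions) == len(self.dosage) == len(self.z)):
            raise ValueError("positions, dosage and z must share length")

    @property
    def n_markers(self) -> int:
        return len(self.z)

    @property
    def length(self) -> float:
        return float(self.positions[-1] - self.positions[0])


@dataclass
class SpectralEntropyResult:
    """Folded power spectrum and its Shannon entropy (nats)."""

    folded_spectrum: np.ndarray
    sw: float
    n_markers: int


@dataclass
class CohortCorrelation:
    """Cohort cross-correlation matrix, its eigenvalues, and Sb."""

    matrix: np.ndarray
    eigenvalues: np.ndarray
    sb: float

    @property
    def n_individuals(self) -> int:
        return self.matrix.shape[0]


def snap_dosage(dosage: np.ndarray, max_deviation: float = 0.5) -> np.ndarray:
    """Snap dosages in [0, 1] to the nearest of {0, 1/2, 1}.

    Ties (0.25 and 0.75) round toward 1/2.  Values farther than
    ``max_deviation`` from every level raise, catching mis-scaled input
    (e.g. diploid [0, 2] dosages passed without halving).
    """
    dosage = np.asarray(dosage, dtype=float)
    if np.any((dosage < 0) | (dosage > 1)) or not np.all(np.isfinite(dosage)):
        raise ValueError("dosages must be finite and within [0, 1]")
    dist = np.abs(dosage[..., None] - _LEVELS)
    if np.any(dist.min(axis=-1) > max_deviation):
        raise ValueError("dosage farther than max_deviation from {0, 1/2, 1}")
    return _LEVELS[np.argmin(dist, axis=-1)]


def to_signal(
    dosages,
    positions=None,
    snap: bool = True,
    max_deviation: float = 0.5,
    phase: str = "balanced",
) -> AncestrySignal:
    """Map per-marker ancestry fractions p1 to the complex unit phasor.

    phase="balanced" (default) uses theta = arg(p1 + i*(1-p1)), the
    label-symmetric convention (heterozygous markers at pi/4).
    phase="arccos" uses theta = arccos(p1) (heterozygous markers at pi/3);
    it is provided for comparison but breaks exact label-swap invariance.
    """
    dosages = np.asarray(dosages, dtype=float)
    if positions is None:
        positions = np.arange(len(dosages), dtype=float)
    p1 = snap_dosage(dosages, max_deviation) if snap else dosages
    if np.any((p1 < 0) | (p1 > 1)):
        raise ValueError("dosages must be within [0, 1]")
    if phase == "balanced":
        theta = np.arctan2(1.0 - p1, p1)
    elif phase == "arccos":
        theta = np.arccos(p1)
    else:
        raise ValueError(f"unknown phase convention {phase!r}")
    return AncestrySignal(positions=positions, dosage=p1, z=np.exp(1j * theta))


def _folded_power(z: np.ndarray) -> np.ndarray:
    """Folded, unit-sum power spectrum of rows of a (..., M) complex array.

    Coefficients are normalized so the total power is one (discrete
    Parseval matching the continuous normalization (1/L) int |z|^2 = 1),
    then folded around zero frequency: zeta_n = |Z_n|^2 + |Z_{-n}|^2 for
    n > 0 (the Nyquist bin of an even-length signal is its own mirror).
    """
    m = z.shape[-1]
    power = np.abs(np.fft.fft(z, axis=-1)) ** 2 / m**2
    total = power.sum(axis=-1, keepdims=True)
    power = power / total
    half = m // 2
    zeta = power[..., : half + 1].copy()
    nmax = (m - 1) // 2
    if nmax >= 1:
        zeta[..., 1 : nmax + 1] += power[..., : m - nmax - 1 : -1]
    return zeta


def _entropy(p: np.ndarray, axis: int = -1) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    return -terms.sum(axis=axis)


def within_entropy(signal: AncestrySignal) -> SpectralEntropyResult:
    """Within-individual spectral entropy Sw of one ancestry signal."""
    if signal.n_markers < 2:
        warnings.warn("single-marker signal: Sw is trivially 0", stacklevel=2)
        return SpectralEntropyResult(np.array([1.0]), 0.0, signal.n_markers)
    zeta = _folded_power(signal.z)
    return SpectralEntropyResult(zeta, float(_entropy(zeta)), signal.n_markers)


def within_entropy_batch(z: np.ndarray) -> np.ndarray:
    """Sw for each row of a (..., M) array of unit phasors (vectorized)."""
    z = np.asarray(z, dtype=complex)
    if z.shape[-1] < 2:
        return np.zeros(z.shape[:-1])
    return _entropy(_folded_power(z))


def between_entropy(signals, clip_tol: float = 1e-9) -> CohortCorrelation:
    """Between-individual entropy Sb of J signals on a common marker grid.

    Accepts a list of :class:`AncestrySignal` (grids must match) or a
    (J, M) complex array.  Eigenvalues of the Hermitian cross-correlation
    matrix within ``-clip_tol`` of zero are clipped to zero.
    """
    if isinstance(signals, np.ndarray):
        Z = np.asarray(signals, dtype=complex)
    else:
        signals = list(signals)
        if len(signals) < 2:
            raise ValueError("between_entropy needs J >= 2 individuals")
        grid = signals[0].positions
        for s in signals[1:]:
            if s.n_markers != len(grid) or not np.array_equal(s.positions, grid):
                raise ValueError("signals must share an identical marker grid")
        Z = np.vstack([s.z for s in signals])
    if Z.ndim != 2 or Z.shape[0] < 2:
        raise ValueError("need a (J >= 2, M) array of signals")
    m = Z.shape[1]
    C = (Z @ Z.conj().T) / m
    lam = np.linalg.eigvalsh(C)
    if np.any(lam < -clip_tol):
        raise np.linalg.LinAlgError("correlation matrix has a significantly negative eigenvalue")
    lam = np.clip(lam, 0.0, None)
    frac = lam / Z.shape[0]
    return CohortCorrelation(matrix=C, eigenvalues=lam, sb=float(_entropy(frac)))
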