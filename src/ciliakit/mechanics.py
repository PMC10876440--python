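"""Antennal mechanics: displacement PSD, harmonic-oscillator fit, fluctuation
energy, and mechanical sensitivity gain.

The fly's antennal sound receiver behaves as a damped simple harmonic
oscillator (SHO).  Its free-fluctuation displacement power spectral density is

    S(f) = F0^2 / ( m^2 [ (w0^2 - w^2)^2 + (w w0 / Q)^2 ] ),   w = 2 pi f

with effective mass m, natural frequency f0 (w0 = 2 pi f0), and quality
factor Q.  The spring constant is Ks = m w0^2 and the damping gamma =
m w0 / Q.  At thermal equilibrium equipartition fixes the mean squared
displacement: Ks <X^2> = kB T, so the fluctuation energy E = Ks <X^2>
expressed in kB T units equals 1 for a passive receiver; active amplification
by the auditory neurons drives E above 1.

Mechanical sensitivity gain for tone stimulation is
gain = displacement * 2 pi f_eigen / SPV (dimensionless), and the
amplification figure of merit is gain_max / gain_min across the stimulus
intensity sweep.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize, signal

__all__ = [
    "BOLTZMANN_J_PER_K",
    "MechTrace",
    "PSDSpectrum",
    "SHOFitResult",
    "StimulusResponse",
    "GainCurve",
    "FluctuationEnergy",
    "sho_psd_model",
    "displacement_psd",
    "fit_sho",
    "fluctuation_energy",
    "gain_curve",
]

BOLTZMANN_J_PER_K = 1.380649e-23

#: default effective mass of the antennal receiver, kg (50 ng)
DEFAULT_MASS_KG = 5.0e-11
#: default analysis band, Hz
DEFAULT_BAND_HZ = (100.0, 1500.0)


@dataclass
class MechTrace:
    """Vibrometry time series; ``kind`` is 'displacement_m' or 'velocity_m_s'."""

    values: np.ndarray
    sample_rate_hz: float
    kind: str = "displacement_m"
    temperature_K: float = 298.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.sample_rate_hz <= 0:
            raise ValueError("sample rate must be positive")
        if self.kind not in ("displacement_m", "velocity_m_s"):
            raise ValueError(f"unknown trace kind {self.kind!r}")
        if self.values.size < 2**12:
            raise ValueError("trace too short for spectral analysis (need >= 4096)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")


@dataclass
class PSDSpectrum:
    """One-sided displacement PSD on an ascending frequency grid (m^2/Hz)."""

    frequencies_hz: np.ndarray
    psd_m2_per_hz: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies_hz = np.asarray(self.frequencies_hz, dtype=float)
        self.psd_m2_per_hz = np.asarray(self.psd_m2_per_hz, dtype=float)
        if self.frequencies_hz.shape != self.psd_m2_per_hz.shape:
            raise ValueError("frequency and PSD arrays must have equal length")
        if np.any(np.diff(self.frequencies_hz) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.psd_m2_per_hz < 0):
            raise ValueError("PSD must be non-negative")


@dataclass
class SHOFitResult:
    F0: float
    m_kg: float
    f0_hz: float
    Q: float
    gamma: float
    Ks: float
    fit_band_hz: tuple[float, float]
    residual: float
    msd_m2: float | None = None
    energy_kBT: float | None = None


@dataclass
class StimulusResponse:
    """Stimulus sweep: sound particle velocity (m/s) vs displacement amplitude
    (m) at the stimulus frequency ``f_eigen_hz``."""

    spv_m_s: np.ndarray
    displacement_m: np.ndarray
    f_eigen_hz: float

    def __post_init__(self) -> None:
        self.spv_m_s = np.asarray(self.spv_m_s, dtype=float)
        self.displacement_m = np.asarray(self.displacement_m, dtype=float)
        if self.spv_m_s.shape != self.displacement_m.shape:
            raise ValueError("SPV and displacement arrays must match")
        if self.spv_m_s.size < 2:
            raise ValueError("need >= 2 stimulus levels")
        if np.any(self.spv_m_s <= 0):
            raise ValueError("SPV values must be positive")
        if np.any(self.displacement_m < 0):
            raise ValueError("displacement amplitudes must be >= 0")


@dataclass
class GainCurve:
    gains: np.ndarray
    gain_max: float
    gain_min: float

    @property
    def sensitivity(self) -> float:
        """gain_max / gain_min: the mechanical amplification figure of merit."""
        return self.gain_max / self.gain_min


@dataclass
class FluctuationEnergy:
    """Fluctuation energy of the receiver in kB T units.

    ``msd_band_m2`` is the trapezoid integral of the measured PSD over the
    analysis band.  ``band_coverage`` is the fraction of the fitted model's
    total variance lying inside that band; dividing by it extrapolates the
    measured band power to the full spectrum (``msd_m2``), from which the
    primary ``energy_kBT`` = Ks * <X^2> / (kB T) is computed.  The raw
    in-band estimate and the fitted-model full integral are kept alongside
    for comparison.
    """

    msd_m2: float
    msd_band_m2: float
    msd_model_m2: float
    band_coverage: float
    stiffness_eff_N_m: float
    energy_kBT: float
    energy_kBT_band: float


# ---------------------------------------------------------------------------


def sho_psd_model(
    f_hz: np.ndarray, F0: float, f0_hz: float, Q: float, m_kg: float
) -> np.ndarray:
    """Displacement PSD of a driven damped harmonic oscillator."""
    w = 2.0 * np.pi * np.asarray(f_hz, dtype=float)
    w0 = 2.0 * np.pi * f0_hz
    denom = m_kg**2 * ((w0**2 - w**2) ** 2 + (w * w0 / Q) ** 2)
    return F0**2 / denom


def displacement_psd(
    trace: MechTrace,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
    resolution_hz: float = 2.0,
) -> PSDSpectrum:
    """Welch one-sided displacement PSD restricted to ``band_hz``.

    Velocity traces are converted to displacement in the spectral domain
    (displacement PSD = velocity PSD / w^2); f = 0 is excluded.  Hann window,
    50% overlap, segment length chosen for <= ``resolution_hz`` resolution
    with at least 8 averaged segments.
    """
    fs = trace.sample_rate_hz
    if band_hz[0] <= 0 and trace.kind == "velocity_m_s":
        raise ValueError("band must start above 0 Hz for velocity traces")
    if band_hz[1] > fs / 2:
        raise ValueError(f"band upper edge {band_hz[1]} Hz exceeds Nyquist {fs/2} Hz")
    nper = int(2 ** np.floor(np.log2(fs / resolution_hz)))
    nper = max(nper, 256)
    # need >= 8 segments at 50% overlap
    if trace.values.size < 4.5 * nper:
        raise ValueError("trace too short for >= 8 averaging segments")
    f, p = signal.welch(
        trace.values, fs=fs, window="hann", nperseg=nper, noverlap=nper // 2
    )
    if trace.kind == "velocity_m_s":
        keep = f > 0
        f, p = f[keep], p[keep]
        p = p / (2.0 * np.pi * f) ** 2
    sel = (f >= band_hz[0]) & (f <= band_hz[1])
    return PSDSpectrum(f[sel], p[sel])


def fit_sho(
    psd: PSDSpectrum,
    m_kg: float = DEFAULT_MASS_KG,
    band_hz: tuple[float, float] | None = None,
) -> SHOFitResult:
    """Least-squares fit of the SHO model to log-PSD over ``band_hz``.

    Initial f0 is the band argmax; initial Q comes from the half-power width.
    Derived quantities: gamma = m w0 / Q and Ks = m w0^2.
    """
    f = psd.frequencies_hz
    p = psd.psd_m2_per_hz
    if band_hz is None:
        band_hz = (float(f[0]), float(f[-1]))
    sel = (f >= band_hz[0]) & (f <= band_hz[1]) & (p > 0)
    f, p = f[sel], p[sel]
    if len(f) < 8:
        raise ValueError("too few PSD points in band")
    i_pk = int(np.argmax(p))
    if i_pk in (0, len(f) - 1):
        raise ValueError("no resonance in band")
    f0_init = f[i_pk]
    half = p[i_pk] / 2.0
    above = p >= half
    width = f[above][-1] - f[above][0]
    df = np.median(np.diff(f))
    Q_init = float(np.clip(f0_init / max(width, df), 0.2, 100.0))
    w0 = 2.0 * np.pi * f0_init
    F0_init = float(np.sqrt(p[i_pk]) * m_kg * w0**2 / Q_init)

    logp = np.log10(p)

    def resid(theta):
        lF0, f0, Q = theta
        model = sho_psd_model(f, 10.0**lF0, f0, Q, m_kg)
        return np.log10(model) - logp

    res = optimize.least_squares(
        resid,
        x0=[np.log10(F0_init), f0_init, Q_init],
        bounds=([-30.0, band_hz[0], 0.05], [0.0, band_hz[1], 1e4]),
        xtol=1e-14,
        ftol=1e-14,
    )
    if not res.success:
        raise RuntimeError(
            f"SHO fit did not converge (residual {np.sqrt(np.mean(res.fun**2)):.3g})"
        )
    F0 = 10.0 ** res.x[0]
    f0 = float(res.x[1])
    Q = float(res.x[2])
    w0 = 2.0 * np.pi * f0
    return SHOFitResult(
        F0=float(F0),
        m_kg=m_kg,
        f0_hz=f0,
        Q=Q,
        gamma=m_kg * w0 / Q,
        Ks=m_kg * w0**2,
        fit_band_hz=(float(band_hz[0]), float(band_hz[1])),
        residual=float(np.sqrt(np.mean(res.fun**2))),
    )


def fluctuation_energy(
    fit: SHOFitResult, psd: PSDSpectrum, temperature_K: float = 298.0
) -> FluctuationEnergy:
    """Fluctuation energy E = Ks <X^2> of the receiver, in kB T units.

    <X^2> is the trapezoid integral of the measured displacement PSD over the
    fit band, extrapolated to the full spectrum by the fitted model's band
    coverage; the effective stiffness is K = kB T / <X^2>, and
    E / kB T = Ks <X^2> / (kB T) = Ks / K.  For a passive receiver at thermal
    equilibrium this is 1 by equipartition.
    """
    lo, hi = fit.fit_band_hz
    f = psd.frequencies_hz
    p = psd.psd_m2_per_hz
    sel = (f >= lo) & (f <= hi)
    if sel.sum() < 2:
        raise ValueError("PSD does not cover the fit band")
    msd_band = float(np.trapezoid(p[sel], f[sel]))
    if msd_band <= 0:
        raise ValueError("zero mean squared displacement in band")
    # model band coverage: fraction of total model variance inside [lo, hi]
    f_full = np.linspace(0.0, 50.0 * fit.f0_hz, 200_001)
    model_full = sho_psd_model(f_full, fit.F0, fit.f0_hz, fit.Q, fit.m_kg)
    total = float(integrate.trapezoid(model_full, f_full))
    in_band = (f_full >= lo) & (f_full <= hi)
    band_model = float(integrate.trapezoid(model_full[in_band], f_full[in_band]))
    coverage = band_model / total
    msd_full = msd_band / coverage
    kT = BOLTZMANN_J_PER_K * temperature_K
    energy = fit.Ks * msd_full / kT
    fit.msd_m2 = msd_band
    fit.energy_kBT = energy
    return FluctuationEnergy(
        msd_m2=msd_full,
        msd_band_m2=msd_band,
        msd_model_m2=total,
        band_coverage=coverage,
        stiffness_eff_N_m=kT / msd_full,
        energy_kBT=energy,
        energy_kBT_band=fit.Ks * msd_band / kT,
    )


def gain_curve(responses: StimulusResponse) -> GainCurve:
    """Per-level mechanical gain = displacement * 2 pi f_eigen / SPV."""
    gains = (
        responses.displacement_m
        * 2.0
        * np.pi
        * responses.f_eigen_hz
        / responses.spv_m_s
    )
    return GainCurve(
        gains=gains, gain_max=float(gains.max()), gain_min=float(gains.min())
    )
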