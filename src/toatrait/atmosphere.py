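"""Lambertian coupling of surface reflectance to top-of-atmosphere reflectance.

Five per-wavelength atmospheric transfer functions — path reflectance,
at-surface total solar irradiance due to scattering, total gas transmittance,
total upwelling scattering transmittance, and spherical albedo — describe the
atmosphere; coupling a bottom-of-atmosphere (BOA) reflectance ``rho`` yields

    rho_TOA = t_g * [ rho_path + T_down * T_up * rho / (1 - S * rho) ]

under the Lambertian, homogeneous-surface assumption, where the geometric
series in ``S * rho`` accounts for multiple surface-atmosphere scattering.

The default transfer functions come from an analytic surrogate atmosphere:
Rayleigh lambda^-4 scattering plus an aerosol term following the Angstrom law
with a Henyey-Greenstein phase function, and gas transmittance as products of
Gaussian absorption windows scaled by the water-vapour and ozone columns.  A
table exported from a full atmospheric RTM (e.g. 6SV) can be loaded instead
via :func:`load_transfer_table`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lut import AtmosphericState, Geometry, Spectrum

__all__ = [
    "TransferFunctions",
    "transfer_functions",
    "couple_toa",
    "uncouple_toa",
    "solar_irradiance",
    "save_transfer_table",
    "load_transfer_table",
]

_TABLE_COLUMNS = ["wavelength_nm", "rho_path", "E_total", "t_g", "T_up", "S"]

_ATM_RANGES = {
    "O3C": (0.25, 0.35), "CWV": (0.4, 4.5), "AOT": (0.0, 0.5),
    "ALPHA": (0.05, 2.0), "G": (0.6, 1.0),
}


def solar_irradiance(grid: np.ndarray) -> np.ndarray:
    """Reference extraterrestrial solar irradiance (W m^-2 nm^-1), smooth.

    A 5778 K Planck shape scaled to ~2.0 W m^-2 nm^-1 near its visible peak;
    used only as the normalization carried inside ``E_total``.
    """
    lam = np.asarray(grid, dtype=float) * 1e-9
    h, c, kb, T = 6.62607015e-34, 2.99792458e8, 1.380649e-23, 5778.0
    B = (2 * h * c**2 / lam**5) / np.expm1(h * c / (lam * kb * T))
    peak = (2 * h * c**2 / (501e-9) ** 5) / np.expm1(h * c / (501e-9 * kb * T))
    return 2.0 * B / peak


@dataclass
class TransferFunctions:
    """The five per-wavelength atmospheric functions plus the solar cosine."""

    wavelengths: np.ndarray
    rho_path: np.ndarray
    E_total: np.ndarray
    t_g: np.ndarray
    T_up: np.ndarray
    S: np.ndarray
    mu_s: float = 1.0

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        for name in ("rho_path", "E_total", "t_g", "T_up", "S"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.wavelengths.shape:
                raise ValueError(f"{name} grid mismatch")
            setattr(self, name, arr)
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength axis must be strictly increasing")
        self.validate()

    def validate(self) -> None:
        if np.any((self.t_g <= 0) | (self.t_g > 1)):
            raise ValueError("t_g must lie in (0, 1]")
        if np.any((self.T_up <= 0) | (self.T_up > 1)):
            raise ValueError("T_up must lie in (0, 1]")
        if np.any((self.S < 0) | (self.S >= 1)):
            raise ValueError("S must lie in [0, 1)")
        if np.any(self.rho_path < 0):
            raise ValueError("rho_path must be non-negative")

    @property
    def T_down(self) -> np.ndarray:
        """Downward scattering transmittance recovered from E_total."""
        return self.E_total / (self.mu_s * solar_irradiance(self.wavelengths))

    @classmethod
    def identity(cls, grid: np.ndarray, mu_s: float = 1.0) -> "TransferFunctions":
        """A fully transparent atmosphere: coupling is the identity map."""
        grid = np.asarray(grid, dtype=float)
        one = np.ones_like(grid)
        return cls(
            wavelengths=grid, rho_path=np.zeros_like(grid),
            E_total=mu_s * solar_irradiance(grid), t_g=one.copy(),
            T_up=one.copy(), S=np.zeros_like(grid), mu_s=mu_s,
        )

    def interp(self, grid: np.ndarray) -> "TransferFunctions":
        """Linear interpolation of all five functions onto a new grid."""
        grid = np.asarray(grid, dtype=float)
        if grid[0] < self.wavelengths[0] or grid[-1] > self.wavelengths[-1]:
            raise ValueError("requested grid extends beyond the tabulated range")
        f = lambda y: np.interp(grid, self.wavelengths, y)
        return TransferFunctions(
            wavelengths=grid, rho_path=f(self.rho_path), E_total=f(self.E_total),
            t_g=f(self.t_g), T_up=f(self.T_up), S=f(self.S), mu_s=self.mu_s,
        )


def rayleigh_optical_depth(grid: np.ndarray) -> np.ndarray:
    """Rayleigh optical depth of a standard atmosphere (Hansen-Travis form)."""
    lam = np.asarray(grid, dtype=float) / 1000.0  # micrometres
    return 0.008569 * lam**-4 * (1.0 + 0.0113 * lam**-2 + 0.00013 * lam**-4)


def aerosol_optical_depth(grid: np.ndarray, aot550: float, alpha: float) -> np.ndarray:
    """Angstrom power law: tau(lambda) = AOT * (lambda / 550)^(-alpha)."""
    return aot550 * (np.asarray(grid, dtype=float) / 550.0) ** (-alpha)


def _gas_absorption(grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    g = np.asarray(grid, dtype=float)
    gauss = lambda c, s: np.exp(-0.5 * ((g - c) / s) ** 2)
    # ozone: Chappuis band, per amt-cm
    k_o3 = 0.10 * gauss(602.0, 70.0) + 0.03 * gauss(510.0, 40.0)
    # water vapour bands, per g cm^-2
    k_wv = (
        0.10 * gauss(940.0, 35.0) + 0.12 * gauss(1130.0, 45.0)
        + 0.45 * gauss(1380.0, 70.0) + 0.55 * gauss(1870.0, 90.0)
        + 0.08 * gauss(2500.0, 150.0) + 0.004
    )
    return k_o3, k_wv


def transfer_functions(atm: AtmosphericState, geom: Geometry,
                       grid: np.ndarray) -> TransferFunctions:
    """Surrogate five-function atmosphere for one atmospheric state.

    Deterministic in its inputs; aerosol optical depth follows the Angstrom
    law, gas transmittance decreases with CWV in the water-absorption windows
    and with O3C in the Chappuis region, and the Henyey-Greenstein asymmetry
    factor modulates the aerosol contribution to path reflectance.
    """
    for key, (lo, hi) in _ATM_RANGES.items():
        v = getattr(atm, key)
        if not (lo <= v <= hi):
            raise ValueError(f"{key}={v} outside supported range [{lo}, {hi}]")
    grid = np.asarray(grid, dtype=float)
    mu_s = float(np.cos(np.deg2rad(geom.theta_s)))
    mu_v = float(np.cos(np.deg2rad(geom.theta_v)))
    tau_r = rayleigh_optical_depth(grid)
    tau_a = aerosol_optical_depth(grid, atm.AOT, atm.ALPHA)

    # scattering angle for sun zenith theta_s, nadir-like view
    cos_theta = -mu_s * mu_v - np.sqrt(max(0.0, 1 - mu_s**2)) * np.sqrt(
        max(0.0, 1 - mu_v**2)) * np.cos(np.deg2rad(geom.phi))
    p_ray = 0.75 * (1.0 + cos_theta**2)
    p_hg = (1.0 - atm.G**2) / (1.0 + atm.G**2 - 2.0 * atm.G * cos_theta) ** 1.5
    omega_a = 0.95  # aerosol single-scattering albedo
    rho_path = (
        p_ray * tau_r * np.exp(-tau_r)
        + omega_a * p_hg * tau_a * np.exp(-tau_a)
    ) / (4.0 * mu_s * mu_v)

    # effective scattering optical depth: aerosols scatter mostly forward
    tau_sc_down = 0.5 * tau_r + 0.2 * tau_a
    T_down = np.exp(-tau_sc_down / mu_s)
    T_up = np.exp(-tau_sc_down / mu_v)
    S = 1.0 - np.exp(-(0.4 * tau_r + 0.25 * (1.0 - atm.G) * tau_a))

    k_o3, k_wv = _gas_absorption(grid)
    t_g = np.exp(-k_o3 * atm.O3C - k_wv * atm.CWV)

    return TransferFunctions(
        wavelengths=grid, rho_path=rho_path,
        E_total=mu_s * solar_irradiance(grid) * T_down,
        t_g=t_g, T_up=T_up, S=S, mu_s=mu_s,
    )


def couple_toa(rho_boa, tf: TransferFunctions):
    """Couple BOA reflectance to TOA reflectance (Lambertian formulation).

    Accepts a :class:`Spectrum` on the transfer-function grid or a bare array
    of matching shape; returns the same kind.
    """
    if isinstance(rho_boa, Spectrum):
        if rho_boa.wavelengths.shape != tf.wavelengths.shape or np.any(
                rho_boa.wavelengths != tf.wavelengths):
            raise ValueError("spectrum and transfer functions on different grids")
        values = rho_boa.values
    else:
        values = np.asarray(rho_boa, dtype=float)
        if values.shape != tf.wavelengths.shape:
            raise ValueError("reflectance and transfer functions on different grids")
    if np.any((values < 0) | (values > 1)):
        raise ValueError("BOA reflectance must lie in [0, 1]")
    if np.any(tf.S * values >= 1.0):
        raise ValueError("non-physical state: S * rho >= 1")
    toa = tf.t_g * (tf.rho_path + tf.T_down * tf.T_up * values / (1.0 - tf.S * values))
    if isinstance(rho_boa, Spectrum):
        return Spectrum(tf.wavelengths, toa)
    return toa


def uncouple_toa(rho_toa, tf: TransferFunctions):
    """Algebraic inverse of :func:`couple_toa` (atmospheric correction)."""
    values = rho_toa.values if isinstance(rho_toa, Spectrum) else np.asarray(rho_toa, dtype=float)
    y = values / tf.t_g - tf.rho_path
    boa = y / (tf.T_down * tf.T_up + tf.S * y)
    if isinstance(rho_toa, Spectrum):
        return Spectrum(tf.wavelengths, boa)
    return boa


def save_transfer_table(tf: TransferFunctions, path) -> None:
    """Write the five functions as delimited text (plus a mu_s header line)."""
    df = pd.DataFrame({
        "wavelength_nm": tf.wavelengths, "rho_path": tf.rho_path,
        "E_total": tf.E_total, "t_g": tf.t_g, "T_up": tf.T_up, "S": tf.S,
    })
    with open(path, "w") as fh:
        fh.write(f"# mu_s={tf.mu_s!r}\n")
        df.to_csv(fh, index=False)


def load_transfer_table(path, grid: np.ndarray | None = None) -> TransferFunctions:
    """Load a five-function table, optionally interpolating onto ``grid``.

    The file is delimited text with columns ``wavelength_nm, rho_path,
    E_total, t_g, T_up, S`` and an optional ``# mu_s=`` comment header.
    Values are validated against the transfer-function invariants.
    """
    mu_s = 1.0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#") and "mu_s=" in first:
            mu_s = float(first.split("mu_s=")[1])
        else:
            fh.seek(0)
        df = pd.read_csv(fh)
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"transfer table missing column(s): {', '.join(missing)}")
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    if np.any(np.diff(wl) <= 0):
        raise ValueError("non-monotone wavelength axis")
    tf = TransferFunctions(
        wavelengths=wl,
        rho_path=df["rho_path"].to_numpy(dtype=float),
        E_total=df["E_total"].to_numpy(dtype=float),
        t_g=df["t_g"].to_numpy(dtype=float),
        T_up=df["T_up"].to_numpy(dtype=float),
        S=df["S"].to_numpy(dtype=float),
        mu_s=mu_s,
    )
    if grid is not None:
        tf = tf.interp(grid)
    return tf
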