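"""Training-data synthesis for top-of-atmosphere trait retrieval.

This module samples the joint leaf/canopy/atmosphere/geometry parameter space,
runs a forward canopy reflectance model, injects instrument-like noise, and
convolves spectra to multispectral sensor bands, producing the look-up-table
(LUT) style training pool that the regression models learn from.

The default forward model is an analytic surrogate: Beer-Lambert leaf
absorption with Gaussian absorption features tied to chlorophyll (visible),
water (SWIR) and dry matter (broad SWIR), mixed toward a brightness-scaled
soil line through an exponential canopy-closure term controlled by LAI and
leaf angle.  It preserves the monotone spectral sensitivities a retrieval
exploits while staying dependency-free; a full radiative-transfer code
(e.g. PROSAIL) can be registered behind the same contract.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "DEFAULT_GRID",
    "TraitSample",
    "AtmosphericState",
    "Geometry",
    "Spectrum",
    "BandSet",
    "TrainingSet",
    "VariableSpec",
    "SamplingConfig",
    "NoiseConfig",
    "NonVegLibrary",
    "default_sampling_config",
    "sentinel2_bands",
    "sample_parameters",
    "forward_canopy",
    "register_forward_model",
    "add_noise",
    "convolve_to_bands",
    "augment_nonvegetated",
    "soil_reference",
    "TRAIT_NAMES",
    "TRAIT_UNITS",
]

#: 1 nm spectral grid covering the support of every default band response.
DEFAULT_GRID = np.arange(400.0, 2501.0, 1.0)

#: Trait label columns carried by every TrainingSet, in canonical order.
TRAIT_NAMES = ["Cab", "Cw", "Cm", "LAI", "FVC", "laiCab", "laiCw", "laiCm"]

TRAIT_UNITS = {
    "Cab": "ug/cm^2",
    "Cw": "cm",
    "Cm": "g/cm^2",
    "LAI": "m^2/m^2",
    "FVC": "fraction",
    "laiCab": "g/m^2",
    "laiCw": "g/m^2",
    "laiCm": "g/m^2",
}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraitSample:
    """One joint draw of leaf and canopy state variables."""

    N: float          # leaf structure parameter (unitless)
    Cab: float        # leaf chlorophyll content (ug/cm^2)
    Cm: float         # leaf dry matter content (g/cm^2)
    Cw: float         # leaf water content (cm EWT)
    LAI: float        # leaf area index (m^2/m^2)
    alpha_soil: float # soil brightness scaling (0-1)
    ALA: float        # average leaf angle (deg)
    HotS: float       # hot spot parameter (m/m)
    skyl: float       # diffuse incoming radiation fraction
    FVC: float        # fractional vegetation cover (derived label)


@dataclass(frozen=True)
class AtmosphericState:
    """One draw of the atmospheric state variables."""

    O3C: float    # ozone column (amt-cm)
    CWV: float    # columnar water vapour (g cm^-2)
    AOT: float    # aerosol optical thickness at 550 nm
    ALPHA: float  # Angstrom coefficient
    G: float      # Henyey-Greenstein asymmetry factor


@dataclass(frozen=True)
class Geometry:
    theta_s: float        # sun zenith (deg)
    theta_v: float = 0.0  # view zenith (deg)
    phi: float = 0.0      # relative azimuth (deg)


@dataclass
class Spectrum:
    """A reflectance spectrum on a strictly increasing wavelength grid."""

    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.shape != self.values.shape:
            raise ValueError("wavelengths and values must have the same shape")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) < 2:
            raise ValueError("spectrum requires a 1-D grid with >= 2 points")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")


# ---------------------------------------------------------------------------
# Sampling configuration
# ---------------------------------------------------------------------------

_DISTRIBUTIONS = ("uniform", "gaussian", "lhs", "fixed")


@dataclass(frozen=True)
class VariableSpec:
    """Range and sampling distribution of one input variable.

    ``dist`` is one of ``uniform`` (flat over [low, high]), ``gaussian``
    (normal truncated to [low, high] by resampling, never clipping),
    ``lhs`` (Latin hypercube: one draw per equal-width stratum) or
    ``fixed`` (constant ``value``).
    """

    dist: str
    low: float | None = None
    high: float | None = None
    mean: float | None = None
    sd: float | None = None
    value: float | None = None

    def __post_init__(self) -> None:
        if self.dist not in _DISTRIBUTIONS:
            raise ValueError(f"unknown distribution tag {self.dist!r}")
        if self.dist == "fixed":
            if self.value is None:
                raise ValueError("fixed variable requires a value")
        else:
            if self.low is None or self.high is None:
                raise ValueError(f"{self.dist} variable requires low/high bounds")
            if self.low >= self.high:
                raise ValueError(f"range with min >= max ({self.low} >= {self.high})")
            if self.dist == "gaussian" and (self.mean is None or self.sd is None):
                raise ValueError("gaussian variable requires mean and sd")


class SamplingConfig(dict):
    """Mapping of variable name -> :class:`VariableSpec` with YAML round-trip."""

    def to_yaml(self) -> str:
        doc = {}
        for name, spec in self.items():
            doc[name] = {k: v for k, v in asdict(spec).items() if v is not None}
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SamplingConfig":
        doc = yaml.safe_load(text)
        return cls({name: VariableSpec(**entry) for name, entry in doc.items()})

    @classmethod
    def from_file(cls, path) -> "SamplingConfig":
        with open(path) as fh:
            return cls.from_yaml(fh.read())


def default_sampling_config() -> SamplingConfig:
    """Default joint parameter space for TOA training-database generation.

    Leaf and canopy variables follow common crop-trait retrieval practice
    (chlorophyll, water and dry matter as truncated Gaussians, structure and
    soil brightness uniform); the atmospheric state is Latin-hypercube sampled
    over globally plausible ranges; the sun is near-nadir summer acquisition
    geometry with nadir view.
    """
    return SamplingConfig(
        {
            # leaf
            "N": VariableSpec("uniform", 1.3, 2.5),
            "Cab": VariableSpec("gaussian", 5.0, 75.0, mean=35.0, sd=30.0),
            "Cm": VariableSpec("gaussian", 0.001, 0.03, mean=0.005, sd=0.001),
            "Cw": VariableSpec("gaussian", 0.002, 0.05, mean=0.02, sd=0.01),
            # canopy
            "LAI": VariableSpec("gaussian", 0.1, 7.0, mean=3.0, sd=2.0),
            "alpha_soil": VariableSpec("uniform", 0.0, 1.0),
            "ALA": VariableSpec("uniform", 40.0, 70.0),
            "HotS": VariableSpec("fixed", value=0.01),
            "skyl": VariableSpec("fixed", value=0.05),
            # atmosphere
            "O3C": VariableSpec("lhs", 0.25, 0.35),
            "CWV": VariableSpec("lhs", 0.4, 4.5),
            "AOT": VariableSpec("lhs", 0.05, 0.5),
            "ALPHA": VariableSpec("lhs", 0.05, 2.0),
            "G": VariableSpec("lhs", 0.6, 1.0),
            # geometry
            "theta_s": VariableSpec("uniform", 20.0, 30.0),
            "theta_v": VariableSpec("fixed", value=0.0),
            "phi": VariableSpec("fixed", value=0.0),
        }
    )


def _draw(spec: VariableSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    if spec.dist == "fixed":
        return np.full(n, float(spec.value))
    if spec.dist == "uniform":
        return rng.uniform(spec.low, spec.high, n)
    if spec.dist == "gaussian":
        a = (spec.low - spec.mean) / spec.sd
        b = (spec.high - spec.mean) / spec.sd
        return stats.truncnorm.rvs(a, b, loc=spec.mean, scale=spec.sd,
                                   size=n, random_state=rng)
    if spec.dist == "lhs":
        edges = np.linspace(spec.low, spec.high, n + 1)
        vals = edges[:-1] + rng.uniform(0.0, 1.0, n) * np.diff(edges)
        return rng.permutation(vals)
    raise ValueError(f"unknown distribution tag {spec.dist!r}")  # pragma: no cover


def canopy_extinction(ala_deg: float | np.ndarray) -> float | np.ndarray:
    """Nadir extinction coefficient as a function of average leaf angle.

    More erectophile canopies (larger ALA) intercept less light per unit LAI.
    """
    return 0.4 + 0.5 * np.cos(np.deg2rad(ala_deg))


def derive_fvc(lai, ala_deg, low: float = 0.05, high: float = 1.0):
    """Fractional vegetation cover label from gap-fraction theory.

    FVC = 1 - exp(-k(ALA) * LAI), clipped to the configured [0.05, 1] range.
    """
    fvc = 1.0 - np.exp(-canopy_extinction(ala_deg) * np.asarray(lai, dtype=float))
    return np.clip(fvc, low, high)


def sample_parameters(
    config: SamplingConfig, n: int, seed: int
) -> list[tuple[TraitSample, AtmosphericState, Geometry]]:
    """Draw ``n`` joint (traits, atmosphere, geometry) states from ``config``.

    Gaussian variables are truncated to their range by resampling (scipy's
    truncated normal), Latin-hypercube variables place exactly one draw in
    each of ``n`` equal-width strata, and fixed variables are constant.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    cols = {name: _draw(spec, n, rng) for name, spec in config.items()}
    fvc = derive_fvc(cols["LAI"], cols["ALA"])
    out = []
    for i in range(n):
        trait = TraitSample(
            N=cols["N"][i], Cab=cols["Cab"][i], Cm=cols["Cm"][i], Cw=cols["Cw"][i],
            LAI=cols["LAI"][i], alpha_soil=cols["alpha_soil"][i], ALA=cols["ALA"][i],
            HotS=cols["HotS"][i], skyl=cols["skyl"][i], FVC=float(fvc[i]),
        )
        atm = AtmosphericState(
            O3C=cols["O3C"][i], CWV=cols["CWV"][i], AOT=cols["AOT"][i],
            ALPHA=cols["ALPHA"][i], G=cols["G"][i],
        )
        geom = Geometry(
            theta_s=cols["theta_s"][i], theta_v=cols["theta_v"][i], phi=cols["phi"][i]
        )
        out.append((trait, atm, geom))
    return out


# ---------------------------------------------------------------------------
# Surrogate forward canopy model
# ---------------------------------------------------------------------------

def _gauss(grid: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((grid - center) / sigma) ** 2)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def soil_reference(grid: np.ndarray) -> np.ndarray:
    """Reference bare-soil reflectance: a smooth line brightening with wavelength."""
    grid = np.asarray(grid, dtype=float)
    return 0.12 + 0.28 * (1.0 - np.exp(-(grid - 400.0) / 1000.0))


def _leaf_reflectance(sample: TraitSample, grid: np.ndarray) -> np.ndarray:
    # green-leaf baseline: low visible, red-edge rise, NIR plateau, SWIR roll-off
    base = 0.05 + 0.45 * _logistic((grid - 718.0) / 20.0) * (
        0.55 + 0.45 * _logistic(-(grid - 1550.0) / 250.0)
    )
    # Beer-Lambert absorption features (optical depth per unit content)
    k_cab = 0.028 * (_gauss(grid, 665.0, 55.0) + 0.55 * _gauss(grid, 490.0, 35.0))
    k_w = (
        30.0 * _gauss(grid, 1450.0, 90.0)
        + 55.0 * _gauss(grid, 1940.0, 110.0)
        + 10.0 * _gauss(grid, 1200.0, 50.0)
        + 6.0 * _gauss(grid, 970.0, 40.0)
        + 12.0 * _logistic((grid - 1300.0) / 250.0)
    )
    k_m = 35.0 * _logistic((grid - 1350.0) / 300.0) + 8.0
    tau = k_cab * sample.Cab + k_w * sample.Cw + k_m * sample.Cm
    # leaf structure: more layers -> more scattering -> brighter leaf
    # (plate-model NIR sensitivity is modest, ~10% over the N range)
    scatter = 0.75 + 0.18 * (sample.N - 1.0) / 1.5
    return scatter * base * np.exp(-tau)


def _surrogate_forward(sample: TraitSample, geometry: Geometry,
                       grid: np.ndarray) -> np.ndarray:
    mu_s = np.cos(np.deg2rad(geometry.theta_s))
    k = canopy_extinction(sample.ALA)
    closure = 1.0 - np.exp(-k * sample.LAI / mu_s)
    leaf = _leaf_reflectance(sample, grid)
    # hot-spot brightening and diffuse-light darkening are small scalar factors
    leaf = leaf * (1.0 + 0.5 * sample.HotS) * (1.0 - 0.1 * sample.skyl)
    # multiple scattering between leaf layers brightens the canopy where the
    # leaf is weakly absorbing (NIR plateau), giving LAI a spectral signature
    # distinct from mere canopy closure
    nir = _logistic((grid - 745.0) / 25.0) * _logistic(-(grid - 1350.0) / 150.0)
    leaf = leaf * (1.0 + 0.3 * nir * (1.0 - np.exp(-0.35 * sample.LAI)))
    soil = sample.alpha_soil * soil_reference(grid)
    return np.clip(closure * leaf + (1.0 - closure) * soil, 0.0, 1.0)


_VALIDITY = {
    "N": (0.5, 4.0), "Cab": (0.0, 120.0), "Cm": (0.0, 0.1), "Cw": (0.0, 0.2),
    "LAI": (0.0, 12.0), "alpha_soil": (0.0, 1.0), "ALA": (0.0, 90.0),
}

_FORWARD_MODELS: dict[str, object] = {"surrogate": _surrogate_forward}


def register_forward_model(name: str, fn) -> None:
    """Register an alternative forward canopy model.

    ``fn(sample, geometry, grid) -> reflectance array`` must be deterministic;
    an external PROSAIL-style implementation plugs in here.
    """
    _FORWARD_MODELS[name] = fn


def forward_canopy(sample: TraitSample, geometry: Geometry,
                   grid: np.ndarray = DEFAULT_GRID,
                   model: str = "surrogate") -> Spectrum:
    """Bottom-of-atmosphere canopy reflectance for one joint state.

    With ``LAI = 0`` the canopy term vanishes and the output is exactly the
    ``alpha_soil``-scaled bare-soil reference.
    """
    for key, (lo, hi) in _VALIDITY.items():
        v = getattr(sample, key)
        if not (lo <= v <= hi):
            raise ValueError(f"{key}={v} outside model validity range [{lo}, {hi}]")
    fn = _FORWARD_MODELS[model]
    return Spectrum(np.asarray(grid, dtype=float), fn(sample, geometry, np.asarray(grid, dtype=float)))


# ---------------------------------------------------------------------------
# Noise injection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseConfig:
    """Zero-mean Gaussian perturbation of reflectance spectra.

    ``additive_sd`` is in reflectance units; ``multiplicative_sd`` is a
    relative fraction.  Both default to the common hybrid-workflow practice of
    a small additive term.
    """

    additive_sd: float = 0.01
    multiplicative_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.additive_sd < 0 or self.multiplicative_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")


def add_noise(spectra: list[Spectrum], noise: NoiseConfig, seed: int) -> list[Spectrum]:
    """Perturb each spectrum independently per wavelength; clip to [0, 1]."""
    rng = np.random.default_rng(seed)
    out = []
    for sp in spectra:
        v = sp.values.copy()
        if noise.multiplicative_sd > 0:
            v = v * (1.0 + noise.multiplicative_sd * rng.standard_normal(v.shape))
        if noise.additive_sd > 0:
            v = v + noise.additive_sd * rng.standard_normal(v.shape)
        if noise.additive_sd > 0 or noise.multiplicative_sd > 0:
            v = np.clip(v, 0.0, 1.0)
        out.append(Spectrum(sp.wavelengths, v))
    return out


# ---------------------------------------------------------------------------
# Band sets and convolution
# ---------------------------------------------------------------------------

@dataclass
class BandSet:
    """Sensor band definitions with Gaussian or tabulated spectral responses."""

    ids: list[str]
    centers: np.ndarray
    fwhm: np.ndarray | None = None
    srf_grid: np.ndarray | None = None     # tabulated responses (optional)
    srf_values: np.ndarray | None = None   # (n_bands, len(srf_grid))

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if self.fwhm is not None:
            self.fwhm = np.asarray(self.fwhm, dtype=float)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def names(self) -> list[str]:
        return [f"{bid}_{int(round(c))}" for bid, c in zip(self.ids, self.centers)]

    def responses(self, grid: np.ndarray) -> np.ndarray:
        """Response weights on ``grid``, each row normalized to unit sum.

        Raises if a band's support falls outside the grid.
        """
        grid = np.asarray(grid, dtype=float)
        n = len(self)
        resp = np.zeros((n, grid.size))
        for b in range(n):
            if self.srf_values is not None:
                support = self.srf_grid[self.srf_values[b] > 1e-8]
                lo, hi = support.min(), support.max()
                r = np.interp(grid, self.srf_grid, self.srf_values[b], left=0.0, right=0.0)
            else:
                sigma = self.fwhm[b] / (2.0 * np.sqrt(2.0 * np.log(2.0)))
                lo = self.centers[b] - 3.0 * sigma
                hi = self.centers[b] + 3.0 * sigma
                r = np.exp(-0.5 * ((grid - self.centers[b]) / sigma) ** 2)
                r[(grid < lo) | (grid > hi)] = 0.0
            if lo < grid[0] or hi > grid[-1]:
                raise ValueError(
                    f"band {self.ids[b]} support [{lo:.0f}, {hi:.0f}] nm outside "
                    f"spectrum grid [{grid[0]:.0f}, {grid[-1]:.0f}] nm"
                )
            total = r.sum()
            if total <= 0:
                raise ValueError(f"band {self.ids[b]} has empty response on the grid")
            resp[b] = r / total
        return resp

    @classmethod
    def from_srf_table(cls, path) -> "BandSet":
        """Load tabulated spectral response functions.

        Delimited text with a ``wavelength_nm`` column and one response column
        per band; band centers are the response-weighted mean wavelengths.
        """
        df = pd.read_csv(path)
        if "wavelength_nm" not in df.columns:
            raise ValueError("SRF table must have a wavelength_nm column")
        grid = df["wavelength_nm"].to_numpy(dtype=float)
        ids = [c for c in df.columns if c != "wavelength_nm"]
        vals = df[ids].to_numpy(dtype=float).T
        if np.any(vals < 0):
            raise ValueError("spectral responses must be non-negative")
        centers = (vals * grid).sum(axis=1) / vals.sum(axis=1)
        return cls(ids=ids, centers=centers, srf_grid=grid, srf_values=vals)


def sentinel2_bands() -> BandSet:
    """The ten Sentinel-2 MSI bands used for trait retrieval (VNIR to SWIR).

    Centers 493...2190 nm; Gaussian responses with the published bandwidths
    (a user-supplied SRF table overrides via :meth:`BandSet.from_srf_table`).
    """
    return BandSet(
        ids=["B2", "B3", "B4", "B5", "B6", "B7", "B8", "B8A", "B11", "B12"],
        centers=[493.0, 560.0, 665.0, 704.0, 740.0, 783.0, 833.0, 865.0, 1610.0, 2190.0],
        fwhm=[66.0, 36.0, 31.0, 15.0, 15.0, 20.0, 106.0, 21.0, 91.0, 175.0],
    )


def convolve_to_bands(spectrum: Spectrum, bands: BandSet) -> np.ndarray:
    """Response-weighted mean reflectance per band."""
    return bands.responses(spectrum.wavelengths) @ spectrum.values


# ---------------------------------------------------------------------------
# Training sets
# ---------------------------------------------------------------------------

PROV_SIMULATED = "simulated"
PROV_NONVEG = "non_vegetated"


@dataclass
class TrainingSet:
    """Paired band reflectances and trait labels with per-row provenance."""

    X: np.ndarray               # (n, D) band reflectances
    traits: pd.DataFrame        # (n, n_traits) labels
    provenance: np.ndarray      # (n,) of {"simulated", "non_vegetated"}
    band_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.provenance = np.asarray(self.provenance, dtype=object)
        if self.X.shape[0] != len(self.traits) or self.X.shape[0] != len(self.provenance):
            raise ValueError("X, traits and provenance row counts disagree")
        if self.X.ndim != 2 or self.X.shape[1] != len(self.band_names):
            raise ValueError("X column count must match band_names")
        nv = self.provenance == PROV_NONVEG
        if nv.any() and not np.all(self.traits.to_numpy()[nv] == 0.0):
            raise ValueError("non-vegetated rows must carry all-zero trait labels")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def trait_names(self) -> list[str]:
        return list(self.traits.columns)

    def subset(self, idx) -> "TrainingSet":
        idx = np.asarray(idx)
        return TrainingSet(
            X=self.X[idx],
            traits=self.traits.iloc[idx].reset_index(drop=True),
            provenance=self.provenance[idx],
            band_names=list(self.band_names),
        )

    def to_frame(self) -> pd.DataFrame:
        df = self.traits.copy()
        for j, name in enumerate(self.band_names):
            df[name] = self.X[:, j]
        df["provenance"] = self.provenance
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, band_names: list[str] | None = None) -> "TrainingSet":
        df = pd.read_csv(path)
        if "provenance" not in df.columns:
            raise ValueError("training-set file must have a provenance column")
        if band_names is None:
            band_names = [c for c in df.columns if c.split("_")[0].startswith("B")
                          and c != "provenance"]
        trait_cols = [c for c in df.columns if c not in band_names and c != "provenance"]
        return cls(
            X=df[band_names].to_numpy(dtype=float),
            traits=df[trait_cols].astype(float).reset_index(drop=True),
            provenance=df["provenance"].to_numpy(),
            band_names=band_names,
        )


# ---------------------------------------------------------------------------
# Non-vegetated augmentation
# ---------------------------------------------------------------------------

class NonVegLibrary:
    """Parametric spectra of non-vegetated surfaces (water, soil, man-made).

    Water is dark and blue-skewed, soils follow brightness-scaled soil lines,
    man-made surfaces are bright and spectrally flat.  ``coupler`` optionally
    maps each bottom-of-atmosphere spectrum to top-of-atmosphere before band
    convolution so the augmented rows live at the same level as the LUT.
    """

    CLASSES = ("water", "soil", "man_made")

    def __init__(self, grid: np.ndarray = DEFAULT_GRID,
                 bands: BandSet | None = None, coupler=None):
        self.grid = np.asarray(grid, dtype=float)
        self.bands = bands if bands is not None else sentinel2_bands()
        self.coupler = coupler

    def _spectrum(self, cls: str, rng: np.random.Generator) -> np.ndarray:
        g = self.grid
        if cls == "water":
            amp = rng.uniform(0.02, 0.08)
            v = amp * np.exp(-(g - 400.0) / rng.uniform(200.0, 400.0)) + 0.002
        elif cls == "soil":
            v = rng.uniform(0.3, 1.2) * soil_reference(g)
            v = v * (1.0 + rng.uniform(-0.1, 0.1) * (g - 1400.0) / 1000.0)
        else:  # man_made
            v = np.full_like(g, rng.uniform(0.2, 0.6))
            v = v * (1.0 + rng.uniform(-0.05, 0.05) * (g - 1400.0) / 1000.0)
        return np.clip(v, 0.0, 1.0)

    def sample_bands(self, n: int, seed: int) -> np.ndarray:
        """Band reflectance vectors for ``n`` random non-vegetated surfaces."""
        if n < 0:
            raise ValueError("n must be non-negative")
        rng = np.random.default_rng(seed)
        resp = self.bands.responses(self.grid)
        rows = np.empty((n, len(self.bands)))
        for i in range(n):
            cls = self.CLASSES[rng.integers(len(self.CLASSES))]
            v = self._spectrum(cls, rng)
            if self.coupler is not None:
                v = np.clip(self.coupler(Spectrum(self.grid, v), rng).values, 0.0, 1.0)
            rows[i] = resp @ v
        return rows


def augment_nonvegetated(tset: TrainingSet, n: int, library: NonVegLibrary,
                         seed: int) -> TrainingSet:
    """Append ``n`` non-vegetated rows with all trait labels set to zero."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if library is None:
        raise ValueError("empty library")
    if n == 0:
        return tset
    Xnew = library.sample_bands(n, seed)
    zeros = pd.DataFrame(0.0, index=range(n), columns=tset.traits.columns)
    return TrainingSet(
        X=np.vstack([tset.X, Xnew]),
        traits=pd.concat([tset.traits, zeros], ignore_index=True),
        provenance=np.concatenate([tset.provenance, np.full(n, PROV_NONVEG, dtype=object)]),
        band_names=list(tset.band_names),
    )
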