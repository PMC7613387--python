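"""Synthetic field campaigns and scenes for end-to-end testing without downloads.

:func:`synth_field_campaign` emulates a temperate-cropland validation
campaign: per plot it draws leaf/canopy traits from truncated Gaussians whose
defaults mirror a wheat/corn field dataset (e.g. LAI over 0.2-3.9 with mean
2.9 and SD 1.2), pushes one joint state through the forward chain (canopy
model -> atmospheric coupling -> band convolution) and perturbs the resulting
top-of-atmosphere band reflectances with measurement noise.  The paired truth
and validation tables drive active learning and validation exactly like an
in situ campaign table would.

:func:`synth_scene` builds a small multi-band raster of rectangular crop
fields, a non-vegetated river strip, and bare-soil background, together with
co-registered per-trait truth rasters and a validity mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .atmosphere import couple_toa, transfer_functions
from .evaluation import upscale_to_canopy
from .lut import (
    DEFAULT_GRID,
    TRAIT_NAMES,
    AtmosphericState,
    BandSet,
    Geometry,
    NonVegLibrary,
    SamplingConfig,
    Spectrum,
    TraitSample,
    default_sampling_config,
    derive_fvc,
    forward_canopy,
    sentinel2_bands,
)
from .rasters import GridMeta, Raster
from scipy import stats

__all__ = [
    "TraitStats",
    "CampaignConfig",
    "FieldSpec",
    "SceneSpec",
    "synth_field_campaign",
    "synth_scene",
    "default_campaign_config",
]


@dataclass(frozen=True)
class TraitStats:
    """Target range, mean and SD of one measured trait."""

    low: float
    high: float
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not (self.low <= self.mean <= self.high):
            raise ValueError("range must contain the mean")
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        # a mean many SDs outside the usable range makes truncation infeasible
        if self.mean - 6 * self.sd > self.high or self.mean + 6 * self.sd < self.low:
            raise ValueError("infeasible truncation: mean too far outside range")


@dataclass(frozen=True)
class CampaignConfig:
    """Synthetic validation-campaign settings.

    Defaults mirror the scale of a two-crop field campaign: 52 plots
    (26 per crop) with trait statistics typical of winter wheat and corn.
    """

    traits: dict = dc_field(default_factory=lambda: {
        "Cab": TraitStats(38.5, 60.8, 52.8, 6.0),
        "Cw": TraitStats(0.012, 0.025, 0.019, 0.003),
        "Cm": TraitStats(0.00262, 0.00758, 0.00503, 0.00138),
        "LAI": TraitStats(0.2, 3.9, 2.9, 1.2),
    })
    n_plots: int = 52
    #: additive Gaussian noise on the recorded band reflectances
    measurement_noise_sd: float = 0.005
    #: relative error of the recorded in situ trait values (instrument and
    #: sampling error, e.g. gap-fraction LAI or SPAD-calibrated chlorophyll);
    #: the truth table keeps the exact values
    trait_noise_rel: float = 0.10
    #: SD of the per-crop systematic spectral mismatch (flat multiplicative
    #: bias plus spectral tilt) between the real canopy and the forward model
    #: — the structural error (row effects, clumping, non-leaf organs) that a
    #: radiative-transfer model does not represent and that no amount of
    #: training data can fit
    structural_mismatch: float = 0.05
    #: number of crops the plots are split into (mismatch is drawn per crop)
    n_crops: int = 2
    seed: int = 0


def default_campaign_config(**overrides) -> CampaignConfig:
    return CampaignConfig(**overrides)


def _draw_truncnorm(ts: TraitStats, n: int, rng) -> np.ndarray:
    a = (ts.low - ts.mean) / ts.sd
    b = (ts.high - ts.mean) / ts.sd
    return stats.truncnorm.rvs(a, b, loc=ts.mean, scale=ts.sd, size=n, random_state=rng)


def _nuisance_draw(config: SamplingConfig, rng) -> dict:
    """Per-plot nuisance variables (structure, soil, leaf angle, atmosphere)."""
    from .lut import sample_parameters

    trait, atm, geom = sample_parameters(config, 1, int(rng.integers(2**31)))[0]
    return {"trait": trait, "atm": atm, "geom": geom}


def _forward_bands(trait: TraitSample, atm: AtmosphericState, geom: Geometry,
                   grid: np.ndarray, resp: np.ndarray,
                   mismatch: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    boa = forward_canopy(trait, geom, grid)
    a, b = mismatch
    if a != 0.0 or b != 0.0:
        values = np.clip(boa.values * (1.0 + a + b * (grid - 1400.0) / 1000.0), 0.0, 1.0)
        boa = Spectrum(boa.wavelengths, values)
    toa = couple_toa(boa, transfer_functions(atm, geom, grid))
    return resp @ toa.values


def synth_field_campaign(
    cfg: CampaignConfig | None = None,
    sampling_config: SamplingConfig | None = None,
    bands: BandSet | None = None,
    grid: np.ndarray = DEFAULT_GRID,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate paired (truth, validation) tables for one synthetic campaign.

    The truth table holds the drawn trait values per plot; the validation
    table repeats them alongside the simulated top-of-atmosphere band
    reflectances perturbed by measurement noise — the format the active-
    learning loop consumes.
    """
    if cfg is None:
        cfg = CampaignConfig()
    if sampling_config is None:
        sampling_config = default_sampling_config()
    if bands is None:
        bands = sentinel2_bands()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_plots
    draws = {name: _draw_truncnorm(ts, n, rng) for name, ts in cfg.traits.items()}
    resp = bands.responses(grid)
    # one systematic spectral mismatch per crop; plots alternate crops
    crop_mismatch = [
        (cfg.structural_mismatch * rng.standard_normal(),
         cfg.structural_mismatch * rng.standard_normal())
        for _ in range(max(1, cfg.n_crops))
    ]

    rows = []
    X = np.empty((n, len(bands)))
    for i in range(n):
        nuis = _nuisance_draw(sampling_config, rng)
        base = nuis["trait"]
        lai = float(draws["LAI"][i])
        trait = TraitSample(
            N=base.N, Cab=float(draws["Cab"][i]), Cm=float(draws["Cm"][i]),
            Cw=float(draws["Cw"][i]), LAI=lai, alpha_soil=base.alpha_soil,
            ALA=base.ALA, HotS=base.HotS, skyl=base.skyl,
            FVC=float(derive_fvc(lai, base.ALA)),
        )
        X[i] = _forward_bands(trait, nuis["atm"], nuis["geom"], grid, resp,
                              mismatch=crop_mismatch[i % len(crop_mismatch)])
        rows.append({
            "plot": i,
            "crop": i % len(crop_mismatch),
            "Cab": trait.Cab, "Cw": trait.Cw, "Cm": trait.Cm,
            "LAI": trait.LAI, "FVC": trait.FVC,
            "laiCab": upscale_to_canopy(trait.Cab, trait.LAI, "Cab"),
            "laiCw": upscale_to_canopy(trait.Cw, trait.LAI, "Cw"),
            "laiCm": upscale_to_canopy(trait.Cm, trait.LAI, "Cm"),
        })
    if cfg.measurement_noise_sd > 0:
        X = np.clip(X + cfg.measurement_noise_sd * rng.standard_normal(X.shape), 0.0, 1.0)
    truth = pd.DataFrame(rows, columns=["plot", "crop"] + TRAIT_NAMES)
    validation = truth.copy()
    if cfg.trait_noise_rel > 0:
        # in situ records carry instrument/sampling error; canopy products are
        # recomputed from the erroneous leaf values, as in a real campaign
        for name in ("Cab", "Cw", "Cm", "LAI", "FVC"):
            err = 1.0 + cfg.trait_noise_rel * rng.standard_normal(n)
            validation[name] = np.maximum(validation[name] * err, 0.0)
        validation["laiCab"] = upscale_to_canopy(
            validation["Cab"].to_numpy(), validation["LAI"].to_numpy(), "Cab")
        validation["laiCw"] = upscale_to_canopy(
            validation["Cw"].to_numpy(), validation["LAI"].to_numpy(), "Cw")
        validation["laiCm"] = upscale_to_canopy(
            validation["Cm"].to_numpy(), validation["LAI"].to_numpy(), "Cm")
    for j, name in enumerate(bands.names):
        validation[name] = X[:, j]
    return truth, validation


# ---------------------------------------------------------------------------
# Synthetic scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FieldSpec:
    """A rectangular field: half-open pixel box [row0:row1, col0:col1]."""

    row0: int
    row1: int
    col0: int
    col1: int
    traits: dict  # Cab, Cw, Cm, LAI at least


@dataclass
class SceneSpec:
    """Layout of a small synthetic scene.

    ``river_cols`` marks a vertical non-vegetated water strip; all pixels not
    covered by a field or the river are bare soil.  Truth traits are zero for
    non-vegetated classes.
    """

    shape: tuple = (32, 32)
    fields: list = dc_field(default_factory=list)
    river_cols: tuple | None = (14, 17)
    #: one atmospheric state for the whole scene (one acquisition);
    #: None draws a random state from the sampling config
    atmosphere: AtmosphericState | None = None
    noise_sd: float = 0.0
    seed: int = 0
    scale_to_int: bool = False  # write as 1e4-scaled integers (L1C convention)

    @staticmethod
    def random(n_fields: int = 6, shape: tuple = (32, 32), seed: int = 0,
               noise_sd: float = 0.0) -> "SceneSpec":
        """A random non-overlapping field layout with campaign-like traits."""
        rng = np.random.default_rng(seed)
        cfg = CampaignConfig()
        rows, cols = shape
        fields = []
        occupied = np.zeros(shape, dtype=bool)
        attempts = 0
        while len(fields) < n_fields and attempts < 100:
            attempts += 1
            h = int(rng.integers(6, max(7, rows // 2)))
            w = int(rng.integers(6, max(7, cols // 3)))
            r0 = int(rng.integers(0, rows - h))
            c0 = int(rng.integers(0, cols - w))
            box = (slice(r0, r0 + h), slice(c0, c0 + w))
            if occupied[box].any():
                continue
            occupied[box] = True
            traits = {name: float(_draw_truncnorm(ts, 1, rng)[0])
                      for name, ts in cfg.traits.items()}
            fields.append(FieldSpec(r0, r0 + h, c0, c0 + w, traits))
        return SceneSpec(shape=shape, fields=fields, noise_sd=noise_sd, seed=seed)


def synth_scene(
    spec: SceneSpec,
    sampling_config: SamplingConfig | None = None,
    bands: BandSet | None = None,
    grid: np.ndarray = DEFAULT_GRID,
) -> tuple[Raster, dict, np.ndarray]:
    """Simulate a 10-band scene with per-trait truth rasters and validity mask.

    Returns ``(scene, truth, mask)`` where ``truth`` maps trait name to a
    co-registered array (zero over non-vegetated pixels) and ``mask`` is all
    True (a caller can degrade it to emulate clouds).
    """
    if sampling_config is None:
        sampling_config = default_sampling_config()
    if bands is None:
        bands = sentinel2_bands()
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.shape
    resp = bands.responses(grid)
    meta = GridMeta(transform=(20.0, 0.0, 0.0, 0.0, -20.0, 0.0), crs="EPSG:32632")

    claimed = np.zeros(spec.shape, dtype=bool)
    data = np.zeros((len(bands), rows, cols))
    truth = {name: np.zeros(spec.shape) for name in TRAIT_NAMES}

    library = NonVegLibrary(grid=grid, bands=bands)

    # one acquisition: a single atmosphere and geometry scene-wide
    scene_nuis = _nuisance_draw(sampling_config, rng)
    atm = spec.atmosphere if spec.atmosphere is not None else scene_nuis["atm"]
    geom = scene_nuis["geom"]

    # background: bare soil at zero trait values
    soil_trait = TraitSample(N=1.5, Cab=0.0, Cm=0.0, Cw=0.0, LAI=0.0,
                             alpha_soil=scene_nuis["trait"].alpha_soil,
                             ALA=55.0, HotS=0.01, skyl=0.05, FVC=0.0)
    soil_bands = _forward_bands(soil_trait, atm, geom, grid, resp)
    data[:] = soil_bands[:, None, None]

    for f in spec.fields:
        box = (slice(f.row0, f.row1), slice(f.col0, f.col1))
        if claimed[box].any():
            raise ValueError("overlapping field polygons")
        claimed[box] = True
        base = _nuisance_draw(sampling_config, rng)["trait"]
        lai = float(f.traits["LAI"])
        trait = TraitSample(
            N=base.N, Cab=float(f.traits["Cab"]), Cm=float(f.traits["Cm"]),
            Cw=float(f.traits["Cw"]), LAI=lai, alpha_soil=base.alpha_soil,
            ALA=base.ALA, HotS=base.HotS, skyl=base.skyl,
            FVC=float(derive_fvc(lai, base.ALA)),
        )
        data[:, box[0], box[1]] = _forward_bands(
            trait, atm, geom, grid, resp)[:, None, None]
        truth["Cab"][box] = trait.Cab
        truth["Cw"][box] = trait.Cw
        truth["Cm"][box] = trait.Cm
        truth["LAI"][box] = trait.LAI
        truth["FVC"][box] = trait.FVC
        truth["laiCab"][box] = upscale_to_canopy(trait.Cab, lai, "Cab")
        truth["laiCw"][box] = upscale_to_canopy(trait.Cw, lai, "Cw")
        truth["laiCm"][box] = upscale_to_canopy(trait.Cm, lai, "Cm")

    if spec.river_cols is not None:
        c0, c1 = spec.river_cols
        water = library._spectrum("water", rng)
        data[:, :, c0:c1] = (resp @ water)[:, None, None]
        for name in TRAIT_NAMES:
            truth[name][:, c0:c1] = 0.0

    if spec.noise_sd > 0:
        data = np.clip(data + spec.noise_sd * rng.standard_normal(data.shape), 0.0, 1.0)

    if spec.scale_to_int:
        data = np.round(data * 1e4).astype(np.uint16)

    scene = Raster(data=data, meta=meta, band_names=bands.names)
    mask = np.ones(spec.shape, dtype=bool)
    return scene, truth, mask
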