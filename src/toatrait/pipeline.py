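"""End-to-end training-database construction.

Chains sampling -> forward canopy model -> noise injection -> Lambertian
TOA coupling -> band convolution -> non-vegetated augmentation into one
call.  Noise is injected on the bottom-of-atmosphere spectra just before
atmospheric coupling; band convolution happens after coupling, on the 1 nm
grid, mimicking sensor integration of the through-atmosphere signal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .atmosphere import couple_toa, transfer_functions
from .evaluation import upscale_to_canopy
from .lut import (
    DEFAULT_GRID,
    TRAIT_NAMES,
    BandSet,
    Geometry,
    NoiseConfig,
    NonVegLibrary,
    SamplingConfig,
    Spectrum,
    TrainingSet,
    add_noise,
    augment_nonvegetated,
    convolve_to_bands,
    default_sampling_config,
    forward_canopy,
    sample_parameters,
    sentinel2_bands,
)

__all__ = ["build_training_set", "trait_labels", "random_atmosphere_coupler"]


def trait_labels(samples) -> pd.DataFrame:
    """Trait label table (leaf, canopy, and upscaled canopy products) per draw."""
    rows = []
    for trait, _, _ in samples:
        rows.append({
            "Cab": trait.Cab, "Cw": trait.Cw, "Cm": trait.Cm,
            "LAI": trait.LAI, "FVC": trait.FVC,
            "laiCab": upscale_to_canopy(trait.Cab, trait.LAI, "Cab"),
            "laiCw": upscale_to_canopy(trait.Cw, trait.LAI, "Cw"),
            "laiCm": upscale_to_canopy(trait.Cm, trait.LAI, "Cm"),
        })
    return pd.DataFrame(rows, columns=TRAIT_NAMES)


def random_atmosphere_coupler(config: SamplingConfig, grid: np.ndarray):
    """A coupler drawing a fresh atmosphere/geometry per spectrum.

    Returns ``f(spectrum, rng) -> Spectrum`` for non-vegetated augmentation,
    so the appended rows live at top-of-atmosphere like the simulated pool.
    """
    def coupler(spectrum: Spectrum, rng: np.random.Generator) -> Spectrum:
        draws = sample_parameters(config, 1, int(rng.integers(2**31)))
        _, atm, geom = draws[0]
        tf = transfer_functions(atm, geom, grid)
        return couple_toa(spectrum, tf)

    return coupler


def build_training_set(
    config: SamplingConfig | None = None,
    n: int = 1000,
    n_nonveg: int = 40,
    seed: int = 0,
    noise: NoiseConfig = NoiseConfig(),
    bands: BandSet | None = None,
    grid: np.ndarray = DEFAULT_GRID,
    couple: bool = True,
) -> TrainingSet:
    """Build the TOA training pool: ``n`` simulated rows plus ``n_nonveg``
    non-vegetated rows with all-zero trait labels.

    With ``couple=False`` the pool stays at bottom-of-atmosphere (useful for
    surface-reflectance workflows and for testing).
    """
    if config is None:
        config = default_sampling_config()
    if bands is None:
        bands = sentinel2_bands()
    samples = sample_parameters(config, n, seed)
    boa = [forward_canopy(t, g, grid) for t, _, g in samples]
    noisy = add_noise(boa, noise, seed + 1)
    resp = bands.responses(grid)
    X = np.empty((n, len(bands)))
    for i, ((_, atm, geom), sp) in enumerate(zip(samples, noisy)):
        if couple:
            sp = couple_toa(sp, transfer_functions(atm, geom, grid))
        X[i] = resp @ sp.values
    tset = TrainingSet(
        X=X, traits=trait_labels(samples),
        provenance=np.full(n, "simulated", dtype=object),
        band_names=bands.names,
    )
    if n_nonveg > 0:
        library = NonVegLibrary(
            grid=grid, bands=bands,
            coupler=random_atmosphere_coupler(config, grid) if couple else None,
        )
        tset = augment_nonvegetated(tset, n_nonveg, library, seed + 2)
    return tset
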