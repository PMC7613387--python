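"""Per-pixel trait mapping: raster prediction, uncertainty masking, compositing.

Rasters are multi-band TIFF files; the affine transform, CRS string, nodata
value and band names travel in a JSON document stored in the TIFF
ImageDescription tag.  Pixel-center registration, row-major traversal; the
CRS is passed through untouched (no reprojection).

Trait maps carry three bands — predictive mean, SD and the coefficient of
variation CV = 100 * SD / mean — plus a validity mask.  Masking by relative
uncertainty removes pixels whose CV exceeds a threshold (default 30%), and
median compositing collapses a time series of maps into one spatially
continuous map, taking per pixel the median of the valid means (lower
central value for even counts) and the SD of the scene that contributed it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .evaluation import coefficient_of_variation
from .gpr import PortableModel, predict_portable

__all__ = [
    "GridMeta",
    "Raster",
    "PredictionMap",
    "read_raster",
    "write_raster",
    "predict_raster",
    "mask_by_uncertainty",
    "median_composite",
    "write_prediction_map",
    "read_prediction_map",
]

DEFAULT_NODATA = -9999.0


@dataclass(frozen=True)
class GridMeta:
    """Georeferencing shared by all bands of one raster."""

    transform: tuple = (1.0, 0.0, 0.0, 0.0, -1.0, 0.0)  # (a, b, c, d, e, f)
    crs: str = ""
    nodata: float = DEFAULT_NODATA

    def to_json(self) -> dict:
        return {"transform": list(self.transform), "crs": self.crs,
                "nodata": self.nodata}

    @classmethod
    def from_json(cls, doc: dict) -> "GridMeta":
        return cls(transform=tuple(doc.get("transform", (1, 0, 0, 0, -1, 0))),
                   crs=doc.get("crs", ""), nodata=doc.get("nodata", DEFAULT_NODATA))


@dataclass
class Raster:
    """A (bands, rows, cols) array with grid metadata and band names."""

    data: np.ndarray
    meta: GridMeta = field(default_factory=GridMeta)
    band_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError("raster data must be (bands, rows, cols)")
        if self.band_names and len(self.band_names) != self.data.shape[0]:
            raise ValueError("band_names length must match band count")

    @property
    def shape(self) -> tuple:
        return self.data.shape


def write_raster(path, raster: Raster) -> None:
    desc = json.dumps({"grid": raster.meta.to_json(),
                       "band_names": raster.band_names})
    tifffile.imwrite(path, raster.data, description=desc,
                     photometric="minisblack")


def read_raster(path) -> Raster:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    meta, band_names = GridMeta(), []
    if desc:
        try:
            doc = json.loads(desc)
            meta = GridMeta.from_json(doc.get("grid", {}))
            band_names = doc.get("band_names", [])
        except (json.JSONDecodeError, TypeError):
            pass
    return Raster(data=data, meta=meta, band_names=band_names)


@dataclass
class PredictionMap:
    """Co-registered mean / SD / CV rasters and validity mask for one trait."""

    meta: GridMeta
    mean: np.ndarray
    sd: np.ndarray
    valid: np.ndarray
    trait: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.mean.shape == self.sd.shape == self.valid.shape):
            raise ValueError("mean, sd and valid must share one grid")
        nodata = self.meta.nodata
        self.mean = np.where(self.valid, self.mean, nodata)
        self.sd = np.where(self.valid, self.sd, nodata)

    @property
    def cv(self) -> np.ndarray:
        """Relative uncertainty in percent; nodata where invalid."""
        out = np.full(self.mean.shape, self.meta.nodata)
        if self.valid.any():
            out[self.valid] = coefficient_of_variation(
                self.mean[self.valid], self.sd[self.valid])
        return out


def _reflectance(image: np.ndarray, divisor: float | None) -> np.ndarray:
    if np.issubdtype(image.dtype, np.integer):
        div = 1e4 if divisor is None else divisor
        return np.clip(image.astype(float) / div, 0.0, 1.0)
    if divisor is not None:
        return np.clip(image.astype(float) / divisor, 0.0, 1.0)
    return image.astype(float)


def predict_raster(pm: PortableModel, raster: Raster,
                   mask: np.ndarray | None = None,
                   divisor: float | None = None,
                   tile_size: int | None = None) -> PredictionMap:
    """Apply a portable model to every valid pixel of a multi-band raster.

    The band count must match the model; integer imagery is interpreted as
    scaled reflectance (divisor 1e4 by default, the Sentinel-2 L1C
    convention).  ``tile_size`` bounds the number of rows processed per
    block; any tiling yields bit-identical results because the portable
    predictor uses fixed-order reductions.
    """
    D = pm.D
    if raster.data.shape[0] != D:
        raise ValueError(
            f"raster has {raster.data.shape[0]} bands but the model expects {D}")
    bands, rows, cols = raster.data.shape
    refl = _reflectance(raster.data, divisor)
    valid = np.ones((rows, cols), dtype=bool)
    if mask is not None:
        valid &= np.asarray(mask).astype(bool)
    nod = raster.meta.nodata
    if nod is not None:
        valid &= ~np.any(raster.data == nod, axis=0)
    valid &= np.all(np.isfinite(refl), axis=0)

    mean = np.full((rows, cols), np.nan)
    sd = np.full((rows, cols), np.nan)
    step = rows if not tile_size else max(1, int(tile_size))
    for r0 in range(0, rows, step):
        r1 = min(rows, r0 + step)
        sub = valid[r0:r1]
        if not sub.any():
            continue
        X = refl[:, r0:r1, :][:, sub].T  # (npix, D)
        res = predict_portable(pm, X)
        mblock = mean[r0:r1]
        sblock = sd[r0:r1]
        mblock[sub] = res.mean
        sblock[sub] = res.sd
    return PredictionMap(
        meta=raster.meta, mean=np.where(valid, mean, raster.meta.nodata),
        sd=np.where(valid, sd, raster.meta.nodata), valid=valid,
        trait=pm.trait, units=pm.units,
    )


def mask_by_uncertainty(pmap: PredictionMap, threshold: float = 30.0) -> PredictionMap:
    """Mask out pixels with more than ``threshold`` percent relative uncertainty.

    Pixels with CV strictly greater than the threshold (including the
    undefined-CV sentinel at near-zero means) become nodata; all others are
    unchanged.  Idempotent.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    keep = pmap.valid.copy()
    if keep.any():
        cv = coefficient_of_variation(pmap.mean[pmap.valid], pmap.sd[pmap.valid])
        keep[pmap.valid] = cv <= threshold
    return PredictionMap(
        meta=pmap.meta, mean=pmap.mean, sd=pmap.sd, valid=keep,
        trait=pmap.trait, units=pmap.units,
    )


def median_composite(maps: list[PredictionMap]) -> PredictionMap:
    """Per-pixel median of valid means across a time series of maps.

    For even counts the lower of the two central values is taken so the
    composited SD can come from the scene that actually produced the median.
    Pixels invalid in every scene stay nodata.
    """
    if not maps:
        raise ValueError("no maps to composite")
    shape = maps[0].mean.shape
    meta = maps[0].meta
    for m in maps[1:]:
        if m.mean.shape != shape or m.meta.transform != meta.transform:
            raise ValueError("inconsistent grids across scenes")
    T = len(maps)
    means = np.stack([np.where(m.valid, m.mean, np.nan) for m in maps])
    sds = np.stack([np.where(m.valid, m.sd, np.nan) for m in maps])
    count = np.sum(~np.isnan(means), axis=0)
    valid = count > 0

    order = np.argsort(means, axis=0, kind="stable")  # NaN sorts last
    sorted_means = np.take_along_axis(means, order, axis=0)
    sorted_sds = np.take_along_axis(sds, order, axis=0)
    med_pos = np.maximum(count - 1, 0) // 2  # lower central value
    med_mean = np.take_along_axis(sorted_means, med_pos[None], axis=0)[0]
    med_sd = np.take_along_axis(sorted_sds, med_pos[None], axis=0)[0]
    return PredictionMap(
        meta=meta,
        mean=np.where(valid, med_mean, meta.nodata),
        sd=np.where(valid, med_sd, meta.nodata),
        valid=valid, trait=maps[0].trait, units=maps[0].units,
    )


def write_prediction_map(path, pmap: PredictionMap) -> None:
    """Write a trait map as a 3-band raster ordered (mean, sd, cv)."""
    data = np.stack([pmap.mean, pmap.sd, pmap.cv])
    raster = Raster(data=data, meta=pmap.meta,
                    band_names=["mean", "sd", "cv"])
    desc = json.dumps({
        "grid": pmap.meta.to_json(), "band_names": raster.band_names,
        "trait": pmap.trait, "units": pmap.units,
    })
    tifffile.imwrite(path, raster.data, description=desc,
                     photometric="minisblack")


def read_prediction_map(path) -> PredictionMap:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    doc = json.loads(desc) if desc else {}
    meta = GridMeta.from_json(doc.get("grid", {}))
    mean, sd = data[0], data[1]
    valid = mean != meta.nodata
    return PredictionMap(meta=meta, mean=mean, sd=sd, valid=valid,
                         trait=doc.get("trait", ""), units=doc.get("units", ""))
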