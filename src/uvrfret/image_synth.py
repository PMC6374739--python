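"""Seeded synthetic confocal fields of epidermal-like cells expressing FRET pairs.

Renders the two acquisition types the quantification pipeline consumes:

* multi-channel fields (donor emission / FRET channel / acceptor emission)
  of a tessellated epidermal-like tissue whose fluorescence is concentrated
  in a thin band along each cell periphery, as in leaf epidermis expressing
  a plasma-membrane-proximal construct;
* photobleaching time series (five pre-bleach donor scans, an instantaneous
  acceptor bleach restricted to a rectangular region, five post-bleach scans)
  together with the bleach-region and control-region masks.

The per-pixel signal model delegates entirely to
:mod:`uvrfret.fret_physics`; this module adds geometry (Voronoi cell
tessellation, periphery bands), expression heterogeneity (log-normal across
cells, modelling transient-transformation variability), and an explicit noise
chain (per-scan illumination gain jitter -> Poisson shot noise -> Gaussian
read noise).  Everything is deterministic given the config seed.

Images and masks are written as multi-page TIFFs with a YAML sidecar that
names every page; the ground-truth efficiency and cell-label maps travel in a
separate float TIFF so the quantification stage never needs them.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml
from scipy import ndimage

from .fret_physics import (
    FretParams,
    PopulationState,
    SpeciesMix,
    control_mixture,
    expected_channel_intensities,
    mean_post_bleach_efficiency,
    expected_bleach_increase,
    species_mixture,
)

__all__ = [
    "SizingError",
    "GeometryError",
    "SimulationConfig",
    "AcquisitionSet",
    "BleachSeries",
    "generate_cells",
    "render_acquisition",
    "render_bleach_series",
    "write_images",
    "quantize_u16",
    "CHANNELS",
]


class SizingError(ValueError):
    """Field too small to hold the requested number of cells."""


class GeometryError(ValueError):
    """Invalid bleach/control region geometry."""


# Channel acquisition metadata mirroring a standard GFP/mCherry FRET setup:
# 488 nm excitation with donor (500-535 nm) and acceptor (590-645 nm)
# detection bands collected in the same scan, plus a separate 552 nm scan for
# the acceptor control channel.
CHANNELS = {
    "donor_488": {"excitation_nm": 488, "band_nm": (500, 535), "gain": "donor"},
    "fret_488": {"excitation_nm": 488, "band_nm": (590, 645), "gain": "acceptor"},
    "acceptor_552": {"excitation_nm": 552, "band_nm": (590, 645), "gain": "acceptor"},
}


@dataclass(frozen=True)
class SimulationConfig:
    """Full generative description of one synthetic acquisition.

    ``expression_level`` is the mean tagged-molecule density on periphery
    pixels; ``expression_cv`` the log-normal coefficient of variation across
    cells.  ``scan_gain_cv`` is the per-scan illumination/gain fluctuation
    (multiplicative, CV units); the donor and FRET channels share one 488 nm
    scan and therefore one gain draw.  Five pre- and five post-bleach scans
    reproduce the standard photobleaching protocol.
    """

    state: PopulationState = field(default_factory=PopulationState)
    params: FretParams = field(default_factory=FretParams)
    n_cells: int = 6
    image_size: tuple[int, int] = (192, 192)
    expression_level: float = 200.0
    expression_cv: float = 0.4
    noise_read_sd: float = 2.0
    shot_noise: bool = True
    scan_gain_cv: float = 0.015
    bleach_completeness: float = 0.95
    n_pre_scans: int = 5
    n_post_scans: int = 5
    periphery_width: int = 3
    wall_width: int = 2
    control: str | None = None  # "donor_only" | "acceptor_only"
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h < 64 or w < 64:
            raise ValueError("image dimensions must be >= 64x64")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.expression_level < 0 or self.expression_cv < 0:
            raise ValueError("expression parameters must be >= 0")
        if self.noise_read_sd < 0 or self.scan_gain_cv < 0:
            raise ValueError("noise parameters must be >= 0")
        if not 0.0 <= self.bleach_completeness <= 1.0:
            raise ValueError("bleach_completeness must be within [0, 1]")
        if self.n_pre_scans < 1 or self.n_post_scans < 1:
            raise ValueError("need at least one pre and one post scan")
        if self.control not in (None, "donor_only", "acceptor_only"):
            raise ValueError(f"unknown control {self.control!r}")

    def mixture(self) -> SpeciesMix:
        if self.control is not None:
            return control_mixture(self.control)
        return species_mixture(self.state, self.params)

    def noiseless(self) -> "SimulationConfig":
        """Copy with every stochastic intensity term switched off."""
        return dataclasses.replace(
            self, shot_noise=False, noise_read_sd=0.0, scan_gain_cv=0.0
        )


@dataclass
class AcquisitionSet:
    """One field of view: the three channel images plus metadata/ground truth."""

    donor_488: np.ndarray
    fret_488: np.ndarray
    acceptor_552: np.ndarray
    metadata: dict
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        shapes = {self.donor_488.shape, self.fret_488.shape, self.acceptor_552.shape}
        if len(shapes) != 1:
            raise ValueError("all channels must share identical dimensions")

    @property
    def channels(self) -> dict[str, np.ndarray]:
        return {
            "donor_488": self.donor_488,
            "fret_488": self.fret_488,
            "acceptor_552": self.acceptor_552,
        }


@dataclass
class BleachSeries:
    """Donor-channel pre/post scan stacks plus bleach and control masks."""

    pre_stack: np.ndarray  # (n_pre, H, W)
    post_stack: np.ndarray  # (n_post, H, W)
    bleach_mask: np.ndarray  # bool (H, W)
    control_mask: np.ndarray  # bool (H, W)
    metadata: dict
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        if self.pre_stack.shape[1:] != self.bleach_mask.shape:
            raise ValueError("stacks and masks must share dimensions")
        if self.post_stack.shape[1:] != self.bleach_mask.shape:
            raise ValueError("stacks and masks must share dimensions")
        if self.control_mask.shape != self.bleach_mask.shape:
            raise ValueError("stacks and masks must share dimensions")
        if np.any(self.bleach_mask & self.control_mask):
            raise GeometryError("bleach and control masks must be disjoint")


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def generate_cells(config: SimulationConfig, rng: np.random.Generator | None = None):
    """Tessellate the field into cells and mark a periphery band per cell.

    Returns ``(labels, periphery, expression_map)``: an integer label map
    (0 = cell-wall background, 1..n = cells), a boolean periphery-band map,
    and a float map with each cell's expression level painted onto its band.
    Cells are Voronoi regions of jittered-grid seed points; each region is
    eroded to leave a wall between neighbours and the band is the outermost
    ``periphery_width`` pixels of the eroded region.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    h, w = config.image_size
    n = config.n_cells
    if (h * w) / n < 28 * 28:
        raise SizingError(
            f"field {h}x{w} too small for {n} cells (need >=28x28 px per cell)"
        )
    # Jittered-grid seed placement keeps cells roughly even in size.
    gr = int(np.ceil(np.sqrt(n)))
    gc = int(np.ceil(n / gr))
    cells_idx = rng.permutation(gr * gc)[:n]
    pitch_r, pitch_c = h / gr, w / gc
    rows = (cells_idx // gc + 0.5) * pitch_r + rng.uniform(-0.25, 0.25, n) * pitch_r
    cols = (cells_idx % gc + 0.5) * pitch_c + rng.uniform(-0.25, 0.25, n) * pitch_c
    rr, cc = np.mgrid[0:h, 0:w]
    d2 = (rr[..., None] - rows) ** 2 + (cc[..., None] - cols) ** 2
    voronoi = np.argmin(d2, axis=-1) + 1

    labels = np.zeros((h, w), dtype=np.int32)
    periphery = np.zeros((h, w), dtype=bool)
    struct = np.ones((3, 3), dtype=bool)
    for k in range(1, n + 1):
        region = voronoi == k
        interior = ndimage.binary_erosion(
            region, structure=struct, iterations=config.wall_width, border_value=0
        )
        if not interior.any():
            raise SizingError(f"cell {k} vanished after wall erosion; field too small")
        core = ndimage.binary_erosion(
            interior, structure=struct, iterations=config.periphery_width,
            border_value=0,
        )
        band = interior & ~core
        if not band.any():
            raise SizingError(f"cell {k} has no periphery band; field too small")
        labels[interior] = k
        periphery |= band

    # Log-normal expression across cells (CV on the natural scale).
    if config.expression_cv > 0:
        sigma2 = np.log1p(config.expression_cv**2)
        mu = np.log(max(config.expression_level, 1e-300)) - sigma2 / 2.0
        levels = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)
    else:
        levels = np.full(n, config.expression_level)
    if config.expression_level == 0:
        levels = np.zeros(n)

    expr = np.zeros((h, w), dtype=float)
    for k in range(1, n + 1):
        expr[(labels == k) & periphery] = levels[k - 1]
    return labels, periphery, expr


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _apply_noise(expected: np.ndarray, gain: float, config: SimulationConfig,
                 rng: np.random.Generator) -> np.ndarray:
    lam = expected * gain
    img = rng.poisson(lam).astype(float) if config.shot_noise else lam.astype(float)
    if config.noise_read_sd > 0:
        img = img + rng.normal(0.0, config.noise_read_sd, size=img.shape)
    return np.clip(img, 0.0, None)


def _scan_gain(config: SimulationConfig, rng: np.random.Generator) -> float:
    if config.scan_gain_cv == 0:
        return 1.0
    return float(max(rng.normal(1.0, config.scan_gain_cv), 0.0))


def _base_metadata(config: SimulationConfig) -> dict:
    return {
        "seed": int(config.seed),
        "config": _plain(dataclasses.asdict(config)),
    }


def render_acquisition(config: SimulationConfig) -> AcquisitionSet:
    """Render one multi-channel field of view.

    Per-pixel expectations come from the species mixture and the expression
    map; the 488 nm scan (donor + FRET channels) and the 552 nm scan each get
    one illumination-gain draw, then shot and read noise are applied per
    channel.  The ground-truth efficiency map, label map and expression map
    are stored alongside.
    """
    rng = np.random.default_rng(config.seed)
    labels, periphery, expr = generate_cells(config, rng)
    mix = config.mixture()
    i_d, i_f, i_a = expected_channel_intensities(mix, config.params, expr)

    g488 = _scan_gain(config, rng)
    g552 = _scan_gain(config, rng)
    donor = _apply_noise(i_d, g488, config, rng)
    fret = _apply_noise(i_f, g488, config, rng)
    acceptor = _apply_noise(i_a, g552, config, rng)

    e_map = np.where(expr > 0, mix.mean_efficiency, 0.0)
    meta = _base_metadata(config)
    meta["kind"] = "acquisition"
    meta["channels"] = {k: dict(v, band_nm=list(v["band_nm"])) for k, v in CHANNELS.items()}
    truth = {
        "efficiency_map": e_map,
        "cell_labels": labels,
        "expression_map": expr,
        "mean_efficiency": float(mix.mean_efficiency),
        "expected_ratio_map": None,
    }
    return AcquisitionSet(donor, fret, acceptor, metadata=meta, ground_truth=truth)


def _mask_from_rect(rect, shape) -> np.ndarray:
    r0, c0, r1, c1 = (int(v) for v in rect)
    h, w = shape
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise GeometryError(f"region {rect} outside image bounds {shape}")
    mask = np.zeros(shape, dtype=bool)
    mask[r0:r1, c0:c1] = True
    return mask


def _auto_regions(labels: np.ndarray, periphery: np.ndarray, margin: int = 3):
    """Pick a bleach rectangle enclosing one full cell periphery and a
    disjoint control rectangle over unbleached periphery signal.

    The bleach box is the margin-padded bounding box of the band of the cell
    with the most periphery pixels; the control box is the bounding box of
    the densest periphery patch in the image strip (above/below/left/right of
    the bleach box) holding the most remaining periphery pixels, which makes
    disjointness structural.
    """
    h, w = labels.shape
    boxes = []
    for k in range(1, labels.max() + 1):
        band = (labels == k) & periphery
        if band.any():
            boxes.append((int(band.sum()), k))
    boxes.sort(reverse=True)
    for _, k in boxes:
        band = (labels == k) & periphery
        rs, cs = np.nonzero(band)
        b = (max(rs.min() - margin, 0), max(cs.min() - margin, 0),
             min(rs.max() + margin + 1, h), min(cs.max() + margin + 1, w))
        other = periphery & (labels != k)
        strips = [
            (0, 0, h, b[1]),       # left of the bleach box
            (0, b[3], h, w),       # right
            (0, 0, b[0], w),       # above
            (b[2], 0, h, w),       # below
        ]
        best = None
        for r0, c0, r1, c1 in strips:
            if r1 <= r0 or c1 <= c0:
                continue
            patch = other[r0:r1, c0:c1]
            n = int(patch.sum())
            if n and (best is None or n > best[0]):
                prs, pcs = np.nonzero(patch)
                best = (n, (r0 + int(prs.min()), c0 + int(pcs.min()),
                            r0 + int(prs.max()) + 1, c0 + int(pcs.max()) + 1))
        if best is not None:
            return b, best[1]
    raise GeometryError("could not place disjoint bleach and control regions")


def render_bleach_series(config: SimulationConfig,
                         bleach_region: tuple[int, int, int, int] | None = None,
                         control_region: tuple[int, int, int, int] | None = None,
                         ) -> BleachSeries:
    """Render a photobleaching series of the donor channel.

    The acceptor population inside the bleach mask is reduced by
    ``bleach_completeness`` between the pre and post stacks, raising the donor
    expectation there by the closed-form recovery; the control region is
    untouched in expectation.  Regions are ``(row0, col0, row1, col1)``
    half-open rectangles; when omitted, two disjoint rectangles each enclosing
    one full cell periphery are chosen automatically.
    """
    rng = np.random.default_rng(config.seed)
    labels, periphery, expr = generate_cells(config, rng)
    shape = labels.shape
    if bleach_region is None or control_region is None:
        auto_b, auto_c = _auto_regions(labels, periphery)
        bleach_region = bleach_region or auto_b
        control_region = control_region or auto_c
    bleach_mask = _mask_from_rect(bleach_region, shape)
    control_mask = _mask_from_rect(control_region, shape)
    if not bleach_mask.any():
        raise GeometryError("bleach region is empty")
    if np.any(bleach_mask & control_mask):
        raise GeometryError("bleach and control regions overlap")

    mix = config.mixture()
    params = config.params
    d = mix.donors_per_molecule
    e_pre = mix.mean_efficiency
    e_post = mean_post_bleach_efficiency(mix, config.bleach_completeness)
    i_pre = params.g_donor * expr * d * (1.0 - e_pre)
    i_post = np.where(bleach_mask,
                      params.g_donor * expr * d * (1.0 - e_post), i_pre)

    def scan(expected):
        return _apply_noise(expected, _scan_gain(config, rng), config, rng)

    pre = np.stack([scan(i_pre) for _ in range(config.n_pre_scans)])
    post = np.stack([scan(i_post) for _ in range(config.n_post_scans)])

    meta = _base_metadata(config)
    meta["kind"] = "bleach_series"
    meta["channel"] = dict(CHANNELS["donor_488"], band_nm=list(CHANNELS["donor_488"]["band_nm"]))
    meta["n_pre_scans"] = config.n_pre_scans
    meta["n_post_scans"] = config.n_post_scans
    meta["bleach_region"] = [int(v) for v in bleach_region]
    meta["control_region"] = [int(v) for v in control_region]
    truth = {
        "cell_labels": labels,
        "expression_map": expr,
        "mean_efficiency": float(e_pre),
        "expected_percent_increase": (
            float(expected_bleach_increase(mix, params, config.bleach_completeness))
            if d > 0 and e_pre < 1.0 else None
        ),
    }
    return BleachSeries(pre, post, bleach_mask, control_mask,
                        metadata=meta, ground_truth=truth)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def quantize_u16(arr: np.ndarray) -> np.ndarray:
    """Round/clip to the 16-bit unsigned confocal export range.

    Emits a warning when pixels saturate at 65535.
    """
    n_sat = int(np.count_nonzero(arr > 65535))
    if n_sat:
        warnings.warn(f"{n_sat} pixels saturated at the 16-bit ceiling",
                      stacklevel=2)
    return np.clip(np.round(arr), 0, 65535).astype(np.uint16)


def _plain(obj):
    """Recursively convert to YAML-safe plain Python types."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _plain(dataclasses.asdict(obj))
    return obj


def _convert(arr: np.ndarray, dtype: str) -> np.ndarray:
    if dtype == "uint16":
        return quantize_u16(arr)
    if dtype == "float32":
        return arr.astype(np.float32)
    raise ValueError(f"unsupported export dtype {dtype!r}")


def write_images(obj: AcquisitionSet | BleachSeries, prefix, dtype: str = "uint16"):
    """Write an acquisition or bleach series to ``<prefix>.tif`` + sidecar.

    Acquisitions become a 3-page TIFF (one page per channel); bleach series a
    ``n_pre + n_post``-page donor TIFF plus two single-page binary mask TIFFs.
    A ``<prefix>.yaml`` sidecar records kind, seed, per-page channel metadata
    and the resolved config; ground truth maps go to ``<prefix>_truth.tif``.
    Returns the list of files written.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    files = []
    sidecar: dict = dict(obj.metadata)
    sidecar["dtype"] = dtype
    if isinstance(obj, AcquisitionSet):
        names = list(obj.channels)
        stack = np.stack([_convert(obj.channels[n], dtype) for n in names])
        tifffile.imwrite(prefix.with_suffix(".tif"), stack, photometric="minisblack")
        files.append(prefix.with_suffix(".tif"))
        sidecar["pages"] = [
            {"index": i, "channel": n, **_plain(CHANNELS[n])}
            for i, n in enumerate(names)
        ]
    elif isinstance(obj, BleachSeries):
        stack = np.concatenate([obj.pre_stack, obj.post_stack])
        tifffile.imwrite(prefix.with_suffix(".tif"), _convert(stack, dtype),
                         photometric="minisblack")
        files.append(prefix.with_suffix(".tif"))
        sidecar["pages"] = [
            {
                "index": i,
                "channel": "donor_488",
                "phase": "pre" if i < obj.pre_stack.shape[0] else "post",
                "scan": i if i < obj.pre_stack.shape[0] else i - obj.pre_stack.shape[0],
                **_plain(CHANNELS["donor_488"]),
            }
            for i in range(stack.shape[0])
        ]
        for name, mask in (("bleach_mask", obj.bleach_mask),
                           ("control_mask", obj.control_mask)):
            p = prefix.parent / f"{prefix.name}_{name}.tif"
            tifffile.imwrite(p, mask.astype(np.uint8), photometric="minisblack")
            files.append(p)
            sidecar[name] = p.name
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")

    if obj.ground_truth is not None:
        truth_pages = []
        arrays = []
        for key in ("efficiency_map", "cell_labels", "expression_map"):
            val = obj.ground_truth.get(key)
            if isinstance(val, np.ndarray):
                truth_pages.append(key)
                arrays.append(val.astype(np.float32))
        if arrays:
            tp = prefix.parent / f"{prefix.name}_truth.tif"
            tifffile.imwrite(tp, np.stack(arrays), photometric="minisblack")
            files.append(tp)
            sidecar["truth_pages"] = truth_pages
            sidecar["truth_file"] = tp.name
        sidecar["ground_truth_scalars"] = _plain({
            k: v for k, v in obj.ground_truth.items()
            if not isinstance(v, np.ndarray)
        })

    ypath = prefix.with_suffix(".yaml")
    with open(ypath, "w") as fh:
        yaml.safe_dump(_plain(sidecar), fh, sort_keys=False)
    files.append(ypath)
    return files
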