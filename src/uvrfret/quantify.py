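"""The two FRET measurement procedures on channel images.

1. **Sensitized-emission ratio** — square regions are sampled at random from
   positions with adequate donor signal; the per-region FRET efficiency proxy
   is the mean-intensity ratio ``fret_488 / donor_488`` (acceptor emission
   under donor excitation over donor emission under donor excitation).
   Regions average into image means, images into experiment means, and the
   standard error is taken across independent experiments, the declared
   replication unit.

2. **Acceptor-photobleaching percent increase** — the donor intensity is
   sampled at ~100 points along one cell's periphery (traced automatically by
   thresholding and contour extraction), averaged over the five pre-bleach and
   five post-bleach scans, and the donor dequenching is reported as
   ``100 * (I_pb - I_pre) / I_pre``, alongside the same statistic on an
   unbleached control region.

The module also reads the TIFF + YAML sidecar convention written by
:mod:`uvrfret.image_synth`; channels are mapped by sidecar metadata, never by
page order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu

from .image_synth import AcquisitionSet, BleachSeries

logger = logging.getLogger("uvrfret")

__all__ = [
    "LoadError",
    "MissingChannelError",
    "SamplingError",
    "TracingError",
    "EmptyResultError",
    "RegionSample",
    "FretRatioResult",
    "PeripheryProfile",
    "BleachResult",
    "read_acquisition",
    "read_bleach_series",
    "select_random_regions",
    "sensitized_emission_ratio",
    "trace_periphery",
    "sample_at_points",
    "bleach_percent_increase",
]


class LoadError(IOError):
    """Malformed or incomplete acquisition on disk."""


class MissingChannelError(LoadError):
    """A required channel page is absent from the TIFF/sidecar."""


class SamplingError(ValueError):
    """Not enough admissible region positions."""


class TracingError(ValueError):
    """No closed periphery contour could be traced."""


class EmptyResultError(ValueError):
    """Every region was excluded; nothing to aggregate."""


REQUIRED_CHANNELS = ("donor_488", "fret_488", "acceptor_552")


# ---------------------------------------------------------------------------
# Reading the TIFF + sidecar convention
# ---------------------------------------------------------------------------

def _load_sidecar(prefix: Path) -> dict:
    ypath = prefix.with_suffix(".yaml")
    if not ypath.exists():
        raise LoadError(f"sidecar not found: {ypath}")
    try:
        with open(ypath) as fh:
            meta = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise LoadError(f"unreadable sidecar metadata {ypath}: {exc}") from exc
    if not isinstance(meta, dict) or "pages" not in meta:
        raise LoadError(f"sidecar {ypath} lacks page metadata")
    return meta


def _load_truth(prefix: Path, meta: dict) -> dict | None:
    truth: dict = dict(meta.get("ground_truth_scalars") or {})
    tf = meta.get("truth_file")
    if tf:
        tpath = prefix.parent / tf
        if tpath.exists():
            pages = tifffile.imread(tpath)
            if pages.ndim == 2:
                pages = pages[None]
            for name, arr in zip(meta.get("truth_pages", []), pages):
                truth[name] = np.asarray(arr)
    return truth or None


def read_acquisition(path) -> AcquisitionSet:
    """Read a multi-channel acquisition from ``<prefix>.tif`` + ``<prefix>.yaml``.

    ``path`` may be the prefix, the TIFF or the YAML file.  Channels are
    identified by the sidecar's per-page ``channel`` entries, so shuffled page
    order is handled; a missing required channel raises
    :class:`MissingChannelError` naming it.
    """
    prefix = Path(path).with_suffix("")
    meta = _load_sidecar(prefix)
    if meta.get("kind") != "acquisition":
        raise LoadError(f"{prefix} is not an acquisition (kind={meta.get('kind')!r})")
    tpath = prefix.with_suffix(".tif")
    if not tpath.exists():
        raise LoadError(f"image file not found: {tpath}")
    pages = tifffile.imread(tpath)
    if pages.ndim == 2:
        pages = pages[None]
    by_channel: dict[str, np.ndarray] = {}
    for page in meta["pages"]:
        idx, name = page["index"], page["channel"]
        if idx >= len(pages):
            raise LoadError(f"sidecar references page {idx} beyond TIFF length")
        by_channel[name] = np.asarray(pages[idx])
    for name in REQUIRED_CHANNELS:
        if name not in by_channel:
            raise MissingChannelError(f"missing channel {name!r} in {tpath}")
    shapes = {by_channel[n].shape for n in REQUIRED_CHANNELS}
    if len(shapes) != 1:
        raise LoadError(f"channel dimension mismatch in {tpath}: {shapes}")
    return AcquisitionSet(
        donor_488=by_channel["donor_488"],
        fret_488=by_channel["fret_488"],
        acceptor_552=by_channel["acceptor_552"],
        metadata=meta,
        ground_truth=_load_truth(prefix, meta),
    )


def read_bleach_series(path) -> BleachSeries:
    """Read a photobleaching series (donor stack + masks) from disk."""
    prefix = Path(path).with_suffix("")
    meta = _load_sidecar(prefix)
    if meta.get("kind") != "bleach_series":
        raise LoadError(f"{prefix} is not a bleach series (kind={meta.get('kind')!r})")
    pages = tifffile.imread(prefix.with_suffix(".tif"))
    if pages.ndim == 2:
        pages = pages[None]
    pre, post = [], []
    for page in meta["pages"]:
        arr = np.asarray(pages[page["index"]])
        (pre if page.get("phase") == "pre" else post).append((page.get("scan", 0), arr))
    if not pre or not post:
        raise LoadError(f"{prefix}: bleach series needs pre and post scans")
    masks = {}
    for name in ("bleach_mask", "control_mask"):
        fname = meta.get(name)
        if not fname:
            raise LoadError(f"{prefix}: sidecar lacks {name}")
        masks[name] = tifffile.imread(prefix.parent / fname).astype(bool)
    return BleachSeries(
        pre_stack=np.stack([a for _, a in sorted(pre, key=lambda t: t[0])]),
        post_stack=np.stack([a for _, a in sorted(post, key=lambda t: t[0])]),
        bleach_mask=masks["bleach_mask"],
        control_mask=masks["control_mask"],
        metadata=meta,
        ground_truth=_load_truth(prefix, meta),
    )


# ---------------------------------------------------------------------------
# Sensitized-emission ratio
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionSample:
    """One randomly placed square region with its per-channel mean intensities."""

    image_id: str
    region_id: int
    center: tuple[int, int]
    side: int
    mean_donor_488: float
    mean_fret_488: float
    mean_acceptor_552: float
    experiment_id: str = "exp0"


def _patch_means(img: np.ndarray, side: int) -> np.ndarray:
    """Mean over every side x side patch, indexed by top-left corner."""
    s = np.cumsum(np.cumsum(np.pad(img.astype(float), ((1, 0), (1, 0))), 0), 1)
    h, w = img.shape
    sums = (s[side:h + 1, side:w + 1] - s[0:h - side + 1, side:w + 1]
            - s[side:h + 1, 0:w - side + 1] + s[0:h - side + 1, 0:w - side + 1])
    return sums / (side * side)


def select_random_regions(acq: AcquisitionSet, n_regions: int = 20,
                          patch_side: int = 16, seed: int = 0,
                          min_signal: float | None = None,
                          image_id: str = "img0",
                          experiment_id: str = "exp0") -> list[RegionSample]:
    """Draw random square regions with adequate donor signal.

    Candidate positions are every patch fully inside the image whose donor
    mean exceeds ``min_signal`` (``None`` -> Otsu threshold of the patch-mean
    image, excluding empty background); accepted regions may not overlap any
    previously accepted one by more than 50% of their area.  Deterministic
    given ``seed``.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    donor = np.asarray(acq.donor_488, dtype=float)
    h, w = donor.shape
    if patch_side > min(h, w):
        raise ValueError("patch does not fit inside the image")
    means_d = _patch_means(donor, patch_side)
    if min_signal is None:
        vals = means_d.ravel()
        min_signal = float(threshold_otsu(vals)) if np.ptp(vals) > 0 else 0.0
        logger.info("min_signal resolved by Otsu to %.4g", min_signal)
    cand = np.argwhere(means_d > min_signal) if min_signal > 0 else \
        np.argwhere(np.isfinite(means_d))
    if len(cand) < n_regions:
        raise SamplingError(
            f"only {len(cand)} admissible positions for {n_regions} regions"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cand))
    chosen: list[tuple[int, int]] = []
    s = patch_side
    for idx in order:
        r, c = map(int, cand[idx])
        ok = True
        for (r2, c2) in chosen:
            inter = max(0, s - abs(r - r2)) * max(0, s - abs(c - c2))
            if inter > 0.5 * s * s:
                ok = False
                break
        if ok:
            chosen.append((r, c))
            if len(chosen) == n_regions:
                break
    if len(chosen) < n_regions:
        raise SamplingError(
            f"only {len(chosen)} regions satisfy the 50% overlap limit "
            f"(requested {n_regions})"
        )
    fret = np.asarray(acq.fret_488, dtype=float)
    acc = np.asarray(acq.acceptor_552, dtype=float)
    out = []
    for i, (r, c) in enumerate(chosen):
        sl = (slice(r, r + s), slice(c, c + s))
        out.append(RegionSample(
            image_id=image_id, region_id=i,
            center=(r + s // 2, c + s // 2), side=s,
            mean_donor_488=float(donor[sl].mean()),
            mean_fret_488=float(fret[sl].mean()),
            mean_acceptor_552=float(acc[sl].mean()),
            experiment_id=experiment_id,
        ))
    return out


@dataclass
class FretRatioResult:
    """Aggregated sensitized-emission ratios.

    ``per_region`` has one row per kept region; ``per_image`` and
    ``per_experiment`` carry the nested means.  ``mean``/``se`` summarize
    across experiments (SE undefined below two experiments).
    """

    per_region: pd.DataFrame
    per_image: pd.Series
    per_experiment: pd.Series
    mean: float
    se: float
    n_excluded: int
    pooled: bool = False

    @property
    def n_experiments(self) -> int:
        return len(self.per_experiment)


def sensitized_emission_ratio(regions: list[RegionSample],
                              pooled: bool = False) -> FretRatioResult:
    """Aggregate per-region FRET ratios: region -> image -> experiment.

    The per-region ratio is ``mean_fret_488 / mean_donor_488``.  Regions with
    non-positive donor mean are excluded with a logged warning.  With
    ``pooled=True`` the per-image value is instead the ratio of pooled channel
    means over the image's regions.
    """
    rows, n_excluded = [], 0
    for r in regions:
        if r.mean_donor_488 <= 0:
            logger.warning("excluding region %s/%s/%s: zero donor mean",
                           r.experiment_id, r.image_id, r.region_id)
            n_excluded += 1
            continue
        rows.append({
            "experiment": r.experiment_id, "image": r.image_id,
            "region": r.region_id,
            "mean_donor_488": r.mean_donor_488,
            "mean_fret_488": r.mean_fret_488,
            "mean_acceptor_552": r.mean_acceptor_552,
            "ratio": r.mean_fret_488 / r.mean_donor_488,
        })
    if not rows:
        raise EmptyResultError("all regions excluded (zero donor signal)")
    df = pd.DataFrame(rows)
    if pooled:
        g = df.groupby(["experiment", "image"])
        per_image = g["mean_fret_488"].mean() / g["mean_donor_488"].mean()
    else:
        per_image = df.groupby(["experiment", "image"])["ratio"].mean()
    per_image.name = "ratio"
    per_exp = per_image.groupby("experiment").mean()
    mean = float(per_exp.mean())
    se = float(per_exp.std(ddof=1) / np.sqrt(len(per_exp))) if len(per_exp) > 1 \
        else float("nan")
    return FretRatioResult(df, per_image, per_exp, mean, se, n_excluded, pooled)


# ---------------------------------------------------------------------------
# Periphery tracing and photobleaching analysis
# ---------------------------------------------------------------------------

@dataclass
class PeripheryProfile:
    """Ordered points along one cell's periphery with sampled intensities."""

    points: np.ndarray  # (n, 2) float row/col coordinates
    intensity: np.ndarray  # intensity at each point on the traced image
    roi: tuple[int, int, int, int]


def trace_periphery(image: np.ndarray, roi: tuple[int, int, int, int] | None = None,
                    n_points: int = 100, window: int = 3,
                    threshold: float | None = None) -> PeripheryProfile:
    """Trace ~``n_points`` ordered points along the brightest cell periphery.

    Thresholds the (donor) image within ``roi`` by Otsu's method on the log
    intensity (robust to cell-to-cell expression differences), extracts the
    longest *closed* iso-contour of the foreground — fragments of neighbouring
    cells clipped by the roi yield open contours and are ignored — and
    resamples it at equal arc length.  Intensities are the ``window x window``
    neighbourhood means at each point.  ``threshold`` overrides Otsu.
    """
    if n_points < 10:
        raise ValueError("n_points must be >= 10")
    img = np.asarray(image, dtype=float)
    if roi is None:
        roi = (0, 0, img.shape[0], img.shape[1])
    r0, c0, r1, c1 = roi
    sub = img[r0:r1, c0:c1]
    if sub.size == 0:
        raise TracingError("empty roi")
    if threshold is None:
        if np.ptp(sub) == 0:
            raise TracingError(
                "uniform image: no contour; pass an explicit threshold")
        threshold = float(np.expm1(threshold_otsu(np.log1p(np.clip(sub, 0, None)))))
    mask = sub > threshold
    if not mask.any():
        raise TracingError("threshold leaves no foreground; override threshold")
    contours = [c for c in measure.find_contours(mask.astype(float), 0.5)
                if np.allclose(c[0], c[-1])]
    if not contours:
        raise TracingError(
            "no closed contour found; enlarge the roi or override the threshold")
    contour = max(contours, key=lambda c: len(c))
    seg = np.sqrt(((np.diff(contour, axis=0)) ** 2).sum(1))
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    if total == 0:
        raise TracingError("degenerate contour of zero length")
    targets = np.linspace(0.0, total, n_points, endpoint=False)
    pts = np.column_stack([
        np.interp(targets, arclen, contour[:, 0]),
        np.interp(targets, arclen, contour[:, 1]),
    ])
    pts += [r0, c0]
    intensity = sample_at_points(img, pts, window=window)
    return PeripheryProfile(points=pts, intensity=intensity, roi=tuple(roi))


def sample_at_points(image: np.ndarray, points: np.ndarray,
                     window: int = 3) -> np.ndarray:
    """Neighbourhood-mean intensity at each (row, col) point."""
    img = ndimage.uniform_filter(np.asarray(image, dtype=float), size=window)
    rr = np.clip(np.rint(points[:, 0]).astype(int), 0, img.shape[0] - 1)
    cc = np.clip(np.rint(points[:, 1]).astype(int), 0, img.shape[1] - 1)
    return img[rr, cc]


@dataclass
class BleachResult:
    """Pre/post donor intensities and the percent increase, with control."""

    i_pre: float
    i_pb: float
    percent_increase: float
    control_i_pre: float
    control_i_pb: float
    control_percent_increase: float
    n_pre_scans: int
    n_post_scans: int
    n_points: int | None = None


def _stack_means(stack: np.ndarray, mask=None, points=None, window=3) -> float:
    per_scan = []
    for scan in stack:
        if points is not None:
            per_scan.append(sample_at_points(scan, points, window=window).mean())
        else:
            per_scan.append(float(scan[mask].mean()))
    return float(np.mean(per_scan))


def bleach_percent_increase(series: BleachSeries,
                            profile: PeripheryProfile | np.ndarray | None = None,
                            window: int = 3) -> BleachResult:
    """Percent donor dequenching ``100*(I_pb - I_pre)/I_pre`` after bleaching.

    ``profile`` selects where the donor is sampled inside the bleach region:
    a :class:`PeripheryProfile` (or bare point array) samples neighbourhood
    means at the traced points across every scan; ``None`` falls back to the
    full bleach-mask mean.  The control statistic always uses the control
    mask.
    """
    if series.pre_stack.shape[0] < 1 or series.post_stack.shape[0] < 1:
        raise ValueError("need at least one pre and one post scan")
    points = None
    if isinstance(profile, PeripheryProfile):
        points = profile.points
    elif profile is not None:
        points = np.asarray(profile, dtype=float)
    if points is not None:
        i_pre = _stack_means(series.pre_stack, points=points, window=window)
        i_pb = _stack_means(series.post_stack, points=points, window=window)
        n_points = len(points)
    else:
        if not series.bleach_mask.any():
            raise ValueError("bleach mask is empty")
        i_pre = _stack_means(series.pre_stack, mask=series.bleach_mask)
        i_pb = _stack_means(series.post_stack, mask=series.bleach_mask)
        n_points = None
    if i_pre <= 0:
        raise ZeroDivisionError("pre-bleach donor mean is non-positive")
    c_pre = _stack_means(series.pre_stack, mask=series.control_mask)
    c_pb = _stack_means(series.post_stack, mask=series.control_mask)
    if c_pre <= 0:
        raise ZeroDivisionError("control pre-bleach donor mean is non-positive")
    return BleachResult(
        i_pre=i_pre, i_pb=i_pb,
        percent_increase=100.0 * (i_pb - i_pre) / i_pre,
        control_i_pre=c_pre, control_i_pb=c_pb,
        control_percent_increase=100.0 * (c_pb - c_pre) / c_pre,
        n_pre_scans=series.pre_stack.shape[0],
        n_post_scans=series.post_stack.shape[0],
        n_points=n_points,
    )
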