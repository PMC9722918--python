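"""Ground-truthed synthetic inputs: mitochondrial images, rhythmic time
series and Mito Stress OCR traces.

The image generator emulates a single confocal slice of cells whose
mitochondria range from fragmented (many short objects) to fused (few
elongated tubules).  Each mitochondrion is drawn as a capsule — a tube
of fixed width with semicircular caps, optionally mildly bent — because
capsules match tubular mitochondrial morphology while keeping the true
centreline length and area analytically known.  The forward model is:
paint anti-aliased capsules on a faint cytoplasmic background, blur with
a Gaussian point-spread function, then add Gaussian read noise.  The
reported ground-truth "length" of an object is its end-to-end extent,
centreline length plus tube width, matching the length convention used
downstream in morphology.

It deliberately does not model 3-D stacks, photobleaching or realistic
organelle texture; see the methods note for what that implies.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import io as mio
from .assays import OCRTrace, PHASES
from .rhythm import TimeSeries
from .types import CalibratedImage, ParameterError

__all__ = [
    "SyntheticImageSpec",
    "GroundTruth",
    "RhythmSimSpec",
    "OCRSimSpec",
    "PlacementError",
    "generate_mito_image",
    "generate_timeseries",
    "generate_ocr_trace",
    "write_image_bundle",
]

#: length classes (µm): short < 1, 1 <= mid <= 3, long > 3
LENGTH_CLASS_RANGES = ((0.5, 0.9), (1.2, 2.8), (3.3, 4.5))


class PlacementError(RuntimeError):
    """Objects could not be placed without overlap within the retry budget."""


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Parameters of one synthetic confocal slice.

    ``length_mix`` gives the fractions of short (<1 µm), mid (1–3 µm)
    and long (>3 µm) mitochondria; lengths are drawn uniformly inside
    each class with a margin to the class boundaries so the true class
    is never ambiguous.  Intensities are on an arbitrary photon-like
    scale; ``intensity_bg`` is the cytoplasmic level inside cells (the
    off-cell background is a small camera offset).
    """

    image_size: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.1
    n_cells: int = 1
    mito_per_cell: int = 8
    length_mix: tuple[float, float, float] = (0.25, 0.5, 0.25)
    mito_width_um: float = 0.4
    intensity_fg: float = 180.0
    intensity_bg: float = 30.0
    noise_sd: float = 4.0
    psf_sigma_um: float = 0.08
    allow_touching: bool = False
    cell_radius_um: float = 5.0
    bend_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        mix = np.asarray(self.length_mix, dtype=float)
        if mix.shape != (3,) or np.any(mix < 0) or np.any(mix > 1):
            raise ParameterError("length_mix must be three fractions in [0, 1]")
        if abs(mix.sum() - 1.0) > 1e-9:
            raise ParameterError(f"length_mix must sum to 1 (got {mix.sum()!r})")
        if self.pixel_size_um <= 0:
            raise ParameterError("pixel_size_um must be > 0")
        if self.n_cells < 0 or self.mito_per_cell < 0:
            raise ParameterError("n_cells and mito_per_cell must be >= 0")
        if self.mito_width_um <= 0 or self.cell_radius_um <= 0:
            raise ParameterError("mito_width_um and cell_radius_um must be > 0")
        if self.noise_sd < 0 or self.psf_sigma_um < 0:
            raise ParameterError("noise_sd and psf_sigma_um must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Exact per-object truth accompanying a synthetic image."""

    cell_labels: np.ndarray
    mito_labels: np.ndarray
    table: pd.DataFrame  # object_id, cell_id, length_um, area_um2, length_class

    def __post_init__(self) -> None:
        ids = set(self.table["object_id"])
        present = set(np.unique(self.mito_labels)) - {0}
        if ids != present:
            raise ParameterError("truth table ids do not match mito label map")

    @property
    def n_objects(self) -> int:
        return len(self.table)


def _sample_centreline(
    rng: np.random.Generator,
    centre_px: np.ndarray,
    length_px: float,
    bend_frac: float,
    n_pts: int = 48,
) -> tuple[np.ndarray, float]:
    """Centreline polyline (n_pts, 2) and its exact polyline length (px).

    Straight segment for ``bend_frac == 0``; otherwise a quadratic
    Bézier whose control point is offset perpendicular to the chord by
    ``bend_frac``·chord, rescaled so the arc length equals ``length_px``.
    """
    theta = rng.uniform(0, np.pi)
    d = np.array([math.sin(theta), math.cos(theta)])  # (dy, dx)
    if bend_frac == 0.0:
        s = np.linspace(-0.5, 0.5, n_pts)[:, None]
        pts = centre_px + s * length_px * d
        return pts, length_px
    perp = np.array([-d[1], d[0]])
    p0 = centre_px - 0.5 * length_px * d
    p2 = centre_px + 0.5 * length_px * d
    p1 = centre_px + bend_frac * length_px * perp * rng.choice([-1.0, 1.0])
    s = np.linspace(0.0, 1.0, n_pts)[:, None]
    pts = (1 - s) ** 2 * p0 + 2 * s * (1 - s) * p1 + s**2 * p2
    arc = float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))
    # rescale about the centroid so the drawn arc length matches the draw
    pts = centre_px + (pts - pts.mean(axis=0)) * (length_px / arc)
    arc = float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))
    return pts, arc


def _polyline_distance_field(
    shape: tuple[int, int], pts: np.ndarray, radius_px: float
) -> tuple[slice, slice, np.ndarray]:
    """Distance (px) to a polyline within its padded bounding box."""
    pad = int(math.ceil(radius_px + 2))
    y0 = max(0, int(math.floor(pts[:, 0].min())) - pad)
    y1 = min(shape[0], int(math.ceil(pts[:, 0].max())) + pad + 1)
    x0 = max(0, int(math.floor(pts[:, 1].min())) - pad)
    x1 = min(shape[1], int(math.ceil(pts[:, 1].max())) + pad + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    grid = np.stack([yy, xx], axis=-1).astype(float)  # (h, w, 2)
    a = pts[:-1]  # (m, 2) segment starts
    b = pts[1:]
    ab = b - a
    denom = np.maximum((ab * ab).sum(axis=1), 1e-12)
    # distance from every pixel to every segment, min over segments
    diff = grid[:, :, None, :] - a[None, None, :, :]
    tproj = np.clip((diff * ab[None, None]).sum(axis=-1) / denom, 0.0, 1.0)
    closest = a[None, None] + tproj[..., None] * ab[None, None]
    dist = np.linalg.norm(grid[:, :, None, :] - closest, axis=-1).min(axis=2)
    return slice(y0, y1), slice(x0, x1), dist


def _min_polyline_gap(p: np.ndarray, q: np.ndarray) -> float:
    """Minimum point-to-point distance between two dense polylines (px)."""
    d = np.linalg.norm(p[:, None, :] - q[None, :, :], axis=-1)
    return float(d.min())


def generate_mito_image(spec: SyntheticImageSpec) -> tuple[CalibratedImage, GroundTruth]:
    """Render one synthetic slice and its exact ground truth.

    Deterministic for a fixed spec (the seed lives in the spec): the
    same spec always yields bit-identical image and truth.  When
    ``allow_touching`` is false, centrelines of distinct objects keep a
    surface gap of at least 2·psf_sigma, so blurred objects remain
    separable; exceeding the retry budget raises :class:`PlacementError`
    naming the cell.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.image_size
    px = spec.pixel_size_um
    radius_px = 0.5 * spec.mito_width_um / px
    cell_r_px = spec.cell_radius_um / px

    cell_labels = np.zeros((H, W), dtype=np.int32)
    mito_labels = np.zeros((H, W), dtype=np.int32)
    fg = np.zeros((H, W), dtype=float)
    yy, xx = np.mgrid[:H, :W]

    # --- place cells on a jittered grid so they never overlap ---
    margin = cell_r_px + 2
    if spec.n_cells > 0:
        n_side = int(math.ceil(math.sqrt(spec.n_cells)))
        if 2 * n_side * margin > min(H, W):
            raise PlacementError(
                f"cannot place {spec.n_cells} cells of radius {spec.cell_radius_um} um "
                f"in a {H}x{W} image at {px} um/px"
            )
        if n_side == 1:
            grid = [(H / 2.0, W / 2.0)]
            jitter = max(0.0, min(H, W) / 2.0 - margin)
        else:
            cy = np.linspace(margin, H - margin, n_side)
            cx = np.linspace(margin, W - margin, n_side)
            grid = [(y, x) for y in cy for x in cx]
            spacing = min((H - 2 * margin), (W - 2 * margin)) / (n_side - 1)
            jitter = max(0.0, spacing / 2.0 - cell_r_px - 1.0)
        centres = [
            (y + rng.uniform(-jitter, jitter), x + rng.uniform(-jitter, jitter))
            for y, x in grid[: spec.n_cells]
        ]
    else:
        centres = []

    rows = []
    obj_id = 0
    min_gap_px = 2.0 * spec.psf_sigma_um / px
    for cell_id, (cy0, cx0) in enumerate(centres, start=1):
        cell_mask = (yy - cy0) ** 2 + (xx - cx0) ** 2 <= cell_r_px**2
        cell_labels[cell_mask] = cell_id

        placed: list[np.ndarray] = []
        for _ in range(spec.mito_per_cell):
            cls = int(rng.choice(3, p=spec.length_mix))
            lo, hi = LENGTH_CLASS_RANGES[cls]
            for _attempt in range(300):
                total_len_um = rng.uniform(lo, hi)
                centre_len_um = max(total_len_um - spec.mito_width_um, 0.05)
                length_px = centre_len_um / px
                reach = length_px / 2 + radius_px + 1
                if reach >= cell_r_px:
                    raise PlacementError(
                        f"cell {cell_id}: a {total_len_um:.2f} um mitochondrion cannot fit "
                        f"inside a cell of radius {spec.cell_radius_um} um"
                    )
                r_max = cell_r_px - reach
                rr = math.sqrt(rng.uniform(0, 1)) * r_max
                ang = rng.uniform(0, 2 * np.pi)
                centre = np.array([cy0 + rr * math.sin(ang), cx0 + rr * math.cos(ang)])
                pts, arc_px = _sample_centreline(rng, centre, length_px, spec.bend_frac)
                if not spec.allow_touching and any(
                    _min_polyline_gap(pts, q) < 2 * radius_px + min_gap_px for q in placed
                ):
                    continue
                break
            else:
                raise PlacementError(
                    f"cell {cell_id}: could not place mitochondrion {len(placed) + 1} "
                    "without overlap after 300 attempts"
                )
            obj_id += 1
            placed.append(pts)
            ys, xs, dist = _polyline_distance_field((H, W), pts, radius_px)
            coverage = np.clip(radius_px + 0.5 - dist, 0.0, 1.0)  # 1-px soft edge
            fg[ys, xs] += coverage * spec.intensity_fg
            core = dist <= radius_px
            region = mito_labels[ys, xs]
            region[(region == 0) & core] = obj_id
            mito_labels[ys, xs] = region
            arc_um = arc_px * px
            rows.append(
                {
                    "object_id": obj_id,
                    "cell_id": cell_id,
                    "length_um": arc_um + spec.mito_width_um,
                    "area_um2": arc_um * spec.mito_width_um
                    + math.pi * (spec.mito_width_um / 2) ** 2,
                    "length_class": ("short", "mid", "long")[cls],
                }
            )

    image = np.full((H, W), 2.0)  # small camera offset off-cell
    image[cell_labels > 0] += spec.intensity_bg
    image += fg
    if spec.psf_sigma_um > 0:
        image = ndimage.gaussian_filter(image, spec.psf_sigma_um / px)
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, None)

    table = pd.DataFrame(
        rows, columns=["object_id", "cell_id", "length_um", "area_um2", "length_class"]
    )
    truth = GroundTruth(cell_labels=cell_labels, mito_labels=mito_labels, table=table)
    return CalibratedImage(image, px), truth


# ---------------------------------------------------------------------------
# Rhythmic time series
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RhythmSimSpec:
    """Truth parameters of a simulated cosinor rhythm.

    value(t) = mesor + amplitude·cos(2π(t − acrophase_h)/period_h) + ε,
    ε ~ N(0, noise_sd²) independent across times and replicates.  The
    default sampling — every 4 h over 48 h, 3 replicates — mirrors a
    serum-shock synchronisation time course.
    """

    mesor: float = 10.0
    amplitude: float = 2.0
    acrophase_h: float = 6.0
    period_h: float = 24.0
    times_h: tuple[float, ...] = tuple(float(t) for t in range(0, 49, 4))
    replicates: int = 3
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ParameterError("amplitude must be >= 0")
        if self.period_h <= 0:
            raise ParameterError("period_h must be > 0")
        if not (0 <= self.acrophase_h < self.period_h):
            raise ParameterError("acrophase_h must lie in [0, period_h)")
        if len(self.times_h) == 0:
            raise ParameterError("times_h must be non-empty")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise ParameterError("replicates must be >= 1")

    def curve(self, t: np.ndarray) -> np.ndarray:
        """Noise-free rhythm values at times ``t``."""
        t = np.asarray(t, dtype=float)
        return self.mesor + self.amplitude * np.cos(
            2 * np.pi * (t - self.acrophase_h) / self.period_h
        )


def generate_timeseries(spec: RhythmSimSpec) -> TimeSeries:
    """Simulate noisy rhythm observations; truth travels as ``.truth``."""
    rng = np.random.default_rng(spec.seed)
    t = np.repeat(np.asarray(spec.times_h, dtype=float), spec.replicates)
    rep = np.tile(np.arange(spec.replicates), len(spec.times_h))
    values = spec.curve(t)
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=t.shape)
    ts = TimeSeries(t, values, replicate=rep, label="simulated")
    object.__setattr__(ts, "truth", spec)  # frozen dataclass: attach via object
    return ts


# ---------------------------------------------------------------------------
# OCR traces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OCRSimSpec:
    """True per-phase rates of a simulated Mito Stress run.

    ``rates`` are the true OCR plateaus for (baseline, post-oligomycin,
    post-FCCP, post-rotenone/antimycin) in that fixed injection order.
    """

    rates: tuple[float, float, float, float] = (100.0, 40.0, 160.0, 20.0)
    n_per_phase: int = 3
    noise_sd: float = 2.0
    interval_min: float = 6.5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.rates) != 4:
            raise ParameterError("rates must have exactly 4 phases (baseline, oligo, fccp, rot/aa)")
        if any(r < 0 for r in self.rates):
            raise ParameterError("rates must be >= 0")
        if self.n_per_phase < 1:
            raise ParameterError("need >= 1 measurement per phase")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


def generate_ocr_trace(spec: OCRSimSpec) -> OCRTrace:
    """Concatenated noisy plateau measurements with the injection schedule."""
    rng = np.random.default_rng(spec.seed)
    values = np.repeat(np.asarray(spec.rates, dtype=float), spec.n_per_phase)
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)
    phases = np.repeat(np.asarray(PHASES, dtype=object), spec.n_per_phase)
    times = np.arange(values.size) * spec.interval_min
    return OCRTrace(values=values, phases=phases, times_min=times)


# ---------------------------------------------------------------------------
# Synthetic imaging time course (t<hours>/ directory layout)
# ---------------------------------------------------------------------------


def simulate_timecourse(
    out_dir: str | Path,
    times_h: tuple[float, ...] = (0.0, 12.0, 24.0, 36.0, 48.0),
    cells_per_timepoint: int = 20,
    short_frac_mesor: float = 0.35,
    short_frac_amplitude: float = 0.25,
    short_frac_acrophase_h: float = 12.0,
    period_h: float = 24.0,
    seed: int = 0,
    **image_kwargs,
) -> Path:
    """Write a ``t<hours>/`` image layout with a planted fission rhythm.

    The short-length fraction of the mitochondrial population oscillates as
    mesor + amplitude·cos(2π(t − acrophase)/period), clipped to [0, 0.9];
    the remainder is split 60/40 between the mid and long classes.  One
    single-cell image is written per cell.  Set ``short_frac_amplitude=0``
    for a rhythm-free (null) course.  Returns the course root directory.
    """
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    base = dict(image_size=(160, 160), n_cells=1, mito_per_cell=8, cell_radius_um=5.5)
    base.update(image_kwargs)
    counter = 0
    for t in times_h:
        short = short_frac_mesor + short_frac_amplitude * math.cos(
            2 * math.pi * (t - short_frac_acrophase_h) / period_h
        )
        short = min(max(short, 0.0), 0.9)
        rest = 1.0 - short
        mix = (short, 0.6 * rest, 0.4 * rest)
        tdir = root / (f"t{t:g}" if float(t) != int(t) else f"t{int(t)}")
        tdir.mkdir(exist_ok=True)
        for i in range(cells_per_timepoint):
            counter += 1
            spec = SyntheticImageSpec(length_mix=mix, seed=seed * 1_000_003 + counter, **base)
            img, _ = generate_mito_image(spec)
            mio.write_image(tdir / f"cell{i:03d}.tif", img)
    return root


# ---------------------------------------------------------------------------
# Bundle writer (TIFF image + 16-bit label TIFFs + truth CSV + spec echo)
# ---------------------------------------------------------------------------


def write_image_bundle(
    out_dir: str | Path, img: CalibratedImage, truth: GroundTruth, spec: SyntheticImageSpec
) -> dict[str, Path]:
    """Write image, label maps, truth table and a JSON spec echo."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": out / "image.tif",
        "cell_labels": out / "cell_labels.tif",
        "mito_labels": out / "mito_labels.tif",
        "truth": out / "truth.csv",
        "spec": out / "spec.json",
    }
    mio.write_image(paths["image"], img)
    mio.write_labels(paths["cell_labels"], truth.cell_labels)
    mio.write_labels(paths["mito_labels"], truth.mito_labels)
    truth.table.to_csv(paths["truth"], index=False)
    paths["spec"].write_text(json.dumps(asdict(spec), indent=2))
    return paths
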