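"""Synthetic chromosome images and annotation tables with known ground truth.

This module emulates the raw material of a metaphase immunofluorescence
banding study so the whole analysis pipeline can be exercised against known
truth: a rendered sister chromatid with a green (immunostain) channel whose
intensity along the medial axis follows a :class:`~chromoband.specs.BandModel`,
a DAPI-like red channel giving the chromatid morphology, and a blue marker
line crossing the axis at the centromere.  Genomic annotation tables
(features, coverage signal, per-gene expression) are drawn with window
densities coupled to the same band model by a tunable strength, so the
correlation between image-derived profiles and sequence-derived tracks has a
known generating value.

Every generator is a pure function of its parameters and a seed.  A master
seed is expanded into per-component substreams so adding one generator never
perturbs the draws of another.
"""

from __future__ import annotations

import dataclasses
import zlib

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import CoordinateRangeError, ValidationError
from .specs import MB, BandModel, ChromSpec, WarpModel
from .tables import ExpressionTable, FeatureTable, SignalTrack

__all__ = [
    "band_intensity",
    "render_chromatid",
    "simulate_features",
    "simulate_signal",
    "simulate_expression",
    "ChromImage",
    "ImageTruth",
    "substream",
    "FeatureTable",
    "SignalTrack",
    "ExpressionTable",
]

# Default feature lengths in bp, by class; a window dwarfs all of them.
_FEATURE_LENGTH_BP = {
    "gene": 30_000,
    "cgi": 1_000,
    "sine": 300,
    "line": 6_000,
    "other": 1_000,
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Named child RNG of a master seed.

    Substreams are keyed by a CRC32 of the component name, so generators
    added later draw from independent streams without shifting existing ones.
    """
    key = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


def band_intensity(model: BandModel, position_mb, spec: ChromSpec):
    """Evaluate the ground-truth band profile at genomic position(s).

    Returns ``baseline`` plus the sum of Gaussian band contributions; inside
    the centromere gap (when set) only the baseline remains.  Vectorised.
    """
    pos = np.atleast_1d(np.asarray(position_mb, dtype=float))
    scalar = np.isscalar(position_mb) or np.ndim(position_mb) == 0
    if (pos < 0).any() or (pos > spec.length_mb).any():
        raise CoordinateRangeError(
            f"position outside [0, {spec.length_mb}] Mb"
        )
    contrib = np.zeros_like(pos)
    for band in model.bands:
        contrib += band.amplitude * np.exp(
            -0.5 * ((pos - band.center_mb) / band.sigma_mb) ** 2
        )
    if model.centromere_gap:
        gap = np.abs(pos - spec.centromere_mb) <= model.gap_halfwidth_mb
        contrib[gap] = 0.0
    out = model.baseline + contrib
    return float(out[0]) if scalar else out


def _mean_intensity(model: BandModel, spec: ChromSpec, n_grid: int = 4096) -> float:
    grid = np.linspace(0.0, spec.length_mb, n_grid)
    return float(band_intensity(model, grid, spec).mean())


@dataclasses.dataclass
class ImageTruth:
    """Ground truth stored alongside a rendered chromatid.

    ``axis_rc`` is the medial axis as (row, col) float coordinates, ordered
    pter first; ``ideal_green`` is the noise-free green intensity at each
    axis point.
    """

    model: BandModel
    warp: WarpModel
    axis_rc: np.ndarray
    arc_fraction: np.ndarray
    genomic_mb: np.ndarray
    ideal_green: np.ndarray
    centromere_fraction: float
    centromere_axis_index: int
    halfwidth_px: float

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "warp": self.warp.to_dict(),
            "axis_rc": self.axis_rc.tolist(),
            "arc_fraction": self.arc_fraction.tolist(),
            "genomic_mb": self.genomic_mb.tolist(),
            "ideal_green": self.ideal_green.tolist(),
            "centromere_fraction": self.centromere_fraction,
            "centromere_axis_index": self.centromere_axis_index,
            "halfwidth_px": self.halfwidth_px,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ImageTruth":
        return cls(
            model=BandModel.from_dict(d["model"]),
            warp=WarpModel.from_dict(d["warp"]),
            axis_rc=np.asarray(d["axis_rc"], dtype=float),
            arc_fraction=np.asarray(d["arc_fraction"], dtype=float),
            genomic_mb=np.asarray(d["genomic_mb"], dtype=float),
            ideal_green=np.asarray(d["ideal_green"], dtype=float),
            centromere_fraction=float(d["centromere_fraction"]),
            centromere_axis_index=int(d["centromere_axis_index"]),
            halfwidth_px=float(d["halfwidth_px"]),
        )


@dataclasses.dataclass
class ChromImage:
    """Three-channel rendered chromatid image.

    Channels are float rasters on the declared intensity range [0, 1]:
    green = immunostain (FITC-like), red = DAPI-like counterstain, blue =
    manually-added centromere marker line (nonzero only on the line).
    """

    green: np.ndarray
    red: np.ndarray
    blue: np.ndarray
    pixel_size_um: float = 0.1
    truth: ImageTruth | None = None
    image_id: str = ""

    @property
    def shape(self) -> tuple[int, int]:
        return self.green.shape

    @property
    def rgb(self) -> np.ndarray:
        """(H, W, 3) stack in R, G, B channel order."""
        return np.stack([self.red, self.green, self.blue], axis=-1)


def render_chromatid(
    spec: ChromSpec,
    model: BandModel,
    warp: WarpModel | None = None,
    noise_sd: float = 0.02,
    bend_amplitude: float = 0.0,
    seed: int = 0,
    *,
    length_px: int = 500,
    halfwidth_px: float = 7.0,
    margin_px: int = 12,
    dapi_level: float = 0.8,
    pixel_size_um: float = 0.1,
    image_id: str = "",
) -> ChromImage:
    """Render one chromatid as a bent constant-width tube with three channels.

    The tube follows a smooth polyline whose arc-length fraction ``s`` maps
    to genomic position via ``warp.inverse(s)``; the green channel at the
    pixel nearest axis point ``s`` equals ``band_intensity`` there plus
    zero-mean Gaussian noise (clipped to [0, 1]).  A blue marker line of
    2 px thickness crosses the axis perpendicular at the warped centromere
    position.  All randomness is fixed by ``seed``.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    warp = warp if warp is not None else WarpModel(spec)
    model.validate_against(spec)
    rng = substream(seed, "render")

    # Smooth bent backbone, re-parameterised to uniform ~1 px arc steps.
    t = np.linspace(0.0, 1.0, 8 * length_px)
    x = t * (length_px - 1)
    y = bend_amplitude * np.sin(np.pi * t)
    seglen = np.hypot(np.diff(x), np.diff(y))
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    total = cum[-1]
    n_axis = int(np.floor(total)) + 1
    targets = np.linspace(0.0, total, n_axis)
    ax = np.interp(targets, cum, x)
    ay = np.interp(targets, cum, y)
    arc_fraction = targets / total

    pad = margin_px + halfwidth_px
    col = ax + pad
    row = ay - ay.min() + pad
    H = int(np.ceil(row.max() + pad))
    W = int(np.ceil(col.max() + pad))

    genomic = warp.inverse(arc_fraction)
    # guard endpoints against float drift outside [0, L]
    genomic = np.clip(genomic, 0.0, spec.length_mb)
    ideal = band_intensity(model, genomic, spec)

    axis_rc = np.column_stack([row, col])
    tree = cKDTree(axis_rc)
    rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    pix = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    dist, idx = tree.query(pix)
    mask = (dist <= halfwidth_px).reshape(H, W)
    nearest = idx.reshape(H, W)

    green = np.zeros((H, W), dtype=np.float32)
    red = np.zeros((H, W), dtype=np.float32)
    blue = np.zeros((H, W), dtype=np.float32)
    green[mask] = ideal[nearest[mask]]
    red[mask] = dapi_level
    if noise_sd > 0:
        n_in = int(mask.sum())
        green[mask] += rng.normal(0.0, noise_sd, n_in).astype(np.float32)
        red[mask] += rng.normal(0.0, noise_sd, n_in).astype(np.float32)
    np.clip(green, 0.0, 1.0, out=green)
    np.clip(red, 0.0, 1.0, out=red)

    # Blue marker: 2 px-thick line perpendicular to the axis at the centromere.
    fc = warp.forward(spec.centromere_mb)
    j = int(np.argmin(np.abs(arc_fraction - fc)))
    j0, j1 = max(j - 2, 0), min(j + 2, n_axis - 1)
    tang = axis_rc[j1] - axis_rc[j0]
    tang = tang / np.linalg.norm(tang)
    norm = np.array([-tang[1], tang[0]])
    offsets = np.arange(-(halfwidth_px + 2.0), halfwidth_px + 2.0 + 1e-9, 0.5)
    for dt in (0.0, 1.0):  # 2 px thickness along the axis
        pts = axis_rc[j] + offsets[:, None] * norm[None, :] + dt * tang[None, :]
        pr = np.round(pts[:, 0]).astype(int)
        pc = np.round(pts[:, 1]).astype(int)
        ok = (pr >= 0) & (pr < H) & (pc >= 0) & (pc < W)
        blue[pr[ok], pc[ok]] = 1.0

    truth = ImageTruth(
        model=model,
        warp=warp,
        axis_rc=axis_rc,
        arc_fraction=arc_fraction,
        genomic_mb=genomic,
        ideal_green=ideal,
        centromere_fraction=float(fc),
        centromere_axis_index=j,
        halfwidth_px=float(halfwidth_px),
    )
    return ChromImage(
        green=green,
        red=red,
        blue=blue,
        pixel_size_um=pixel_size_um,
        truth=truth,
        image_id=image_id,
    )


def _band_position_sampler(model: BandModel, spec: ChromSpec, n_grid: int = 8192):
    """Inverse-CDF sampler for positions with density proportional to the model."""
    grid = np.linspace(0.0, spec.length_mb, n_grid)
    dens = band_intensity(model, grid, spec)
    if dens.sum() <= 0:
        # degenerate all-zero model: fall back to uniform
        dens = np.ones_like(dens)
    cdf = np.cumsum(dens)
    cdf = cdf / cdf[-1]

    def sample(rng: np.random.Generator, n: int) -> np.ndarray:
        return np.interp(rng.random(n), cdf, grid)

    return sample


def simulate_features(
    spec: ChromSpec,
    model: BandModel,
    n_features: int,
    coupling: float,
    feature_class: str = "gene",
    seed: int = 0,
    feature_length_bp: int | None = None,
) -> FeatureTable:
    """Draw interval features whose window density tracks the band model.

    Each feature midpoint is drawn, with probability ``coupling``, from a
    density proportional to ``band_intensity`` and otherwise uniformly, so
    10-Mb window counts correlate with the band model with a strength
    controlled by ``coupling`` in [0, 1].
    """
    if n_features < 0:
        raise ValidationError("n_features must be >= 0")
    if not 0.0 <= coupling <= 1.0:
        raise ValidationError("coupling must be in [0, 1]")
    flen = (
        int(feature_length_bp)
        if feature_length_bp is not None
        else _FEATURE_LENGTH_BP.get(feature_class, 1_000)
    )
    rng = substream(seed, f"features:{feature_class}")
    from_band = rng.random(n_features) < coupling
    pos_mb = np.empty(n_features)
    n_band = int(from_band.sum())
    if n_band:
        pos_mb[from_band] = _band_position_sampler(model, spec)(rng, n_band)
    n_unif = n_features - n_band
    if n_unif:
        pos_mb[~from_band] = rng.uniform(0.0, spec.length_mb, n_unif)

    mid_bp = np.round(pos_mb * MB).astype(np.int64)
    start = np.sort(np.clip(mid_bp - flen // 2, 0, max(spec.length_bp - flen, 0)))
    df = pd.DataFrame(
        {
            "chrom": spec.name,
            "start": start,
            "end": start + flen,
            "feature_class": feature_class,
        }
    )
    return FeatureTable(df, chrom_length_bp=spec.length_bp)


def simulate_signal(
    spec: ChromSpec,
    model: BandModel,
    mean_depth: float,
    seed: int = 0,
    step_bp: int = 100_000,
) -> SignalTrack:
    """Poisson fixed-step coverage with expectation proportional to the model.

    The per-bin expectation is the band intensity at the bin centre, scaled
    so the chromosome-wide mean equals ``mean_depth``.
    """
    if mean_depth <= 0:
        raise ValidationError("mean_depth must be > 0")
    rng = substream(seed, "signal")
    starts = np.arange(0, spec.length_bp, step_bp, dtype=np.int64)
    ends = np.minimum(starts + step_bp, spec.length_bp)
    centers_mb = (starts + ends) / 2.0 / MB
    lam = band_intensity(model, centers_mb, spec)
    mean_lam = lam.mean()
    if mean_lam <= 0:
        lam = np.full_like(lam, mean_depth)
    else:
        lam = lam * (mean_depth / mean_lam)
    counts = rng.poisson(lam).astype(float)
    return SignalTrack(spec.name, starts, ends, counts, step_bp=step_bp)


def simulate_expression(
    features: FeatureTable,
    model: BandModel,
    coupling: float,
    seed: int = 0,
    spec: ChromSpec | None = None,
    base_expr: float = 100.0,
    shape: float = 2.0,
) -> ExpressionTable:
    """Per-gene Gamma-distributed expression coupled to the band model.

    Expectation at a gene is ``base_expr * ((1-coupling) + coupling * b)``
    where ``b`` is the band intensity at the gene midpoint normalised to
    chromosome-wide mean 1; coupling 0 makes values exchangeable across
    positions.
    """
    if not 0.0 <= coupling <= 1.0:
        raise ValidationError("coupling must be in [0, 1]")
    classes = set(features.df["feature_class"].unique())
    if classes - {"gene"}:
        raise ValidationError(f"non-gene features present: {sorted(classes - {'gene'})}")
    if len(features) == 0:
        return ExpressionTable(
            pd.DataFrame(columns=["gene_id", "chrom", "pos", "value"])
        )
    if spec is None:
        chrom = features.df["chrom"].iloc[0]
        length_bp = features.chrom_length_bp or int(features.df["end"].max())
        spec = ChromSpec(chrom, length_bp / MB, length_bp / MB / 2.0)
    rng = substream(seed, "expression")
    pos_bp = np.round(features.midpoints_bp).astype(np.int64)
    b = band_intensity(model, pos_bp / MB, spec)
    mean_b = _mean_intensity(model, spec)
    bnorm = b / mean_b if mean_b > 0 else np.ones_like(b)
    mu = base_expr * ((1.0 - coupling) + coupling * bnorm)
    values = rng.gamma(shape, mu / shape)
    df = pd.DataFrame(
        {
            "gene_id": [f"g{i:06d}" for i in range(len(features))],
            "chrom": features.df["chrom"].to_numpy(),
            "pos": pos_bp,
            "value": values,
        }
    )
    return ExpressionTable(df)
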