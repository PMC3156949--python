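"""Fixed-window aggregation of genomic annotations and tracks.

Windows are defined in base pairs internally (1 Mb = 1,000,000 bp exactly),
half-open with the last window closed at the chromosome end.  Interval
features are assigned to exactly one window (by midpoint by default — a
10-Mb window dwarfs any gene or repeat); signal tracks are averaged per
window with length weighting across intervals straddling a boundary.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .errors import SchemeMismatchError, ValidationError
from .specs import MB, ChromSpec
from .tables import ExpressionTable, FeatureTable, SignalTrack

logger = logging.getLogger("chromoband.features")

__all__ = [
    "WindowScheme",
    "WindowTrack",
    "make_windows",
    "count_features",
    "bin_signal",
    "sum_expression",
    "resample_step",
]


@dataclasses.dataclass(frozen=True)
class WindowScheme:
    """A tiling of one chromosome into contiguous windows (bp edges)."""

    chrom: str
    edges_bp: tuple

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges_bp, dtype=float)
        if len(edges) < 2 or (np.diff(edges) <= 0).any() or edges[0] != 0:
            raise ValidationError("edges must start at 0 and strictly increase")
        object.__setattr__(self, "edges_bp", tuple(float(e) for e in edges))

    @property
    def edges(self) -> np.ndarray:
        return np.asarray(self.edges_bp, dtype=float)

    @property
    def n_windows(self) -> int:
        return len(self.edges_bp) - 1

    @property
    def starts(self) -> np.ndarray:
        return self.edges[:-1]

    @property
    def ends(self) -> np.ndarray:
        return self.edges[1:]

    @property
    def widths_bp(self) -> np.ndarray:
        return np.diff(self.edges)

    @property
    def length_bp(self) -> float:
        return self.edges_bp[-1]

    def assign(self, positions_bp) -> np.ndarray:
        """Window index per position; half-open windows, last closed."""
        pos = np.asarray(positions_bp, dtype=float)
        if (pos < 0).any() or (pos > self.length_bp).any():
            bad = np.flatnonzero((pos < 0) | (pos > self.length_bp))
            raise ValidationError(
                f"{len(bad)} positions outside [0, {self.length_bp}] bp "
                f"(indices {list(bad[:10])})"
            )
        idx = np.searchsorted(self.edges, pos, side="right") - 1
        return np.minimum(idx, self.n_windows - 1)

    def compatible_with(self, other: "WindowScheme") -> bool:
        return (
            self.chrom == other.chrom
            and self.n_windows == other.n_windows
            and np.allclose(self.edges, other.edges)
        )


@dataclasses.dataclass
class WindowTrack:
    """One numeric value per window — the common currency of comparisons."""

    scheme: WindowScheme
    values: np.ndarray
    kind: str = "other"
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.scheme.n_windows:
            raise ValidationError(
                f"track length {len(self.values)} != {self.scheme.n_windows} windows"
            )


def make_windows(
    spec: ChromSpec,
    width_mb: float | None = None,
    n_windows: int | None = None,
) -> WindowScheme:
    """Tile the chromosome by fixed width (last window partial) or count.

    Exactly one of ``width_mb`` / ``n_windows`` must be given.  Width wider
    than the chromosome yields a single window with a warning.
    """
    if (width_mb is None) == (n_windows is None):
        raise ValidationError("give exactly one of width_mb or n_windows")
    L = spec.length_bp
    if width_mb is not None:
        w = int(round(width_mb * MB))
        if w <= 0:
            raise ValidationError("width_mb must be > 0")
        if w >= L:
            if w > L:
                logger.warning(
                    "window width %s bp exceeds chromosome length %s bp; "
                    "using a single window",
                    w,
                    L,
                )
            edges = [0.0, float(L)]
        else:
            edges = list(np.arange(0, L, w, dtype=float))
            if edges[-1] < L:
                edges.append(float(L))
    else:
        if n_windows < 1:
            raise ValidationError("n_windows must be >= 1")
        edges = list(np.linspace(0.0, float(L), n_windows + 1))
    return WindowScheme(spec.name, tuple(edges))


def count_features(
    table: FeatureTable,
    scheme: WindowScheme,
    assign_by: str = "midpoint",
) -> WindowTrack:
    """Count features per window, each feature in exactly one window.

    Records on other chromosomes are dropped with a logged count; records on
    this chromosome must lie within its bounds.
    """
    if assign_by not in ("midpoint", "start"):
        raise ValidationError("assign_by must be 'midpoint' or 'start'")
    df = table.df
    on_chrom = df["chrom"] == scheme.chrom
    n_dropped = int((~on_chrom).sum())
    if n_dropped:
        logger.info("count_features: dropped %d records on other chromosomes", n_dropped)
    df = df[on_chrom]
    out = df.index[(df["start"] < 0) | (df["end"] > scheme.length_bp)]
    if len(out):
        raise ValidationError(
            f"{len(out)} features outside chromosome bounds (rows {list(out[:10])})"
        )
    classes = df["feature_class"].unique()
    kind = f"{classes[0]}_count" if len(classes) == 1 else "feature_count"
    if len(df) == 0:
        return WindowTrack(scheme, np.zeros(scheme.n_windows), kind=kind)
    if assign_by == "midpoint":
        pos = (df["start"].to_numpy() + df["end"].to_numpy()) / 2.0
    else:
        pos = df["start"].to_numpy().astype(float)
    idx = scheme.assign(pos)
    counts = np.bincount(idx, minlength=scheme.n_windows).astype(float)
    return WindowTrack(scheme, counts, kind=kind, units="count")


def resample_step(
    src_edges: np.ndarray, src_values: np.ndarray, dst_edges: np.ndarray
) -> np.ndarray:
    """Length-weighted average of a step function over destination windows.

    The step function is ``src_values[i]`` on ``[src_edges[i], src_edges[i+1])``
    and 0 outside its span.  Denominators are the full destination widths,
    so uncovered stretches count as zero signal.
    """
    src_edges = np.asarray(src_edges, dtype=float)
    src_values = np.asarray(src_values, dtype=float)
    dst_edges = np.asarray(dst_edges, dtype=float)
    s, e = src_edges[:-1], src_edges[1:]
    out = np.empty(len(dst_edges) - 1)
    for j in range(len(out)):
        ws, we = dst_edges[j], dst_edges[j + 1]
        ov = np.clip(np.minimum(e, we) - np.maximum(s, ws), 0.0, None)
        out[j] = (src_values * ov).sum() / (we - ws)
    return out


def bin_signal(track: SignalTrack, scheme: WindowScheme) -> WindowTrack:
    """Per-window mean signal, length-weighted across straddling intervals."""
    if track.chrom != scheme.chrom:
        raise ValidationError(
            f"track chromosome {track.chrom!r} != scheme {scheme.chrom!r}"
        )
    # SignalTrack validates nonnegativity and non-overlap on construction.
    s = track.start.astype(float)
    e = np.minimum(track.end.astype(float), scheme.length_bp)
    keep = e > s
    out = np.empty(scheme.n_windows)
    edges = scheme.edges
    sv, ev, vv = s[keep], e[keep], track.value[keep]
    for j in range(scheme.n_windows):
        ws, we = edges[j], edges[j + 1]
        ov = np.clip(np.minimum(ev, we) - np.maximum(sv, ws), 0.0, None)
        out[j] = (vv * ov).sum() / (we - ws)
    return WindowTrack(scheme, out, kind="signal_mean", units="mean coverage")


def sum_expression(expr: ExpressionTable, scheme: WindowScheme) -> WindowTrack:
    """Sum expression values of genes per window (grand total conserved)."""
    df = expr.df
    on_chrom = df["chrom"] == scheme.chrom
    n_dropped = int((~on_chrom).sum())
    if n_dropped:
        logger.info("sum_expression: dropped %d genes on other chromosomes", n_dropped)
    df = df[on_chrom]
    if len(df) == 0:
        return WindowTrack(scheme, np.zeros(scheme.n_windows), kind="expression_sum")
    idx = scheme.assign(df["pos"].to_numpy().astype(float))
    sums = np.bincount(idx, weights=df["value"].to_numpy(), minlength=scheme.n_windows)
    return WindowTrack(scheme, sums, kind="expression_sum", units="summed expression")
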