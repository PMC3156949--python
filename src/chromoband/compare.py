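"""Correlation of window tracks: metaphase band profiles against genomic
feature densities, expression sums and interphase signal.

Correlations are Pearson product-moment by default, with the two-sided
p-value from the t transform ``t = r * sqrt((n-2) / (1-r^2))`` on ``n-2``
degrees of freedom (Spearman is available as an option).  No multiple-
testing correction is applied to the matrix, but Benjamini-Hochberg
adjusted values are reported alongside raw p-values for transparency.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, SchemeMismatchError, ValidationError
from .features import WindowTrack, make_windows, resample_step
from .scan import MeanProfile

__all__ = [
    "CorrelationResult",
    "CorrelationMatrix",
    "AlignedComparison",
    "correlate",
    "correlation_matrix",
    "align_metaphase_interphase",
    "profile_to_track",
]


@dataclasses.dataclass(frozen=True)
class CorrelationResult:
    """A correlation coefficient with its significance and sample size."""

    r: float
    p: float
    n: int
    excluded_windows: tuple = ()
    method: str = "pearson"

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValidationError("|r| must be <= 1")


def _included_values(x: WindowTrack, y: WindowTrack, exclusions):
    if not x.scheme.compatible_with(y.scheme):
        raise SchemeMismatchError("tracks are on different window schemes")
    excl = sorted(set(int(i) for i in exclusions))
    for i in excl:
        if not 0 <= i < x.scheme.n_windows:
            raise ValidationError(f"excluded window {i} out of range")
    mask = np.ones(x.scheme.n_windows, dtype=bool)
    mask[excl] = False
    return x.values[mask], y.values[mask], tuple(excl)


def correlate(
    x: WindowTrack,
    y: WindowTrack,
    exclusions: Sequence[int] = (),
    method: str = "pearson",
) -> CorrelationResult:
    """Correlate two window tracks on their shared scheme.

    Requires at least 3 included windows and nonzero variance in both
    tracks.
    """
    xv, yv, excl = _included_values(x, y, exclusions)
    n = len(xv)
    if n < 3:
        raise ValidationError(f"need >= 3 included windows, got {n}")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise DegenerateInputError("zero variance in a track")
    if method == "pearson":
        res = stats.pearsonr(xv, yv)
    elif method == "spearman":
        res = stats.spearmanr(xv, yv)
    else:
        raise ValidationError(f"unknown method {method!r}")
    return CorrelationResult(
        r=float(res.statistic),
        p=float(res.pvalue),
        n=n,
        excluded_windows=excl,
        method=method,
    )


@dataclasses.dataclass
class CorrelationMatrix:
    """Symmetric pairwise correlation table over named tracks."""

    names: list
    r: pd.DataFrame
    p: pd.DataFrame
    n: int
    failures: dict
    method: str = "pearson"

    def to_long_frame(self) -> pd.DataFrame:
        """Upper-triangle pairs with r, raw p and Benjamini-Hochberg q."""
        rows = []
        for i, a in enumerate(self.names):
            for b in self.names[i + 1 :]:
                rows.append(
                    {
                        "track_a": a,
                        "track_b": b,
                        "r": self.r.loc[a, b],
                        "p": self.p.loc[a, b],
                    }
                )
        out = pd.DataFrame(rows)
        if len(out):
            ok = out["p"].notna()
            q = np.full(len(out), np.nan)
            if ok.any():
                q[ok.to_numpy()] = stats.false_discovery_control(
                    out.loc[ok, "p"].to_numpy()
                )
            out["q_bh"] = q
        return out


def correlation_matrix(
    tracks: Mapping[str, WindowTrack],
    exclusions: Sequence[int] = (),
    method: str = "pearson",
) -> CorrelationMatrix:
    """All pairwise correlations among named tracks on one shared scheme.

    Degenerate cells (e.g. zero-variance tracks) are recorded as missing
    with the reason rather than aborting the whole matrix.
    """
    names = list(tracks)
    if not names:
        raise ValidationError("no tracks given")
    first = tracks[names[0]]
    r = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    p = pd.DataFrame(np.full((len(names), len(names)), np.nan), index=names, columns=names)
    failures: dict = {}
    n_used = first.scheme.n_windows - len(set(exclusions))
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            try:
                res = correlate(tracks[a], tracks[b], exclusions, method=method)
                r.loc[a, b] = r.loc[b, a] = res.r
                p.loc[a, b] = p.loc[b, a] = res.p
                n_used = res.n
            except (DegenerateInputError, SchemeMismatchError, ValidationError) as exc:
                r.loc[a, b] = r.loc[b, a] = np.nan
                failures[(a, b)] = str(exc)
    return CorrelationMatrix(
        names=names, r=r, p=p, n=n_used, failures=failures, method=method
    )


def profile_to_track(profile: MeanProfile, channel: str = "green") -> WindowTrack:
    """View a mean scan profile as a window track on the equal-window scheme."""
    scheme = make_windows(profile.spec, n_windows=profile.spec.n_scan_windows)
    values = profile.mean_green if channel == "green" else profile.mean_red
    return WindowTrack(scheme, values, kind="scan_profile", units=f"% max ({profile.stat})")


@dataclasses.dataclass
class AlignedComparison:
    """Paired metaphase/interphase window values with their correlation."""

    pairs: pd.DataFrame
    correlation: CorrelationResult
    resampled: bool


def align_metaphase_interphase(
    meta: MeanProfile,
    inter: WindowTrack,
    exclusions: Sequence[int] = (),
    method: str = "pearson",
) -> AlignedComparison:
    """Align an interphase window track with a metaphase scan profile.

    If the interphase track uses a different tiling (e.g. fixed 10-Mb
    windows against 25 equal scan windows), it is resampled onto the scan
    scheme by length-weighted averaging of its step function.
    """
    if inter.scheme.chrom != meta.spec.name:
        raise ValidationError(
            f"different chromosomes: {inter.scheme.chrom!r} vs {meta.spec.name!r}"
        )
    meta_track = profile_to_track(meta)
    scheme = meta_track.scheme
    resampled = not inter.scheme.compatible_with(scheme)
    if resampled:
        values = resample_step(inter.scheme.edges, inter.values, scheme.edges)
        inter_aligned = WindowTrack(scheme, values, kind=inter.kind, units=inter.units)
    else:
        inter_aligned = WindowTrack(scheme, inter.values, kind=inter.kind, units=inter.units)
    res = correlate(meta_track, inter_aligned, exclusions, method=method)
    pairs = pd.DataFrame(
        {
            "window_start_bp": scheme.starts,
            "window_end_bp": scheme.ends,
            "metaphase": meta_track.values,
            "interphase": inter_aligned.values,
        }
    )
    return AlignedComparison(pairs=pairs, correlation=res, resampled=resampled)
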