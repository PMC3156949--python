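"""Chromosome geometry, ground-truth band models and arm-stretch warps.

A :class:`ChromSpec` fixes the genomic geometry everything else is expressed
against: the physical length of the chromosome in megabases, the centromere
position, the number of equal scan windows used when binning fluorescence
profiles, and the window width used when binning genomic features.  The
human chromosome 1 geometry used throughout (247 Mb, centromere at 120 Mb,
25 scan windows of nominally 10 Mb) is available as :data:`CHR1`.

A :class:`BandModel` is the simulator's ground truth: a baseline intensity
plus a sum of smooth unimodal bumps, one per immunofluorescent band.  Bands
are Gaussian in genomic coordinate, parameterised by centre, full width at
half maximum and amplitude, which matches the 10-50 Mb scale of the bands
the model emulates while keeping evaluation closed-form.

A :class:`WarpModel` maps true genomic position to arc-length fraction along
a rendered chromatid.  Chromosome arms stretch by different factors during
spreading, so the map is piecewise linear per arm: one stretch factor for
the p arm and one for the q arm, renormalised so pter maps to 0 and qter to
1.  The map is strictly increasing and invertible.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from .errors import ValidationError

__all__ = ["ChromSpec", "Band", "BandModel", "WarpModel", "CHR1"]

MB = 1_000_000  # base pairs per megabase, exact


@dataclasses.dataclass(frozen=True)
class ChromSpec:
    """Genomic geometry of one chromosome.

    Parameters
    ----------
    name
        Chromosome label, e.g. ``"chr1"``.
    length_mb
        Physical length in megabases (> 0).
    centromere_mb
        Centromere position in megabases, strictly inside the chromosome.
    n_scan_windows
        Number of equal windows the scan profile is binned into.
    feature_window_mb
        Window width (Mb) used when binning genomic features.
    """

    name: str
    length_mb: float
    centromere_mb: float
    n_scan_windows: int = 25
    feature_window_mb: float = 10.0

    def __post_init__(self) -> None:
        if not self.length_mb > 0:
            raise ValidationError("length_mb must be > 0")
        if not 0 < self.centromere_mb < self.length_mb:
            raise ValidationError(
                "centromere_mb must satisfy 0 < centromere_mb < length_mb"
            )
        if self.n_scan_windows < 2:
            raise ValidationError("n_scan_windows must be >= 2")
        if not self.feature_window_mb > 0:
            raise ValidationError("feature_window_mb must be > 0")

    @property
    def length_bp(self) -> int:
        return int(round(self.length_mb * MB))

    @property
    def centromere_bp(self) -> int:
        return int(round(self.centromere_mb * MB))

    @property
    def scan_window_width_mb(self) -> float:
        """Width of one of the equal scan windows (e.g. 247/25 = 9.88 Mb)."""
        return self.length_mb / self.n_scan_windows

    def scan_window_of(self, position_mb: float) -> int:
        """Index of the scan window containing ``position_mb``.

        Windows are half-open, the last window closed at qter.
        """
        if not 0 <= position_mb <= self.length_mb:
            raise ValidationError(
                f"position {position_mb} Mb outside [0, {self.length_mb}]"
            )
        idx = int(position_mb / self.scan_window_width_mb)
        return min(idx, self.n_scan_windows - 1)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ChromSpec":
        return cls(**d)


#: Human chromosome 1 geometry: 247 Mb, centromere at 120 Mb, 25 scan windows.
CHR1 = ChromSpec("chr1", 247.0, 120.0)

# FWHM = 2*sqrt(2 ln 2) * sigma for a Gaussian bump
_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclasses.dataclass(frozen=True)
class Band:
    """One enriched band: a Gaussian bump in genomic coordinate."""

    center_mb: float
    width_mb: float  # full width at half maximum
    amplitude: float

    def __post_init__(self) -> None:
        if self.width_mb <= 0:
            raise ValidationError("band width_mb must be > 0")
        if self.amplitude < 0:
            raise ValidationError("band amplitude must be >= 0")

    @property
    def sigma_mb(self) -> float:
        return self.width_mb * _FWHM_TO_SIGMA


@dataclasses.dataclass(frozen=True)
class BandModel:
    """Ground-truth band profile: baseline plus a sum of Gaussian bands.

    ``centromere_gap`` zeroes all band contributions (leaving the baseline)
    within ``gap_halfwidth_mb`` of the centromere, emulating the unstained
    centric heterochromatin block.
    """

    bands: tuple[Band, ...] = ()
    baseline: float = 0.0
    centromere_gap: bool = True
    gap_halfwidth_mb: float = 5.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "bands",
            tuple(b if isinstance(b, Band) else Band(*b) for b in self.bands),
        )
        if self.baseline < 0:
            raise ValidationError("baseline must be >= 0")
        if self.gap_halfwidth_mb < 0:
            raise ValidationError("gap_halfwidth_mb must be >= 0")

    def validate_against(self, spec: ChromSpec) -> None:
        for b in self.bands:
            if not 0 <= b.center_mb <= spec.length_mb:
                raise ValidationError(
                    f"band center {b.center_mb} Mb outside [0, {spec.length_mb}]"
                )

    def to_dict(self) -> dict:
        return {
            "bands": [[b.center_mb, b.width_mb, b.amplitude] for b in self.bands],
            "baseline": self.baseline,
            "centromere_gap": self.centromere_gap,
            "gap_halfwidth_mb": self.gap_halfwidth_mb,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BandModel":
        return cls(
            bands=tuple(Band(*b) for b in d.get("bands", [])),
            baseline=d.get("baseline", 0.0),
            centromere_gap=d.get("centromere_gap", True),
            gap_halfwidth_mb=d.get("gap_halfwidth_mb", 5.0),
        )


@dataclasses.dataclass(frozen=True)
class WarpModel:
    """Piecewise-linear map from genomic position (Mb) to arc fraction [0, 1].

    Each arm carries one stretch factor; the map is renormalised so that
    pter maps to 0 and qter to 1, with the centromere landing at the arc
    fraction implied by the relative stretched arm lengths.
    """

    spec: ChromSpec
    stretch_p: float = 1.0
    stretch_q: float = 1.0

    def __post_init__(self) -> None:
        if self.stretch_p <= 0 or self.stretch_q <= 0:
            raise ValidationError("stretch factors must be > 0 (monotone warp)")

    @property
    def centromere_fraction(self) -> float:
        """Arc fraction of the centromere on the rendered chromatid."""
        cen = self.spec.centromere_mb
        p = cen * self.stretch_p
        q = (self.spec.length_mb - cen) * self.stretch_q
        return p / (p + q)

    def forward(self, position_mb):
        """Genomic position (Mb) -> arc fraction in [0, 1]. Vectorised."""
        pos = np.asarray(position_mb, dtype=float)
        L = self.spec.length_mb
        cen = self.spec.centromere_mb
        fc = self.centromere_fraction
        out = np.where(
            pos <= cen,
            fc * pos / cen,
            fc + (1.0 - fc) * (pos - cen) / (L - cen),
        )
        return out if out.ndim else float(out)

    def inverse(self, arc_fraction):
        """Arc fraction in [0, 1] -> genomic position (Mb). Vectorised."""
        f = np.asarray(arc_fraction, dtype=float)
        L = self.spec.length_mb
        cen = self.spec.centromere_mb
        fc = self.centromere_fraction
        out = np.where(
            f <= fc,
            cen * f / fc,
            cen + (L - cen) * (f - fc) / (1.0 - fc),
        )
        return out if out.ndim else float(out)

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "stretch_p": self.stretch_p,
            "stretch_q": self.stretch_q,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WarpModel":
        return cls(
            spec=ChromSpec.from_dict(d["spec"]),
            stretch_p=d.get("stretch_p", 1.0),
            stretch_q=d.get("stretch_q", 1.0),
        )
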