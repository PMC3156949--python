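"""Readers and writers for the formats the pipeline owns.

All text outputs are TSV with fixed headers, floats serialized at 9
significant digits ('.' for missing), so reruns with identical seeds are
byte-stable.  Every derived output gets a JSON metadata sidecar
(``<file>.json``) recording the parameters that produced it.

BED and bedGraph parsing is line-by-line so that malformed input can be
reported with its line number, and overlapping bedGraph intervals with both
offending lines.  Reading is gzip-transparent (``.gz`` suffix).
"""

from __future__ import annotations

import dataclasses
import gzip
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

from .errors import ParseError, ValidationError
from .features import WindowScheme, WindowTrack
from .scan import MeanProfile, MedialPath, RawScan, WindowProfile
from .specs import ChromSpec
from .synth import ChromImage, ImageTruth
from .tables import ExpressionTable, FeatureTable, SignalTrack

__all__ = [
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_expression",
    "write_expression",
    "read_window_track",
    "write_window_track",
    "read_mean_profile",
    "write_mean_profile",
    "read_window_profile",
    "write_window_profile",
    "write_raw_scan",
    "read_path_tsv",
    "write_image",
    "read_image",
    "read_chrom_spec",
    "write_chrom_spec",
    "fmt_float",
]

MISSING = "."


def fmt_float(v) -> str:
    """Serialize a float at 9 significant digits ('.' for missing)."""
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return MISSING
    return format(float(v), ".9g")


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _skip(line: str) -> bool:
    s = line.strip()
    return not s or s.startswith("#") or s.startswith("track") or s.startswith("browser")


# ---------------------------------------------------------------------------
# BED / bedGraph


def read_bed(path, chrom_length_bp: int | None = None) -> FeatureTable:
    """Read a BED3+ file; column 4 (name), when present, is the feature class."""
    records = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _skip(line):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno}: fewer than 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-numeric coordinates"
                ) from None
            if start >= end:
                raise ParseError(f"{path}: line {lineno}: start >= end ({start} >= {end})")
            if start < 0:
                raise ParseError(f"{path}: line {lineno}: negative start")
            fclass = parts[3] if len(parts) > 3 and parts[3] not in ("", MISSING) else "other"
            records.append((parts[0], start, end, fclass))
    df = pd.DataFrame(records, columns=["chrom", "start", "end", "feature_class"])
    return FeatureTable(df, chrom_length_bp=chrom_length_bp)


def write_bed(table: FeatureTable, path) -> None:
    with open(path, "wt") as fh:
        for row in table.df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.feature_class}\n")


def read_bedgraph(path) -> SignalTrack:
    """Read a bedGraph file into a signal track; overlapping intervals error."""
    chroms, starts, ends, values, lines = [], [], [], [], []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _skip(line):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}: line {lineno}: fewer than 4 bedGraph columns")
            try:
                start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-numeric field") from None
            if start >= end:
                raise ParseError(f"{path}: line {lineno}: start >= end")
            if value < 0:
                raise ParseError(f"{path}: line {lineno}: negative signal value")
            chroms.append(parts[0])
            starts.append(start)
            ends.append(end)
            values.append(value)
            lines.append(lineno)
    if not starts:
        raise ParseError(f"{path}: no data lines")
    if len(set(chroms)) > 1:
        raise ParseError(f"{path}: multiple chromosomes in one track")
    order = np.argsort(starts, kind="stable")
    for a, b in zip(order[:-1], order[1:]):
        if ends[a] > starts[b]:
            raise ParseError(
                f"{path}: overlapping intervals at lines {lines[a]} and {lines[b]}"
            )
    return SignalTrack(
        chroms[0],
        np.asarray(starts)[order],
        np.asarray(ends)[order],
        np.asarray(values)[order],
    )


def write_bedgraph(track: SignalTrack, path) -> None:
    with open(path, "wt") as fh:
        for s, e, v in zip(track.start, track.end, track.value):
            fh.write(f"{track.chrom}\t{s}\t{e}\t{fmt_float(v)}\n")


# ---------------------------------------------------------------------------
# expression TSV


def read_expression(path) -> ExpressionTable:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    expected = ["gene_id", "chrom", "pos", "value"]
    if list(df.columns) != expected:
        raise ParseError(f"{path}: expected header {expected}, got {list(df.columns)}")
    return ExpressionTable(df)


def write_expression(expr: ExpressionTable, path) -> None:
    with open(path, "wt") as fh:
        fh.write("gene_id\tchrom\tpos\tvalue\n")
        for row in expr.df.itertuples(index=False):
            fh.write(f"{row.gene_id}\t{row.chrom}\t{int(row.pos)}\t{fmt_float(row.value)}\n")


# ---------------------------------------------------------------------------
# window tracks and profiles


def _write_sidecar(path, meta: dict) -> None:
    with open(str(path) + ".json", "wt") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _read_sidecar(path) -> dict:
    p = Path(str(path) + ".json")
    if p.exists():
        return json.loads(p.read_text())
    return {}


def write_window_track(track: WindowTrack, path) -> None:
    with open(path, "wt") as fh:
        fh.write("window_start_bp\twindow_end_bp\tvalue\n")
        for s, e, v in zip(track.scheme.starts, track.scheme.ends, track.values):
            fh.write(f"{fmt_float(s)}\t{fmt_float(e)}\t{fmt_float(v)}\n")
    _write_sidecar(
        path,
        {"chrom": track.scheme.chrom, "kind": track.kind, "units": track.units},
    )


def read_window_track(path) -> WindowTrack:
    df = pd.read_csv(path, sep="\t", na_values=[MISSING])
    meta = _read_sidecar(path)
    edges = tuple(df["window_start_bp"].tolist() + [float(df["window_end_bp"].iloc[-1])])
    scheme = WindowScheme(meta.get("chrom", "chr?"), edges)
    return WindowTrack(
        scheme,
        df["value"].to_numpy(),
        kind=meta.get("kind", "other"),
        units=meta.get("units", ""),
    )


def write_window_profile(profile: WindowProfile, path) -> None:
    spec = profile.spec
    n = spec.n_scan_windows
    w = spec.length_mb / n
    with open(path, "wt") as fh:
        fh.write("window_start_mb\twindow_end_mb\tgreen\tred\tn_samples\n")
        for i in range(n):
            ns = int(profile.n_samples[i]) if profile.n_samples is not None else 0
            fh.write(
                f"{fmt_float(i * w)}\t{fmt_float(min((i + 1) * w, spec.length_mb))}\t"
                f"{fmt_float(profile.green[i])}\t{fmt_float(profile.red[i])}\t{ns}\n"
            )
    _write_sidecar(
        path,
        {
            "spec": spec.to_dict(),
            "stat": profile.stat,
            "chromatid_id": profile.chromatid_id,
        },
    )


def read_window_profile(path) -> WindowProfile:
    df = pd.read_csv(path, sep="\t", na_values=[MISSING])
    meta = _read_sidecar(path)
    if "spec" not in meta:
        raise ParseError(f"{path}: missing JSON sidecar with the chromosome spec")
    spec = ChromSpec.from_dict(meta["spec"])
    return WindowProfile(
        green=df["green"].to_numpy(),
        red=df["red"].to_numpy(),
        spec=spec,
        stat=meta.get("stat", "sum"),
        chromatid_id=meta.get("chromatid_id", ""),
        n_samples=df["n_samples"].to_numpy(),
    )


def write_mean_profile(profile: MeanProfile, path) -> None:
    spec = profile.spec
    n = spec.n_scan_windows
    w = spec.length_mb / n
    with open(path, "wt") as fh:
        fh.write("window_start_mb\twindow_end_mb\tmean_green\tsd_green\tmean_red\tsd_red\n")
        for i in range(n):
            fh.write(
                f"{fmt_float(i * w)}\t{fmt_float(min((i + 1) * w, spec.length_mb))}\t"
                f"{fmt_float(profile.mean_green[i])}\t{fmt_float(profile.sd_green[i])}\t"
                f"{fmt_float(profile.mean_red[i])}\t{fmt_float(profile.sd_red[i])}\n"
            )
    _write_sidecar(
        path,
        {
            "spec": spec.to_dict(),
            "stat": profile.stat,
            "n_chromatids": profile.n_chromatids,
            "background_window": profile.background_window,
            "background": profile.background,
        },
    )


def read_mean_profile(path) -> MeanProfile:
    df = pd.read_csv(path, sep="\t", na_values=[MISSING])
    meta = _read_sidecar(path)
    if "spec" not in meta:
        raise ParseError(f"{path}: missing JSON sidecar with the chromosome spec")
    return MeanProfile(
        mean_green=df["mean_green"].to_numpy(),
        sd_green=df["sd_green"].to_numpy(),
        mean_red=df["mean_red"].to_numpy(),
        sd_red=df["sd_red"].to_numpy(),
        n_chromatids=int(meta.get("n_chromatids", 1)),
        spec=ChromSpec.from_dict(meta["spec"]),
        stat=meta.get("stat", "sum"),
        background_window=meta.get("background_window"),
        background=meta.get("background"),
    )


def write_raw_scan(scan: RawScan, path) -> None:
    with open(path, "wt") as fh:
        fh.write("arc_fraction\tmean_green\tmean_red\tmean_blue\n")
        for f, g, r, b in zip(
            scan.arc_fraction, scan.mean_green, scan.mean_red, scan.mean_blue
        ):
            fh.write(f"{fmt_float(f)}\t{fmt_float(g)}\t{fmt_float(r)}\t{fmt_float(b)}\n")
    _write_sidecar(path, {"width_px": scan.width_px, "image_id": scan.image_id})


def read_path_tsv(path) -> MedialPath:
    """Read a manual medial-axis polyline as TSV (x=col, y=row per line)."""
    pts = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _skip(line):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ParseError(f"{path}: line {lineno}: expected 'x<TAB>y'")
            try:
                x, y = float(parts[0]), float(parts[1])
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-numeric coordinate") from None
            pts.append((y, x))  # (row, col)
    if len(pts) < 2:
        raise ParseError(f"{path}: fewer than 2 path vertices")
    return MedialPath.from_points(np.asarray(pts, dtype=float))


# ---------------------------------------------------------------------------
# images and specs


def write_image(image: ChromImage, path, preview_png=None) -> None:
    """Write a multi-channel float TIFF (+ optional 8-bit RGB PNG preview)
    and, when truth is attached, a JSON truth sidecar next to the TIFF."""
    arr = image.rgb.astype(np.float32)
    tifffile.imwrite(str(path), arr, photometric="rgb")
    if image.truth is not None:
        _write_sidecar(
            path, {"truth": image.truth.to_dict(), "pixel_size_um": image.pixel_size_um}
        )
    if preview_png is not None:
        rgb8 = np.clip(np.round(arr * 255), 0, 255).astype(np.uint8)
        Image.fromarray(rgb8, mode="RGB").save(str(preview_png))


def read_image(path) -> ChromImage:
    arr = tifffile.imread(str(path)).astype(np.float32)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ParseError(f"{path}: expected an (H, W, 3) image")
    meta = _read_sidecar(path)
    truth = ImageTruth.from_dict(meta["truth"]) if "truth" in meta else None
    return ChromImage(
        green=arr[..., 1],
        red=arr[..., 0],
        blue=arr[..., 2],
        pixel_size_um=float(meta.get("pixel_size_um", 0.1)),
        truth=truth,
        image_id=Path(str(path)).stem,
    )


def read_chrom_spec(path) -> ChromSpec:
    with open(path, "rt") as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ParseError(f"{path}: expected a YAML mapping")
    return ChromSpec.from_dict(d)


def write_chrom_spec(spec: ChromSpec, path) -> None:
    with open(path, "wt") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=True)
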