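"""Profile-overlay figures (metaphase scan profile vs window tracks)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .compare import profile_to_track
from .scan import MeanProfile
from .specs import MB

__all__ = ["plot_profile_overlay"]


def plot_profile_overlay(profile: MeanProfile, tracks=None, path=None):
    """Plot the mean band profile (line +/- SD) with window tracks as bars.

    ``tracks`` maps labels to :class:`~chromoband.features.WindowTrack`
    objects (each rescaled to its own maximum for overlay).  Returns the
    matplotlib figure; saves to ``path`` when given.
    """
    meta = profile_to_track(profile)
    centers = (meta.scheme.starts + meta.scheme.ends) / 2.0 / MB
    fig, ax = plt.subplots(figsize=(9, 4))
    if tracks:
        width = float(np.diff(meta.scheme.edges).min()) / MB * 0.8 / len(tracks)
        for k, (label, tr) in enumerate(tracks.items()):
            tc = (tr.scheme.starts + tr.scheme.ends) / 2.0 / MB
            vmax = tr.values.max() if tr.values.max() > 0 else 1.0
            ax.bar(
                tc + (k - (len(tracks) - 1) / 2) * width,
                tr.values / vmax,
                width=width,
                alpha=0.5,
                label=label,
            )
    vmax = meta.values.max() if meta.values.max() > 0 else 1.0
    ax.errorbar(
        centers,
        meta.values / vmax,
        yerr=profile.sd_green / vmax,
        color="darkgreen",
        lw=1.5,
        capsize=2,
        label=f"band profile (n={profile.n_chromatids})",
    )
    ax.axvline(profile.spec.centromere_mb, color="gray", ls=":", label="centromere")
    ax.set_xlabel("position (Mb)")
    ax.set_ylabel("relative level")
    ax.set_title(profile.spec.name)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(str(path), dpi=150)
    return fig
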