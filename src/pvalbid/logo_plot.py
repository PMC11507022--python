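"""Minimal stacked-letter frequency plot (logo-style convenience)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .motifs import PositionProfile


def plot_profiles(
    profiles: list[PositionProfile], path: str | Path,
    scale_by_information: bool = True,
) -> None:
    """Stacked letters per position, heights scaled by frequency times
    (optionally) column information content."""
    fig, ax = plt.subplots(figsize=(max(6, len(profiles) / 6), 3))
    for p in profiles:
        height_scale = p.information_bits if scale_by_information else 1.0
        bottom = 0.0
        for res, freq in sorted(p.frequencies.items(), key=lambda kv: kv[1]):
            h = freq * height_scale
            ax.text(
                p.position, bottom + h / 2, res,
                ha="center", va="center",
                fontsize=6 + 10 * freq, family="monospace",
            )
            bottom += h
    ax.set_xlim(0, len(profiles) + 1)
    ax.set_ylim(0, 4.5)
    ax.set_xlabel("canonical position")
    ax.set_ylabel("bits")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
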