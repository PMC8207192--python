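"""Genome-scan plots: per-variant DSI scatter with fitted DSI/ADSI curves.

Mirrors the standard presentation of bulked-segregant scans: one panel per
genome (chromosomes concatenated along x, alternating shading) or per
chromosome, grey points for per-SNV DSI, a red fitted DSI curve, a blue
fitted ADSI curve, and the candidate region shaded.
"""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .mapping import retained_snvs


def plot_genome_scan(mapping, path=None, chrom: Optional[str] = None):
    """Plot a fitted PopulationMapping; returns the matplotlib figure."""
    frame = mapping.frame
    snvs = retained_snvs(frame)
    curves = [c for c in mapping.curves if chrom is None or c.chrom == chrom]
    chrom_names = [c.chrom for c in curves]
    if chrom is not None:
        snvs = snvs[snvs["chrom"] == chrom]

    # cumulative x offsets so chromosomes sit side by side
    offsets, cum = {}, 0
    for c in chrom_names:
        offsets[c] = cum
        span = snvs.loc[snvs["chrom"] == c, "pos"]
        cum += int(span.max()) + 1 if len(span) else 1

    fig, ax = plt.subplots(figsize=(14, 4) if chrom is None else (8, 4))
    for i, c in enumerate(chrom_names):
        sub = snvs[snvs["chrom"] == c]
        x = sub["pos"].to_numpy() + offsets[c]
        ax.scatter(x, sub["dsi"], s=3, c="0.75" if i % 2 else "0.55", rasterized=True)
    for curve in curves:
        if len(curve.points) == 0:
            continue
        x = curve.points["midpoint_bp"].to_numpy() + offsets[curve.chrom]
        ax.plot(x, curve.points["mean_dsi"], color="red", lw=1.2, label="DSI")
        ax.plot(x, curve.points["mean_adsi"], color="blue", lw=1.2, label="ADSI")
    region = mapping.region
    if chrom is None or region.chrom == chrom:
        x0 = region.start_bp + offsets.get(region.chrom, 0)
        x1 = region.end_bp + offsets.get(region.chrom, 0)
        ax.axvspan(x0, x1, color="gold", alpha=0.25, label="candidate region")
    ax.axhline(0.0, color="black", lw=0.5)
    ax.set_ylim(-1.05, 1.05)
    ax.set_ylabel("delta SNP index")
    ax.set_xlabel("position (bp)" if chrom else "chromosome")
    if chrom is None:
        ticks = [offsets[c] + 0.5 * (offsets.get(chrom_names[i + 1], cum) - offsets[c])
                 for i, c in enumerate(chrom_names[:-1])] + (
            [offsets[chrom_names[-1]] + 0.5 * (cum - offsets[chrom_names[-1]])]
            if chrom_names else []
        )
        ax.set_xticks(ticks)
        ax.set_xticklabels(chrom_names, rotation=90, fontsize=7)
    handles, labels = ax.get_legend_handles_labels()
    seen = dict(zip(labels, handles))
    ax.legend(seen.values(), seen.keys(), loc="upper right", fontsize=8)
    title = f"{mapping.population_id} — window {mapping.window_n} SNVs"
    if mapping.zero_centered:
        title += " (zero-centered)"
    ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
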