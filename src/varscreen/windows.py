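"""Windowed SNV density: counts per fixed-size sector along each contig.

Windows are per-contig, 0-based half-open, tiling the contig without gaps or
overlaps; the final window may be short.  A variant at 1-based position p
falls in window floor((p - 1) / window_size).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import GenomeIndex, ModelError, VariantClass, VariantSet

DEFAULT_WINDOW_SIZE = 50_000


def snv_window_counts(
    vset: VariantSet,
    samples_carrying: Sequence[str],
    genome: Optional[GenomeIndex] = None,
    window_size: int = DEFAULT_WINDOW_SIZE,
) -> pd.DataFrame:
    """Count SNVs carried by >= 1 of ``samples_carrying`` per window.

    Returns a DataFrame with columns (contig, start, end, count); the sum of
    counts equals the number of SNVs counted.
    """
    if window_size < 1:
        raise ModelError("window_size must be >= 1")
    genome = genome if genome is not None else vset.genome
    unknown = set(samples_carrying) - set(vset.samples)
    if unknown:
        raise ModelError(f"unknown sample name(s): {sorted(unknown)}")
    rows = []
    index: dict[tuple[str, int], int] = {}
    for name, length in genome.contigs:
        n_windows = (length + window_size - 1) // window_size
        for w in range(n_windows):
            index[(name, w)] = len(rows)
            rows.append(
                {
                    "contig": name,
                    "start": w * window_size,
                    "end": min((w + 1) * window_size, length),
                    "count": 0,
                }
            )
    for rec in vset.records:
        if rec.variant_class is not VariantClass.SNV:
            continue
        if not any(rec.carried_by(s) for s in samples_carrying):
            continue
        rows[index[(rec.contig, (rec.pos - 1) // window_size)]]["count"] += 1
    return pd.DataFrame(rows, columns=["contig", "start", "end", "count"])


def write_window_table(counts: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    counts.to_csv(path, sep="\t", index=False)
    return path


def export_circular_plot(
    counts: pd.DataFrame,
    path: str | Path,
    label: str = "SNVs per sector",
    color: str = "#e8b821",
) -> tuple[Path, Path]:
    """Render a circular (polar) bar plot of window counts and its TSV.

    One bar per window, ordered by genome coordinate; bars are labelled with
    absolute counts.  The TSV written alongside the image is the testable
    artifact.  Raises on an empty window table.
    """
    if counts.empty:
        raise ModelError("cannot plot an empty window table")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    tsv_path = path.with_suffix(".tsv")
    write_window_table(counts, tsv_path)

    values = counts["count"].to_numpy()
    n = len(values)
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    width = 2.0 * np.pi / n * 0.9
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(7, 7))
    ax.bar(theta, values, width=width, bottom=0.0, color=color, edgecolor="none")
    top = max(int(values.max()), 1)
    for t, v in zip(theta, values):
        if v > 0:
            ax.text(t, v + top * 0.04, str(int(v)), ha="center", va="center",
                    fontsize=6)
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title(label)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path, tsv_path
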