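"""Color-coded per-residue annotation heatmap.

One colored cell per position, wrapped into rows: functional pink,
structural metallic blue, adaptable yellow, unlabeled white.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import ListedColormap

from .classify import AnnotationTrack
from .errors import EmptyInputError

PALETTE = {
    "functional": "#f36ba2",   # pink
    "structural": "#4f6d8f",   # metallic blue
    "adaptable": "#ffd42a",    # yellow
    "unlabeled": "#ffffff",    # white
}
_LABEL_CODE = {label: i for i, label in enumerate(PALETTE)}


def label_color(label: str) -> str:
    """Hex color assigned to an FSA label."""
    return PALETTE[label]


def render_heatmap(
    track: AnnotationTrack, out: str | Path, wrap: int = 50
) -> Path:
    """Render the annotation track as a wrapped single-channel heatmap.

    Raises
    ------
    EmptyInputError
        For an empty track.
    OSError
        If the output path is unwritable.
    """
    if track.L == 0:
        raise EmptyInputError("cannot render an empty annotation track")
    codes = np.array([_LABEL_CODE[l] for l in track.labels], dtype=float)
    nrows = int(np.ceil(track.L / wrap))
    grid = np.full(nrows * wrap, np.nan)
    grid[: track.L] = codes
    grid = grid.reshape(nrows, wrap)

    cmap = ListedColormap(list(PALETTE.values()))
    cmap.set_bad("#dddddd")
    fig, ax = plt.subplots(figsize=(max(6, wrap * 0.18), max(1.2, nrows * 0.4)))
    ax.imshow(grid, cmap=cmap, vmin=-0.5, vmax=len(PALETTE) - 0.5, aspect="auto")
    ax.set_yticks(range(nrows))
    ax.set_yticklabels([str(r * wrap + 1) for r in range(nrows)], fontsize=7)
    ax.set_xticks([])
    ax.set_ylabel("position")
    for code, (label, color) in enumerate(PALETTE.items()):
        ax.plot([], [], "s", color=color, markeredgecolor="0.5", label=label)
    ax.legend(loc="upper center", bbox_to_anchor=(0.5, -0.08), ncol=4, fontsize=7)
    # thin grid lines make single cells countable
    ax.set_xticks(np.arange(-0.5, wrap, 1), minor=True)
    ax.set_yticks(np.arange(-0.5, nrows, 1), minor=True)
    ax.grid(which="minor", color="0.85", linewidth=0.3)
    ax.tick_params(which="minor", length=0)
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out
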