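"""Recombination summaries, pedigree-error flags and block-image rendering.

On a chromosome of known genetic length, each paternal meiosis carries
roughly Poisson(length in Morgans) crossovers; an offspring whose block
structure implies far more strand switches than that points at a pedigree
error (it is not actually a half-sib of the family) or a blocking failure.
The block image mirrors the familiar two-colour strand-of-origin plot used
to eyeball phasing quality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image

from .blocking import U, BlockMatrix


def recombination_counts(blocks: BlockMatrix) -> pd.Series:
    """Strand switches per offspring, ignoring unknown cells.

    A transition is counted between the nearest flanking non-U codes, so a
    P..U..M run counts one switch across the gap.
    """
    counts = {}
    for ind, row in zip(blocks.individuals, blocks.codes):
        known = row[row != U]
        counts[ind] = int((known[1:] != known[:-1]).sum()) if len(known) else 0
    return pd.Series(counts, name="recombinations", dtype=int)


@dataclass
class RecombinationSummary:
    counts: pd.Series
    expected: float
    flagged: list[str]

    def to_frame(self) -> pd.DataFrame:
        df = self.counts.rename("recombinations").to_frame()
        df["flagged"] = df.index.isin(self.flagged)
        return df.reset_index(names="offspring")


def flag_outliers(
    counts: pd.Series, map_length_cm: float, k: float = 4.0
) -> list[str]:
    """Offspring whose switch count is implausibly high for the map length.

    The expected paternal crossover count is the map length in Morgans; an
    offspring is flagged when its count exceeds expected + k*sqrt(expected)
    (Poisson-motivated, default k = 4).
    """
    expected = map_length_cm / 100.0
    threshold = expected + k * math.sqrt(expected)
    return [str(ind) for ind, c in counts.items() if c > threshold]


def summarize_recombination(
    blocks: BlockMatrix, map_length_cm: float, k: float = 4.0
) -> RecombinationSummary:
    counts = recombination_counts(blocks)
    return RecombinationSummary(
        counts, map_length_cm / 100.0, flag_outliers(counts, map_length_cm, k)
    )


# two strand colours + white for unknown, as in the usual block plots
_COLOURS = {U: (255, 255, 255), 0: (202, 0, 32), 1: (5, 113, 176)}


def render_block_image(
    blocks: BlockMatrix, path, cell_size: int = 1, row_size: int | None = None
) -> None:
    """Write a PNG with one row of pixels per offspring, two colours for the
    strands and white for unknown.  Byte-deterministic for identical input."""
    h, w = blocks.codes.shape
    rgb = np.zeros((h, w, 3), dtype=np.uint8)
    for code, colour in _COLOURS.items():
        rgb[blocks.codes == code] = colour
    if row_size is None:
        row_size = cell_size
    img = Image.fromarray(rgb, mode="RGB")
    if cell_size != 1 or row_size != 1:
        img = img.resize((w * cell_size, h * row_size), Image.NEAREST)
    img.save(path, format="PNG")
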