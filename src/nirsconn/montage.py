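"""Fixed 22-channel prefrontal fNIRS probe geometry and ROI partition.

The default montage covers the prefrontal cortex with 15 optodes (7 sources,
8 detectors) at 30 mm source-detector separation, defining 22 measurement
channels grouped into three regions of interest:

* dlPFC - dorsolateral prefrontal cortex (Brodmann 9/46),
  channels 1-6, 8, 9, 14, 18
* FPC   - frontopolar cortex (Brodmann 10), channels 7, 10-13, 15-17
* OFC   - orbitofrontal cortex (Brodmann 11), channels 19-22

Channel indices are 1-based everywhere user-facing (CH01..CH22); internal
array order is fixed ascending.  MNI coordinates and Brodmann areas are read
from a packaged TSV table.  The table's ``weight`` column (a registration
probability in [0, 1]) is carried as metadata only; no computation consumes
it.  The channel-to-optode pairing is a reconstructed standard 3x5
alternating-grid assignment (the published montage gives only optode counts),
and is likewise metadata only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Literal

import numpy as np
import pandas as pd

from .errors import InvalidChannelError, InvalidParameterError, DataError

ROI = Literal["dlPFC", "FPC", "OFC"]
ROI_NAMES: tuple[str, ...] = ("dlPFC", "FPC", "OFC")

#: 1-based channel indices of each region of interest.
ROI_CHANNELS: dict[str, tuple[int, ...]] = {
    "dlPFC": (1, 2, 3, 4, 5, 6, 8, 9, 14, 18),
    "FPC": (7, 10, 11, 12, 13, 15, 16, 17),
    "OFC": (19, 20, 21, 22),
}

#: Brodmann area -> ROI mapping used to validate the packaged table.
BRODMANN_TO_ROI = {9: "dlPFC", 46: "dlPFC", 10: "FPC", 11: "OFC"}

N_CHANNELS = 22

_ROI_COLOR = {"dlPFC": 1, "FPC": 2, "OFC": 3}


@dataclass(frozen=True)
class Optode:
    id: str
    role: Literal["source", "detector"]


@dataclass(frozen=True)
class Channel:
    index: int
    source_id: str
    detector_id: str
    mni: tuple[int, int, int]
    brodmann_area: int
    roi: str
    registration_weight: float


@dataclass(frozen=True)
class Montage:
    """22-channel prefrontal probe: optodes, channels, separation."""

    optodes: tuple[Optode, ...]
    channels: tuple[Channel, ...]
    separation_mm: float = 30.0

    def __post_init__(self) -> None:
        if len(self.channels) != N_CHANNELS:
            raise DataError(f"expected {N_CHANNELS} channels, got {len(self.channels)}")
        for expect, ch in zip(range(1, N_CHANNELS + 1), self.channels):
            if ch.index != expect:
                raise DataError(f"channels out of order at index {ch.index}")
            if ch.roi != roi_of_index(ch.index):
                raise DataError(f"channel {ch.index}: roi {ch.roi!r} contradicts the fixed partition")
            if BRODMANN_TO_ROI.get(ch.brodmann_area) != ch.roi:
                raise DataError(
                    f"channel {ch.index}: Brodmann {ch.brodmann_area} inconsistent with roi {ch.roi!r}"
                )
            if not 0.0 <= ch.registration_weight <= 1.0:
                raise DataError(f"channel {ch.index}: registration weight outside [0, 1]")
        optode_ids = {o.id for o in self.optodes}
        for ch in self.channels:
            if ch.source_id not in optode_ids or ch.detector_id not in optode_ids:
                raise DataError(f"channel {ch.index} references an unknown optode")

    # -- lookups ------------------------------------------------------------

    def channel(self, index: int) -> Channel:
        if not 1 <= index <= N_CHANNELS:
            raise InvalidChannelError(f"channel index {index} outside 1..{N_CHANNELS}")
        return self.channels[index - 1]

    @property
    def labels(self) -> list[str]:
        return [f"CH{c.index:02d}" for c in self.channels]

    @property
    def coordinates(self) -> np.ndarray:
        """(22, 3) MNI coordinates in channel order."""
        return np.array([c.mni for c in self.channels], dtype=float)

    def roi_indices(self, roi: str) -> np.ndarray:
        """0-based array positions of the channels in ``roi``."""
        if roi not in ROI_CHANNELS:
            raise InvalidParameterError(f"unknown ROI {roi!r}")
        return np.array(ROI_CHANNELS[roi], dtype=int) - 1

    # -- export -------------------------------------------------------------

    def to_brainnet_node(self, path, sizes=None) -> None:
        """Write the BrainNet-Viewer .node text format.

        Six whitespace-separated columns: x, y, z, color code (by ROI),
        node size, label.
        """
        if sizes is None:
            sizes = np.ones(N_CHANNELS)
        sizes = np.asarray(sizes, dtype=float)
        with open(path, "w") as fh:
            for ch, size in zip(self.channels, sizes):
                x, y, z = ch.mni
                fh.write(f"{x}\t{y}\t{z}\t{_ROI_COLOR[ch.roi]}\t{size:g}\tCH{ch.index:02d}\n")


def roi_of_index(channel_index: int) -> str:
    """ROI label of a 1-based channel index under the fixed partition."""
    for roi, members in ROI_CHANNELS.items():
        if channel_index in members:
            return roi
    raise InvalidChannelError(f"channel index {channel_index} outside 1..{N_CHANNELS}")


def roi_of(montage: Montage, channel_index: int) -> str:
    """ROI label of ``channel_index`` (1-based) in ``montage``."""
    return montage.channel(channel_index).roi


def roi_block_mask(montage: Montage, roi_a: str, roi_b: str) -> np.ndarray:
    """Boolean 22x22 mask of channel pairs with one endpoint in each ROI.

    Symmetric, with an all-False diagonal.  Over all unordered ROI pairs
    (including within-ROI blocks) the masks partition the 231 off-diagonal
    unordered channel pairs.
    """
    ia = montage.roi_indices(roi_a)
    ib = montage.roi_indices(roi_b)
    mask = np.zeros((N_CHANNELS, N_CHANNELS), dtype=bool)
    mask[np.ix_(ia, ib)] = True
    mask[np.ix_(ib, ia)] = True
    np.fill_diagonal(mask, False)
    return mask


def _default_optodes_and_pairing() -> tuple[tuple[Optode, ...], list[tuple[str, str]]]:
    """Reconstructed 3x5 alternating grid: 8 detectors, 7 sources, 22 channels.

    Grid nodes (r, c) host a detector when (r + c) is even, a source
    otherwise.  Channels are the 30 mm nearest-neighbour pairs, numbered
    row-block-wise (4 horizontal, 5 vertical, 4, 5, 4).  Metadata only.
    """
    grid: dict[tuple[int, int], str] = {}
    n_s = n_d = 0
    optodes: list[Optode] = []
    for r in range(3):
        for c in range(5):
            if (r + c) % 2 == 0:
                n_d += 1
                oid, role = f"D{n_d}", "detector"
            else:
                n_s += 1
                oid, role = f"S{n_s}", "source"
            grid[(r, c)] = oid
            optodes.append(Optode(oid, role))

    pairs: list[tuple[tuple[int, int], tuple[int, int]]] = []
    for r in range(3):
        pairs.extend(((r, c), (r, c + 1)) for c in range(4))
        if r < 2:
            pairs.extend(((r, c), (r + 1, c)) for c in range(5))
    # reorder to: row0 horiz, row0-1 vert, row1 horiz, row1-2 vert, row2 horiz
    order = pairs[0:4] + pairs[4:9] + pairs[9:13] + pairs[13:18] + pairs[18:22]

    def sd(a, b):
        ida, idb = grid[a], grid[b]
        return (ida, idb) if ida.startswith("S") else (idb, ida)

    return tuple(optodes), [sd(a, b) for a, b in order]


def load_default_montage() -> Montage:
    """Load the packaged 22-channel prefrontal montage (MNI, Brodmann, ROI)."""
    with resources.files("nirsconn.data").joinpath("montage.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t")
    return montage_from_table(table)


def montage_from_table(table: pd.DataFrame, separation_mm: float = 30.0) -> Montage:
    """Build and validate a Montage from a table with columns
    channel, brodmann, x, y, z, weight, roi."""
    required = {"channel", "brodmann", "x", "y", "z", "weight", "roi"}
    if not required.issubset(table.columns):
        raise DataError(f"montage table missing columns {sorted(required - set(table.columns))}")
    optodes, pairing = _default_optodes_and_pairing()
    table = table.sort_values("channel")
    channels = []
    for row, (src, det) in zip(table.itertuples(index=False), pairing):
        channels.append(
            Channel(
                index=int(row.channel),
                source_id=src,
                detector_id=det,
                mni=(int(row.x), int(row.y), int(row.z)),
                brodmann_area=int(row.brodmann),
                roi=str(row.roi),
                registration_weight=float(row.weight),
            )
        )
    return Montage(optodes=optodes, channels=tuple(channels), separation_mm=separation_mm)
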