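"""DNA <-> grayscale image codification.

A nucleotide sequence is rendered as an 8-bit grayscale image: each base
becomes one pixel, filled row-major into a fixed-width raster.  A database
sequence is tiled into fixed-size, overlapping *scenes*; a query becomes a
variable-height *object* image searched inside those scenes by the
correlator.  Because the raster is row-major, base index ``i`` and pixel
``(r, c)`` satisfy ``i = r * width + c``, so a one-row displacement of a
correlation peak equals exactly ``width`` bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GrayCode",
    "GRAY_EQUISPACED",
    "GRAY_ASCII",
    "PRESETS",
    "ObjectImage",
    "SceneImage",
    "encode",
    "decode",
    "tile_database",
    "read_fasta",
    "write_fasta",
    "write_png",
]

_ALPHABET = "ACGT"


@dataclass(frozen=True)
class GrayCode:
    """A fixed base -> gray-level mapping (one byte per nucleotide).

    Exactly the four bases A, C, G, T are mapped to distinct integers in
    [0, 255].  The default mapping spreads the four levels at constant
    separation over the full range.
    """

    mapping: Mapping[str, int]

    def __post_init__(self) -> None:
        m = dict(self.mapping)
        if set(m) != set(_ALPHABET):
            raise ValueError(f"mapping must cover exactly {{A,C,G,T}}, got {sorted(m)}")
        levels = list(m.values())
        if len(set(levels)) != 4:
            raise ValueError("gray levels must be distinct")
        if not all(0 <= v <= 255 for v in levels):
            raise ValueError("gray levels must lie in [0, 255]")
        object.__setattr__(self, "mapping", m)

    @property
    def levels(self) -> tuple[int, ...]:
        """Gray levels in base order A, C, G, T."""
        return tuple(self.mapping[b] for b in _ALPHABET)

    @property
    def equispaced(self) -> bool:
        """True when adjacent sorted levels have constant separation."""
        s = sorted(self.mapping.values())
        diffs = {b - a for a, b in zip(s, s[1:])}
        return len(diffs) == 1

    def lookup_table(self) -> np.ndarray:
        """256-entry table from ASCII byte to gray level (-1 = invalid)."""
        table = np.full(256, -1, dtype=np.int16)
        for base, level in self.mapping.items():
            table[ord(base)] = level
            table[ord(base.lower())] = level
        return table

    def inverse(self) -> dict[int, str]:
        return {v: k for k, v in self.mapping.items()}


#: Equispaced 4-level partition of [0, 255], bases in alphabetical order.
GRAY_EQUISPACED = GrayCode({"A": 0, "C": 85, "G": 170, "T": 255})
#: ASCII codes of the base letters, usable without a codification step.
GRAY_ASCII = GrayCode({"A": 65, "C": 67, "G": 71, "T": 84})

PRESETS: dict[str, GrayCode] = {"equispaced": GRAY_EQUISPACED, "ascii": GRAY_ASCII}


@dataclass
class ObjectImage:
    """A query ("object") as a padded grayscale raster.

    ``pixels`` is a ``h x width`` integer matrix with ``h = ceil(length /
    width)``; the ``h * width - length`` trailing cells of the last row all
    equal ``pad_value``.
    """

    pixels: np.ndarray
    length: int
    pad_value: int = 0

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]


@dataclass
class SceneImage:
    """One database window as a ``height x width`` grayscale raster.

    ``db_offset`` is the 0-based index of the scene's first base in the
    database sequence; ``scene_index`` its ordinal in the tiling.  Capacity
    is ``width * height`` bases (default 100 x 100 = 10,000).
    """

    pixels: np.ndarray
    db_offset: int
    scene_index: int = 0

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def capacity(self) -> int:
        return self.pixels.size


def _codes(sequence: str, graycode: GrayCode, pad_value: int, ambiguity: str) -> np.ndarray:
    """Map a sequence to gray levels, applying the ambiguity policy."""
    raw = np.frombuffer(sequence.encode("ascii", errors="replace"), dtype=np.uint8)
    vals = graycode.lookup_table()[raw]
    bad = np.flatnonzero(vals < 0)
    if bad.size:
        if ambiguity == "strict":
            pos = int(bad[0])
            raise ValueError(
                f"invalid symbol {sequence[pos]!r} at position {pos}; "
                "only A/C/G/T are accepted (ambiguity='mask' replaces them by pad_value)"
            )
        elif ambiguity == "mask":
            vals = vals.copy()
            vals[bad] = pad_value
        else:
            raise ValueError(f"unknown ambiguity policy {ambiguity!r}")
    return vals.astype(np.int64)


def encode(
    sequence: str,
    width: int = 100,
    pad_value: int = 0,
    graycode: GrayCode = GRAY_EQUISPACED,
    ambiguity: str = "strict",
) -> ObjectImage:
    """Encode a DNA string as a row-major grayscale object image.

    Base ``i`` lands at row ``i // width``, column ``i % width``; cells past
    the last base are filled with ``pad_value``.

    Parameters
    ----------
    sequence : str
        Non-empty string over A/C/G/T (case-insensitive).
    width : int
        Pixels per row (bases per row).
    pad_value : int
        Gray level for the trailing cells of the last row.
    graycode : GrayCode
        Base -> gray-level mapping.
    ambiguity : {"strict", "mask"}
        "strict" raises on a non-ACGT symbol (naming its position);
        "mask" replaces it with ``pad_value``.
    """
    if not sequence:
        raise ValueError("cannot encode an empty sequence")
    if width <= 0:
        raise ValueError("width must be positive")
    vals = _codes(sequence, graycode, pad_value, ambiguity)
    n = len(sequence)
    height = -(-n // width)
    pixels = np.full(height * width, pad_value, dtype=np.int64)
    pixels[:n] = vals
    return ObjectImage(pixels.reshape(height, width), length=n, pad_value=pad_value)


def decode(
    image: ObjectImage | SceneImage | np.ndarray,
    length: int | None = None,
    graycode: GrayCode = GRAY_EQUISPACED,
) -> str:
    """Recover the DNA string from the first ``length`` row-major cells.

    Inverse of :func:`encode`; padded cells beyond ``length`` are ignored.
    A cell value outside the gray code raises with its pixel coordinate.
    """
    pixels = image if isinstance(image, np.ndarray) else image.pixels
    if length is None:
        if isinstance(image, ObjectImage):
            length = image.length
        else:
            length = pixels.size
    flat = pixels.reshape(-1)[:length]
    inv = graycode.inverse()
    width = pixels.shape[1]
    out = []
    for i, v in enumerate(flat.tolist()):
        try:
            out.append(inv[v])
        except KeyError:
            raise ValueError(
                f"pixel ({i // width}, {i % width}) has value {v}, not a gray-code level"
            ) from None
    return "".join(out)


def tile_database(
    db: str,
    width: int = 100,
    height: int = 100,
    overlap: int = 0,
    pad_value: int = 0,
    graycode: GrayCode = GRAY_EQUISPACED,
    ambiguity: str = "strict",
) -> list[SceneImage]:
    """Tile a database sequence into overlapping fixed-size scenes.

    Scene ``k`` starts at ``db_offset = k * (capacity - overlap)``; scenes
    are emitted until the database tail is covered, the final scene being
    padded with ``pad_value`` if needed.  With ``overlap >= q``, every
    length-``q`` window of the database lies wholly within at least one
    scene, which is how boundary spanning is handled downstream.
    """
    if not db:
        raise ValueError("database sequence is empty")
    capacity = width * height
    if not 0 <= overlap < capacity:
        raise ValueError(
            f"overlap must satisfy 0 <= overlap < capacity ({capacity}); got {overlap}"
        )
    stride = capacity - overlap
    vals = _codes(db, graycode, pad_value, ambiguity)
    scenes: list[SceneImage] = []
    offset = 0
    while True:
        window = vals[offset : offset + capacity]
        pixels = np.full(capacity, pad_value, dtype=np.int64)
        pixels[: window.size] = window
        scenes.append(
            SceneImage(pixels.reshape(height, width), db_offset=offset, scene_index=len(scenes))
        )
        if offset + capacity >= len(db):
            break
        offset += stride
    return scenes


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (multi-record) FASTA file as ``[(id, sequence), ...]``."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write ``(id, sequence)`` pairs to a FASTA file."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(recs, str(path), "fasta")


def write_png(image: ObjectImage | SceneImage | np.ndarray, path: str | Path) -> None:
    """Export an encoded image as an 8-bit grayscale PNG (requires Pillow)."""
    from PIL import Image

    pixels = image if isinstance(image, np.ndarray) else image.pixels
    Image.fromarray(pixels.astype(np.uint8), mode="L").save(str(path))
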