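"""One-hot DNA encoding for the convolutional classifier.

Windows are encoded base-wise into 4 channels (A, C, G, T); the unknown
base ``N`` maps to the all-zero vector.  A batch has shape S x H x W x C
with H = 1 and C = 4, matching the input contract of the network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
# byte → channel index; 4 = N (all-zero row), -1 = invalid
_LUT = np.full(256, -1, dtype=np.int16)
for _ch, _i in _CODE.items():
    _LUT[ord(_ch)] = _i
    _LUT[ord(_ch.lower())] = _i
_LUT[ord("N")] = 4
_LUT[ord("n")] = 4
# rows 0-3 are the base one-hots, row 4 (N) is all zeros
_ONEHOT5 = np.vstack([np.eye(4, dtype=np.float32), np.zeros((1, 4), dtype=np.float32)])


@dataclass
class EncodedBatch:
    """A stack of encoded windows plus their binary labels.

    data : float32 array, shape (S, 1, W, 4)
    labels : int array, shape (S,), values in {0, 1}
    """

    data: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        if self.data.ndim != 4 or self.data.shape[1] != 1 or self.data.shape[3] != 4:
            raise ValueError(f"batch data must have shape S×1×W×4, got {self.data.shape}")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("label count does not match batch size")

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[2]

    def subset(self, idx: np.ndarray) -> "EncodedBatch":
        return EncodedBatch(self.data[idx], self.labels[idx])


def encode_one_hot(window: str) -> np.ndarray:
    """Encode a DNA string into a 1 x W x 4 float array.

    A→(1,0,0,0), C→(0,1,0,0), G→(0,0,1,0), T→(0,0,0,1), N→(0,0,0,0).
    Case-insensitive; any other character raises with its position.
    """
    codes = _LUT[np.frombuffer(window.encode("ascii", errors="replace"), dtype=np.uint8)]
    bad = np.nonzero(codes < 0)[0]
    if bad.size:
        pos = int(bad[0])
        raise ValueError(f"invalid nucleotide {window[pos]!r} at position {pos + 1}")
    return _ONEHOT5[codes][np.newaxis, :, :]


def decode_one_hot(array: np.ndarray) -> str:
    """Inverse of :func:`encode_one_hot`; all-zero rows decode to ``N``.

    Rows must be exactly one-hot or all-zero; anything else raises.
    """
    arr = np.asarray(array)
    if arr.ndim == 3 and arr.shape[0] == 1:
        arr = arr[0]
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise ValueError(f"expected a W×4 (or 1×W×4) array, got shape {array.shape}")
    is_one = arr == 1.0
    is_zero = arr == 0.0
    if not np.all(is_one | is_zero):
        raise ValueError("array contains values other than 0 and 1")
    ones_per_row = is_one.sum(axis=1)
    if np.any(ones_per_row > 1):
        raise ValueError("row with more than one set channel")
    chars = np.where(ones_per_row == 0, "N", np.array(list("ACGT"))[arr.argmax(axis=1)])
    return "".join(chars)


def encode_batch(windows: Sequence[str], labels: Sequence[int]) -> EncodedBatch:
    """Encode equal-length windows into an S x 1 x W x 4 batch.

    An empty batch is rejected: training or evaluating on nothing is always
    a caller bug.
    """
    if len(windows) == 0:
        raise ValueError("cannot encode an empty batch")
    if len(windows) != len(labels):
        raise ValueError("windows and labels differ in length")
    width = len(windows[0])
    for i, w in enumerate(windows):
        if len(w) != width:
            raise ValueError(f"window {i} has length {len(w)}, expected {width}")
    data = np.stack([encode_one_hot(w) for w in windows])
    labels_arr = np.asarray(labels, dtype=np.int64)
    if not np.isin(labels_arr, (0, 1)).all():
        raise ValueError("labels must be 0 or 1")
    return EncodedBatch(data=data, labels=labels_arr)
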