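"""Gradient-weighted class activation maps for trained splice models.

For a window and a target class, the map is the ReLU of the channel sum of
the last convolutional layer's activation, weighted by the spatially
averaged gradient of that class's pre-softmax logit — the standard Grad-CAM
recipe.  The conv-resolution map is linearly interpolated back to the full
window length and min-max normalized to [0, 1] (a perfectly flat map
degenerates to all zeros).  Class-averaged maps, computed over thousands of
examples, expose which positions a model has learned to rely on; for a
well-trained model the splice-site class concentrates on the central
dinucleotide and its immediate context.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .encoding import EncodedBatch, encode_batch
from .model import SpliceCNNResults


class GradCamError(ValueError):
    pass


@dataclass
class Heatmap:
    """Per-position importance scores in [0, 1].

    ``scores`` is min-max stretched to span [0, 1] (the display scale).
    For class averages, ``unscaled_scores`` keeps the plain mean of the
    per-window normalized maps — the right scale for comparing flatness
    across classes, which the display stretch deliberately discards.
    """

    scores: np.ndarray
    target_class: int
    site_type: str
    n_averaged: int = 1
    unscaled_scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.ndim != 1:
            raise GradCamError("scores must be a 1-D vector")
        if self.unscaled_scores is None:
            self.unscaled_scores = self.scores.copy()
        else:
            self.unscaled_scores = np.asarray(self.unscaled_scores, dtype=np.float64)

    @property
    def positional_variance(self) -> float:
        """Variance of the pre-stretch scores across positions (flatness)."""
        return float(self.unscaled_scores.var())

    @property
    def width(self) -> int:
        return len(self.scores)

    @property
    def peak_position(self) -> int:
        """1-based position of the maximum score."""
        return int(self.scores.argmax()) + 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": np.arange(1, self.width + 1),
                             "score": self.scores})

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _normalize(scores: np.ndarray) -> np.ndarray:
    lo, hi = scores.min(), scores.max()
    if hi - lo <= 0:
        return np.zeros_like(scores)
    return (scores - lo) / (hi - lo)


def _upsample(cam: np.ndarray, W: int, stride: int, rf_width: int) -> np.ndarray:
    """Linear interpolation from conv-layer resolution back to W positions.

    Each conv-layer unit is anchored at the center of its receptive field
    (0-based position ``stride*j + (rf_width-1)/2``) so that the upsampled
    map is spatially aligned with the input window; positions outside the
    outermost anchors take the edge values.
    """
    L = len(cam)
    if L == 1:
        return np.full(W, cam[0])
    src = stride * np.arange(L) + (rf_width - 1) / 2.0
    dst = np.arange(W, dtype=np.float64)
    return np.interp(dst, src, cam)


def _raw_maps(results: SpliceCNNResults, x: np.ndarray,
              target_class: int) -> np.ndarray:
    """Per-sample normalized heatmaps, shape (N, W)."""
    W = results.config.input_length
    stride, rf_width = results.net.last_conv_receptive_field()
    cams = results.net.gradcam_raw(x, target_class)      # (N, L_conv)
    out = np.empty((len(cams), W))
    for i, cam in enumerate(cams):
        out[i] = _normalize(_upsample(cam.astype(np.float64), W, stride, rf_width))
    return out


def gradcam_heatmap(results: SpliceCNNResults,
                    window: EncodedBatch | np.ndarray | str,
                    target_class: int = 1) -> Heatmap:
    """Grad-CAM heatmap of one window for one class."""
    if target_class not in (0, 1):
        raise GradCamError("target_class must be 0 or 1")
    if isinstance(window, str):
        window = encode_batch([window], [target_class])
    x = window.data[:, 0] if isinstance(window, EncodedBatch) else np.asarray(window)
    if x.ndim == 2:
        x = x[None]
    if x.shape[0] != 1:
        raise GradCamError("gradcam_heatmap takes a single window; "
                           "use average_heatmaps for many")
    scores = _raw_maps(results, x, target_class)[0]
    return Heatmap(scores=scores, target_class=target_class,
                   site_type=results.site_type, n_averaged=1)


def average_heatmaps(results: SpliceCNNResults, examples: EncodedBatch,
                     target_class: int = 1, n: int = 10000,
                     seed: int = 0, chunk: int = 256) -> Heatmap:
    """Class-averaged Grad-CAM over up to ``n`` examples of the class.

    Samples without replacement among the examples whose label equals the
    target class, averages their per-window normalized heatmaps
    position-wise, and re-normalizes the mean to [0, 1].
    """
    if target_class not in (0, 1):
        raise GradCamError("target_class must be 0 or 1")
    idx = np.nonzero(examples.labels == target_class)[0]
    if len(idx) == 0:
        raise GradCamError(f"no examples of class {target_class}")
    rng = np.random.Generator(np.random.PCG64(seed))
    take = min(n, len(idx))
    chosen = rng.choice(idx, size=take, replace=False)
    x = examples.data[chosen, 0]
    total = np.zeros(results.config.input_length)
    for i in range(0, take, chunk):
        total += _raw_maps(results, x[i:i + chunk], target_class).sum(axis=0)
    mean = total / take
    return Heatmap(scores=_normalize(mean), target_class=target_class,
                   site_type=results.site_type, n_averaged=take,
                   unscaled_scores=mean)


def write_heatmap(heatmap: Heatmap, tsv_path: str | Path,
                  json_sidecar: str | Path | None = None) -> None:
    heatmap.to_tsv(tsv_path)
    if json_sidecar is not None:
        import json
        meta = {"target_class": heatmap.target_class,
                "site_type": heatmap.site_type,
                "n_averaged": heatmap.n_averaged,
                "width": heatmap.width}
        Path(json_sidecar).write_text(json.dumps(meta, indent=2))


def plot_heatmap(heatmap: Heatmap, path: str | Path,
                 title: str | None = None) -> None:
    """Render the heatmap as a position/score strip chart (PNG/SVG/PDF)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 2.2))
    pos = np.arange(1, heatmap.width + 1)
    ax.imshow(heatmap.scores[None, :], aspect="auto", cmap="viridis",
              extent=(0.5, heatmap.width + 0.5, 0, 1), vmin=0, vmax=1)
    ax.set_yticks([])
    ax.set_xlabel("window position (nt)")
    cls = "SS" if heatmap.target_class == 1 else "non-SS"
    ax.set_title(title or f"{heatmap.site_type} / class {cls} "
                          f"(n={heatmap.n_averaged})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
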