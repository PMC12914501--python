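"""Gradient-based frequency-offset selection.

The sensitivity of the trained network's outputs to each input offset is
measured by the mean absolute input gradient over the training set
(absolute gradients of the two outputs summed per input before
averaging).  Offsets whose gradient magnitude strictly exceeds the mean
over all offsets are retained; the reduced grid is then used to retrain
a faster model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import TrainedModel

__all__ = ["AttributionResult", "gradient_attribution", "select_offsets"]


@dataclass
class AttributionResult:
    """Per-offset gradient magnitudes g and the mean-threshold selection."""

    g: np.ndarray
    offsets_ppm: np.ndarray
    threshold: float = np.nan
    selected_indices: np.ndarray | None = None

    @property
    def selected_offsets_ppm(self) -> np.ndarray:
        if self.selected_indices is None:
            raise ValueError("selection has not been performed")
        return self.offsets_ppm[self.selected_indices]


def gradient_attribution(model: TrainedModel, X: np.ndarray) -> AttributionResult:
    """Mean absolute input gradient of the model outputs over ``X``.

    g_i = mean over samples of Σ_k |∂y_k/∂x_i|; invariant to sample
    order.  Requires a trained model.
    """
    if not model.net.trained:
        raise ValueError("attribution requires a trained model")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.net.n_inputs:
        raise ValueError("dataset does not match the model input dimension")
    g = model.input_gradients(X).mean(axis=0)
    return AttributionResult(g=g, offsets_ppm=np.asarray(model.input_offsets_ppm, dtype=float))


def select_offsets(attribution: AttributionResult | np.ndarray, offsets_ppm=None) -> AttributionResult:
    """Keep offsets whose gradient magnitude strictly exceeds mean(g).

    A constant gradient vector has no offset strictly above the mean and
    is rejected as degenerate.
    """
    if isinstance(attribution, AttributionResult):
        g = attribution.g
        offs = attribution.offsets_ppm
    else:
        g = np.asarray(attribution, dtype=float)
        offs = np.arange(g.size, dtype=float) if offsets_ppm is None else np.asarray(offsets_ppm, dtype=float)
    if g.size == 0 or not np.all(np.isfinite(g)):
        raise ValueError("g must be non-empty and finite")
    thr = float(g.mean())
    idx = np.flatnonzero(g > thr)
    if idx.size == 0:
        raise ValueError("constant gradient vector: no offset strictly exceeds the mean")
    return AttributionResult(g=g, offsets_ppm=offs, threshold=thr, selected_indices=idx)
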