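"""Model interpretation: Grad-CAM saliency over beats and 2D embedding of
last-layer features.

Grad-CAM weights each last-stage channel by the temporal mean of the class
score's gradient with respect to that channel's activations, rectifies the
weighted sum, linearly upsamples the coarse map (temporal length 4 for a
120-sample beat) back to beat resolution, and normalizes to [0, 1] by the
map maximum.  The 2D embedding applies t-SNE to the global-average-pooled
last-stage features; the embedding procedure is delegated to scikit-learn,
with the determinism and shape contracts owned here.
"""

from __future__ import annotations

import numpy as np
from sklearn.manifold import TSNE

from .errors import InvalidArgumentError
from .preprocess import Beat, Label
from .resnet1d import ResNet1D, feature_maps_and_grads


def grad_cam(model: ResNet1D, beat: np.ndarray, class_index: int) -> np.ndarray:
    """Saliency over the beat for one class: length-120 values in [0, 1]."""
    acts, grads = feature_maps_and_grads(model, beat, class_index)
    channel_weights = grads.mean(axis=1)
    cam = np.maximum(channel_weights @ acts, 0.0)
    length = model.spec.input_length
    upsampled = np.interp(np.linspace(0.0, cam.size - 1.0, length),
                          np.arange(cam.size), cam)
    peak = upsampled.max()
    return upsampled / peak if peak > 0 else upsampled


def average_class_beats(beats: list[Beat]) -> dict[Label, np.ndarray]:
    """Pointwise mean beat per class (the two average-beat curves)."""
    groups: dict[Label, list[np.ndarray]] = {}
    for b in beats:
        groups.setdefault(b.label, []).append(b.samples)
    if Label.HYPER not in groups or Label.NORMO not in groups:
        raise InvalidArgumentError("both labels must be present")
    return {label: np.mean(np.stack(arrs), axis=0)
            for label, arrs in groups.items()}


def pooled_features(model: ResNet1D, beats: np.ndarray,
                    batch_size: int = 512) -> np.ndarray:
    """Global-average-pooled last-stage activations, shape (n, channels)."""
    beats = np.asarray(beats, dtype=np.float32)
    chunks = []
    for i in range(0, len(beats), batch_size):
        model.forward(beats[i: i + batch_size], train=False)
        chunks.append(model.pooled_features.copy())
    return np.concatenate(chunks)


def embed_tsne(features: np.ndarray, perplexity: float = 30.0,
               seed: int = 0) -> np.ndarray:
    """Deterministic (seeded) t-SNE embedding of n x d features to n x 2."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2:
        raise InvalidArgumentError("features must be a 2D array")
    n = features.shape[0]
    if n <= 3 * perplexity:
        raise InvalidArgumentError(
            f"need n > 3 x perplexity (n={n}, perplexity={perplexity})")
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                init="pca", learning_rate="auto")
    return tsne.fit_transform(features)
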