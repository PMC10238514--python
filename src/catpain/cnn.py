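"""Lightweight convolutional classifier for the image branch.

A deliberately small, CPU-friendly architecture written directly in numpy:

    input (resized, standardized grayscale)
      -> single convolutional layer (K filters, f x f, stride s), ReLU
      -> global average pooling
      -> linear layer -> 2 logits -> softmax

Trained full-batch with Adam on the cross-entropy.  Because the head is a
global-average-pooled linear layer, Grad-CAM has a closed form: the channel
weights are the head weights of the target class, and the class activation
map is the rectified weighted sum of the (rectified) convolutional feature
maps, upsampled to the input frame.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.transform import resize

from .errors import ParameterError, ValidationError


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class CnnStandin:
    """Small numpy CNN with a scikit-learn-like fit/predict surface."""

    is_convolutional = True

    def __init__(
        self,
        input_size: int = 64,
        n_filters: int = 8,
        filter_size: int = 5,
        stride: int = 2,
        lr: float = 0.02,
        epochs: int = 250,
        weight_decay: float = 1e-4,
        seed: int = 0,
    ) -> None:
        if filter_size < 1 or stride < 1 or n_filters < 1:
            raise ParameterError("filter_size, stride and n_filters must be >= 1")
        self.input_size = int(input_size)
        self.n_filters = int(n_filters)
        self.filter_size = int(filter_size)
        self.stride = int(stride)
        self.lr = float(lr)
        self.epochs = int(epochs)
        self.weight_decay = float(weight_decay)
        self.seed = int(seed)
        self._fitted = False
        self._mean = 0.0
        self._std = 1.0

    # -- plumbing ---------------------------------------------------------

    def _prepare(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, float)
        if images.ndim == 2:
            images = images[None]
        if images.ndim != 3:
            raise ValidationError("images must be a (n, H, W) stack or one (H, W) array")
        if images.max() > 1.5:  # 8-bit input
            images = images / 255.0
        if images.shape[1:] != (self.input_size, self.input_size):
            images = np.stack(
                [resize(im, (self.input_size, self.input_size), order=1,
                        anti_aliasing=True, preserve_range=True) for im in images]
            )
        return images

    def _patches(self, images: np.ndarray) -> np.ndarray:
        """(n, P, f*f) sliding patches at the layer's stride."""
        f, s = self.filter_size, self.stride
        win = sliding_window_view(images, (f, f), axis=(1, 2))[:, ::s, ::s]
        n, oh, ow = win.shape[:3]
        self._out_shape = (oh, ow)
        return win.reshape(n, oh * ow, f * f)

    def init_parameters(self, rng: np.random.Generator | None = None) -> None:
        rng = rng or np.random.default_rng(self.seed)
        f2 = self.filter_size ** 2
        self.W1 = rng.normal(0.0, np.sqrt(2.0 / f2), size=(self.n_filters, f2))
        self.b1 = np.zeros(self.n_filters)
        self.W2 = rng.normal(0.0, np.sqrt(1.0 / self.n_filters), size=(2, self.n_filters))
        self.b2 = np.zeros(2)

    # -- training ---------------------------------------------------------

    def fit(self, images: np.ndarray, y: np.ndarray) -> "CnnStandin":
        images = self._prepare(images)
        y = np.asarray(y, int)
        if len(np.unique(y)) < 2:
            raise ValidationError("training data must contain both classes")
        self._mean = float(images.mean())
        self._std = float(images.std()) or 1.0
        X = self._patches((images - self._mean) / self._std)
        n = X.shape[0]
        onehot = np.eye(2)[y]

        self.init_parameters()
        params = [self.W1, self.b1, self.W2, self.b2]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8

        for t in range(1, self.epochs + 1):
            z = X @ self.W1.T + self.b1          # (n, P, K)
            a = np.maximum(z, 0.0)
            g = a.mean(axis=1)                   # (n, K) global average pool
            logits = g @ self.W2.T + self.b2
            p = _softmax(logits)

            dlogits = (p - onehot) / n           # (n, 2)
            dW2 = dlogits.T @ g + self.weight_decay * self.W2
            db2 = dlogits.sum(axis=0)
            dg = dlogits @ self.W2               # (n, K)
            da = (dg[:, None, :] / z.shape[1]) * (z > 0)
            dW1 = np.einsum("npk,npf->kf", da, X) + self.weight_decay * self.W1
            db1 = da.sum(axis=(0, 1))

            for i, (par, grad) in enumerate(zip(params, (dW1, db1, dW2, db2))):
                m[i] = beta1 * m[i] + (1 - beta1) * grad
                v[i] = beta2 * v[i] + (1 - beta2) * grad ** 2
                par -= self.lr * (m[i] / (1 - beta1 ** t)) / (
                    np.sqrt(v[i] / (1 - beta2 ** t)) + eps
                )
        self._fitted = True
        return self

    # -- inference --------------------------------------------------------

    def conv_activations(self, images: np.ndarray) -> np.ndarray:
        """Rectified maps of the last (only) conv layer: (n, oh, ow, K)."""
        images = self._prepare(images)
        X = self._patches((images - self._mean) / self._std)
        a = np.maximum(X @ self.W1.T + self.b1, 0.0)
        oh, ow = self._out_shape
        return a.reshape(images.shape[0], oh, ow, self.n_filters)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        a = self.conv_activations(images)
        g = a.mean(axis=(1, 2))
        return _softmax(g @ self.W2.T + self.b2)

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.predict_proba(images).argmax(axis=1)

    def gradcam(self, image: np.ndarray, target_class: int) -> np.ndarray:
        """Class activation heatmap in [0, 1] at the model's input frame.

        Channel weights are the gradient of the target-class score with
        respect to the pooled activations, i.e. the head weights; the map is
        rectified at zero, bilinearly upsampled, and scaled by its maximum.
        """
        a = self.conv_activations(image)[0]                 # (oh, ow, K)
        cam = np.maximum(a @ self.W2[int(target_class)], 0.0)
        cam = resize(cam, (self.input_size, self.input_size), order=1,
                     anti_aliasing=False, preserve_range=True)
        peak = cam.max()
        return cam / peak if peak > 0 else cam
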