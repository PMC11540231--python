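"""Plugin contract for image→feature extractors.

The core package never imports a deep-learning framework: an extractor
(e.g. a pre-trained ResNet-18 truncated at its penultimate layer, giving
512 features per image) is registered at run time by whoever has one.
The contract fixes the output width and the per-image preprocessing —
each image is standardized pixel-wise by subtracting its own mean and
dividing by its own standard deviation (ε-guarded), with no augmentation
— so that any backend plugs into the evaluation pipeline unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict

import numpy as np

from .data import ValidationError

__all__ = [
    "ExtractorContract",
    "register_extractor",
    "get_extractor",
    "list_extractors",
    "preprocess_images",
    "run_extractor",
]

#: Guard against zero-variance (constant) images during standardization.
_STD_EPS = 1e-8

_REGISTRY: Dict[str, "ExtractorContract"] = {}


@dataclass(frozen=True)
class ExtractorContract:
    """A named backend mapping an image batch to an (n_images, width)
    feature matrix.

    ``backend`` receives the *preprocessed* batch (same shape as the
    input) and must return a 2-D float array with exactly ``width``
    columns.  ``normalization`` selects the standardization statistics:
    ``"per_image"`` (default) or ``"per_channel"`` (axis 1 of an
    (n, channels, ...) batch).
    """

    name: str
    width: int
    backend: Callable[[np.ndarray], np.ndarray]
    normalization: str = "per_image"

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValidationError("extractor width must be ≥ 1")
        if self.normalization not in ("per_image", "per_channel"):
            raise ValidationError(
                "normalization must be 'per_image' or 'per_channel'"
            )


def register_extractor(contract: ExtractorContract) -> None:
    _REGISTRY[contract.name] = contract


def list_extractors() -> list[str]:
    return sorted(_REGISTRY)


def get_extractor(name: str) -> ExtractorContract:
    if name not in _REGISTRY:
        raise ValidationError(
            f"no extractor backend named {name!r} is registered; register one "
            "with subspace_fewshot.extractors.register_extractor("
            "ExtractorContract(name=..., width=..., backend=callable)). "
            f"Currently registered: {list_extractors() or 'none'}"
        )
    return _REGISTRY[name]


def preprocess_images(
    images: np.ndarray, normalization: str = "per_image"
) -> np.ndarray:
    """Standardize each image (or each channel) to zero mean, unit std."""
    x = np.asarray(images, dtype=np.float64)
    if x.ndim < 2:
        raise ValidationError("images must be a batch: (n_images, ...)")
    axes = tuple(range(1, x.ndim))
    if normalization == "per_channel" and x.ndim >= 3:
        axes = tuple(range(2, x.ndim))
    mean = x.mean(axis=axes, keepdims=True)
    std = x.std(axis=axes, keepdims=True)
    return (x - mean) / (std + _STD_EPS)


def run_extractor(contract: ExtractorContract, images: np.ndarray) -> np.ndarray:
    """Preprocess a batch and run the backend, enforcing the declared width."""
    batch = preprocess_images(images, contract.normalization)
    feats = np.asarray(contract.backend(batch), dtype=np.float64)
    if feats.ndim != 2 or feats.shape[0] != batch.shape[0]:
        raise ValidationError(
            f"backend {contract.name!r} returned shape {feats.shape}; expected "
            f"({batch.shape[0]}, {contract.width})"
        )
    if feats.shape[1] != contract.width:
        raise ValidationError(
            f"backend {contract.name!r} declared width {contract.width} but "
            f"returned {feats.shape[1]} features per image"
        )
    return feats
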