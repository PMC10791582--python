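"""Canonical configurations for the desk-scale analyses.

The full tRNet architecture (1.33M parameters) is what the architecture
checks describe; for training experiments on synthetic flanks the
desk-scale variant below keeps the same layer pattern (wide initial
convolution, dilated convolution with residual skip, global max pool,
hidden layer, softmax head) at a width that trains in seconds per epoch
on one CPU core.  The desk-scale optimisation schedule trains on the
full training split for a fixed number of epochs: with a few hundred
sequences, a validation holdout both starves training and triggers
loss-based early stopping prematurely (validation cross-entropy rises
from overconfidence while discrimination is still improving).
"""

from __future__ import annotations

from .trnet import TrainConfig, TRNetSpec

__all__ = ["desk_spec", "desk_train_config", "tiny_spec"]


def desk_spec() -> TRNetSpec:
    """Reduced-width tRNet used for desk-scale training experiments."""
    return TRNetSpec(
        conv0_filters=64,
        conv0_width=20,
        n_dilated=1,
        dilated_filters=64,
        dilated_width=9,
        dilation_start=32,
        hidden_units=32,
    )


def desk_train_config(seed: int = 0, max_epochs: int = 50) -> TrainConfig:
    """Fixed-schedule optimisation for the desk-scale model (use with
    ``train(..., early_stopping=False)``)."""
    return TrainConfig(
        learning_rate=0.004,
        batch_size=16,
        max_epochs=max_epochs,
        seed=seed,
    )


def tiny_spec() -> TRNetSpec:
    """Minimal valid architecture for fast unit tests and attribution."""
    return TRNetSpec(
        conv0_filters=16,
        conv0_width=12,
        n_dilated=1,
        dilated_filters=16,
        dilated_width=9,
        dilation_start=32,
        hidden_units=8,
    )
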