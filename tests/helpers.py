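"""Shared test helpers (not fixtures)."""

import numpy as np

from parseg.pixel_data import PixelDataset


def make_dataset(labels, rng=None, separation=0.6, noise_sd=0.0):
    """Small dataset whose R channel carries the labels.

    With ``noise_sd=0`` the classes are perfectly separable on R;
    positive noise makes the classification problem genuinely hard so
    sensitivities fall below 1.
    """
    labels = np.asarray(labels, dtype=np.uint8)
    rng = rng or np.random.default_rng(0)
    base = np.where(labels == 1, separation + 0.2, 0.2)
    r = base + rng.normal(0.0, noise_sd, len(labels)) if noise_sd else base
    feats = np.clip(
        np.column_stack(
            [r, rng.uniform(0.3, 0.5, len(labels)), rng.uniform(0.3, 0.5, len(labels))]
        ),
        0,
        1,
    )
    return PixelDataset(feats, labels)
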