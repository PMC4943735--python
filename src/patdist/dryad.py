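"""Optional runner for the original field-photograph corpus.

The study's cropped body images and labels are archived externally
(Dryad doi:10.5061/dryad.9kd74 and the authors' public repository);
they are not distributed with this package. Users who download them can
reproduce the pairwise distinguishability table at full scale with
:func:`run_reference_corpus`. Nothing else in the package depends on
this module.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .distinguish import pairwise_distinguishability
from .features import build_signature_matrix
from .imaging import load_image


def run_reference_corpus(
    images_dir: str,
    labels_csv: str,
    mode: str = "color",
    n_templates: int = 1000,
    n_permutations: int = 10_000,
    max_side: int | None = None,
    seed: int = 0,
):
    """Compute the pairwise distinguishability table on a downloaded
    corpus of cropped body images.

    ``labels_csv`` must have columns ``filename`` and ``pattern``. With
    the defaults (1000 templates, 10,000 permutations, full resolution)
    this is a long computation intended for the original corpus; it is
    not part of the test suite.
    """
    if not os.path.isdir(images_dir):
        raise FileNotFoundError(
            f"image directory {images_dir!r} not found; the field-photograph "
            "corpus is external (Dryad doi:10.5061/dryad.9kd74) and must be "
            "downloaded separately"
        )
    if not os.path.isfile(labels_csv):
        raise FileNotFoundError(f"labels table {labels_csv!r} not found")
    table = pd.read_csv(labels_csv)
    if not {"filename", "pattern"}.issubset(table.columns):
        raise ValueError("labels CSV needs 'filename' and 'pattern' columns")
    images = [load_image(os.path.join(images_dir, f)) for f in table["filename"]]
    kwargs = {} if max_side is None else {"max_side": max_side}
    matrix, _ = build_signature_matrix(
        images, mode=mode, n_templates=n_templates, seed=seed, **kwargs
    )
    labels = table["pattern"].astype(str).to_numpy()
    return pairwise_distinguishability(
        matrix, labels, n_permutations=n_permutations, seed=seed,
        holm_alpha=0.05,
    )
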