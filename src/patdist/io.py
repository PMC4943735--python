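"""CSV/JSON/NPZ readers and writers for signatures, labels and templates."""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

from .features import Template, TemplateSet
from .imaging import ValidationError


def write_signatures_csv(path: str, matrix: np.ndarray, image_ids: list[str]) -> None:
    """Signature matrix as CSV: one row per image, columns image_id, t0..t{T-1}."""
    matrix = np.asarray(matrix, dtype=float)
    df = pd.DataFrame(matrix, columns=[f"t{j}" for j in range(matrix.shape[1])])
    df.insert(0, "image_id", image_ids)
    df.to_csv(path, index=False)


def read_signatures_csv(path: str) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path)
    if "image_id" not in df.columns:
        raise ValidationError(f"{path}: missing image_id column")
    ids = df["image_id"].astype(str).tolist()
    return df.drop(columns="image_id").to_numpy(dtype=float), ids


def read_labels_csv(path: str) -> dict[str, str]:
    """Labels CSV with columns image_id, label (header required)."""
    df = pd.read_csv(path)
    if not {"image_id", "label"}.issubset(df.columns):
        raise ValidationError(f"{path}: need image_id and label columns")
    return dict(zip(df["image_id"].astype(str), df["label"].astype(str)))


def save_template_set(path_prefix: str, templates: TemplateSet) -> None:
    """Template patches as an .npz archive plus a JSON manifest."""
    arrays = {
        f"patch_{i}": t.patch for i, t in enumerate(templates.templates)
    }
    np.savez_compressed(path_prefix + ".npz", **arrays)
    manifest = {
        "mode": templates.mode,
        "seed": templates.seed,
        "channel_names": list(templates.channel_names),
        "templates": [
            {"size_class": t.size_class, "source": list(t.source)}
            for t in templates.templates
        ],
    }
    with open(path_prefix + ".json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def load_template_set(path_prefix: str) -> TemplateSet:
    with open(path_prefix + ".json") as fh:
        manifest = json.load(fh)
    with np.load(path_prefix + ".npz") as npz:
        templates = [
            Template(
                size_class=meta["size_class"],
                patch=npz[f"patch_{i}"],
                source=tuple(meta["source"]),
            )
            for i, meta in enumerate(manifest["templates"])
        ]
    return TemplateSet(
        templates=templates,
        mode=manifest["mode"],
        seed=manifest["seed"],
        channel_names=tuple(manifest["channel_names"]),
    )


def write_run_log(path: str, **entries) -> None:
    """JSON run log of resolved parameters, per-image gains and seeds."""
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)

    with open(path, "w") as fh:
        json.dump(entries, fh, indent=1, default=_default)
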