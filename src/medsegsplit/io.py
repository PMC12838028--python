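"""Dataset folder and checkpoint IO.

Dataset layout: ``<root>/images/<id>.png``, ``<root>/masks/<id>.png`` and a
``manifest.csv`` with columns (sample_id, client_id, role) where role is
train/val/test and client_id is empty for test samples.  Masks are stored
as single-channel 8-bit PNGs holding raw label values 0..C-1 (lossless).
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .synthetic_data import SegmentationSample


def save_dataset(root, samples, manifest: pd.DataFrame) -> None:
    root = Path(root)
    (root / "images").mkdir(parents=True, exist_ok=True)
    (root / "masks").mkdir(parents=True, exist_ok=True)
    for s in samples:
        img8 = np.clip(np.round(s.image * 255.0), 0, 255).astype(np.uint8)
        iio.imwrite(root / "images" / f"{s.sample_id}.png", img8)
        iio.imwrite(root / "masks" / f"{s.sample_id}.png", s.mask.astype(np.uint8))
    manifest.to_csv(root / "manifest.csv", index=False)


def load_dataset(root):
    """Returns (samples keyed by id, manifest DataFrame)."""
    root = Path(root)
    manifest = pd.read_csv(root / "manifest.csv", dtype={"sample_id": str})
    samples = {}
    for sid in manifest["sample_id"]:
        img = iio.imread(root / "images" / f"{sid}.png").astype(np.float32) / 255.0
        mask = iio.imread(root / "masks" / f"{sid}.png").astype(np.int64)
        samples[sid] = SegmentationSample(img, mask, sid)
    return samples, manifest


def build_manifest(shards, test, train_frac: float = 0.85, seed: int = 0) -> pd.DataFrame:
    """Assign train/val roles within each client shard and tag the test
    shard; returns the manifest DataFrame."""
    from .synthetic_data import train_val_split

    rows = []
    for ci, shard in enumerate(shards):
        if shard:
            train, val = train_val_split(shard, train_frac, seed=seed + ci)
            rows += [(s.sample_id, ci, "train") for s in train]
            rows += [(s.sample_id, ci, "val") for s in val]
    rows += [(s.sample_id, "", "test") for s in test]
    return pd.DataFrame(rows, columns=["sample_id", "client_id", "role"])


def shards_from_manifest(samples: dict, manifest: pd.DataFrame):
    """Rebuild ((train, val) per client, test) from a manifest."""
    shards = []
    cid = pd.to_numeric(manifest["client_id"], errors="coerce")
    client_ids = sorted(int(c) for c in cid.dropna().unique())
    for ci in client_ids:
        rows = manifest[cid == ci]
        train = [samples[s] for s in rows.loc[rows.role == "train", "sample_id"]]
        val = [samples[s] for s in rows.loc[rows.role == "val", "sample_id"]]
        shards.append((train, val))
    test = [samples[s] for s in manifest.loc[manifest.role == "test", "sample_id"]]
    return shards, test


def save_checkpoint(model, out_dir, arch_name: str, seed: int | None = None) -> None:
    """One .npz archive per role plus a JSON sidecar describing the model."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    for role, params in state.items():
        np.savez(out / f"{role.lower()}.npz", **params)
    sidecar = {
        "arch_name": arch_name,
        "num_classes": model.num_classes,
        "base_width": model.base_width,
        "seed": seed,
        "split_spec": {
            "cut_after_fe": model.spec.cut_after_fe,
            "cut_before_be": model.spec.cut_before_be,
            "side_channel_routes": model.spec.side_channel_routes,
        },
    }
    (out / "model.json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(ckpt_dir):
    """Rebuild the model described by a checkpoint directory."""
    from .models import build_model

    ckpt = Path(ckpt_dir)
    meta = json.loads((ckpt / "model.json").read_text())
    model = build_model(
        meta["arch_name"],
        num_classes=meta["num_classes"],
        base_width=meta["base_width"],
        seed=meta.get("seed") or 0,
    )
    state = {}
    for role in ("FE", "SS", "BE"):
        with np.load(ckpt / f"{role.lower()}.npz") as z:
            state[role] = {k: z[k] for k in z.files}
    model.load_state_dict(state)
    return model, meta
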