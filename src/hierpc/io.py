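"""Array-bundle and table I/O with provenance manifests.

Arrays are stored as ``.npz`` containers with a JSON sidecar manifest
(``<name>.json``) carrying labels, shapes, seeds and content hashes, so a
result directory documents how each stage's outputs were produced.  Tables
are TSV.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .contrasts import ContrastDefinition, ContrastTensor
from .spectral import EpochSet

__all__ = [
    "content_hash",
    "save_bundle",
    "load_bundle",
    "save_tensor",
    "load_tensor",
    "save_epochs",
    "load_epochs",
    "save_table",
    "load_table",
    "load_config_file",
]


class ManifestError(ValueError):
    """Raised when a bundle's sidecar manifest is missing or corrupt."""


def content_hash(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        a = np.ascontiguousarray(a)
        h.update(str(a.dtype).encode())
        h.update(str(a.shape).encode())
        h.update(a.tobytes())
    return h.hexdigest()


def save_bundle(path, arrays: dict, manifest: dict = None) -> Path:
    """Save named arrays to ``<path>.npz`` plus a JSON manifest sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    npz = path.with_suffix(".npz")
    np.savez(npz, **arrays)
    man = dict(manifest or {})
    man["arrays"] = {k: {"shape": list(np.shape(v)), "hash": content_hash(np.asarray(v))} for k, v in arrays.items()}
    path.with_suffix(".json").write_text(json.dumps(man, indent=1, default=str))
    return npz


def load_bundle(path):
    """Load ``(arrays, manifest)``; fails fast on a corrupt manifest."""
    path = Path(path)
    side = path.with_suffix(".json")
    if not side.exists():
        raise ManifestError(f"missing manifest {side}")
    try:
        manifest = json.loads(side.read_text())
    except json.JSONDecodeError as err:
        raise ManifestError(f"corrupt manifest {side}: {err}") from err
    if "arrays" not in manifest:
        raise ManifestError(f"manifest {side} lacks an 'arrays' section")
    with np.load(path.with_suffix(".npz")) as npz:
        arrays = {k: npz[k] for k in npz.files}
    for k, meta in manifest["arrays"].items():
        if k not in arrays:
            raise ManifestError(f"manifest {side} lists array {k!r} not present in bundle")
        if content_hash(arrays[k]) != meta["hash"]:
            raise ManifestError(f"array {k!r} in {path} does not match its manifest hash")
    return arrays, manifest


def save_tensor(path, tensor: ContrastTensor, extra: dict = None) -> Path:
    manifest = {
        "kind": "contrast_tensor",
        "n_freqs": tensor.n_freqs,
        "n_times": tensor.n_times,
        "flattening": "frequency-major",
        "contrasts": [
            {"scope": c.scope, "minuend": list(c.minuend), "subtrahend": list(c.subtrahend), "index": c.index}
            for c in tensor.contrasts
        ],
    }
    manifest.update(extra or {})
    arrays = {"values": tensor.values}
    if tensor.masks is not None:
        arrays["masks"] = np.packbits(np.stack([m.astype(bool) for m in tensor.masks]))
        manifest["masks_shape"] = list(np.stack(tensor.masks).shape)
    return save_bundle(path, arrays, manifest)


def load_tensor(path) -> ContrastTensor:
    arrays, manifest = load_bundle(path)
    if manifest.get("kind") != "contrast_tensor":
        raise ManifestError(f"{path} is not a contrast-tensor bundle")
    defs = tuple(
        ContrastDefinition(c["scope"], tuple(c["minuend"]), tuple(c["subtrahend"]), c["index"])
        for c in manifest["contrasts"]
    )
    masks = None
    if "masks" in arrays:
        shape = manifest["masks_shape"]
        flat = np.unpackbits(arrays["masks"], count=int(np.prod(shape)))
        masks = tuple(flat.reshape(shape).astype(bool))
    return ContrastTensor(arrays["values"], defs, manifest["n_freqs"], manifest["n_times"], masks)


def save_epochs(path, epochs: EpochSet, extra: dict = None) -> Path:
    manifest = {
        "kind": "epochs",
        "sfreq": epochs.sfreq,
        "ch_names": list(epochs.ch_names),
        "tmin": epochs.tmin,
        "last_tone": epochs.last_tone,
        "trial_info": epochs.trial_info.to_dict(orient="list"),
    }
    manifest.update(extra or {})
    arrays = {"data": epochs.data}
    if epochs.montage is not None:
        arrays["montage"] = epochs.montage
    return save_bundle(path, arrays, manifest)


def load_epochs(path) -> EpochSet:
    arrays, manifest = load_bundle(path)
    if manifest.get("kind") != "epochs":
        raise ManifestError(f"{path} is not an epochs bundle")
    return EpochSet(
        data=arrays["data"],
        sfreq=manifest["sfreq"],
        ch_names=manifest["ch_names"],
        tmin=manifest["tmin"],
        trial_info=pd.DataFrame(manifest["trial_info"]),
        last_tone=manifest["last_tone"],
        montage=arrays.get("montage"),
    )


def save_table(path, frame: pd.DataFrame) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False)
    return path


def load_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_config_file(path) -> dict:
    """Read a YAML (or JSON, a YAML subset) configuration file."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg
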