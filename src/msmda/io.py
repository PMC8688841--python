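"""File formats: manifest-based NPZ/CSV exchange and the SEED .mat loader.

The internal exchange layout is a directory with a ``manifest.json``
listing one matrix file per domain (NPZ by default, CSV for
interoperability), the class count, the raw-to-contiguous label mapping
and the electrode x band column layout.  Real SEED / SEED-IV
"ExtractedFeatures" directories (MATLAB files of per-trial DE features)
are read by :func:`load_seed_features`, supporting both classic and
v7.3/HDF5 .mat flavors.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np

from .data import (DataError, DomainCollection, DomainDataset,
                   MultiSourceTask, SchemaError, reshape_channel_band)

__all__ = ["save_collection", "load_generic", "load_seed_features",
           "as_collection", "LoadError"]


class LoadError(IOError):
    """A dataset directory or file could not be read as described."""


def as_collection(obj) -> DomainCollection:
    """View a task as a 1-session collection (sources then target as subjects)."""
    if isinstance(obj, DomainCollection):
        return obj
    if isinstance(obj, MultiSourceTask):
        domains = {(i + 1, 1): d for i, d in enumerate(obj.sources)}
        domains[(len(obj.sources) + 1, 1)] = obj.target
        return DomainCollection(domains=domains, n_classes=obj.n_classes)
    raise TypeError(f"cannot view {type(obj).__name__} as a DomainCollection")


def save_collection(coll: DomainCollection, directory, fmt: str = "npz",
                    n_electrodes: int | None = None, n_bands: int | None = None,
                    label_map: dict | None = None) -> Path:
    """Write one file per domain plus manifest.json; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if fmt not in ("npz", "csv"):
        raise ValueError(f"unsupported format {fmt!r}")
    entries = []
    for (s, k), d in sorted(coll.domains.items()):
        stem = f"subj{s:02d}_sess{k}"
        if fmt == "npz":
            path = directory / f"{stem}.npz"
            payload = {"features": d.features}
            if d.labels is not None:
                payload["labels"] = d.labels
            np.savez(path, **payload)
        else:
            path = directory / f"{stem}.csv"
            cols = d.features
            header = ",".join(f"f{j}" for j in range(d.n_features))
            if d.labels is not None:
                cols = np.column_stack([cols, d.labels.astype(np.float64)])
                header += ",label"
            np.savetxt(path, cols, delimiter=",", header=header, comments="")
        entries.append({"subject_index": s, "session_index": k,
                        "path": path.name, "n_samples": d.n_samples})
    any_domain = next(iter(coll.domains.values()))
    layout = {"n_electrodes": n_electrodes or any_domain.n_features // 5,
              "n_bands": n_bands or 5, "column_order": "channel_major"}
    if layout["n_electrodes"] * layout["n_bands"] != any_domain.n_features:
        layout = {"n_electrodes": any_domain.n_features, "n_bands": 1,
                  "column_order": "channel_major"}
    manifest = {"format": fmt, "n_classes": coll.n_classes,
                "label_map": label_map, "feature_layout": layout,
                "domains": entries}
    mpath = directory / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath


def _read_domain_file(path: Path, fmt: str):
    if fmt == "npz":
        with np.load(path) as z:
            features = z["features"]
            labels = z["labels"] if "labels" in z.files else None
        return features, labels
    rows = np.genfromtxt(path, delimiter=",", names=True)
    names = list(rows.dtype.names)
    has_label = names[-1] == "label"
    feat_names = names[:-1] if has_label else names
    features = np.column_stack([rows[n] for n in feat_names])
    labels = rows["label"].astype(np.int64) if has_label else None
    return features, labels


def load_generic(manifest_path) -> DomainCollection:
    """Load a manifest-described directory into a validated collection."""
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "manifest.json"
    if not manifest_path.exists():
        raise LoadError(f"no manifest at {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    fmt = manifest.get("format", "npz")
    n_classes = int(manifest["n_classes"])
    layout = manifest.get("feature_layout") or {}
    domains = {}
    for entry in manifest["domains"]:
        path = manifest_path.parent / entry["path"]
        if not path.exists():
            raise LoadError(f"manifest references missing file {path}")
        features, labels = _read_domain_file(path, fmt)
        key = (int(entry["subject_index"]), int(entry["session_index"]))
        d = DomainDataset(features=features, labels=labels,
                          domain_id=f"subj{key[0]:02d}/sess{key[1]}")
        if d.n_samples != int(entry["n_samples"]):
            raise SchemaError(
                f"{path.name}: manifest says {entry['n_samples']} samples, "
                f"file has {d.n_samples}")
        if labels is not None and (labels.min() < 0 or labels.max() >= n_classes):
            raise SchemaError(
                f"{path.name}: label values outside [0, {n_classes})")
        if layout:
            expected = int(layout["n_electrodes"]) * int(layout["n_bands"])
            if expected != d.n_features:
                raise SchemaError(
                    f"{path.name}: layout implies {expected} features, "
                    f"file has {d.n_features}")
        domains[key] = d
    return DomainCollection(domains=domains, n_classes=n_classes)


# ----------------------------------------------------------------- SEED .mat
def _load_mat(path: Path) -> dict:
    """Classic .mat via scipy, v7.3/HDF5 via h5py (transposed storage)."""
    import scipy.io

    try:
        return scipy.io.loadmat(path)
    except (NotImplementedError, ValueError):
        import h5py

        out = {}
        with h5py.File(path, "r") as f:
            for key, ds in f.items():
                if key.startswith("#"):
                    continue
                arr = np.array(ds)
                out[key] = arr.transpose(range(arr.ndim - 1, -1, -1))
        return out


def _trial_arrays(mat: dict, pattern: str) -> list[np.ndarray]:
    rx = re.compile(pattern)
    keyed = []
    for key, val in mat.items():
        m = rx.fullmatch(key)
        if m:
            keyed.append((int(m.group(1)), np.asarray(val)))
    keyed.sort()
    return [v for _, v in keyed]


def load_seed_features(root, dataset: str = "seed",
                       feature_key: str = r"de_LDS(\d+)",
                       session_labels: dict | None = None) -> DomainCollection:
    """Load a SEED-style "ExtractedFeatures" directory.

    Expects per subject-session files named ``<subject>_<date>.mat`` whose
    keys match ``feature_key`` (default the ``de_LDS<trial>`` DE features),
    each of shape channels x samples x bands; trials are concatenated
    along time and merged into trial x (channels*bands).  Per-trial labels
    come from ``label.mat`` (key ``label``) or a ``session_labels`` mapping
    session -> label list; raw labels are remapped to contiguous 0-based
    integers in sorted raw order.
    """
    root = Path(root)
    if not root.is_dir():
        raise LoadError(f"{root} is not a directory")
    files = sorted(p for p in root.glob("*.mat")
                   if re.fullmatch(r"\d+_\d+\.mat", p.name))
    if not files:
        raise LoadError(f"no <subject>_<date>.mat files under {root}")

    # label source
    labels_by_session: dict[int, np.ndarray] = {}
    label_path = root / "label.mat"
    if label_path.exists():
        raw = np.asarray(_load_mat(label_path)["label"]).ravel()
        shared = raw
    elif session_labels is not None:
        shared = None
        labels_by_session = {int(k): np.asarray(v).ravel()
                             for k, v in session_labels.items()}
    else:
        raise LoadError(f"no label.mat under {root} and no session_labels given")

    # session index = rank of the date within each subject's files
    by_subject: dict[int, list[Path]] = {}
    for p in files:
        subj = int(p.name.split("_")[0])
        by_subject.setdefault(subj, []).append(p)

    domains, raw_label_values = {}, set()
    parsed = {}
    for subj, paths in by_subject.items():
        for sess, path in enumerate(sorted(paths, key=lambda q: q.name), start=1):
            mat = _load_mat(path)
            trials = _trial_arrays(mat, feature_key)
            if not trials:
                raise LoadError(f"{path.name}: no keys matching {feature_key!r}")
            raw = shared if shared is not None else labels_by_session.get(sess)
            if raw is None or len(raw) != len(trials):
                raise LoadError(
                    f"{path.name}: {len(trials)} trials but "
                    f"{'no' if raw is None else len(raw)} labels for session {sess}")
            feats, labs = [], []
            for t, arr in enumerate(trials):
                if arr.ndim != 3:
                    raise LoadError(f"{path.name}: trial {t + 1} is not 3-D")
                # channels x samples x bands -> samples x channels x bands
                cube = np.transpose(arr, (1, 0, 2))
                feats.append(reshape_channel_band(cube))
                labs.append(np.full(cube.shape[0], raw[t]))
            parsed[(subj, sess)] = (np.vstack(feats), np.concatenate(labs))
            raw_label_values.update(np.unique(parsed[(subj, sess)][1]).tolist())

    mapping = {v: i for i, v in enumerate(sorted(raw_label_values))}
    for key, (X, y) in parsed.items():
        domains[key] = DomainDataset(
            features=X, labels=np.array([mapping[v] for v in y]),
            domain_id=f"subj{key[0]:02d}/sess{key[1]}")
    return DomainCollection(domains=domains, n_classes=len(mapping))
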