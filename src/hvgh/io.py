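"""Reading and writing datasets, labels, segmentations and model bundles.

On disk a dataset is a directory of per-sequence CSV files (frames x
dimensions, optional single header row) with optional ``*.labels.csv``
companions (one integer per frame) and a JSON manifest.  Frame indices
in all files are 0-based with half-open [start, end) extents; the GP's
1-based within-segment position is an internal convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .hsmm import Tile

SCALE_FLOOR = 1e-8


@dataclass
class Normalizer:
    """Per-dimension z-scoring with a scale floor for constant columns."""

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, frames: np.ndarray) -> "Normalizer":
        frames = np.atleast_2d(np.asarray(frames, dtype=float))
        return cls(
            mean=frames.mean(axis=0),
            scale=np.maximum(frames.std(axis=0), SCALE_FLOOR),
        )

    def transform(self, X):
        return (np.asarray(X, dtype=float) - self.mean) / self.scale

    def inverse(self, Z):
        return np.asarray(Z, dtype=float) * self.scale + self.mean


def _has_header(path) -> bool:
    with open(path) as fh:
        first = fh.readline()
    for tok in first.replace("\t", ",").split(","):
        tok = tok.strip()
        if not tok:
            continue
        try:
            float(tok)
        except ValueError:
            return True
    return False


def read_sequence_csv(path) -> np.ndarray:
    """One (T, D) sequence from CSV/TSV, with or without a header row."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    header = 0 if _has_header(path) else None
    df = pd.read_csv(path, sep=sep, header=header)
    return df.to_numpy(dtype=float)


def sequence_files(directory) -> list[Path]:
    directory = Path(directory)
    return sorted(
        p
        for p in list(directory.glob("*.csv")) + list(directory.glob("*.tsv"))
        if not p.name.endswith(".labels.csv")
    )


def read_sequences(path):
    """Sequences plus a fitted Normalizer.

    ``path`` may be a directory of per-sequence files or a single file.
    Returns (sequences, normalizer); normalization stats are fitted on
    all frames pooled.
    """
    path = Path(path)
    files = sequence_files(path) if path.is_dir() else [path]
    if not files:
        raise FileNotFoundError(f"no sequence CSV files under {path}")
    seqs = [read_sequence_csv(f) for f in files]
    D = seqs[0].shape[1]
    for f, s in zip(files, seqs):
        if s.shape[1] != D:
            raise ValueError(f"{f} has {s.shape[1]} dims, expected {D}")
    norm = Normalizer.fit(np.vstack(seqs))
    return seqs, norm


def read_labels(path) -> np.ndarray:
    """Per-frame integer labels, one per line."""
    return np.loadtxt(path, dtype=int, ndmin=1)


def write_labels(labels, path) -> None:
    np.savetxt(path, np.asarray(labels, dtype=int), fmt="%d")


def write_segmentation(segmentations, path) -> None:
    """Tiles of every sequence as CSV rows (sequence_id, start, end, class)."""
    rows = [
        {"sequence_id": n, "start": t.start, "end": t.end, "class": t.cls}
        for n, tiles in enumerate(segmentations)
        for t in tiles
    ]
    df = pd.DataFrame(rows, columns=["sequence_id", "start", "end", "class"])
    if rows:
        df = df.sort_values(["sequence_id", "start"])
    df.to_csv(path, index=False)


def read_segmentation(path):
    """Inverse of write_segmentation: list (per sequence) of Tile lists."""
    df = pd.read_csv(path)
    out: list[list[Tile]] = []
    if df.empty:
        return out
    for n in range(int(df["sequence_id"].max()) + 1):
        sub = df[df["sequence_id"] == n].sort_values("start")
        out.append(
            [Tile(int(r.start), int(r.end), int(r["class"])) for _, r in sub.iterrows()]
        )
    return out


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


# --------------------------------------------------------------- model bundle


def save_model(est, path) -> None:
    """Serialize a fitted HVGH estimator to one .npz archive."""
    arrays = {
        "config_json": np.frombuffer(
            json.dumps(est.get_params()).encode(), dtype=np.uint8
        ),
        "mean": est.mean_,
        "scale": est.scale_,
        "beta_atoms": est._state.beta.atoms,
        "beta_remainder": np.array([est._state.beta.remainder]),
        "n_class_keys": np.array(list(est._state.counts.n_class.keys()), dtype=int),
        "n_class_vals": np.array(list(est._state.counts.n_class.values()), dtype=int),
        "n_trans_keys": np.array(
            [list(k) for k in est._state.counts.n_trans.keys()], dtype=int
        ).reshape(-1, 2),
        "n_trans_vals": np.array(list(est._state.counts.n_trans.values()), dtype=int),
        "seg_rows": np.array(
            [
                (n, t.start, t.end, t.cls)
                for n, tiles in enumerate(est.segmentation_)
                for t in tiles
            ],
            dtype=int,
        ),
        "n_sequences": np.array([len(est.segmentation_)]),
        "latents": np.vstack(est._latents),
        "latent_lengths": np.array([z.shape[0] for z in est._latents]),
    }
    if est.vae_ is not None:
        for k, v in est.vae_.params.items():
            arrays[f"vae_{k}"] = v
    np.savez(path, **arrays)


def load_model(path):
    """Reconstruct a fitted HVGH estimator from save_model output."""
    from .hdp import StickWeights, TransitionCounts
    from .hsmm import GibbsState
    from .model import HVGH
    from .vae import VAE

    with np.load(path) as z:
        data = {k: z[k] for k in z.files}
    params = json.loads(bytes(data["config_json"]).decode())
    params["hidden"] = tuple(params["hidden"])
    est = HVGH(**params)
    est.mean_ = data["mean"]
    est.scale_ = data["scale"]
    lengths = data["latent_lengths"]
    offs = np.concatenate([[0], np.cumsum(lengths)])
    est._latents = [
        data["latents"][offs[i] : offs[i + 1]] for i in range(len(lengths))
    ]
    n_seq = int(data["n_sequences"][0])
    segs: list[list[Tile]] = [[] for _ in range(n_seq)]
    for n, s, e, c in data["seg_rows"]:
        segs[n].append(Tile(int(s), int(e), int(c)))
    beta = StickWeights(
        atoms=data["beta_atoms"], remainder=float(data["beta_remainder"][0])
    )
    counts = TransitionCounts(
        n_class={int(k): int(v) for k, v in zip(data["n_class_keys"], data["n_class_vals"])},
        n_trans={
            (int(a), int(b)): int(v)
            for (a, b), v in zip(data["n_trans_keys"], data["n_trans_vals"])
        },
    )
    _, _, rng_gibbs, rng_pred = est._rngs()
    state = GibbsState(
        config=est._gibbs_config(),
        latent_dim=est.latent_dim,
        rng=rng_gibbs,
        beta=beta,
        counts=counts,
    )
    state.segmentations = segs
    state.handles = [[] for _ in range(n_seq)]
    est._state = state
    est._rng_predict = rng_pred
    est._reseat(state, est._latents)
    if any(k.startswith("vae_") for k in data):
        est.vae_ = VAE(
            input_dim=est.mean_.size,
            latent_dim=est.latent_dim,
            hidden=tuple(est.hidden),
            learning_rate=est.learning_rate,
        )
        for k in est.vae_.params:
            est.vae_.params[k] = data[f"vae_{k}"]
    else:
        est.vae_ = None
    est.segmentation_ = segs
    est.labels_ = [
        HVGH._tiles_to_labels(tiles, int(T)) for tiles, T in zip(segs, lengths)
    ]
    est.n_classes_ = len(state.classes_in_use())
    return est
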