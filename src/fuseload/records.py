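"""Sharded record files for assembled sample sets.

Plays the role a TFRecord dataset plays in a TensorFlow pipeline —
shuffle/batch/split over serialized multimodal samples — but is
format-agnostic: each shard is a compressed ``.npz`` holding stacked
per-modality tensors, labels and ids, with a JSON manifest alongside.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .segmentation import MultimodalSample, SampleSet

__all__ = ["save_shards", "load_sample_set"]


def save_shards(sample_set: SampleSet, out_dir, shard_size: int = 256) -> list[Path]:
    """Write a sample set as ``shard_NNNN.npz`` files plus ``manifest.json``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    n = len(sample_set)
    modalities = list(sample_set.samples[0].windows) if n else []
    for shard_idx, lo in enumerate(range(0, max(n, 1), shard_size)):
        chunk = sample_set.samples[lo : lo + shard_size]
        if not chunk and n:
            break
        payload = {
            f"mod_{m}": np.stack([s.windows[m] for s in chunk]).astype(np.float32)
            for m in modalities
        } if chunk else {}
        payload["labels"] = np.array([s.label for s in chunk], dtype=np.float64)
        payload["puzzle_ids"] = np.array([s.puzzle_id for s in chunk], dtype=np.int64)
        payload["marker_times"] = np.array([s.marker_time for s in chunk])
        payload["participant_ids"] = np.array([s.participant_id for s in chunk])
        p = out / f"shard_{shard_idx:04d}.npz"
        np.savez_compressed(p, **payload)
        paths.append(p)
        if not chunk:
            break
    (out / "manifest.json").write_text(
        json.dumps(
            {
                "n_samples": n,
                "n_shards": len(paths),
                "modalities": modalities,
                "labelling_scheme": sample_set.labelling_scheme,
                "label_counts": {str(k): v for k, v in sample_set.label_counts.items()},
            },
            indent=2,
        )
    )
    return paths


def load_sample_set(shard_dir) -> SampleSet:
    """Reassemble a :class:`SampleSet` from a shard directory."""
    d = Path(shard_dir)
    manifest = json.loads((d / "manifest.json").read_text())
    modalities = manifest["modalities"]
    samples: list[MultimodalSample] = []
    for p in sorted(d.glob("shard_*.npz")):
        with np.load(p, allow_pickle=False) as z:
            labels = z["labels"]
            for i in range(len(labels)):
                samples.append(
                    MultimodalSample(
                        windows={m: z[f"mod_{m}"][i] for m in modalities},
                        label=float(labels[i]),
                        participant_id=str(z["participant_ids"][i]),
                        puzzle_id=int(z["puzzle_ids"][i]),
                        marker_time=float(z["marker_times"][i]),
                    )
                )
    return SampleSet(samples=samples, labelling_scheme=manifest["labelling_scheme"])
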