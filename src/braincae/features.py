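"""Feature matrices: flattened latent vectors and ROI-mean baselines.

The latent features of a subject are the activations of the trained
encoder's extraction layer, flattened in a fixed channel-major order
(channel, then x, y, z).  The baseline features are mean intensities
over the parcels of an anatomical parcellation (116 regions in the
reference atlas), restricted to the subject's GM mask — the
conventional ROI-averaging representation the autoencoder is compared
against.

For phantom work a synthetic Voronoi-style parcellation of the GM
shell is provided, so the ROI baseline is testable without an atlas
file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .architecture import CAE
from .volume import GreyMatterVolume

__all__ = [
    "FeatureMatrix",
    "AtlasParcellation",
    "extract_features",
    "roi_features",
    "synthetic_parcellation",
]

FLATTEN_ORDER = "channel-major (channel, x, y, z), C order"


@dataclass
class FeatureMatrix:
    matrix: np.ndarray          # subjects x features
    subject_ids: list[str]
    kind: str                   # "latent" | "roi"
    provenance: dict

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2:
            raise ValueError("feature matrix must be 2D")
        if self.matrix.shape[0] != len(self.subject_ids):
            raise ValueError("row count does not match subject ids")
        if not np.isfinite(self.matrix).all():
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def rows_for(self, ids) -> np.ndarray:
        index = {s: i for i, s in enumerate(self.subject_ids)}
        return self.matrix[[index[s] for s in ids]]

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.matrix,
                          columns=[f"f{i}" for i in range(self.n_features)])
        df.insert(0, "id", self.subject_ids)
        df.to_csv(path, sep="\t", index=False)
        sidecar = {"kind": self.kind, "flatten_order": FLATTEN_ORDER,
                   "provenance": self.provenance}
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def from_tsv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"id": str})
        with open(str(path) + ".json") as fh:
            sidecar = json.load(fh)
        return cls(matrix=df.drop(columns="id").to_numpy(),
                   subject_ids=list(df["id"]), kind=sidecar["kind"],
                   provenance=sidecar["provenance"])


@dataclass
class AtlasParcellation:
    """Integer label volume; 0 = outside, parcels are 1..n (all non-empty)."""

    labels: np.ndarray
    parcel_ids: list[int]
    parcel_names: list[str] | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.min() < 0:
            raise ValueError("parcel labels must be >= 0")
        present = set(np.unique(self.labels)) - {0}
        empty = [p for p in self.parcel_ids if p not in present]
        if empty:
            raise ValueError(f"empty parcels in atlas: {empty}")

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_ids)


def extract_features(model: CAE, cohort, batch_size: int = 8) -> FeatureMatrix:
    """Run the frozen encoder over a cohort and flatten the latent maps.

    Rows are independent — each subject's features depend on that
    subject's volume alone — and the flattening order is fixed and
    recorded in the matrix provenance.
    """
    ids, rows = [], []
    vols = list(cohort)
    for i in range(0, len(vols), batch_size):
        chunk = vols[i : i + batch_size]
        arr = np.stack([v.data if isinstance(v, GreyMatterVolume) else np.asarray(v)
                        for v in chunk]).astype(np.float32)
        if arr.shape[1:] != model.input_shape:
            raise ValueError(
                f"cohort grid {arr.shape[1:]} incompatible with model grid "
                f"{model.input_shape}")
        z = model.encode(arr, keep=False)           # (C, B, d, h, w)
        z = np.moveaxis(z, 1, 0)                    # (B, C, d, h, w)
        rows.append(z.reshape(z.shape[0], -1))
        ids += [v.subject_id if isinstance(v, GreyMatterVolume) else str(i + j)
                for j, v in enumerate(chunk)]
    return FeatureMatrix(
        matrix=np.concatenate(rows, axis=0), subject_ids=ids, kind="latent",
        provenance={"spec": {"n_blocks": model.spec.n_blocks,
                             "extraction_channels": model.spec.extraction_channels},
                    "input_shape": list(model.input_shape),
                    "flatten_order": FLATTEN_ORDER})


def roi_features(cohort, atlas: AtlasParcellation) -> FeatureMatrix:
    """Mean intensity per parcel (parcel ∩ subject GM mask) per subject."""
    ids, rows = [], []
    for vol in cohort:
        if atlas.labels.shape != vol.data.shape:
            raise ValueError("atlas grid does not match cohort grid")
        feats = np.empty(atlas.n_parcels, dtype=np.float64)
        for j, pid in enumerate(atlas.parcel_ids):
            sel = (atlas.labels == pid) & vol.mask
            if not sel.any():
                sel = atlas.labels == pid  # mask may not cover a site's parcel
                if not sel.any():
                    raise ValueError(f"parcel {pid} is empty")
            feats[j] = vol.data[sel].mean()
        rows.append(feats)
        ids.append(vol.subject_id)
    return FeatureMatrix(matrix=np.stack(rows), subject_ids=ids, kind="roi",
                         provenance={"atlas": "parcellation",
                                     "n_parcels": atlas.n_parcels})


def synthetic_parcellation(mask: np.ndarray, n_parcels: int = 116,
                           seed: int = 0) -> AtlasParcellation:
    """Voronoi-style partition of a GM mask into ``n_parcels`` regions.

    Seeds are drawn uniformly from the mask and every mask voxel joins
    its nearest seed, yielding contiguous-ish, non-empty parcels.
    """
    mask = np.asarray(mask, dtype=bool)
    coords = np.argwhere(mask)
    if len(coords) < n_parcels:
        raise ValueError(
            f"mask has {len(coords)} voxels, fewer than {n_parcels} parcels")
    rng = np.random.default_rng(seed)
    seed_idx = rng.choice(len(coords), size=n_parcels, replace=False)
    seeds = coords[seed_idx].astype(np.float64)
    # nearest-seed assignment, chunked to bound memory
    labels = np.zeros(mask.shape, dtype=np.int32)
    pts = coords.astype(np.float64)
    assign = np.empty(len(pts), dtype=np.int32)
    chunk = 200_000
    for i in range(0, len(pts), chunk):
        d2 = ((pts[i : i + chunk, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
        assign[i : i + chunk] = np.argmin(d2, axis=1)
    labels[tuple(coords.T)] = assign + 1
    return AtlasParcellation(labels=labels,
                             parcel_ids=list(range(1, n_parcels + 1)))
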