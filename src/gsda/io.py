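"""Delimited-text readers/writers and manifests.

All on-disk formats are plain text: CSV for tables and matrices, JSON for
manifests, models, masks and provenance.  Readers validate shapes and
columns and fail with row/column context.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from gsda.features import ATLAS_COLUMNS, AtlasTable, HemisphereSample
from gsda.workflow import FirstOrderEnsemble, FirstOrderRecord, LateralizationMask

__all__ = [
    "read_manifest",
    "write_manifest",
    "read_timeseries",
    "write_timeseries",
    "read_matrix",
    "write_matrix",
    "read_atlas",
    "write_atlas",
    "read_samples",
    "write_samples",
    "read_ensemble",
    "write_ensemble",
    "read_mask",
    "write_mask",
]

MANIFEST_KEYS = ("subject_id", "group", "session", "run", "path")


def read_manifest(path: str | Path) -> list[dict]:
    """JSON array of {subject_id, group, session, run, path} records."""
    path = Path(path)
    entries = json.loads(path.read_text())
    if not isinstance(entries, list):
        raise ValueError(f"{path}: manifest must be a JSON array")
    for k, entry in enumerate(entries):
        missing = [key for key in MANIFEST_KEYS if key not in entry]
        if missing:
            raise ValueError(f"{path}: entry {k} missing keys {missing}")
        if entry["group"] not in (0, 1):
            raise ValueError(f"{path}: entry {k} has invalid group {entry['group']!r}")
    return entries


def write_manifest(entries: Sequence[dict], path: str | Path) -> None:
    for k, entry in enumerate(entries):
        missing = [key for key in MANIFEST_KEYS if key not in entry]
        if missing:
            raise ValueError(f"manifest entry {k} missing keys {missing}")
    Path(path).write_text(json.dumps(list(entries), indent=2))


def read_timeseries(path: str | Path) -> tuple[np.ndarray, list[int]]:
    """Frames-by-ROIs CSV with a roi_id header row; returns (array, roi_ids)."""
    df = pd.read_csv(path)
    try:
        roi_ids = [int(c) for c in df.columns]
    except ValueError as err:
        raise ValueError(f"{path}: header must hold integer roi_ids ({err})") from None
    values = df.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        bad = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(f"{path}: non-finite value at frame {bad[0]}, column {bad[1]}")
    return values, roi_ids


def write_timeseries(values: np.ndarray, roi_ids: Sequence[int], path: str | Path) -> None:
    pd.DataFrame(np.asarray(values, dtype=float), columns=[str(r) for r in roi_ids]).to_csv(
        path, index=False
    )


def read_matrix(path: str | Path) -> np.ndarray:
    """Square connectivity CSV with roi_id header row and index column."""
    df = pd.read_csv(path, index_col=0)
    mat = df.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{path}: matrix is {mat.shape}, expected square")
    if not np.isfinite(mat).all():
        raise ValueError(f"{path}: matrix contains non-finite entries")
    return mat


def write_matrix(mat: np.ndarray, path: str | Path) -> None:
    mat = np.asarray(mat, dtype=float)
    labels = [str(i) for i in range(mat.shape[0])]
    pd.DataFrame(mat, index=labels, columns=labels).to_csv(path)


def read_atlas(path: str | Path) -> AtlasTable:
    df = pd.read_csv(path)
    missing = [c for c in ATLAS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: atlas missing columns {missing}")
    return AtlasTable(df)


def write_atlas(atlas: AtlasTable, path: str | Path) -> None:
    atlas.table.to_csv(path, index=False)


def write_samples(samples: Sequence[HemisphereSample], path: str | Path) -> None:
    """Wide CSV: subject_id, session, hemisphere, group, f0..f{p-1}."""
    p = samples[0].features.shape[0]
    feat = np.vstack([s.features for s in samples])
    df = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in samples],
            "session": [s.session for s in samples],
            "hemisphere": [s.hemisphere for s in samples],
            "group": [s.group for s in samples],
        }
    )
    df = pd.concat([df, pd.DataFrame(feat, columns=[f"f{i}" for i in range(p)])], axis=1)
    df.to_csv(path, index=False)


def read_samples(path: str | Path) -> list[HemisphereSample]:
    df = pd.read_csv(path)
    required = ["subject_id", "session", "hemisphere", "group"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: samples table missing columns {missing}")
    feat_cols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    feat_cols.sort(key=lambda c: int(c[1:]))
    if not feat_cols:
        raise ValueError(f"{path}: no feature columns (f0, f1, ...)")
    feats = df[feat_cols].to_numpy(dtype=float)
    return [
        HemisphereSample(
            subject_id=str(row.subject_id),
            session=str(row.session),
            hemisphere=int(row.hemisphere),
            group=int(row.group),
            features=feats[i],
        )
        for i, row in enumerate(df.itertuples())
    ]


def write_ensemble(ensemble: FirstOrderEnsemble, directory: str | Path) -> None:
    """Ensemble as records CSV + weights CSV + JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ensemble.to_dataframe().to_csv(directory / "records.csv", index=False)
    W = np.vstack([r.weights for r in ensemble.records])
    pd.DataFrame(W, columns=[f"w{i}" for i in range(W.shape[1])]).to_csv(
        directory / "weights.csv", index=False
    )
    (directory / "ensemble.json").write_text(json.dumps(ensemble.meta, indent=2))


def read_ensemble(directory: str | Path) -> FirstOrderEnsemble:
    directory = Path(directory)
    records_df = pd.read_csv(directory / "records.csv")
    W = pd.read_csv(directory / "weights.csv").to_numpy(dtype=float)
    meta = json.loads((directory / "ensemble.json").read_text())
    if len(records_df) != W.shape[0]:
        raise ValueError(f"{directory}: records/weights row mismatch")
    records = []
    for i, row in records_df.iterrows():
        records.append(
            FirstOrderRecord(
                repetition=int(row["repetition"]),
                seed=int(row["seed"]),
                lam=float(row["lam"]),
                alpha=float(row["alpha"]),
                target_group=int(row["target_group"]),
                weights=W[i],
                bat=float(row["bat"]),
                bant=float(row["bant"]),
                gsi=float(row["gsi"]),
                bat_heldout=None if pd.isna(row["bat_heldout"]) else float(row["bat_heldout"]),
                bant_heldout=None
                if pd.isna(row["bant_heldout"])
                else float(row["bant_heldout"]),
            )
        )
    return FirstOrderEnsemble(records, meta)


def write_mask(
    mask: LateralizationMask,
    path: str | Path,
    atlas: AtlasTable | None = None,
    h: int | None = None,
    weights: np.ndarray | None = None,
) -> None:
    """Mask as JSON; optionally an edge-list CSV next to it (same stem).

    The edge list has one row per chord: roi_i, roi_j, lobe_i, lobe_j,
    sign, weight -- suitable for chord-diagram tools.
    """
    path = Path(path)
    payload = {
        "indices": mask.sorted_indices(),
        "top_fraction": mask.top_fraction,
        "provenance": list(mask.provenance),
    }
    path.write_text(json.dumps(payload, indent=2))
    if atlas is not None or h is not None:
        from gsda.features import linear_index_to_pair

        hh = atlas.h if atlas is not None else h
        lobes = atlas.homologue_lobes() if atlas is not None else None
        rows = []
        for idx in mask.sorted_indices():
            i, j = linear_index_to_pair(idx, hh)
            w = float(weights[idx]) if weights is not None else np.nan
            rows.append(
                {
                    "connection": idx,
                    "roi_i": i,
                    "roi_j": j,
                    "lobe_i": lobes[i] if lobes is not None else "",
                    "lobe_j": lobes[j] if lobes is not None else "",
                    "sign": "negative" if w < 0 else "positive",
                    "weight": w,
                }
            )
        pd.DataFrame(
            rows,
            columns=["connection", "roi_i", "roi_j", "lobe_i", "lobe_j", "sign", "weight"],
        ).to_csv(path.with_suffix(".edges.csv"), index=False)


def read_mask(path: str | Path) -> LateralizationMask:
    payload = json.loads(Path(path).read_text())
    return LateralizationMask(
        indices=frozenset(int(i) for i in payload["indices"]),
        top_fraction=float(payload["top_fraction"]),
        provenance=tuple(payload.get("provenance", ())),
    )
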