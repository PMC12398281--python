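"""Intrahemispheric connectivity feature extraction.

Pipeline: ROI time series -> Pearson correlation -> Fisher z -> (average
across runs) -> reorder into per-hemisphere matrices aligned by homologue
index -> strictly-upper-triangle feature vectors.

Connectivity matrices are plain square :class:`numpy.ndarray` objects:
symmetric, zero diagonal, finite, Fisher-z units.  The atlas table is the
single source of truth for hemisphere membership and homologue pairing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AtlasTable",
    "HemisphereSample",
    "default_atlas",
    "correlation_fisher_z",
    "average_runs",
    "split_hemispheres",
    "upper_triangle_vector",
    "vector_to_matrix",
    "pair_to_linear_index",
    "linear_index_to_pair",
]

ATLAS_COLUMNS = ("roi_id", "name", "hemisphere", "homologue_index", "lobe", "gyrus")

#: Clamp bound applied to correlations before atanh.
R_CLAMP = 1.0 - 1e-12

DEFAULT_LOBES = (
    "Frontal",
    "Temporal",
    "Parietal",
    "Insular",
    "Limbic",
    "Occipital",
    "Subcortical",
)


@dataclass
class AtlasTable:
    """ROI atlas: id, name, hemisphere (L/R), homologue index, lobe, gyrus.

    Invariants: equal ROI counts per hemisphere; within each hemisphere the
    homologue indices are a bijection onto 0..h-1, so left/right ROIs pair
    one-to-one by homologue index.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ATLAS_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"atlas table missing columns: {missing}")
        table = self.table.reset_index(drop=True)
        hemis = set(table["hemisphere"])
        if hemis != {"L", "R"}:
            raise ValueError(f"hemisphere column must contain exactly L and R, got {hemis}")
        counts = table["hemisphere"].value_counts()
        if counts["L"] != counts["R"]:
            raise ValueError("unequal ROI counts per hemisphere")
        h = int(counts["L"])
        for hemi in ("L", "R"):
            idx = sorted(table.loc[table["hemisphere"] == hemi, "homologue_index"])
            if idx != list(range(h)):
                raise ValueError(f"homologue_index not a bijection onto 0..{h - 1} in {hemi}")
        if sorted(table["roi_id"]) != list(range(2 * h)):
            raise ValueError("roi_id must enumerate 0..n_rois-1")
        self.table = table

    @property
    def n_rois(self) -> int:
        return len(self.table)

    @property
    def h(self) -> int:
        """ROIs per hemisphere."""
        return self.n_rois // 2

    def hemisphere_rows(self, hemisphere: str) -> np.ndarray:
        """Row positions (by roi_id order) of one hemisphere, homologue-ordered."""
        sub = self.table[self.table["hemisphere"] == hemisphere]
        sub = sub.sort_values("homologue_index")
        return sub["roi_id"].to_numpy()

    def homologue_lobes(self, hemisphere: str = "L") -> np.ndarray:
        """Lobe label per homologue index (taken from one hemisphere)."""
        sub = self.table[self.table["hemisphere"] == hemisphere]
        sub = sub.sort_values("homologue_index")
        return sub["lobe"].to_numpy()

    def lobe_sizes(self, hemisphere: str = "L") -> dict[str, int]:
        lobes = self.homologue_lobes(hemisphere)
        labels, counts = np.unique(lobes, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))


@dataclass
class HemisphereSample:
    """One brain-hemisphere observation.

    ``hemisphere`` is the classification label (left = 0, right = 1),
    ``group`` the grouping-factor code (e.g. male = 0, female = 1).
    """

    subject_id: str
    session: str
    hemisphere: int
    group: int
    features: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float).ravel()
        if self.hemisphere not in (0, 1):
            raise ValueError("hemisphere label must be 0 (left) or 1 (right)")
        if self.group not in (0, 1):
            raise ValueError("group code must be 0 or 1")


def default_atlas(h: int = 123, lobes: tuple[str, ...] = DEFAULT_LOBES) -> AtlasTable:
    """A BNA-style atlas with odd/even interleaved left/right ROIs.

    ``roi_id`` 2k is the left member and 2k+1 the right member of homologue
    pair k; lobes are contiguous blocks of homologue indices.
    """
    blocks = np.array_split(np.arange(h), len(lobes))
    lobe_of = np.empty(h, dtype=object)
    for label, block in zip(lobes, blocks):
        lobe_of[block] = label
    rows = []
    for k in range(h):
        for hemi, offset in (("L", 0), ("R", 1)):
            rows.append(
                {
                    "roi_id": 2 * k + offset,
                    "name": f"ROI{k:03d}_{hemi}",
                    "hemisphere": hemi,
                    "homologue_index": k,
                    "lobe": lobe_of[k],
                    "gyrus": f"G{k // 3:02d}_{hemi}",
                }
            )
    return AtlasTable(pd.DataFrame(rows))


def correlation_fisher_z(timeseries: np.ndarray) -> np.ndarray:
    """Fisher-z connectivity matrix from a frames-by-ROIs time-series array.

    Pearson correlations are clamped to +-(1 - 1e-12) before atanh so that
    numerically perfect correlations stay finite; the diagonal is set to 0.

    Raises
    ------
    ValueError
        If fewer than 3 frames, or a constant column is present (named).
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 3:
        raise ValueError("timeseries must be a frames-by-ROIs array with >= 3 frames")
    constant = np.flatnonzero(ts.std(axis=0) == 0)
    if constant.size:
        raise ValueError(f"constant time series for ROI column(s) {constant.tolist()}")
    r = np.corrcoef(ts, rowvar=False)
    r = np.clip(r, -R_CLAMP, R_CLAMP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return z


def average_runs(matrices) -> np.ndarray:
    """Elementwise arithmetic mean of connectivity matrices in z-space."""
    mats = [np.asarray(m, dtype=float) for m in matrices]
    if not mats:
        raise ValueError("no matrices to average")
    shape = mats[0].shape
    for m in mats[1:]:
        if m.shape != shape:
            raise ValueError("connectivity matrices differ in shape")
    return np.mean(mats, axis=0)


def split_hemispheres(full: np.ndarray, atlas: AtlasTable) -> tuple[np.ndarray, np.ndarray]:
    """Reorder a whole-brain matrix into homologue-ordered (left, right) blocks.

    Row/column k of each output corresponds to homologue pair k, so the two
    intrahemispheric matrices align feature-for-feature.
    """
    full = np.asarray(full, dtype=float)
    n = atlas.n_rois
    if full.shape != (n, n):
        raise ValueError(f"matrix shape {full.shape} does not match atlas with {n} ROIs")
    left_idx = atlas.hemisphere_rows("L")
    right_idx = atlas.hemisphere_rows("R")
    left = full[np.ix_(left_idx, left_idx)]
    right = full[np.ix_(right_idx, right_idx)]
    return left, right


def upper_triangle_vector(mat: np.ndarray) -> np.ndarray:
    """Strictly-upper-triangle entries in row-major order; length h(h-1)/2."""
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("expected a square matrix")
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def vector_to_matrix(vec: np.ndarray, h: int) -> np.ndarray:
    """Inverse of :func:`upper_triangle_vector` (symmetric, zero diagonal)."""
    vec = np.asarray(vec, dtype=float)
    if vec.shape[0] != h * (h - 1) // 2:
        raise ValueError(f"vector length {vec.shape[0]} != {h * (h - 1) // 2}")
    mat = np.zeros((h, h))
    iu = np.triu_indices(h, k=1)
    mat[iu] = vec
    return mat + mat.T


def pair_to_linear_index(i: int, j: int, h: int) -> int:
    """Linear index of ROI pair (i, j), i < j, in upper-triangle order."""
    if not 0 <= i < j < h:
        raise ValueError(f"need 0 <= i < j < h, got (i={i}, j={j}, h={h})")
    return i * h - i * (i + 1) // 2 + (j - i - 1)


def linear_index_to_pair(idx: int, h: int) -> tuple[int, int]:
    """ROI pair (i, j) of a linear upper-triangle index; inverse of
    :func:`pair_to_linear_index`."""
    p = h * (h - 1) // 2
    if not 0 <= idx < p:
        raise ValueError(f"index {idx} outside [0, {p})")
    # solve smallest i with cumulative count > idx
    i = int((2 * h - 1 - np.sqrt((2 * h - 1) ** 2 - 8 * idx)) / 2)
    # guard floating error at block boundaries
    while pair_to_linear_index(i, i + 1, h) > idx:
        i -= 1
    while i + 1 < h - 1 and pair_to_linear_index(i + 1, i + 2, h) <= idx:
        i += 1
    j = idx - pair_to_linear_index(i, i + 1, h) + i + 1
    return i, j


def hemisphere_samples_from_matrix(
    full: np.ndarray,
    atlas: AtlasTable,
    subject_id: str,
    session: str,
    group: int,
) -> tuple[HemisphereSample, HemisphereSample]:
    """Split, vectorize and wrap one whole-brain matrix into its two samples."""
    left, right = split_hemispheres(full, atlas)
    return (
        HemisphereSample(subject_id, session, 0, group, upper_triangle_vector(left)),
        HemisphereSample(subject_id, session, 1, group, upper_triangle_vector(right)),
    )
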