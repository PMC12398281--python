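"""Synthetic paired left/right hemisphere connectivity data.

Generates Fisher-z feature vectors with controllable group structure so the
full first-order / second-order workflow is testable without restricted
neuroimaging data.  The signal model is additive in z-space:

* a population baseline symmetric matrix (sd ``baseline_z_sd``) shared by
  everyone, plus a per-subject symmetric random effect (sd
  ``subject_effect_sd``) shared by that subject's two hemispheres;
* *shared* lateralized connections: the left copy is shifted by
  ``+offset/2`` and the right copy by ``-offset/2``, scaled per group, so
  both groups lateralize the same connections with group-dependent
  strength;
* *exclusive* lateralized connections: the same +-offset/2 pattern applied
  in one group only, plus an optional group mean shift applied to both
  hemispheres (``+shift/2`` in the effect's group, ``-shift/2`` in the
  other).  The mean-shift component is what makes the linear score
  group-dependent -- a purely antisymmetric lateralization offset has
  identical group means once both hemispheres are pooled, leaving the
  dependence term nothing to latch onto;
* elementwise white noise (sd ``noise_sd``), re-symmetrized.

Group codes follow the estimator's convention ({0, 1}); hemisphere labels
are left = 0, right = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gsda.features import (
    HemisphereSample,
    pair_to_linear_index,
    upper_triangle_vector,
)

__all__ = [
    "SharedEffect",
    "ExclusiveEffect",
    "SyntheticConfig",
    "GroundTruth",
    "generate",
    "default_config",
    "null_config",
    "planted_recovery_report",
]


@dataclass(frozen=True)
class SharedEffect:
    """A lateralized connection present in both groups.

    ``scales`` multiplies the lateralization offset per group (index by
    group code), modelling shared connections that differ in strength of
    lateralization between groups.
    """

    connection: tuple[int, int]
    offset: float
    scales: tuple[float, float] = (1.0, 1.0)


@dataclass(frozen=True)
class ExclusiveEffect:
    """A lateralized connection present in exactly one group.

    ``sign`` flips the left/right direction.  ``group_shift`` adds a
    hemisphere-independent group mean difference at the same connection
    (``+group_shift/2`` for this group, ``-group_shift/2`` for the other),
    coupling the connection to the grouping factor.
    """

    connection: tuple[int, int]
    offset: float
    group: int
    sign: int = 1
    group_shift: float = 0.0


@dataclass(frozen=True)
class SyntheticConfig:
    n_subjects_per_group: int = 100
    h: int = 20
    n_lobes: int = 3
    shared_lateralized: tuple[SharedEffect, ...] = ()
    exclusive_lateralized: tuple[ExclusiveEffect, ...] = ()
    noise_sd: float = 0.2
    baseline_z_sd: float = 0.3
    subject_effect_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_group < 1 or self.h < 3:
            raise ValueError("need >= 1 subject per group and h >= 3")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.baseline_z_sd < 0 or self.subject_effect_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        for eff in list(self.shared_lateralized) + list(self.exclusive_lateralized):
            i, j = eff.connection
            if not 0 <= i < j < self.h:
                raise ValueError(f"connection {eff.connection} invalid for h={self.h}")
            if not np.isfinite(eff.offset):
                raise ValueError("offsets must be finite")
        for eff in self.exclusive_lateralized:
            if eff.group not in (0, 1):
                raise ValueError("exclusive effect group must be 0 or 1")


@dataclass
class GroundTruth:
    """Planted-effect record emitted alongside a generated dataset."""

    h: int
    shared_indices: list[int]
    exclusive_indices: dict[int, list[int]] = field(default_factory=dict)
    effects: dict[int, dict] = field(default_factory=dict)

    @property
    def all_planted(self) -> set[int]:
        out = set(self.shared_indices)
        for idxs in self.exclusive_indices.values():
            out.update(idxs)
        return out


def _symmetric_noise(rng: np.random.Generator, h: int, sd: float) -> np.ndarray:
    a = rng.normal(0.0, sd, size=(h, h))
    a = (a + a.T) / np.sqrt(2.0)
    np.fill_diagonal(a, 0.0)
    return a


def generate(config: SyntheticConfig) -> tuple[list[HemisphereSample], GroundTruth]:
    """Generate paired hemisphere samples and the planted ground truth.

    Each subject contributes exactly one left (label 0) and one right
    (label 1) sample, in homologue-ordered upper-triangle feature space of
    length ``h (h - 1) / 2``.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    h = config.h
    baseline = _symmetric_noise(rng, h, config.baseline_z_sd)

    # per-group, per-hemisphere structured offsets (constant across subjects)
    delta = {(g, hemi): np.zeros((h, h)) for g in (0, 1) for hemi in (0, 1)}
    truth = GroundTruth(h=h, shared_indices=[], exclusive_indices={0: [], 1: []})

    def add(mat: np.ndarray, conn: tuple[int, int], value: float) -> None:
        i, j = conn
        mat[i, j] += value
        mat[j, i] += value

    for eff in config.shared_lateralized:
        idx = pair_to_linear_index(*eff.connection, h)
        truth.shared_indices.append(idx)
        truth.effects[idx] = {"kind": "shared", "offset": eff.offset, "scales": eff.scales}
        for g in (0, 1):
            d = eff.offset * eff.scales[g]
            add(delta[(g, 0)], eff.connection, +d / 2.0)
            add(delta[(g, 1)], eff.connection, -d / 2.0)

    for eff in config.exclusive_lateralized:
        idx = pair_to_linear_index(*eff.connection, h)
        truth.exclusive_indices[eff.group].append(idx)
        truth.effects[idx] = {
            "kind": "exclusive",
            "group": eff.group,
            "offset": eff.offset,
            "sign": eff.sign,
            "group_shift": eff.group_shift,
        }
        d = eff.offset * eff.sign
        add(delta[(eff.group, 0)], eff.connection, +d / 2.0)
        add(delta[(eff.group, 1)], eff.connection, -d / 2.0)
        if eff.group_shift:
            for hemi in (0, 1):
                add(delta[(eff.group, hemi)], eff.connection, +eff.group_shift / 2.0)
                add(delta[(1 - eff.group, hemi)], eff.connection, -eff.group_shift / 2.0)

    samples: list[HemisphereSample] = []
    for g in (0, 1):
        for s in range(config.n_subjects_per_group):
            subject_id = f"g{g}s{s:04d}"
            subj = baseline + _symmetric_noise(rng, h, config.subject_effect_sd)
            for hemi in (0, 1):
                mat = subj + delta[(g, hemi)] + _symmetric_noise(rng, h, config.noise_sd)
                np.fill_diagonal(mat, 0.0)
                samples.append(
                    HemisphereSample(
                        subject_id=subject_id,
                        session="1",
                        hemisphere=hemi,
                        group=g,
                        features=upper_triangle_vector(mat),
                    )
                )
    return samples, truth


def default_config(
    seed: int = 0,
    n_subjects_per_group: int = 100,
    h: int = 20,
    shared_offset: float = 0.6,
    shared_scales: tuple[float, float] = (1.0, 0.85),
    exclusive_offset: float = 0.15,
    group_shift: float = 1.2,
    n_shared: int = 8,
    n_exclusive: int = 4,
    noise_sd: float = 0.6,
) -> SyntheticConfig:
    """A planted group-divergent configuration used throughout the tests.

    Shared lateralized connections carry the largest offsets (stronger in
    group 0), and each group additionally has ``n_exclusive`` exclusive
    connections coupled to the grouping factor via ``group_shift``.
    """
    # scale planted counts down for small feature spaces (at most half planted)
    budget = max(3, h * (h - 1) // 4)
    if n_shared + 2 * n_exclusive > budget:
        scale = budget / (n_shared + 2 * n_exclusive)
        n_shared = max(1, int(n_shared * scale))
        n_exclusive = max(1, int(n_exclusive * scale))
    connections = _spread_connections(h, n_shared + 2 * n_exclusive)
    shared = tuple(
        SharedEffect(conn, shared_offset, shared_scales)
        for conn in connections[:n_shared]
    )
    exclusive = []
    for k, conn in enumerate(connections[n_shared : n_shared + n_exclusive]):
        exclusive.append(
            ExclusiveEffect(conn, exclusive_offset, group=0, sign=(-1) ** k,
                            group_shift=group_shift)
        )
    for k, conn in enumerate(connections[n_shared + n_exclusive :]):
        exclusive.append(
            ExclusiveEffect(conn, exclusive_offset, group=1, sign=(-1) ** k,
                            group_shift=group_shift)
        )
    return SyntheticConfig(
        n_subjects_per_group=n_subjects_per_group,
        h=h,
        shared_lateralized=shared,
        exclusive_lateralized=tuple(exclusive),
        noise_sd=noise_sd,
        seed=seed,
    )


def null_config(seed: int = 0, n_subjects_per_group: int = 100, h: int = 20) -> SyntheticConfig:
    """No planted effects: both hemispheres drawn from the same distribution."""
    return SyntheticConfig(n_subjects_per_group=n_subjects_per_group, h=h, seed=seed)


def _spread_connections(h: int, n: int) -> list[tuple[int, int]]:
    """Deterministic, well-spread distinct ROI pairs."""
    from gsda.features import linear_index_to_pair

    total = h * (h - 1) // 2
    if n > total:
        raise ValueError(f"cannot place {n} distinct connections with h={h}")
    idxs = np.unique(np.linspace(0, total - 1, n).round().astype(int))
    if idxs.size < n:  # collisions only when n ~ total
        idxs = np.arange(n)
    return [linear_index_to_pair(int(k), h) for k in idxs]


def planted_recovery_report(
    predicted: set[int] | list[int],
    truth_indices: set[int] | list[int],
    weights: np.ndarray | None = None,
) -> dict[str, float]:
    """Set-overlap (and optional rank) metrics against planted connections.

    Returns precision and recall of ``predicted`` vs ``truth_indices``.
    If ``weights`` (a full-length connection-weight vector) is given, a
    rank-based retrieval score is added: the fraction of planted
    connections found in the top-``len(truth)`` positions by absolute
    weight.
    """
    pred = set(int(i) for i in predicted)
    truth = set(int(i) for i in truth_indices)
    tp = len(pred & truth)
    report = {
        "precision": tp / len(pred) if pred else 0.0,
        "recall": tp / len(truth) if truth else 0.0,
    }
    if weights is not None and truth:
        w = np.abs(np.asarray(weights, dtype=float))
        k = len(truth)
        top = set(np.argsort(-w, kind="stable")[:k].tolist())
        report["rank_retrieval"] = len(top & truth) / k
    return report
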