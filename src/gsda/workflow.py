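"""Experiment orchestration: partitions, first-order sweeps, second-order
classification, lateralization masks and lobe statistics.

First-order: repeated subject-aware partitions, one GSDA-Logit fit per
(repetition, lambda, target group), balanced accuracies and GSI on the
held-out side.  Second-order: the first-order connection-weight vectors
become features for a standard logistic classifier separating the two
ensembles' models; its weights localise where group-specific models differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split

from gsda import estimator
from gsda.estimator import GroupedDesign, GSDAHyperparams
from gsda.features import AtlasTable, HemisphereSample, linear_index_to_pair
from gsda.metrics import GroupedEvaluation, balanced_accuracy, gsi

__all__ = [
    "PartitionScheme",
    "HoldoutPartition",
    "FirstOrderRecord",
    "FirstOrderEnsemble",
    "LateralizationMask",
    "SecondOrderResult",
    "hemisphere_split_partition",
    "subject_holdout_partition",
    "run_first_order",
    "assemble_second_order_design",
    "run_second_order",
    "derive_mask",
    "apply_mask_to_model",
    "shared_exclusive_partition",
    "lobe_average_degree",
    "interaction_sign_counts",
]


@dataclass(frozen=True)
class PartitionScheme:
    """How to split samples into train/test for one repetition."""

    kind: str = "hemisphere_split"
    holdout_fraction: float = 0.2
    stratify_by_group: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("hemisphere_split", "subject_holdout"):
            raise ValueError(f"unknown partition kind {self.kind!r}")
        if not 0.0 < self.holdout_fraction < 1.0:
            raise ValueError("holdout_fraction must lie in (0, 1)")


class HoldoutPartition(NamedTuple):
    """Indices from :func:`subject_holdout_partition`.

    ``test`` is the hemisphere-split test side of the retained subjects;
    ``heldout`` contains both hemispheres of the fully held-out subjects.
    """

    train: np.ndarray
    test: np.ndarray
    heldout: np.ndarray


def _subject_table(samples: Sequence[HemisphereSample]) -> dict[str, dict]:
    """subject_id -> {'left': idx, 'right': idx, 'group': g}, validated."""
    table: dict[str, dict] = {}
    for i, s in enumerate(samples):
        rec = table.setdefault(s.subject_id, {"group": s.group})
        key = "left" if s.hemisphere == 0 else "right"
        if key in rec:
            raise ValueError(f"subject {s.subject_id} has duplicate {key} samples")
        if rec["group"] != s.group:
            raise ValueError(f"subject {s.subject_id} has inconsistent group codes")
        rec[key] = i
    for sid, rec in table.items():
        if "left" not in rec or "right" not in rec:
            raise ValueError(f"subject {sid} is missing a hemisphere")
    return table


def _split_subjects(
    subjects: list[str],
    groups: Mapping[str, int],
    rng: np.random.Generator,
    stratify: bool,
) -> tuple[list[str], list[str]]:
    """Split subjects into halves A and B, stratified by group.

    Odd strata alternate the extra subject between A and B so overall
    |A| - |B| stays within 1 (exactly 0 when each group has even size, or
    both groups are odd).
    """
    half_a: list[str] = []
    half_b: list[str] = []
    if stratify:
        strata = {}
        for sid in subjects:
            strata.setdefault(groups[sid], []).append(sid)
        keys = sorted(strata)
    else:
        strata = {None: list(subjects)}
        keys = [None]
    extra_to_a = True
    for key in keys:
        ids = sorted(strata[key])
        rng.shuffle(ids)
        n = len(ids)
        cut = n // 2
        if n % 2 == 1:
            if extra_to_a:
                cut += 1
            extra_to_a = not extra_to_a
        half_a.extend(ids[:cut])
        half_b.extend(ids[cut:])
    return half_a, half_b


def hemisphere_split_partition(
    samples: Sequence[HemisphereSample],
    seed: int,
    stratify_by_group: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Subject-aware 50/50 partition.

    Subjects are split into two halves; training takes the left hemispheres
    of half A and the right hemispheres of half B, testing takes the
    complements.  No subject contributes both hemispheres to the training
    set, and train/test are label-balanced whenever |A| = |B|.
    """
    table = _subject_table(samples)
    groups = {sid: rec["group"] for sid, rec in table.items()}
    rng = np.random.default_rng(seed)
    half_a, half_b = _split_subjects(sorted(table), groups, rng, stratify_by_group)
    train = [table[sid]["left"] for sid in half_a] + [table[sid]["right"] for sid in half_b]
    test = [table[sid]["right"] for sid in half_a] + [table[sid]["left"] for sid in half_b]
    return np.asarray(sorted(train)), np.asarray(sorted(test))


def subject_holdout_partition(
    samples: Sequence[HemisphereSample],
    holdout_fraction: float = 0.2,
    seed: int = 0,
    stratify_by_group: bool = True,
) -> HoldoutPartition:
    """Hold out a fraction of subjects entirely, split the rest by hemisphere.

    Held-out subjects contribute both hemispheres to ``heldout``; the
    remaining subjects are partitioned by :func:`hemisphere_split_partition`
    (seeded from the same generator).
    """
    if not 0.0 < holdout_fraction < 1.0:
        raise ValueError("holdout_fraction must lie in (0, 1)")
    table = _subject_table(samples)
    rng = np.random.default_rng(seed)
    if stratify_by_group:
        strata: dict[int, list[str]] = {}
        for sid, rec in table.items():
            strata.setdefault(rec["group"], []).append(sid)
    else:
        strata = {0: sorted(table)}
    heldout_subjects: list[str] = []
    for key in sorted(strata):
        ids = sorted(strata[key])
        rng.shuffle(ids)
        k = int(round(holdout_fraction * len(ids)))
        heldout_subjects.extend(ids[:k])
    heldout_set = set(heldout_subjects)
    heldout_idx = sorted(
        idx
        for sid in heldout_subjects
        for idx in (table[sid]["left"], table[sid]["right"])
    )
    remaining = [s for i, s in enumerate(samples) if samples[i].subject_id not in heldout_set]
    keep_positions = [i for i, s in enumerate(samples) if s.subject_id not in heldout_set]
    sub_seed = int(rng.integers(0, 2**31 - 1))
    train_rel, test_rel = hemisphere_split_partition(remaining, sub_seed, stratify_by_group)
    train = np.asarray([keep_positions[i] for i in train_rel])
    test = np.asarray([keep_positions[i] for i in test_rel])
    return HoldoutPartition(np.sort(train), np.sort(test), np.asarray(heldout_idx))


@dataclass
class FirstOrderRecord:
    """One fitted model and its grouped evaluation."""

    repetition: int
    seed: int
    lam: float
    alpha: float
    target_group: int
    weights: np.ndarray = field(repr=False)
    bat: float = np.nan
    bant: float = np.nan
    gsi: float = np.nan
    bat_heldout: float | None = None
    bant_heldout: float | None = None


@dataclass
class FirstOrderEnsemble:
    """All first-order records of one experiment plus its metadata."""

    records: list[FirstOrderRecord]
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def select(self, lam: float | None = None, target_group: int | None = None):
        out = self.records
        if lam is not None:
            out = [r for r in out if r.lam == lam]
        if target_group is not None:
            out = [r for r in out if r.target_group == target_group]
        return out

    def weight_matrix(self, lam: float, target_group: int) -> np.ndarray:
        """Stacked full weight vectors (bias at column 0), one row per model."""
        recs = self.select(lam, target_group)
        if not recs:
            raise ValueError(f"no records with lam={lam}, target_group={target_group}")
        return np.vstack([r.weights for r in recs])

    def mean_weights(self, lam: float, target_group: int) -> np.ndarray:
        """Elementwise mean of signed *connection* weights (bias dropped)."""
        return self.weight_matrix(lam, target_group)[:, 1:].mean(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "repetition": r.repetition,
                    "seed": r.seed,
                    "lam": r.lam,
                    "alpha": r.alpha,
                    "target_group": r.target_group,
                    "bat": r.bat,
                    "bant": r.bant,
                    "gsi": r.gsi,
                    "bat_heldout": r.bat_heldout,
                    "bant_heldout": r.bant_heldout,
                }
            )
        return pd.DataFrame(rows)


def _evaluate_groups(model, X, y, g, target_group) -> GroupedEvaluation:
    pred = estimator.predict(model, X)
    tmask = g == target_group
    bat = balanced_accuracy(y[tmask], pred[tmask])
    bant = balanced_accuracy(y[~tmask], pred[~tmask])
    return GroupedEvaluation(bat, bant, int(tmask.sum()), int((~tmask).sum()))


def run_first_order(
    samples: Sequence[HemisphereSample],
    scheme: PartitionScheme | None = None,
    lam_grid: Sequence[float] = (0.0, 1.0, 2.0, 5.0, 8.0, 10.0),
    alpha: float = 0.1,
    target_groups: Sequence[int] = (0, 1),
    n_repetitions: int = 1,
    base_seed: int = 0,
    params: GSDAHyperparams | None = None,
    heldout_samples: Sequence[HemisphereSample] | None = None,
) -> FirstOrderEnsemble:
    """Repeated-partition first-order sweep.

    Repetition ``r`` partitions with seed ``base_seed + r``, then fits one
    model per (lambda, target group) and evaluates balanced accuracies and
    GSI on the test side (plus the fully held-out side for the
    ``subject_holdout`` scheme).  ``params`` carries optimiser settings;
    its ``alpha``/``lam`` fields are overridden by the sweep arguments.
    ``heldout_samples`` optionally attaches an extra test set (e.g. a
    held-out session) evaluated for every record.

    Note the workflow default enables ``normalize_dependence`` so that the
    lambda grid is comparable across sample sizes.
    """
    if n_repetitions < 1:
        raise ValueError("n_repetitions must be >= 1")
    scheme = scheme or PartitionScheme()
    base = params or GSDAHyperparams(normalize_dependence=True)
    X = np.vstack([s.features for s in samples])
    y = np.asarray([s.hemisphere for s in samples])
    g = np.asarray([s.group for s in samples])
    sids = np.asarray([s.subject_id for s in samples])
    X_extra = y_extra = g_extra = None
    if heldout_samples is not None:
        X_extra = np.vstack([s.features for s in heldout_samples])
        y_extra = np.asarray([s.hemisphere for s in heldout_samples])
        g_extra = np.asarray([s.group for s in heldout_samples])

    records: list[FirstOrderRecord] = []
    for rep in range(n_repetitions):
        seed = base_seed + rep
        if scheme.kind == "hemisphere_split":
            train_idx, test_idx = hemisphere_split_partition(
                samples, seed, scheme.stratify_by_group
            )
            extra_idx = None
        else:
            part = subject_holdout_partition(
                samples, scheme.holdout_fraction, seed, scheme.stratify_by_group
            )
            train_idx, test_idx, extra_idx = part.train, part.test, part.heldout
        design = GroupedDesign(X[train_idx], y[train_idx], g[train_idx], sids[train_idx])
        for lam in lam_grid:
            if lam < 0:
                raise ValueError("lambda values must be >= 0")
            run_params = GSDAHyperparams(
                alpha=alpha,
                lam=float(lam),
                optimizer=base.optimizer,
                learning_rate=base.learning_rate,
                max_iter=base.max_iter,
                tol=base.tol,
                exact_dependence_gradient=base.exact_dependence_gradient,
                normalize_dependence=base.normalize_dependence,
                standardize=base.standardize,
            )
            for tg in target_groups:
                model = estimator.fit(design, tg, run_params, seed=seed)
                ev = _evaluate_groups(model, X[test_idx], y[test_idx], g[test_idx], tg)
                rec = FirstOrderRecord(
                    repetition=rep,
                    seed=seed,
                    lam=float(lam),
                    alpha=alpha,
                    target_group=tg,
                    weights=model.weights,
                    bat=ev.bat,
                    bant=ev.bant,
                    gsi=gsi(ev),
                )
                extra_X = extra_y = extra_g = None
                if extra_idx is not None and len(extra_idx):
                    extra_X, extra_y, extra_g = X[extra_idx], y[extra_idx], g[extra_idx]
                elif X_extra is not None:
                    extra_X, extra_y, extra_g = X_extra, y_extra, g_extra
                if extra_X is not None:
                    ev2 = _evaluate_groups(model, extra_X, extra_y, extra_g, tg)
                    rec.bat_heldout = ev2.bat
                    rec.bant_heldout = ev2.bant
                records.append(rec)
    meta = {
        "scheme": scheme.kind,
        "holdout_fraction": scheme.holdout_fraction,
        "lam_grid": [float(v) for v in lam_grid],
        "alpha": alpha,
        "target_groups": list(target_groups),
        "n_repetitions": n_repetitions,
        "base_seed": base_seed,
        "n_samples": len(samples),
        "normalize_dependence": base.normalize_dependence,
    }
    return FirstOrderEnsemble(records, meta)


def assemble_second_order_design(
    ensemble_a: FirstOrderEnsemble,
    ensemble_b: FirstOrderEnsemble,
    lam: float,
    target_group_a: int | None = None,
    target_group_b: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack two ensembles' connection weights into a labelled design.

    Rows from ``ensemble_a`` get label 0, rows from ``ensemble_b`` label 1.
    The bias weight is excluded: second-order classification compares
    lateralization patterns.
    """
    recs_a = ensemble_a.select(lam=lam, target_group=target_group_a)
    recs_b = ensemble_b.select(lam=lam, target_group=target_group_b)
    if not recs_a or not recs_b:
        raise ValueError(f"one of the ensembles has no records at lam={lam}")
    Wa = np.vstack([r.weights[1:] for r in recs_a])
    Wb = np.vstack([r.weights[1:] for r in recs_b])
    if Wa.shape[1] != Wb.shape[1]:
        raise ValueError("ensembles have different feature dimensions")
    X = np.vstack([Wa, Wb])
    y = np.concatenate([np.zeros(len(Wa), dtype=int), np.ones(len(Wb), dtype=int)])
    return X, y


@dataclass
class SecondOrderResult:
    accuracies: np.ndarray
    weights: np.ndarray = field(repr=False)
    meta: dict = field(default_factory=dict)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    def mean_weights(self) -> np.ndarray:
        return self.weights.mean(axis=0)


def run_second_order(
    X: np.ndarray,
    y: np.ndarray,
    n_splits: int = 1000,
    train_fraction: float = 0.8,
    base_seed: int = 0,
) -> SecondOrderResult:
    """Repeated stratified splits + default L2 logistic classification.

    Each split uses seed ``base_seed + split`` for the stratified
    ``train_fraction`` / ``1 - train_fraction`` division, fits a
    scikit-learn ``LogisticRegression`` with default hyperparameters and
    records the test accuracy and coefficient vector.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    accs = np.empty(n_splits)
    weights = np.empty((n_splits, X.shape[1]))
    for split in range(n_splits):
        X_tr, X_te, y_tr, y_te = train_test_split(
            X,
            y,
            train_size=train_fraction,
            stratify=y,
            random_state=base_seed + split,
        )
        clf = LogisticRegression(max_iter=1000)
        clf.fit(X_tr, y_tr)
        accs[split] = clf.score(X_te, y_te)
        weights[split] = clf.coef_[0]
    return SecondOrderResult(
        accs,
        weights,
        meta={"n_splits": n_splits, "train_fraction": train_fraction, "base_seed": base_seed},
    )


@dataclass(frozen=True)
class LateralizationMask:
    """Connection indices surviving the top-fraction overlap rule."""

    indices: frozenset
    top_fraction: float
    provenance: tuple = ()

    def __contains__(self, idx: int) -> bool:
        return idx in self.indices

    def __len__(self) -> int:
        return len(self.indices)

    def sorted_indices(self) -> list[int]:
        return sorted(self.indices)

    def to_pairs(self, h: int) -> list[tuple[int, int]]:
        return [linear_index_to_pair(i, h) for i in self.sorted_indices()]


def top_fraction_indices(weights: np.ndarray, top_fraction: float = 0.05) -> np.ndarray:
    """Indices of the floor(top_fraction * p) largest-|w| entries.

    Ties at the cut are broken by lower index (stable sort on -|w|).
    """
    if not 0.0 < top_fraction < 1.0:
        raise ValueError("top_fraction must lie in (0, 1)")
    w = np.abs(np.asarray(weights, dtype=float))
    k = int(np.floor(top_fraction * w.shape[0]))
    order = np.argsort(-w, kind="stable")
    return np.sort(order[:k])


def derive_mask(
    avg_weights_a: np.ndarray,
    avg_weights_b: np.ndarray,
    top_fraction: float = 0.05,
) -> LateralizationMask:
    """Intersection of the two top-fraction largest-|w| index sets."""
    wa = np.asarray(avg_weights_a, dtype=float)
    wb = np.asarray(avg_weights_b, dtype=float)
    if wa.shape != wb.shape:
        raise ValueError(f"weight vectors differ in shape: {wa.shape} vs {wb.shape}")
    top_a = set(top_fraction_indices(wa, top_fraction).tolist())
    top_b = set(top_fraction_indices(wb, top_fraction).tolist())
    return LateralizationMask(
        indices=frozenset(top_a & top_b),
        top_fraction=top_fraction,
        provenance=("intersection", len(top_a), len(top_b)),
    )


def apply_mask_to_model(
    avg_first_order_weights: np.ndarray,
    mask: LateralizationMask,
    top_fraction: float = 0.05,
) -> list[tuple[int, float]]:
    """Masked selection: mask intersected with the model's own top set.

    Returns (connection index, signed average weight) pairs, sorted by
    index.
    """
    w = np.asarray(avg_first_order_weights, dtype=float)
    own_top = set(top_fraction_indices(w, top_fraction).tolist())
    selected = sorted(own_top & set(mask.indices))
    return [(i, float(w[i])) for i in selected]


def shared_exclusive_partition(
    selections: Mapping[str, Mapping[int, Iterable[int]]],
) -> dict:
    """Shared vs group-"exclusive" connections, per dataset and overall.

    ``selections[dataset][group]`` is an iterable of connection indices
    (e.g. from :func:`apply_mask_to_model`).  Within each dataset the
    shared set is the intersection across groups and each group's
    exclusive set is its difference from the other groups' union.  The
    overall ``unique`` set deduplicates connections across all inputs.
    """
    out: dict = {"datasets": {}, "unique": set()}
    for dataset, by_group in selections.items():
        sets = {grp: {int(i) for i in idxs} for grp, idxs in by_group.items()}
        union: set = set()
        for s in sets.values():
            union |= s
        shared = set.intersection(*sets.values()) if sets else set()
        exclusive = {
            grp: s - set.union(*(o for k, o in sets.items() if k != grp))
            if len(sets) > 1
            else set()
            for grp, s in sets.items()
        }
        out["datasets"][dataset] = {"shared": shared, "exclusive": exclusive}
        out["unique"] |= union
    return out


def lobe_average_degree(
    mask: LateralizationMask | Iterable[int],
    atlas: AtlasTable,
) -> dict[str, float]:
    """Average chords per ROI for each lobe.

    Each selected connection contributes one endpoint to the lobe of each
    of its two ROIs (two endpoints to the same lobe for intra-lobe
    chords); counts are divided by the lobe's per-hemisphere ROI count.
    """
    indices = mask.sorted_indices() if isinstance(mask, LateralizationMask) else sorted(mask)
    lobes = atlas.homologue_lobes()
    sizes = atlas.lobe_sizes()
    endpoints = {lobe: 0 for lobe in sizes}
    for idx in indices:
        i, j = linear_index_to_pair(int(idx), atlas.h)
        endpoints[lobes[i]] += 1
        endpoints[lobes[j]] += 1
    return {lobe: endpoints[lobe] / sizes[lobe] for lobe in sizes}


def interaction_sign_counts(
    selections: Mapping[int, Iterable[tuple[int, float]]],
    atlas: AtlasTable,
) -> dict[tuple[int, str, str], int]:
    """Counts of selected connections by (group, intra/inter-lobe, sign).

    ``selections[group]`` holds (connection index, signed weight) pairs.
    Zero weights count as positive.
    """
    lobes = atlas.homologue_lobes()
    counts: dict[tuple[int, str, str], int] = {}
    for grp in selections:
        for placement in ("intra", "inter"):
            for sign in ("positive", "negative"):
                counts[(grp, placement, sign)] = 0
    for grp, pairs in selections.items():
        for idx, weight in pairs:
            i, j = linear_index_to_pair(int(idx), atlas.h)
            placement = "intra" if lobes[i] == lobes[j] else "inter"
            sign = "negative" if weight < 0 else "positive"
            counts[(grp, placement, sign)] += 1
    return counts
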