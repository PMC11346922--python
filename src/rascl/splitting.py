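"""Replicate holdout construction and covariate-balanced stratified k-folds.

Test sets are class-exact (default 10 FTMH + 40 control eyes, about 15% of a
334-eye cohort), pairwise disjoint across replicates, and patient-grouped:
both eyes of a patient always land on the same side of a split and in the
same fold.  The 8-fold partition of each training set is stratified primarily
by diagnosis (a hard +/-1-of-proportional constraint) and balanced on age,
sex (ordinal) and pre-operative vision by minimising, over folds and
features, the scaled L1 distance of fold means and SDs from the overall
moments.  The optimiser is random-restart greedy pairwise swapping between
groups with identical class composition, which preserves the hard constraint
by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import CapacityError, ConfigurationError

__all__ = [
    "SplitPlan",
    "DEFAULT_FEATURES",
    "make_replicates",
    "stratified_kfold",
    "balance_objective",
]

DEFAULT_FEATURES = ("diagnosis", "age", "sex", "preop_vision")


@dataclass
class SplitPlan:
    replicate_id: int
    test_eye_ids: list[str]
    train_eye_ids: list[str]
    fold_assignment: dict[str, int] = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        return {
            "replicate_id": self.replicate_id,
            "test_eye_ids": list(self.test_eye_ids),
            "train_eye_ids": list(self.train_eye_ids),
            "fold_assignment": dict(self.fold_assignment),
        }


def _patient_groups(manifest: pd.DataFrame) -> list[dict]:
    groups = []
    for pid, sub in manifest.groupby("patient_id", sort=True):
        groups.append(
            {
                "patient_id": pid,
                "eye_ids": sorted(sub["eye_id"]),
                "diagnoses": sorted(sub["diagnosis"]),
            }
        )
    return groups


def make_replicates(
    manifest: pd.DataFrame,
    n_replicates: int = 3,
    test_counts: dict[str, int] | None = None,
    seed: int = 0,
) -> list[SplitPlan]:
    """Build ``n_replicates`` plans with class-exact, pairwise-disjoint test sets.

    ``test_counts`` maps diagnosis to the number of test eyes per replicate
    (default ``{"FTMH": 10, "ERM": 40}``).  Patient groups are kept intact;
    each replicate's training set is every eye outside its own test set.
    """
    if test_counts is None:
        test_counts = {"FTMH": 10, "ERM": 40}
    counts = manifest["diagnosis"].value_counts().to_dict()
    for cls, per_rep in test_counts.items():
        need = n_replicates * per_rep
        have = counts.get(cls, 0)
        if need > have:
            raise CapacityError(
                f"class {cls}: {n_replicates} replicates x {per_rep} test eyes "
                f"= {need} needed, only {have} available"
            )

    rng = np.random.default_rng(seed)
    groups = _patient_groups(manifest)
    pool = list(range(len(groups)))
    plans = []
    all_eyes = list(manifest["eye_id"])
    for rep in range(n_replicates):
        chosen = _draw_class_exact(groups, pool, test_counts, rng)
        test_eyes = sorted(e for gi in chosen for e in groups[gi]["eye_ids"])
        pool = [gi for gi in pool if gi not in chosen]
        train_eyes = sorted(set(all_eyes) - set(test_eyes))
        plans.append(SplitPlan(rep, test_eyes, train_eyes))
    return plans


def _draw_class_exact(groups, pool, test_counts, rng, max_tries: int = 200):
    """Randomly select patient groups so class eye-counts match exactly."""
    for _ in range(max_tries):
        order = list(pool)
        rng.shuffle(order)
        remaining = dict(test_counts)
        chosen = set()
        for gi in order:
            diags = groups[gi]["diagnoses"]
            if all(d in remaining for d in diags) and all(
                remaining[d] >= diags.count(d) for d in set(diags)
            ):
                fits = {d: remaining[d] - diags.count(d) for d in set(diags)}
                if all(v >= 0 for v in fits.values()):
                    chosen.add(gi)
                    for d in diags:
                        remaining[d] -= 1
            if all(v == 0 for v in remaining.values()):
                return chosen
        # retry with a new shuffle if exact counts were not reached
    raise CapacityError(
        f"could not assemble a class-exact test set for counts {test_counts}"
    )


# ---------------------------------------------------------------------------
# Stratified k-fold with moment balancing


def _encode_features(manifest: pd.DataFrame, features) -> np.ndarray:
    cols = []
    for f in features:
        if f == "diagnosis":
            cols.append((manifest["diagnosis"] == "FTMH").astype(float).to_numpy())
        elif f in ("age", "preop_vision", "sex"):
            cols.append(manifest[f].astype(float).to_numpy())
        else:
            raise ConfigurationError(f"unknown stratification feature {f!r}")
    return np.column_stack(cols)


def balance_objective(
    assignment: dict[str, int],
    manifest: pd.DataFrame,
    features=DEFAULT_FEATURES,
) -> float:
    """Sum over folds and features of scaled L1 moment mismatch.

    For each feature the fold mean and SD are compared with the overall mean
    and SD, both scaled by the overall SD (population SD; a constant feature
    contributes zero).  Zero is attained iff every fold matches the overall
    moments exactly; the value is invariant to fold relabelling.
    """
    eyes = manifest["eye_id"].to_numpy()
    missing = [e for e in eyes if e not in assignment]
    if missing:
        raise ConfigurationError(f"assignment does not cover eyes: {missing[:5]}")
    x = _encode_features(manifest, features)
    fold_of = np.array([assignment[e] for e in eyes])
    mean_all = x.mean(axis=0)
    sd_all = x.std(axis=0)
    scale = np.where(sd_all > 0, sd_all, 1.0)
    total = 0.0
    for f in np.unique(fold_of):
        sub = x[fold_of == f]
        total += float(
            np.sum(np.abs(sub.mean(axis=0) - mean_all) / scale)
            + np.sum(np.abs(sub.std(axis=0) - sd_all) / scale)
        )
    return total


def _diagnosis_ok(fold_counts: np.ndarray, totals: np.ndarray, k: int) -> bool:
    """Hard constraint: per-fold class counts within +/-1 of n_c / k."""
    target = totals / k
    return bool(np.all(np.abs(fold_counts - target[None, :]) <= 1.0 + 1e-9))


def _initial_assignment(groups, k, classes, rng):
    """Greedy min-fill per class signature, largest groups first."""
    fold_counts = np.zeros((k, len(classes)))
    cls_index = {c: i for i, c in enumerate(classes)}
    assign = np.empty(len(groups), dtype=int)
    order = sorted(
        range(len(groups)),
        key=lambda gi: (-len(groups[gi]["diagnoses"]), rng.random()),
    )
    for gi in order:
        diags = groups[gi]["diagnoses"]
        vec = np.zeros(len(classes))
        for d in diags:
            vec[cls_index[d]] += 1
        load = fold_counts @ vec  # how much of this signature each fold holds
        best = np.flatnonzero(load == load.min())
        f = int(rng.choice(best))
        assign[gi] = f
        fold_counts[f] += vec
    return assign, fold_counts


def stratified_kfold(
    train_manifest: pd.DataFrame,
    k: int = 8,
    features=DEFAULT_FEATURES,
    seed: int = 0,
    n_restarts: int = 50,
    n_swaps: int = 500,
) -> dict[str, int]:
    """Patient-grouped k-fold assignment balancing covariate moments.

    Diagnosis proportionality (within +/-1 per fold) is a hard constraint;
    subject to it, random-restart greedy pairwise swaps between groups of
    identical class composition minimise :func:`balance_objective`.
    """
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    groups = _patient_groups(train_manifest)
    if k > len(groups):
        raise ConfigurationError(f"k={k} exceeds the {len(groups)} patient groups")
    classes = sorted(train_manifest["diagnosis"].unique())
    cls_index = {c: i for i, c in enumerate(classes)}
    totals = np.zeros(len(classes))
    for g in groups:
        for d in g["diagnoses"]:
            totals[cls_index[d]] += 1

    # groups swappable only within identical class-composition buckets
    signature = [tuple(g["diagnoses"]) for g in groups]
    buckets: dict[tuple, list[int]] = {}
    for gi, sig in enumerate(signature):
        buckets.setdefault(sig, []).append(gi)
    swappable = [b for b in buckets.values() if len(b) >= 2]

    # fast incremental objective over per-fold feature sums / sums of squares
    x = _encode_features(train_manifest, features)
    eye_row = {e: i for i, e in enumerate(train_manifest["eye_id"])}
    group_rows = [np.array([eye_row[e] for e in g["eye_ids"]]) for g in groups]
    group_sum = np.stack([x[r].sum(axis=0) for r in group_rows])
    group_sq = np.stack([(x[r] ** 2).sum(axis=0) for r in group_rows])
    group_n = np.array([len(r) for r in group_rows], dtype=float)
    mean_all = x.mean(axis=0)
    sd_all = x.std(axis=0)
    scale = np.where(sd_all > 0, sd_all, 1.0)

    def objective(fs, fq, fn):
        if np.any(fn == 0):
            return np.inf
        mean = fs / fn[:, None]
        var = np.maximum(fq / fn[:, None] - mean**2, 0.0)
        sd = np.sqrt(var)
        return float(
            np.sum(np.abs(mean - mean_all[None, :]) / scale[None, :])
            + np.sum(np.abs(sd - sd_all[None, :]) / scale[None, :])
        )

    rng = np.random.default_rng(seed)
    best_assign, best_obj = None, np.inf
    for _ in range(n_restarts):
        assign, fold_counts = _initial_assignment(groups, k, classes, rng)
        if not _diagnosis_ok(fold_counts, totals, k):
            continue
        fs = np.zeros((k, x.shape[1]))
        fq = np.zeros((k, x.shape[1]))
        fn = np.zeros(k)
        for gi, f in enumerate(assign):
            fs[f] += group_sum[gi]
            fq[f] += group_sq[gi]
            fn[f] += group_n[gi]
        obj = objective(fs, fq, fn)
        for _ in range(n_swaps):
            if not swappable:
                break
            bucket = swappable[int(rng.integers(0, len(swappable)))]
            gi, gj = rng.choice(np.asarray(bucket), size=2, replace=False)
            fi, fj = int(assign[gi]), int(assign[gj])
            if fi == fj:
                continue
            for g, src, dst in ((gi, fi, fj), (gj, fj, fi)):
                fs[src] -= group_sum[g]; fq[src] -= group_sq[g]; fn[src] -= group_n[g]
                fs[dst] += group_sum[g]; fq[dst] += group_sq[g]; fn[dst] += group_n[g]
            cand_obj = objective(fs, fq, fn)
            if cand_obj < obj - 1e-12:
                obj = cand_obj
                assign[gi], assign[gj] = fj, fi
            else:  # revert
                for g, src, dst in ((gi, fj, fi), (gj, fi, fj)):
                    fs[src] -= group_sum[g]; fq[src] -= group_sq[g]; fn[src] -= group_n[g]
                    fs[dst] += group_sum[g]; fq[dst] += group_sq[g]; fn[dst] += group_n[g]
        if obj < best_obj:
            best_obj = obj
            best_assign = _group_to_eye_assignment(groups, assign)
    if best_assign is None:
        raise ConfigurationError(
            "no assignment satisfying the diagnosis +/-1 constraint was found"
        )
    return best_assign


def _group_to_eye_assignment(groups, assign) -> dict[str, int]:
    return {e: int(assign[gi]) for gi, g in enumerate(groups) for e in g["eye_ids"]}
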