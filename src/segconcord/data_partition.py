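"""Balanced stratified train/validation splitting and k-fold partitioning.

The hold-out split stratifies on the cross of several categorical
acquisition covariates (vendor, field strength, tumor location, MR
sequence) so that both partitions preserve the cohort's composition:
each composite stratum contributes floor/ceil of its proportional share
to the validation set, with leftover slots assigned by largest remainder
under per-level marginal caps.  Fold assignment for cross-validation is
a plain seeded shuffle into near-equal folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .mask_io import CaseRecord, cohort_to_frame

__all__ = [
    "SplitAssignment",
    "stratified_split",
    "random_split",
    "kfold_partition",
    "balance_report",
    "DEFAULT_COVARIATES",
]

DEFAULT_COVARIATES = ("vendor", "field_strength", "location", "sequence")


@dataclass(frozen=True)
class SplitAssignment:
    """Immutable case -> partition mapping produced under one seed.

    ``assignment`` maps each case id to either a label in
    {"train", "validation"} (hold-out split) or an integer fold index
    (k-fold partition).
    """

    assignment: dict[str, object]
    seed: int
    covariates_used: tuple[str, ...] = ()
    kind: str = "holdout"

    def ids_with(self, label: object) -> list[str]:
        return sorted(k for k, v in self.assignment.items() if v == label)

    @property
    def validation_ids(self) -> list[str]:
        return self.ids_with("validation")

    @property
    def train_ids(self) -> list[str]:
        return self.ids_with("train")

    def folds(self) -> list[list[str]]:
        labels = sorted({v for v in self.assignment.values()})
        return [self.ids_with(lab) for lab in labels]

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.assignment.items())
        return pd.DataFrame(rows, columns=["case_id", "partition"])


def _records_frame(records: Iterable[CaseRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = cohort_to_frame(list(records))
    if df.empty:
        raise ValueError("no cohort records supplied")
    if df["case_id"].duplicated().any():
        raise ValueError("duplicate case_id in cohort records")
    df["case_id"] = df["case_id"].astype(str)
    return df


def stratified_split(
    records: Iterable[CaseRecord] | pd.DataFrame,
    validation_fraction: float,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    seed: int = 0,
) -> SplitAssignment:
    """Hold out ``round(fraction * n)`` cases, balanced over covariates.

    Composite strata are the observed cells of the covariate cross.
    Each stratum's validation quota starts at the floor of its
    proportional share; remaining slots go to strata by largest
    fractional remainder, preferring strata whose marginal covariate
    levels are still below their own proportional ceiling, so per-level
    validation counts stay within one case of exact proportionality.
    Single-case strata stay wholly in training (with a warning).
    """
    if not 0.0 < validation_fraction < 1.0:
        raise ValueError("validation_fraction must lie in (0, 1)")
    df = _records_frame(records)
    for cov in covariates:
        if cov not in df.columns:
            raise KeyError(f"covariate {cov!r} not in records")
    n = len(df)
    target = int(round(validation_fraction * n))
    rng = np.random.default_rng(seed)

    if covariates:
        key = df[list(covariates)].astype(str).agg("|".join, axis=1)
    else:
        key = pd.Series(["all"] * n, index=df.index)
    df = df.assign(_stratum=key)
    strata = {
        name: grp["case_id"].sort_values().tolist()
        for name, grp in df.groupby("_stratum", sort=True)
    }

    singletons = [s for s, ids in strata.items() if len(ids) < 2]
    if singletons and covariates:
        warnings.warn(
            f"{len(singletons)} single-case strata kept wholly in training",
            stacklevel=2,
        )
    eligible = {s: ids for s, ids in strata.items() if len(ids) >= 2}

    quota = {s: validation_fraction * len(ids) for s, ids in eligible.items()}
    alloc = {s: int(np.floor(q)) for s, q in quota.items()}
    # Keep at least one training case per stratum.
    for s, ids in eligible.items():
        alloc[s] = min(alloc[s], len(ids) - 1)
    deficit = target - sum(alloc.values())

    # Marginal targets: validation count per covariate level should stay
    # close to fraction * level size.  Leftover slots (and trims) are
    # assigned greedily to the stratum whose +/-1 change most reduces
    # the total absolute marginal deviation, with the fractional
    # remainder and then the stratum name as deterministic tie-breaks.
    level_target: dict[tuple[str, str], float] = {}
    level_used: dict[tuple[str, str], float] = {}
    stratum_levels: dict[str, list[tuple[str, str]]] = {}
    if covariates:
        for cov in covariates:
            for lev, cnt in df[cov].astype(str).value_counts().items():
                level_target[(cov, lev)] = validation_fraction * cnt
                level_used[(cov, lev)] = 0
        stratum_levels = {s: list(zip(covariates, s.split("|"))) for s in strata}
        for s, a in alloc.items():
            for key2 in stratum_levels[s]:
                level_used[key2] += a

    def deviation_gain(s: str, delta: int) -> float:
        if not covariates:
            return 0.0
        gain = 0.0
        for k in stratum_levels[s]:
            before = abs(level_used[k] - level_target[k])
            after = abs(level_used[k] + delta - level_target[k])
            gain += before - after
        return gain

    def apply(s: str, delta: int) -> None:
        alloc[s] += delta
        if covariates:
            for k in stratum_levels[s]:
                level_used[k] += delta

    remainder = {s: quota[s] - np.floor(quota[s]) for s in eligible}
    while deficit != 0:
        delta = 1 if deficit > 0 else -1
        if delta > 0:
            candidates = [s for s in eligible if alloc[s] < len(eligible[s]) - 1]
        else:
            candidates = [s for s in eligible if alloc[s] > 0]
        if not candidates:
            break  # no capacity left anywhere
        best = max(
            candidates,
            key=lambda s: (deviation_gain(s, delta), delta * remainder[s], s),
        )
        apply(best, delta)
        deficit -= delta

    # Swap refinement: at fixed validation size, move single slots
    # between strata while doing so lowers the (max, sum) of absolute
    # marginal deviations.  Handles cohorts whose rare levels are locked
    # up in single-case strata that never enter validation.
    if covariates:

        def objective() -> tuple[float, float]:
            devs = [abs(level_used[k] - level_target[k]) for k in level_target]
            return (max(devs), sum(devs))

        for _ in range(200):
            current = objective()
            best_move: tuple[str, str] | None = None
            best_obj = current
            for a in sorted(eligible):
                if alloc[a] >= len(eligible[a]) - 1:
                    continue
                for b in sorted(eligible):
                    if b == a or alloc[b] <= 0:
                        continue
                    apply(a, 1)
                    apply(b, -1)
                    obj = objective()
                    apply(a, -1)
                    apply(b, 1)
                    if obj < best_obj:
                        best_obj, best_move = obj, (a, b)
            if best_move is None:
                break
            apply(best_move[0], 1)
            apply(best_move[1], -1)

    assignment: dict[str, object] = {}
    for s in sorted(strata):
        ids = strata[s]
        k = alloc.get(s, 0)
        chosen = set(rng.choice(ids, size=k, replace=False)) if k else set()
        for cid in ids:
            assignment[cid] = "validation" if cid in chosen else "train"
    return SplitAssignment(
        assignment=assignment,
        seed=int(seed),
        covariates_used=tuple(covariates),
        kind="holdout",
    )


def random_split(
    records: Iterable[CaseRecord] | pd.DataFrame,
    validation_fraction: float,
    seed: int = 0,
) -> SplitAssignment:
    """Naive (unstratified) hold-out split; baseline for balance checks."""
    return stratified_split(
        records, validation_fraction, covariates=(), seed=seed
    )


def kfold_partition(
    case_ids: Iterable[str], k: int, seed: int = 0
) -> SplitAssignment:
    """Shuffle cases into ``k`` non-overlapping folds of near-equal size.

    Fold sizes are ``ceil(n/k)`` or ``floor(n/k)`` (max - min <= 1); the
    union of folds is exactly the input set.
    """
    ids = sorted(str(c) for c in case_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate case ids")
    n = len(ids)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError(f"k={k} exceeds number of cases n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ids)
    assignment: dict[str, object] = {}
    for fold_idx, chunk in enumerate(np.array_split(perm, k)):
        for cid in chunk:
            assignment[str(cid)] = int(fold_idx)
    return SplitAssignment(
        assignment=assignment, seed=int(seed), covariates_used=(), kind="kfold"
    )


def balance_report(
    assignment: SplitAssignment,
    records: Iterable[CaseRecord] | pd.DataFrame,
    covariates: Sequence[str] | None = None,
    nominal_fraction: float | None = None,
) -> dict:
    """Per-covariate-level composition of a hold-out split.

    Returns a dict with a ``table`` (DataFrame: counts and proportions
    per level in each partition, plus each level's deviation from exact
    proportionality in cases) and the scalar ``max_count_deviation`` /
    ``max_prop_deviation`` over all levels.  Deviations are measured
    against ``nominal_fraction`` when given (the fraction the split was
    asked for), else against the realised validation fraction.
    """
    df = _records_frame(records)
    covs = list(covariates or assignment.covariates_used or DEFAULT_COVARIATES)
    part = df["case_id"].map(assignment.assignment)
    if part.isna().any():
        missing = df.loc[part.isna(), "case_id"].tolist()
        raise ValueError(f"assignment does not cover cases: {missing[:5]}")
    n_val_total = int((part == "validation").sum())
    frac = (
        float(nominal_fraction)
        if nominal_fraction is not None
        else n_val_total / len(df)
    )
    rows = []
    for cov in covs:
        for lev, grp in df.groupby(df[cov].astype(str), sort=True):
            sub_part = part.loc[grp.index]
            n_level = len(grp)
            n_val = int((sub_part == "validation").sum())
            expected = frac * n_level
            rows.append(
                {
                    "covariate": cov,
                    "level": lev,
                    "n_total": n_level,
                    "n_train": n_level - n_val,
                    "n_validation": n_val,
                    "validation_prop": n_val / n_level,
                    "expected_validation": expected,
                    "count_deviation": abs(n_val - expected),
                }
            )
    table = pd.DataFrame(rows)
    return {
        "table": table,
        "validation_fraction": frac,
        "max_count_deviation": float(table["count_deviation"].max()),
        "max_prop_deviation": float(
            (table["count_deviation"] / table["n_total"]).max()
        ),
        "seed": assignment.seed,
    }
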