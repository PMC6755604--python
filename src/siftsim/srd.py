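"""Sum of ranking differences (SRD) with cross-validation and a
randomization test.

SRD compares column vectors (here: similarity measures evaluated on the
same ligands) to a reference ranking. The protocol:

1. build the reference (consensus) vector by row-wise data fusion —
   row-maximum for active ligands, row-minimum for inactives, so the
   reference behaves like a hypothetical ideal similarity measure;
2. rank the ligands within the reference and within every measure column
   (ascending, ties averaged);
3. for every measure, sum the absolute ligand-wise rank differences to the
   reference. The smaller the sum, the closer the measure's ranking is to
   the consensus.

Without ties this is the Spearman footrule distance. SRD values are
normalized to percent of the theoretical maximum (n^2/2 for even n,
(n^2-1)/2 for odd n). Validation is by a permutation (randomization) test
— the SRD distribution of random rankings, exact up to n = 8 and
Monte-Carlo beyond — and by fivefold cross-validation plus one round on
the whole dataset ("All").
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .pretreatment import pretreat
from .similarity import measure_columns

#: Largest n for which the permutation null is enumerated exactly (8! = 40,320).
EXACT_PERMUTATION_LIMIT = 8

CV_ALL_ROUND = "All"


def fuse_reference(frame: pd.DataFrame, activities=None) -> np.ndarray:
    """Consensus reference: row-max over measures for actives, row-min for
    inactives.

    ``frame`` is a (pretreated) similarity matrix; activities default to its
    ``active`` column.
    """
    cols = measure_columns(frame)
    if not cols or not len(frame):
        raise ValueError("similarity matrix is empty")
    if activities is None:
        if "active" not in frame.columns:
            raise ValueError("no activities given and no 'active' column present")
        activities = frame["active"].to_numpy()
    activities = np.asarray(activities).astype(bool)
    if activities.size != len(frame):
        raise ValueError("activities do not align with matrix rows")
    values = frame[cols].to_numpy(dtype=float)
    return np.where(activities, values.max(axis=1), values.min(axis=1))


def rank_vector(values) -> np.ndarray:
    """Ascending ranks 1..n with average (fractional) ranks for ties."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot rank an empty vector")
    return rankdata(values, method="average")


def srd_value(column_ranks, reference_ranks) -> float:
    """Sum of absolute rank differences (Manhattan rank distance)."""
    x = np.asarray(column_ranks, dtype=float)
    y = np.asarray(reference_ranks, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"rank vectors differ in length: {x.shape} vs {y.shape}")
    return float(np.abs(x - y).sum())


def max_srd(n: int) -> int:
    """Theoretical maximum SRD for n tie-free objects.

    Attained by reversing the reference order: n^2/2 for even n,
    (n^2 - 1)/2 for odd n.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    return n * n // 2 if n % 2 == 0 else (n * n - 1) // 2


def normalize_srd(srd_raw: float, n: int) -> float:
    """SRD as a percentage of the theoretical maximum; 0 for n = 1."""
    m = max_srd(n)
    if m == 0:
        return 0.0
    if srd_raw > m + 1e-9:
        raise RuntimeError(f"SRD {srd_raw} exceeds the maximum {m} for n={n}")
    return 100.0 * srd_raw / m


def srd_per_measure(frame: pd.DataFrame, activities=None) -> pd.DataFrame:
    """Raw and normalized SRD of every measure column against the fused
    reference. Returns a frame indexed by measure with ``srd_raw`` and
    ``srd_norm`` columns."""
    cols = measure_columns(frame)
    reference = fuse_reference(frame, activities)
    ref_ranks = rank_vector(reference)
    n = len(frame)
    rows = {}
    for col in cols:
        raw = srd_value(rank_vector(frame[col].to_numpy(dtype=float)), ref_ranks)
        rows[col] = (raw, normalize_srd(raw, n))
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["srd_raw", "srd_norm"]
    ).rename_axis("measure")


# ---------------------------------------------------------------------------
# randomization (permutation) test


@dataclass(frozen=True)
class PermutationSummary:
    """Null distribution of SRD under random rankings of n objects."""

    n: int
    exact: bool
    mean: float
    p5: float
    p95: float
    values: np.ndarray  # SRD values of the sampled/enumerated permutations

    def p_value(self, observed: float) -> float:
        """One-sided p: probability a random ranking scores <= observed."""
        return float(np.count_nonzero(self.values <= observed + 1e-9) / self.values.size)


def permutation_test(n: int, reps: int = 10_000, seed=None) -> PermutationSummary:
    """SRD null distribution against a fixed reference ranking.

    Exact enumeration of all n! permutations for n <= 8, seeded Monte-Carlo
    with ``reps`` draws beyond. The tie-free null mean is (n^2 - 1)/3.
    """
    if n < 2:
        raise ValueError("permutation test needs at least 2 objects")
    ref = np.arange(1, n + 1)
    if n <= EXACT_PERMUTATION_LIMIT:
        perms = np.array(list(itertools.permutations(range(1, n + 1))), dtype=float)
        values = np.abs(perms - ref).sum(axis=1)
        exact = True
    else:
        if reps < 100:
            raise ValueError("Monte-Carlo permutation test needs reps >= 100")
        rng = np.random.default_rng(seed)
        values = np.empty(reps)
        for i in range(reps):
            values[i] = np.abs(rng.permutation(n) + 1 - ref).sum()
        exact = False
    return PermutationSummary(
        n=n,
        exact=exact,
        mean=float(values.mean()),
        p5=float(np.percentile(values, 5)),
        p95=float(np.percentile(values, 95)),
        values=values,
    )


# ---------------------------------------------------------------------------
# cross-validation


def crossvalidate_srd(
    frame: pd.DataFrame,
    activities=None,
    k: int = 5,
    seed=None,
) -> pd.DataFrame:
    """k-fold cross-validated SRD (k rounds + one "All" round).

    ``frame`` is a (pretreated) similarity matrix. Rows are split into k
    near-equal folds by a seeded random permutation; round j removes fold j
    and reruns the whole SRD analysis (reference fusion, ranking,
    normalization) on the remaining rows; the final round uses every row.
    Returns a frame indexed by measure with one column per round
    ("1".."k", "All") of normalized SRD values.
    """
    n = len(frame)
    if k < 2 or k > n:
        raise ValueError(f"fold count k={k} must be in [2, {n}]")
    if activities is None:
        activities = frame["active"].to_numpy().astype(bool)
    activities = np.asarray(activities).astype(bool)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    results = {}
    for j, fold in enumerate(folds, start=1):
        keep = np.setdiff1d(np.arange(n), fold)
        sub = frame.iloc[keep].reset_index(drop=True)
        results[str(j)] = srd_per_measure(sub, activities[keep])["srd_norm"]
    results[CV_ALL_ROUND] = srd_per_measure(frame, activities)["srd_norm"]
    return pd.DataFrame(results).rename_axis("measure")


@dataclass(frozen=True)
class SRDResult:
    """Full SRD analysis of one measure column."""

    measure: str
    srd_raw: float
    srd_norm: float
    cv_values: tuple[float, ...]
    perm_summary: PermutationSummary
    p_value: float


def run_srd(
    frame: pd.DataFrame,
    activities=None,
    pretreatment: str = "AUTO",
    k: int = 5,
    perm_reps: int = 10_000,
    seed=None,
) -> list[SRDResult]:
    """End-to-end SRD analysis of a similarity matrix.

    Pretreats the matrix, computes per-measure SRD, k-fold CV values and
    the permutation null, and returns one :class:`SRDResult` per measure.
    """
    treated = pretreat(frame, pretreatment)
    base = srd_per_measure(treated, activities)
    cv = crossvalidate_srd(treated, activities, k=k, seed=seed)
    perm = permutation_test(len(frame), reps=perm_reps, seed=seed)
    out = []
    for measure, row in base.iterrows():
        out.append(
            SRDResult(
                measure=measure,
                srd_raw=row["srd_raw"],
                srd_norm=row["srd_norm"],
                cv_values=tuple(cv.loc[measure]),
                perm_summary=perm,
                p_value=perm.p_value(row["srd_raw"]),
            )
        )
    return out
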