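"""ROC-AUC scoring, the factorial evaluation grid, and ANOVA summaries.

The grid crosses every dataset with the three bit-selection schemes
(ALL/WO1/WO3) and the three filtering rules (NO/RES/INTS). For each of the
resulting variants it builds the reference-vs-query similarity matrix for
all requested measures, pretreats it, runs cross-validated SRD, and scores
each measure column by ROC-AUC on the raw scaled similarities. With 10
datasets there are 90 variants; with 44 measures and fivefold CV the long
SRD table has 10 x 3 x 3 x 6 x 44 = 23,760 rows.

Factor effects on normalized SRD (measure, bit selection, filtering rule,
symmetricity, metricity, ...) are summarized with fixed-effects ANOVA.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from sklearn.metrics import roc_auc_score

from .fingerprints import (
    BIT_SELECTIONS,
    FILTERING_RULES,
    FingerprintDataset,
    InteractionFingerprint,
    apply_filtering,
    conform_fingerprint,
    select_bits,
)
from .pretreatment import pretreat
from .similarity import measure_columns, resolve_measures, similarity_matrix
from .srd import crossvalidate_srd

logger = logging.getLogger(__name__)


def roc_auc(scores, labels) -> float:
    """Probability that a random active outranks a random inactive.

    Mann-Whitney formulation with midrank tie handling (delegates to
    scikit-learn). Raises if only one class is present.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if labels.size != scores.size:
        raise ValueError("scores and labels differ in length")
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC-AUC needs at least one active and one inactive")
    return float(roc_auc_score(labels, scores))


@dataclass(frozen=True)
class GridConfig:
    """Configuration of the factorial evaluation grid."""

    measures: tuple | None = None  # None = full 44-measure catalog
    bit_selections: tuple[str, ...] = tuple(BIT_SELECTIONS)
    filterings: tuple[str, ...] = tuple(FILTERING_RULES)
    pretreatment: str = "AUTO"
    folds: int = 5
    seed: int | None = None


@dataclass(frozen=True)
class GridResult:
    """Long-format grid output.

    ``srd``: one row per (dataset, bit_selection, filtering, measure,
    cv_round) with ``srd_norm`` plus the measure's symmetricity/metricity;
    ``auc``: one row per (dataset, bit_selection, filtering, measure);
    ``skipped``: variants emptied by filtering, if any.
    """

    srd: pd.DataFrame
    auc: pd.DataFrame
    skipped: tuple[tuple[str, str, str], ...] = field(default_factory=tuple)

    @property
    def n_variants(self) -> int:
        return len(
            self.auc.groupby(["dataset", "bit_selection", "filtering"], sort=False)
        )


def run_grid(
    datasets: Sequence[FingerprintDataset],
    references: Sequence[InteractionFingerprint],
    config: GridConfig = GridConfig(),
) -> GridResult:
    """Run the full dataset x bit-selection x filtering grid.

    Bit selection is applied before filtering; the reference fingerprint is
    projected onto each variant's surviving columns by name. A variant
    emptied by filtering is skipped with a logged warning and recorded in
    ``GridResult.skipped``.
    """
    if len(datasets) != len(references):
        raise ValueError("need exactly one reference per dataset")
    measures = resolve_measures(config.measures)
    classes = {
        m.abbrev: (m.symmetricity, m.metricity) for m in measures
    }
    srd_rows: list[pd.DataFrame] = []
    auc_rows: list[dict] = []
    skipped: list[tuple[str, str, str]] = []
    for dataset, reference in zip(datasets, references):
        for selection in config.bit_selections:
            selected = select_bits(dataset, selection)
            for filtering in config.filterings:
                try:
                    variant = apply_filtering(selected, filtering)
                except ValueError:
                    logger.warning(
                        "variant (%s, %s, %s) emptied by filtering; skipped",
                        dataset.name, selection, filtering,
                    )
                    skipped.append((dataset.name, selection, filtering))
                    continue
                ref = conform_fingerprint(reference, dataset.layout, variant.layout)
                matrix = similarity_matrix(variant, ref, measures)
                treated = pretreat(matrix, config.pretreatment)
                cv = crossvalidate_srd(
                    treated, k=config.folds, seed=config.seed
                )
                long = (
                    cv.reset_index()
                    .melt(id_vars="measure", var_name="cv_round", value_name="srd_norm")
                )
                long.insert(0, "dataset", dataset.name)
                long.insert(1, "bit_selection", selection)
                long.insert(2, "filtering", filtering)
                srd_rows.append(long)
                labels = matrix["active"].to_numpy()
                for abbrev in measure_columns(matrix):
                    auc_rows.append(
                        {
                            "dataset": dataset.name,
                            "bit_selection": selection,
                            "filtering": filtering,
                            "measure": abbrev,
                            "auc": roc_auc(matrix[abbrev].to_numpy(), labels),
                        }
                    )
    if not srd_rows:
        raise ValueError("every grid variant was emptied by filtering")
    srd = pd.concat(srd_rows, ignore_index=True)
    srd["symmetricity"] = srd["measure"].map(lambda m: classes[m][0])
    srd["metricity"] = srd["measure"].map(lambda m: classes[m][1])
    return GridResult(srd=srd, auc=pd.DataFrame(auc_rows), skipped=tuple(skipped))


# ---------------------------------------------------------------------------
# factor effects


@dataclass(frozen=True)
class FactorEffect:
    """Fixed-effects ANOVA summary for one factor (or interaction)."""

    factors: tuple[str, ...]
    levels: pd.DataFrame  # level(s), mean, ci_half, n
    f_statistic: float
    df: tuple[float, float]
    p_value: float

    @property
    def significant(self) -> bool:
        """Significance at the conventional alpha = 0.05 level."""
        return self.p_value < 0.05


def factor_anova(
    table: pd.DataFrame,
    factors: Sequence[str],
    interactions: Sequence[tuple[str, str]] = (),
    response: str = "srd_norm",
) -> list[FactorEffect]:
    """Fixed-effects ANOVA of normalized SRD on grouping factors.

    ``factors`` are main effects; ``interactions`` optional two-way terms.
    Sequential (type-I) sums of squares — on the balanced full-factorial
    grid all SS types coincide. Per-level means carry 95% t-based
    confidence half-widths. Raises for a factor with fewer than two levels
    or an interaction with an empty cell.
    """
    factors = list(factors)
    if not factors:
        raise ValueError("at least one factor is required")
    for f in factors:
        if f not in table.columns:
            raise ValueError(f"factor {f!r} not in table")
        if table[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
    for pair in interactions:
        counts = table.groupby(list(pair), observed=True).size()
        full = np.prod([table[f].nunique() for f in pair])
        if len(counts) < full:
            present = set(counts.index)
            levels = [table[f].unique() for f in pair]
            for cell in itertools.product(*levels):
                if cell not in present:
                    raise ValueError(f"empty cell {cell} in interaction {pair}")
    terms = [f"C({f})" for f in factors]
    terms += [f"C({f1}):C({f2})" for f1, f2 in interactions]
    data = table[[response, *factors]].copy()
    model = smf.ols(f"{response} ~ {' + '.join(terms)}", data=data).fit()
    aov = sm.stats.anova_lm(model, typ=1)
    df_resid = float(aov.loc["Residual", "df"])
    effects = []
    requested = [(f,) for f in factors] + [tuple(pair) for pair in interactions]
    for key in requested:
        term = ":".join(f"C({f})" for f in key)
        row = aov.loc[term]
        grouped = table.groupby(list(key), observed=True)[response]
        levels = grouped.agg(["mean", "std", "count"]).reset_index()
        tcrit = stats.t.ppf(0.975, np.maximum(levels["count"] - 1, 1))
        levels["ci_half"] = tcrit * levels["std"] / np.sqrt(levels["count"])
        levels = levels.drop(columns="std").rename(columns={"count": "n"})
        effects.append(
            FactorEffect(
                factors=key,
                levels=levels,
                f_statistic=float(row["F"]),
                df=(float(row["df"]), df_resid),
                p_value=float(row["PR(>F)"]),
            )
        )
    return effects
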