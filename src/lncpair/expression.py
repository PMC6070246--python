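"""Presence filtering, differential expression, and fold-change formatting.

The expression unit is FPKM.  A feature counts as expressed when its mean
FPKM reaches 1.0 in at least one treatment group; features below that in
every group are "not expressed".  The built-in differential-expression test
is Welch's two-sample t on log2(FPKM + 1) — a deliberately simple,
well-calibrated test; externally computed DE tables (e.g. from a
count-model tool) can be imported instead and flow through the same
downstream machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "Comparison",
    "DEResult",
    "ExpressionPartition",
    "FoldChange",
    "read_expression_tsv",
    "read_groups_tsv",
    "group_means",
    "is_expressed",
    "expressed_features",
    "run_de",
    "de_to_frame",
    "de_from_frame",
    "import_de_table",
    "write_de_table",
    "partition_features",
    "format_fold_change",
]

EXPRESSION_THRESHOLD = 1.0
DEFAULT_ALPHA = 0.05
PSEUDOCOUNT_RATIO = 1e-3  # added to both means when forming fold-change ratios
PSEUDOCOUNT_LOG = 1.0  # inside the log2 transform for the test statistic

DE_COLUMNS = [
    "feature_id", "comparison", "control_mean", "treated_mean",
    "log2fc", "p_value", "adjusted_p", "significant", "direction",
]


@dataclass(frozen=True)
class Comparison:
    """A treated-vs-control contrast between two sample groups."""

    name: str
    control_group: str
    treated_group: str

    def __post_init__(self) -> None:
        if self.control_group == self.treated_group:
            raise ValueError(
                f"comparison {self.name!r}: control and treated groups are identical"
            )


@dataclass
class ExpressionMatrix:
    """Feature x sample FPKM matrix with a sample -> group assignment."""

    values: pd.DataFrame  # index: feature ids, columns: sample ids
    groups: dict[str, str]  # sample id -> group label

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains NaN values")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("FPKM values must be non-negative")
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without a group assignment: {missing}")
        self.values = self.values.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def group_labels(self) -> list[str]:
        seen: list[str] = []
        for s in self.values.columns:
            g = self.groups[s]
            if g not in seen:
                seen.append(g)
        return seen

    def samples_in_group(self, group: str) -> list[str]:
        cols = [s for s in self.values.columns if self.groups[s] == group]
        if not cols:
            raise ValueError(f"no samples in group {group!r}")
        return cols

    def subset(self, feature_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = [f for f in feature_ids]
        return ExpressionMatrix(self.values.loc[ids], dict(self.groups))


def read_expression_tsv(path: str, groups_path: str) -> ExpressionMatrix:
    """Load a feature x sample FPKM TSV plus a two-column sample->group TSV."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    groups_df = pd.read_csv(groups_path, sep="\t")
    if groups_df.shape[1] < 2:
        raise ValueError(f"{groups_path}: expected columns sample_id, group")
    groups = dict(zip(groups_df.iloc[:, 0].astype(str), groups_df.iloc[:, 1].astype(str)))
    return ExpressionMatrix(values, groups)


def read_groups_tsv(path: str) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def group_means(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Arithmetic mean FPKM per feature per group (feature x group)."""
    out = {}
    for g in matrix.group_labels:
        out[g] = matrix.values[matrix.samples_in_group(g)].mean(axis=1)
    return pd.DataFrame(out)


def is_expressed(mean_row: Sequence[float],
                 threshold: float = EXPRESSION_THRESHOLD) -> bool:
    """True iff the max group mean reaches the threshold (boundary inclusive)."""
    arr = np.asarray(mean_row, dtype=float)
    if arr.size == 0:
        raise ValueError("is_expressed requires at least one group mean")
    return bool(arr.max() >= threshold)


def expressed_features(matrix: ExpressionMatrix,
                       threshold: float = EXPRESSION_THRESHOLD) -> list[str]:
    means = group_means(matrix)
    mask = means.max(axis=1) >= threshold
    return list(means.index[mask])


@dataclass(frozen=True)
class DEResult:
    """Differential-expression call for one feature in one comparison."""

    feature_id: str
    comparison: str
    control_mean: float
    treated_mean: float
    log2fc: float
    p_value: float
    adjusted_p: Optional[float]
    significant: bool
    direction: str  # "up", "down", or "none"

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down", "none"):
            raise ValueError(f"invalid direction {self.direction!r}")
        if self.significant and self.direction == "none":
            raise ValueError(
                f"{self.feature_id}: significant result must have a direction"
            )


def _direction(log2fc: float, significant: bool) -> str:
    if not significant or log2fc == 0.0:
        return "none"
    return "up" if log2fc > 0 else "down"


def run_de(matrix: ExpressionMatrix, comparison: Comparison,
           alpha: float = DEFAULT_ALPHA, adjust: str = "none") -> list[DEResult]:
    """Welch's t-test on log2(FPKM + 1), treated vs control, per feature.

    ``adjust`` is "none" (raw p < alpha) or "BH" (Benjamini-Hochberg across
    the features of this comparison, adjusted p < alpha).  Both-group
    zero-variance features are never significant (p treated as 1).
    """
    if adjust not in ("none", "BH"):
        raise ValueError(f"adjust must be 'none' or 'BH', got {adjust!r}")
    control_cols = matrix.samples_in_group(comparison.control_group)
    treated_cols = matrix.samples_in_group(comparison.treated_group)
    for label, cols in ((comparison.control_group, control_cols),
                        (comparison.treated_group, treated_cols)):
        if len(cols) < 2:
            raise ValueError(
                f"group {label!r} has {len(cols)} sample(s); "
                "at least 2 are required for the built-in test"
            )

    control = matrix.values[control_cols].to_numpy()
    treated = matrix.values[treated_cols].to_numpy()
    control_mean = control.mean(axis=1)
    treated_mean = treated.mean(axis=1)
    log2fc = np.log2(
        (treated_mean + PSEUDOCOUNT_RATIO) / (control_mean + PSEUDOCOUNT_RATIO)
    )

    log_c = np.log2(control + PSEUDOCOUNT_LOG)
    log_t = np.log2(treated + PSEUDOCOUNT_LOG)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # zero-variance rows trigger a precision warning; they are handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(log_t, log_c, axis=1, equal_var=False)
    p = np.asarray(p, dtype=float)
    zero_var = (log_c.var(axis=1) == 0) & (log_t.var(axis=1) == 0)
    p[zero_var | ~np.isfinite(p)] = 1.0

    if adjust == "BH":
        adjusted = multipletests(p, method="fdr_bh")[1]
        significant = adjusted < alpha
    else:
        adjusted = np.full_like(p, np.nan)
        significant = p < alpha

    results = []
    for i, fid in enumerate(matrix.feature_ids):
        sig = bool(significant[i]) and log2fc[i] != 0.0
        results.append(DEResult(
            feature_id=fid,
            comparison=comparison.name,
            control_mean=float(control_mean[i]),
            treated_mean=float(treated_mean[i]),
            log2fc=float(log2fc[i]),
            p_value=float(p[i]),
            adjusted_p=None if adjust == "none" else float(adjusted[i]),
            significant=sig,
            direction=_direction(float(log2fc[i]), sig),
        ))
    return results


def de_to_frame(results: Iterable[DEResult]) -> pd.DataFrame:
    rows = [
        (r.feature_id, r.comparison, r.control_mean, r.treated_mean,
         r.log2fc, r.p_value, np.nan if r.adjusted_p is None else r.adjusted_p,
         r.significant, r.direction)
        for r in results
    ]
    return pd.DataFrame(rows, columns=DE_COLUMNS)


def de_from_frame(frame: pd.DataFrame) -> list[DEResult]:
    out = []
    for row in frame.itertuples(index=False):
        adj = getattr(row, "adjusted_p", np.nan)
        out.append(DEResult(
            feature_id=str(row.feature_id),
            comparison=str(row.comparison),
            control_mean=float(getattr(row, "control_mean", np.nan)),
            treated_mean=float(getattr(row, "treated_mean", np.nan)),
            log2fc=float(row.log2fc),
            p_value=float(row.p_value),
            adjusted_p=None if pd.isna(adj) else float(adj),
            significant=bool(row.significant),
            direction=str(row.direction),
        ))
    return out


def write_de_table(results: Iterable[DEResult], path: str) -> None:
    de_to_frame(results).to_csv(path, sep="\t", index=False)


def import_de_table(path: str, alpha: float = DEFAULT_ALPHA) -> list[DEResult]:
    """Import an externally computed DE table (TSV) and recompute significance.

    Required columns: feature_id, comparison, p_value, and either log2fc or
    fold_change.  Significance is recomputed as strict raw p < alpha.
    """
    frame = pd.read_csv(path, sep="\t")
    required = {"feature_id", "comparison", "p_value"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    if "log2fc" not in frame.columns:
        if "fold_change" not in frame.columns:
            raise ValueError(f"{path}: need a log2fc or fold_change column")
        frame = frame.assign(log2fc=np.log2(frame["fold_change"].astype(float)))
    results = []
    for row in frame.itertuples(index=False):
        log2fc = float(row.log2fc)
        p = float(row.p_value)
        sig = p < alpha and log2fc != 0.0
        results.append(DEResult(
            feature_id=str(row.feature_id),
            comparison=str(row.comparison),
            control_mean=float(getattr(row, "control_mean", np.nan)),
            treated_mean=float(getattr(row, "treated_mean", np.nan)),
            log2fc=log2fc,
            p_value=p,
            adjusted_p=None,
            significant=sig,
            direction=_direction(log2fc, sig),
        ))
    return results


@dataclass(frozen=True)
class ExpressionPartition:
    """Three-way split of the feature universe: not expressed anywhere /
    stably expressed / differentially expressed in >= 1 comparison."""

    not_expressed: frozenset[str]
    stable: frozenset[str]
    differential: frozenset[str]

    def __post_init__(self) -> None:
        if (self.not_expressed & self.stable or
                self.not_expressed & self.differential or
                self.stable & self.differential):
            raise ValueError("partition sets must be pairwise disjoint")

    @property
    def total(self) -> int:
        return len(self.not_expressed) + len(self.stable) + len(self.differential)

    def sizes(self) -> dict[str, int]:
        return {
            "not_expressed": len(self.not_expressed),
            "stable": len(self.stable),
            "differential": len(self.differential),
        }


def partition_features(matrix: ExpressionMatrix,
                       de_results: Iterable[DEResult],
                       threshold: float = EXPRESSION_THRESHOLD) -> ExpressionPartition:
    """Partition all matrix features into not-expressed / stable / differential.

    Differential means expressed and significant in at least one of the
    supplied comparisons' results.
    """
    all_ids = set(matrix.feature_ids)
    means = group_means(matrix)
    expressed = set(means.index[means.max(axis=1) >= threshold])
    significant_ids = set()
    for r in de_results:
        if r.feature_id not in all_ids:
            raise ValueError(
                f"DE result for {r.feature_id!r} has no row in the expression matrix"
            )
        if r.significant:
            significant_ids.add(r.feature_id)
    differential = expressed & significant_ids
    return ExpressionPartition(
        not_expressed=frozenset(all_ids - expressed),
        stable=frozenset(expressed - differential),
        differential=frozenset(differential),
    )


@dataclass(frozen=True)
class FoldChange:
    """Dual-format effect size: fold-increase when the ratio is >= 1,
    percent decrease otherwise."""

    ratio: float
    kind: str  # "fold_increase" or "percent_decrease"
    value: float

    @property
    def label(self) -> str:
        if self.kind == "fold_increase":
            return f"{self.value:.2f}"
        return f"{self.value:.0f}% decrease"


def format_fold_change(control_mean: float, treated_mean: float,
                       pseudocount: float = PSEUDOCOUNT_RATIO) -> FoldChange:
    """Present a treated/control ratio the way toxicology tables report it."""
    if control_mean < 0 or treated_mean < 0:
        raise ValueError("means must be non-negative")
    ratio = (treated_mean + pseudocount) / (control_mean + pseudocount)
    if ratio >= 1.0:
        return FoldChange(ratio=ratio, kind="fold_increase", value=round(ratio, 2))
    return FoldChange(ratio=ratio, kind="percent_decrease",
                      value=float(round((1.0 - ratio) * 100)))
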