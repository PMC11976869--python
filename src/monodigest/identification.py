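"""Statistics over peptide/protein identification tables.

An identification table is a long-format :class:`pandas.DataFrame` with one
row per (protein, peptide, condition, replicate) carrying an abundance and a
q-value — the shape of a search-engine export.  This module provides the
downstream comparison layer: confidence filtering, count summaries, replicate
CV distributions, completeness of quantitation, rank-abundance tables,
exclusive set intersections (upset-style), and the hypothesis tests used to
compare conditions (one- and two-sample Kolmogorov-Smirnov, Wilcoxon
rank-sum / Mann-Whitney U, Welch's t).

The tests wrap scipy.stats; exact small-sample modes are selected
automatically where scipy offers them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "REQUIRED_COLUMNS",
    "load_table",
    "filter_confident",
    "summarize_counts",
    "cv_per_protein",
    "proportion_quantified",
    "rank_abundance",
    "exclusive_intersections",
    "ks_rank_uniformity",
    "two_sample_ks",
    "wilcoxon_rank_sum",
    "two_sample_t",
    "TestResult",
]

REQUIRED_COLUMNS = ("protein", "peptide", "condition", "replicate", "abundance", "q_value")


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test: name, statistic, p-value, method detail."""

    test: str
    statistic: float
    p_value: float
    method: str = ""


def load_table(path, column_map: Mapping[str, str] | None = None, sep: str | None = None) -> pd.DataFrame:
    """Read a TSV/CSV identification table, renaming columns via ``column_map``.

    ``column_map`` maps required names to the file's column names, e.g.
    ``{"protein": "Master Protein Accessions"}``.  The separator is sniffed
    from the extension unless given (``.csv`` -> comma, else tab).
    """
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, comment="#")
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"identification table missing columns: {missing}")
    return df


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"identification table missing columns: {missing}")


def filter_confident(table: pd.DataFrame, q_threshold: float = 0.01) -> pd.DataFrame:
    """Keep rows with ``q_value < q_threshold`` (high-confidence identifications)."""
    _check_table(table)
    if not 0.0 < q_threshold <= 1.0:
        raise ValueError(f"q_threshold must lie in (0, 1], got {q_threshold}")
    kept = table[table["q_value"] < q_threshold].reset_index(drop=True)
    logger.info("filter_confident: kept %d / %d rows at q < %g", len(kept), len(table), q_threshold)
    return kept


def summarize_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Distinct protein and peptide counts per replicate, with condition means.

    Returns one row per condition with columns ``n_replicates``,
    ``mean_proteins``, ``sd_proteins``, ``mean_peptides``, ``sd_peptides``
    (sample standard deviations; NaN for a single replicate).
    """
    _check_table(table)
    if table.empty:
        raise ValueError("empty identification table")
    per_rep = (
        table.groupby(["condition", "replicate"])
        .agg(n_proteins=("protein", "nunique"), n_peptides=("peptide", "nunique"))
        .reset_index()
    )
    return (
        per_rep.groupby("condition")
        .agg(
            n_replicates=("replicate", "nunique"),
            mean_proteins=("n_proteins", "mean"),
            sd_proteins=("n_proteins", "std"),
            mean_peptides=("n_peptides", "mean"),
            sd_peptides=("n_peptides", "std"),
        )
        .reset_index()
    )


def _replicate_abundances(
    table: pd.DataFrame, condition, level: str
) -> pd.DataFrame:
    """Entity x replicate abundance matrix for one condition.

    ``level`` is "protein" (peptide abundances summed within protein and
    replicate) or "peptide" (keyed by (protein, peptide))."""
    sub = table[table["condition"] == condition]
    if sub.empty:
        raise ValueError(f"condition {condition!r} not present in table")
    keys = ["protein"] if level == "protein" else ["protein", "peptide"]
    agg = sub.groupby(keys + ["replicate"])["abundance"].sum().reset_index()
    return agg.pivot_table(index=keys, columns="replicate", values="abundance")


def cv_per_protein(
    table: pd.DataFrame,
    condition,
    min_replicates: int = 2,
    level: str = "protein",
    log_scale: bool = False,
) -> pd.DataFrame:
    """Replicate coefficient of variation per protein (or peptide) in percent.

    For each entity observed in at least ``min_replicates`` replicates,
    ``cv_pct = 100 * sample_sd / mean`` over the raw abundances (n-1
    standard deviation).  With ``log_scale`` the CV is computed on
    log-transformed abundances instead.  Entities below ``min_replicates``
    are omitted and their number logged.  CV is scale-invariant: rescaling
    all abundances by a positive constant leaves it unchanged.
    """
    if level not in ("protein", "peptide"):
        raise ValueError("level must be 'protein' or 'peptide'")
    mat = _replicate_abundances(table, condition, level)
    values = np.log10(mat) if log_scale else mat
    n_obs = values.notna().sum(axis=1)
    eligible = values[n_obs >= min_replicates]
    n_skipped = len(values) - len(eligible)
    if n_skipped:
        logger.info(
            "cv_per_protein(%r): omitted %d entit(ies) with < %d replicates",
            condition, n_skipped, min_replicates,
        )
    mean = eligible.mean(axis=1)
    sd = eligible.std(axis=1, ddof=1)
    cv = 100.0 * sd / mean
    cv = cv[mean != 0]
    out = cv.reset_index()
    out.columns = list(out.columns[:-1]) + ["cv_pct"]
    return out


def proportion_quantified(table: pd.DataFrame, condition) -> float:
    """Fraction of identified peptides with an abundance in every replicate.

    "Quantified" means complete: the (protein, peptide) entity carries a
    non-missing abundance in each replicate of the condition.
    """
    mat = _replicate_abundances(table, condition, level="peptide")
    return float(mat.notna().all(axis=1).mean())


def rank_abundance(table: pd.DataFrame, condition) -> pd.DataFrame:
    """Proteins ranked by decreasing mean abundance (rank 1 = most abundant).

    Mean is over the replicates in which the protein was observed; ties
    are broken by accession lexicographic order for determinism.
    """
    mat = _replicate_abundances(table, condition, level="protein")
    mean = mat.mean(axis=1)
    out = mean.reset_index()
    out.columns = ["protein", "mean_abundance"]
    out = out.sort_values(
        ["mean_abundance", "protein"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def exclusive_intersections(
    protein_sets: Mapping[str, Set[str]]
) -> Dict[FrozenSet[str], int]:
    """Exclusive (upset-style) intersection sizes over >= 2 named sets.

    Each element of the union is assigned to the signature of exactly the
    sets containing it; the returned counts therefore sum to the union
    size.  Signatures with zero members are omitted.
    """
    if len(protein_sets) < 2:
        raise ValueError("need at least two sets to intersect")
    counts: Dict[FrozenSet[str], int] = {}
    union = set().union(*protein_sets.values())
    for element in union:
        sig = frozenset(name for name, s in protein_sets.items() if element in s)
        counts[sig] = counts.get(sig, 0) + 1
    return counts


def intersections_to_frame(counts: Mapping[FrozenSet[str], int], conditions: Sequence[str]) -> pd.DataFrame:
    """Matrix-format table of exclusive intersections (upset-tool input)."""
    rows = []
    for sig, n in counts.items():
        row = {c: (c in sig) for c in conditions}
        row["count"] = n
        rows.append(row)
    return (
        pd.DataFrame(rows)
        .sort_values("count", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )


def ks_rank_uniformity(unique_ranks: Sequence[int], n_total: int) -> TestResult:
    """One-sample KS test of rank uniformity.

    Asks whether proteins unique to a condition are spread uniformly
    through the full abundance ranking (ranks 1..n_total) or concentrated
    in part of it.  Ranks are mapped to mid-rank fractions
    ``(rank - 0.5) / n_total`` and compared against Uniform(0, 1); the
    p-value is exact for n <= 10, asymptotic otherwise.
    """
    ranks = np.asarray(unique_ranks, dtype=float)
    if ranks.size == 0:
        raise ValueError("empty rank list")
    if n_total < 1 or ranks.min() < 1 or ranks.max() > n_total:
        raise ValueError("ranks must lie in [1, n_total]")
    fracs = (ranks - 0.5) / n_total
    method = "exact" if ranks.size <= 10 else "asymp"
    res = stats.kstest(fracs, "uniform", method=method)
    return TestResult("ks_rank_uniformity", float(res.statistic), float(res.pvalue), method)


def two_sample_ks(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test (exact for small samples)."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("two_sample_ks requires non-empty samples")
    res = stats.ks_2samp(a, b, method="auto")
    return TestResult("two_sample_ks", float(res.statistic), float(res.pvalue), "auto")


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Average ranks on ties.  Exact null enumeration when both samples have
    n <= 10 and no ties cross the groups; otherwise the normal
    approximation with continuity and tie correction.  The statistic is
    the Mann-Whitney U of the first sample.
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("wilcoxon_rank_sum requires non-empty samples")
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    exact_ok = a.size <= 10 and b.size <= 10
    method = "exact" if exact_ok else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    if ties and exact_ok:
        method = "exact (ties present; untied null)"
    return TestResult("wilcoxon_rank_sum", float(res.statistic), float(min(res.pvalue, 1.0)), method)


def two_sample_t(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Welch's two-sided t test (unequal variances, Welch-Satterthwaite df)."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("two_sample_t requires n >= 2 per sample")
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        # degenerate: no variability, no difference
        return TestResult("welch_t", 0.0, 1.0, "degenerate")
    if np.var(a) == 0 and np.var(b) == 0:
        raise ValueError("zero variance in both samples")
    res = stats.ttest_ind(a, b, equal_var=False)
    return TestResult("welch_t", float(res.statistic), float(res.pvalue), "welch")
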