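"""Intra-species reproducibility across biological repeats.

Quantifies two modes of between-individual variation: the maximal mRNA
level a gene reaches, and its initiation time t0. Both are summarized
per gene as a coefficient of variation (sample SD over mean, percent),
repeats are compared pairwise (Pearson correlations and zero-intercept
slopes of t0), and the coupling between the two variation modes is the
across-gene correlation of the two CVs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .errors import InsufficientDataError
from .types import ExpressionProfile

__all__ = [
    "max_level",
    "normalized_sd",
    "zero_intercept_slope",
    "repeat_pair_stats",
    "variation_coupling",
    "fold_difference_of_maxima",
    "VariabilityReport",
    "variability_report",
]


def max_level(profile: ExpressionProfile) -> tuple[float, float]:
    """Maximal observed level within the measured window and its time.

    Ties are broken by the earliest time (``argmax`` returns the first
    occurrence on purpose).
    """
    if len(profile) == 0:
        raise InsufficientDataError(f"{profile.gene_id}: empty profile")
    i = int(np.argmax(profile.levels))
    return float(profile.levels[i]), float(profile.times[i])


def normalized_sd(values) -> float:
    """Percent normalized SD (CV): 100 * sample SD / mean.

    Scale-invariant for positive scalings. A zero mean is undefined and
    returns ``nan`` with a warning.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InsufficientDataError("normalized_sd needs >= 2 values")
    mean = v.mean()
    if mean == 0:
        warnings.warn("normalized_sd undefined for zero mean")
        return float("nan")
    return float(100.0 * v.std(ddof=1) / mean)


def zero_intercept_slope(x, y) -> float:
    """Least-squares slope of y = s*x through the origin: sum(xy)/sum(x^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise InsufficientDataError("zero_intercept_slope: sum(x^2) == 0")
    return float(np.sum(x * y) / sxx)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("degenerate variance in Pearson correlation")
        return float("nan")
    return float(pearsonr(x, y)[0])


@dataclass
class RepeatPairStats:
    repeat_a: str
    repeat_b: str
    pearson_max: float
    pearson_t0: float
    slope_t0: float
    n_genes: int


def repeat_pair_stats(
    max_a, max_b, t0_a, t0_b, repeat_a: str = "A", repeat_b: str = "B"
) -> RepeatPairStats:
    """Statistics for one pair of biological repeats over shared genes.

    ``max_*`` and ``t0_*`` are aligned per-gene vectors (``t0`` entries
    may be nan for non-zygotic genes and are dropped pairwise). The t0
    slope is the zero-intercept regression slope; slopes near 1 indicate
    matched developmental rates between the two individuals.
    """
    max_a = np.asarray(max_a, dtype=float)
    max_b = np.asarray(max_b, dtype=float)
    t0_a = np.asarray(t0_a, dtype=float)
    t0_b = np.asarray(t0_b, dtype=float)
    ok_max = np.isfinite(max_a) & np.isfinite(max_b)
    ok_t0 = np.isfinite(t0_a) & np.isfinite(t0_b)
    if ok_max.sum() < 3 or ok_t0.sum() < 3:
        raise InsufficientDataError("repeat_pair_stats needs >= 3 shared genes")
    return RepeatPairStats(
        repeat_a=repeat_a,
        repeat_b=repeat_b,
        pearson_max=_pearson(max_a[ok_max], max_b[ok_max]),
        pearson_t0=_pearson(t0_a[ok_t0], t0_b[ok_t0]),
        slope_t0=zero_intercept_slope(t0_a[ok_t0], t0_b[ok_t0]),
        n_genes=int(ok_max.sum()),
    )


def variation_coupling(cv_max, cv_t0) -> float:
    """Across-gene Pearson correlation between level CV and timing CV."""
    cv_max = np.asarray(cv_max, dtype=float)
    cv_t0 = np.asarray(cv_t0, dtype=float)
    ok = np.isfinite(cv_max) & np.isfinite(cv_t0)
    if ok.sum() < 3:
        raise InsufficientDataError("variation_coupling needs >= 3 genes")
    return _pearson(cv_max[ok], cv_t0[ok])


def fold_difference_of_maxima(maxima) -> float:
    """Mean over repeat pairs of max(x, y)/min(x, y) for one gene.

    Zero maxima are excluded with a warning.
    """
    m = np.asarray(maxima, dtype=float)
    m = m[np.isfinite(m)]
    if np.any(m == 0):
        warnings.warn("zero maxima excluded from fold difference")
        m = m[m > 0]
    if m.size < 2:
        raise InsufficientDataError("fold_difference_of_maxima needs >= 2 positive maxima")
    folds = [max(x, y) / min(x, y) for x, y in itertools.combinations(m, 2)]
    return float(np.mean(folds))


@dataclass
class VariabilityReport:
    """Per-gene, pairwise and summary intra-species variability statistics.

    ``mean_fold`` is the headline per-gene-mean of pairwise fold
    differences of maxima; ``pooled_fold`` pools all gene x pair folds.
    """

    per_gene: pd.DataFrame
    pairwise: pd.DataFrame
    coupling: float
    mean_cv_t0: float
    mean_cv_max: float
    mean_cv_fitted_max: float
    mean_fold: float
    pooled_fold: float
    warnings: list[str] = field(default_factory=list)


def variability_report(
    fit_table: pd.DataFrame, profiles: list[ExpressionProfile]
) -> VariabilityReport:
    """Build the full intra-species variability report.

    Parameters
    ----------
    fit_table
        Output of :func:`devochron.sigmoid.fit_profiles` for the same
        profiles (columns gene_id, repeat_id, a, t0, zygotic, ...).
    profiles
        The measured expression profiles (one per gene x repeat).

    Genes need >= 2 valid repeats to enter the per-gene table. Genes
    failing the zygotic gate contribute level statistics only.
    """
    prof_map = {(p.gene_id, p.repeat_id): p for p in profiles}
    fits = fit_table.set_index(["gene_id", "repeat_id"])

    genes = sorted({g for g, _ in prof_map})
    repeats = sorted({r for _, r in prof_map})

    notes: list[str] = []
    rows = []
    all_folds: list[float] = []
    for gene in genes:
        reps = [r for r in repeats if (gene, r) in prof_map]
        if len(reps) < 2:
            notes.append(f"{gene}: <2 repeats, skipped")
            continue
        maxima = np.array([max_level(prof_map[(gene, r)])[0] for r in reps])
        t0s, fitted_max = [], []
        for r in reps:
            row = fits.loc[(gene, r)]
            zyg = bool(row["zygotic"]) and np.isfinite(row["t0"])
            t0s.append(float(row["t0"]) if zyg else float("nan"))
            fitted_max.append(10.0 ** float(row["a"]) if np.isfinite(row["a"]) else float("nan"))
        t0s = np.array(t0s)
        fitted_max = np.array(fitted_max)

        rec = dict(gene_id=gene, n_repeats=len(reps))
        for r, m, t0 in zip(reps, maxima, t0s):
            rec[f"max_{r}"] = m
            rec[f"t0_{r}"] = t0
        rec["mean_max"] = float(np.mean(maxima))
        rec["sd_max"] = float(np.std(maxima, ddof=1))
        rec["cv_max_percent"] = normalized_sd(maxima)
        fm = fitted_max[np.isfinite(fitted_max)]
        rec["cv_fitted_max_percent"] = normalized_sd(fm) if fm.size >= 2 else float("nan")
        tz = t0s[np.isfinite(t0s)]
        if tz.size >= 2:
            rec["mean_t0"] = float(tz.mean())
            rec["sd_t0"] = float(tz.std(ddof=1))
            rec["cv_t0_percent"] = normalized_sd(tz)
        else:
            rec["mean_t0"] = rec["sd_t0"] = rec["cv_t0_percent"] = float("nan")
            notes.append(f"{gene}: <2 zygotic repeats, timing stats skipped")
        try:
            rec["mean_pairwise_fold"] = fold_difference_of_maxima(maxima)
            all_folds.extend(
                max(x, y) / min(x, y)
                for x, y in itertools.combinations(maxima[maxima > 0], 2)
            )
        except InsufficientDataError:
            rec["mean_pairwise_fold"] = float("nan")
        rows.append(rec)
    per_gene = pd.DataFrame(rows)

    pair_rows = []
    for ra, rb in itertools.combinations(repeats, 2):
        shared = [
            g for g in genes if (g, ra) in prof_map and (g, rb) in prof_map
        ]
        if len(shared) < 3:
            continue
        max_a = [max_level(prof_map[(g, ra)])[0] for g in shared]
        max_b = [max_level(prof_map[(g, rb)])[0] for g in shared]

        def _t0(g, r):
            row = fits.loc[(g, r)]
            return float(row["t0"]) if bool(row["zygotic"]) else float("nan")

        t0_a = [_t0(g, ra) for g in shared]
        t0_b = [_t0(g, rb) for g in shared]
        try:
            st = repeat_pair_stats(max_a, max_b, t0_a, t0_b, ra, rb)
        except InsufficientDataError as exc:
            notes.append(f"pair ({ra}, {rb}): {exc}")
            continue
        pair_rows.append(vars(st))
    pairwise = pd.DataFrame(pair_rows)

    if len(per_gene):
        try:
            coupling = variation_coupling(
                per_gene["cv_max_percent"], per_gene["cv_t0_percent"]
            )
        except InsufficientDataError as exc:
            notes.append(f"coupling: {exc}")
            coupling = float("nan")
        mean_cv_t0 = float(np.nanmean(per_gene["cv_t0_percent"]))
        mean_cv_max = float(np.nanmean(per_gene["cv_max_percent"]))
        mean_cv_fmax = float(np.nanmean(per_gene["cv_fitted_max_percent"]))
        mean_fold = float(np.nanmean(per_gene["mean_pairwise_fold"]))
    else:
        coupling = mean_cv_t0 = mean_cv_max = mean_cv_fmax = mean_fold = float("nan")
    pooled_fold = float(np.mean(all_folds)) if all_folds else float("nan")

    return VariabilityReport(
        per_gene=per_gene,
        pairwise=pairwise,
        coupling=coupling,
        mean_cv_t0=mean_cv_t0,
        mean_cv_max=mean_cv_max,
        mean_cv_fitted_max=mean_cv_fmax,
        mean_fold=mean_fold,
        pooled_fold=pooled_fold,
        warnings=notes,
    )
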