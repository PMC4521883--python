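"""Full analysis pipeline: quantify -> fit -> variability -> scaling -> comparison.

The pipeline consumes either a raw Ct table (quantified first through
the spike-in) or ready expression profiles for species A, optionally a
second species' profiles for the cross-species stages, and writes the
stage outputs plus a JSON summary. Deterministic for a fixed
configuration and seed.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import interspecies, sigmoid, variability
from .errors import DevochronError
from .quant import QuantConfig, build_profiles
from .types import ExpressionProfile, average_profiles

logger = logging.getLogger("devochron")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs.

    Either ``ct_table`` (with ``quant``) or ``profiles_a`` must be given.
    ``ratio=None`` estimates the rate ratio from initiation times;
    a float fixes it. ``orthologs`` maps species-A gene ids to species-B
    ones (default: identity on shared ids).
    """

    profiles_a: list[ExpressionProfile] | None = None
    profiles_b: list[ExpressionProfile] | None = None
    ct_table: pd.DataFrame | None = None
    quant: QuantConfig | None = None
    floor: float | None = None
    zygotic_min_rise: float = sigmoid.ZYGOTIC_MIN_RISE
    ratio: float | None = None
    exclude: tuple[str, ...] = ()
    orthologs: dict[str, str] | None = None
    random_pair_mode: str = "exhaustive"
    random_pairs: int = 200
    seed: int = 0
    out_dir: Path | None = None


def _group_by_gene(profiles: list[ExpressionProfile]) -> dict[str, list[ExpressionProfile]]:
    by_gene: dict[str, list[ExpressionProfile]] = defaultdict(list)
    for p in profiles:
        by_gene[p.gene_id].append(p)
    return dict(by_gene)


def _species_means(profiles: list[ExpressionProfile]) -> dict[str, ExpressionProfile]:
    return {g: average_profiles(ps) for g, ps in _group_by_gene(profiles).items()}


def _species_t0(means: dict[str, ExpressionProfile], floor, min_rise) -> dict[str, float]:
    t0s = {}
    for gene, prof in means.items():
        fit = sigmoid.fit_sigmoid(prof, floor=floor)
        if sigmoid.is_zygotic(fit, min_rise):
            t0s[gene] = fit.t0
        else:
            logger.info("gene %s: below zygotic gate, excluded from timing", gene)
    return t0s


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every applicable stage and return the summary dict.

    Writes ``fits.csv``, ``variability_report.csv``, ``repeat_pairs.csv``
    and, when species B is present, ``scaling_estimate.json``,
    ``aligned_profiles.csv``, ``correlations.csv``, plus ``summary.json``
    to ``config.out_dir`` if set.
    """
    profiles_a = config.profiles_a
    if profiles_a is None:
        if config.ct_table is None or config.quant is None:
            raise DevochronError("pipeline needs profiles_a or (ct_table and quant)")
        logger.info("stage quantify: %d Ct rows", len(config.ct_table))
        profiles_a = build_profiles(config.ct_table, config.quant)

    logger.info("stage fit: %d profiles", len(profiles_a))
    fit_table = sigmoid.fit_profiles(profiles_a, floor=config.floor, min_rise=config.zygotic_min_rise)

    logger.info("stage variability")
    report = variability.variability_report(fit_table, profiles_a)

    summary: dict = {
        "seed": config.seed,
        "n_genes": int(fit_table["gene_id"].nunique()),
        "n_zygotic": int(fit_table.groupby("gene_id")["zygotic"].all().sum()),
        "mean_cv_t0_percent": report.mean_cv_t0,
        "mean_cv_max_percent": report.mean_cv_max,
        "mean_cv_fitted_max_percent": report.mean_cv_fitted_max,
        "mean_pairwise_fold": report.mean_fold,
        "pooled_pairwise_fold": report.pooled_fold,
        "variation_coupling": report.coupling,
        # Fit quality is summarized over zygotic fits: an activation-model
        # R^2 is meaningless for flat maternal profiles.
        "min_fit_r2": (
            float(np.nanmin(fit_table.loc[fit_table["zygotic"], "r2"]))
            if fit_table["zygotic"].any() else float("nan")
        ),
        "warnings": report.warnings,
    }
    if len(report.pairwise):
        summary["mean_pair_pearson_t0"] = float(report.pairwise["pearson_t0"].mean())
        summary["mean_pair_pearson_max"] = float(report.pairwise["pearson_max"].mean())
        summary["mean_pair_slope_t0"] = float(report.pairwise["slope_t0"].mean())

    aligned_rows = []
    corr_rows = []
    if config.profiles_b is not None:
        logger.info("stage scaling")
        means_a = _species_means(profiles_a)
        means_b = _species_means(config.profiles_b)
        orthologs = config.orthologs or {g: g for g in set(means_a) & set(means_b)}

        t0_a = _species_t0(means_a, config.floor, config.zygotic_min_rise)
        t0_b_raw = _species_t0(means_b, config.floor, config.zygotic_min_rise)
        # Key species-B times by the species-A gene id via the orthologue map.
        t0_b = {ga: t0_b_raw[gb] for ga, gb in orthologs.items() if gb in t0_b_raw}

        if config.ratio is None:
            estimate = interspecies.estimate_rate_ratio(t0_a, t0_b, exclude=config.exclude)
            ratio = estimate.ratio
            summary["rate_ratio"] = estimate.ratio
            summary["rate_ratio_r2"] = estimate.r2
            summary["rate_ratio_pearson"] = estimate.pearson
            summary["rate_ratio_n_genes"] = estimate.n_genes
            summary["excluded_genes"] = estimate.excluded_genes
        else:
            ratio = config.ratio
            summary["rate_ratio"] = ratio
            summary["rate_ratio_r2"] = None

        logger.info("stage comparison: ratio %.4f", ratio)
        pairs = []
        for ga, gb in sorted(orthologs.items()):
            if ga not in means_a or gb not in means_b:
                continue
            try:
                pair = interspecies.align_pair(means_a[ga], means_b[gb], ratio, gene_id=ga)
            except DevochronError as exc:
                logger.warning("alignment failed for %s: %s", ga, exc)
                continue
            pairs.append(pair)
            for t, na, nb in zip(pair.times_common, pair.norm_levels_a, pair.norm_levels_b):
                aligned_rows.append(dict(gene_id=ga, time=t, norm_a=na, norm_b=nb))
        per_gene, mean_corr = interspecies.dynamics_correlation(pairs)
        corr_rows = [dict(gene_id=g, pearson=r) for g, r in sorted(per_gene.items())]
        summary["matched_mean_correlation"] = mean_corr
        summary["random_pair_baseline"] = interspecies.random_pair_baseline(
            means_a, means_b, ratio,
            mode=config.random_pair_mode, n_pairs=config.random_pairs, seed=config.seed,
        )

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fit_table.to_csv(out / "fits.csv", index=False)
        report.per_gene.to_csv(out / "variability_report.csv", index=False)
        report.pairwise.to_csv(out / "repeat_pairs.csv", index=False)
        if config.profiles_b is not None:
            pd.DataFrame(aligned_rows).to_csv(out / "aligned_profiles.csv", index=False)
            pd.DataFrame(corr_rows).to_csv(out / "correlations.csv", index=False)
            with open(out / "scaling_estimate.json", "w") as fh:
                json.dump(
                    {k: summary[k] for k in summary if k.startswith("rate_ratio") or k == "excluded_genes"},
                    fh, indent=2,
                )
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
    return summary
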