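"""Synthetic two-species time-course generator with known ground truth.

Emulates the statistical structure of developmental qPCR time courses:
per-gene log10-sigmoidal activation profiles sampled on species-specific
time grids, a constant multiplicative developmental rate ratio rho
between the species (species-B initiation times are rho times species-A
ones, and the rise rate slows by the same factor, so noiseless dynamics
are an exact time dilation), lognormal biological-repeat jitter on
timing and on maximal level, a maternal (constitutively present, no
measurable rise) gene fraction, and multiplicative log-normal
measurement noise. Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quant import QuantConfig
from .sigmoid import log_sigmoid
from .types import SPIKE_ID

__all__ = ["SimConfig", "generate_dataset", "to_ct_table"]


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative jitter with mean 1 and the given coefficient of variation."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


@dataclass
class SimConfig:
    """Study conditions for the synthetic two-species dataset.

    Defaults mirror a typical high-density developmental qPCR study:
    25 genes x 3 biological repeats per species, timing CV 8% and
    maximal-level CV 29% across repeats, measurement noise of 0.1 log10
    units, rate ratio 1.3, species A sampled 0-30 h at 1-h steps and
    species B over the correspondingly dilated window.
    """

    n_genes: int = 25
    n_repeats: int = 3
    rate_ratio: float = 1.3
    t0_range_a: tuple[float, float] = (4.0, 24.0)
    a_range: tuple[float, float] = (2.0, 6.0)
    b_range: tuple[float, float] = (1.0, 3.0)
    c_range: tuple[float, float] = (0.5, 2.5)
    timing_cv: float = 0.08
    level_cv: float = 0.29
    meas_sigma: float = 0.1
    grid_a: np.ndarray | None = None
    grid_b: np.ndarray | None = None
    maternal_fraction: float = 0.12
    maternal_b_range: tuple[float, float] = (0.02, 0.3)
    seed: int = 0
    max_retries: int = 10

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_repeats < 1:
            raise ValueError("counts must be >= 1")
        if not self.rate_ratio > 0:
            raise ValueError("rate_ratio must be positive")
        if self.timing_cv < 0 or self.level_cv < 0 or self.meas_sigma < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.grid_a is None:
            self.grid_a = np.arange(0.0, 30.0 + 0.5, 1.0)
        else:
            self.grid_a = np.asarray(self.grid_a, dtype=float)
        if self.grid_b is None:
            self.grid_b = np.arange(0.0, round(30.0 * self.rate_ratio) + 0.5, 1.0)
        else:
            self.grid_b = np.asarray(self.grid_b, dtype=float)
        for g in (self.grid_a, self.grid_b):
            if len(g) < 2 or not np.all(np.diff(g) > 0):
                raise ValueError("grids must be strictly increasing")


def _gene_ids(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"g{i + 1:0{width}d}" for i in range(n)]


def generate_dataset(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw a two-species dataset and its ground truth.

    Returns
    -------
    (df_a, df_b, truth)
        ``df_a``/``df_b`` are long-format expression tables with columns
        ``gene_id, repeat_id, time, level``. ``truth`` holds one row per
        gene x species x repeat with the realized (a, b, c, t0), plus
        per-gene ``repeat_id == "baseline"`` rows with the species-level
        truth; the global rate ratio is in column ``rate_ratio``.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    rho = config.rate_ratio

    expr_rows: dict[str, list] = {"A": [], "B": []}
    truth_rows = []
    for gene in genes:
        maternal = bool(rng.uniform() < config.maternal_fraction)
        a0 = rng.uniform(*config.a_range)
        b0 = rng.uniform(*config.maternal_b_range if maternal else config.b_range)
        c0 = rng.uniform(*config.c_range)
        t00 = rng.uniform(*config.t0_range_a)

        for species, grid, t0_base, c_sp in (
            ("A", config.grid_a, t00, c0),
            ("B", config.grid_b, t00 * rho, c0 / rho),
        ):
            truth_rows.append(
                dict(
                    gene_id=gene, species=species, repeat_id="baseline",
                    a=a0, b=b0, c=c_sp, t0=t0_base,
                    maternal=maternal, rate_ratio=rho, in_window=True,
                )
            )
            for r in range(1, config.n_repeats + 1):
                rep = f"R{r}"
                in_window = True
                for attempt in range(config.max_retries + 1):
                    t0_r = t0_base * _lognormal_factor(rng, config.timing_cv)
                    if grid.min() < t0_r < grid.max() or maternal:
                        break
                else:
                    in_window = False
                a_r = a0 + math.log10(_lognormal_factor(rng, config.level_cv))
                y = log_sigmoid(grid, a_r, b0, c_sp, t0_r)
                if config.meas_sigma > 0:
                    y = y + rng.normal(0.0, config.meas_sigma, size=len(grid))
                levels = 10.0 ** y
                expr_rows[species].extend(
                    (gene, rep, float(t), float(lv)) for t, lv in zip(grid, levels)
                )
                truth_rows.append(
                    dict(
                        gene_id=gene, species=species, repeat_id=rep,
                        a=a_r, b=b0, c=c_sp, t0=t0_r,
                        maternal=maternal, rate_ratio=rho, in_window=in_window,
                    )
                )

    cols = ["gene_id", "repeat_id", "time", "level"]
    df_a = pd.DataFrame(expr_rows["A"], columns=cols)
    df_b = pd.DataFrame(expr_rows["B"], columns=cols)
    truth = pd.DataFrame(truth_rows)
    return df_a, df_b, truth


def to_ct_table(
    expression: pd.DataFrame,
    config: QuantConfig,
    seed: int = 0,
    ct_spike: float = 20.0,
    ct_noise_sd: float = 0.0,
    n_tech: int = 3,
) -> pd.DataFrame:
    """Invert quantification: emit a tidy Ct table for an expression table.

    Ct_gene = Ct_spike - log_eff(level / spike_copies), replicated
    ``n_tech`` times with optional Gaussian Ct noise; spike-in rows with
    ``gene_id == "SPIKE"`` are emitted per (time, repeat) sample. Zero
    levels become undetected rows (Ct above the configured cutoff).
    """
    rng = np.random.default_rng(seed)
    ln_eff = math.log(config.efficiency)
    undetected_ct = config.undetected_ct_cutoff + 2.0
    rows = []
    for (time, rep), grp in expression.groupby(["time", "repeat_id"], sort=True):
        for k in range(1, n_tech + 1):
            noise = rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
            rows.append((SPIKE_ID, float(time), str(rep), k, ct_spike + noise))
        for _, row in grp.iterrows():
            level = float(row["level"])
            if level <= 0:
                for k in range(1, n_tech + 1):
                    rows.append((str(row["gene_id"]), float(time), str(rep), k, undetected_ct))
                continue
            ct = ct_spike - math.log(level / config.spike_copies) / ln_eff
            for k in range(1, n_tech + 1):
                noise = rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
                rows.append((str(row["gene_id"]), float(time), str(rep), k, ct + noise))
    return pd.DataFrame(rows, columns=["gene_id", "time", "repeat_id", "tech_rep", "ct"])
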