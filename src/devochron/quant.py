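"""Spike-in based absolute qPCR quantification.

A known number of exogenous template molecules (here conventionally a GFP
cDNA spike-in) is added to every sample, anchoring relative Ct values to
absolute copy numbers:

    copies = spike_copies * efficiency ** (Ct_spike - Ct_gene)

with a pooled per-cycle amplification efficiency (default 1.9). Technical
triplicates are aggregated on the Ct scale, converted, and their standard
errors propagated to a combined technical error per point.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Iterable
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    GroupingError,
    InvalidMeasurementError,
    MissingSpikeInError,
)
from .types import SPIKE_ID, CtRecord, ExpressionProfile


@dataclass
class QuantConfig:
    """Quantification settings.

    Parameters
    ----------
    spike_copies
        Molecules of spike-in template per sample (> 0).
    efficiency
        Per-cycle amplification base used for conversion; 2 is perfect
        doubling, the pooled default is 1.9.
    efficiency_accept_range
        Closed interval of acceptable measured primer efficiencies
        (default [1.85, 2.03], i.e. 89-103%).
    undetected_ct_cutoff
        Mean Ct above this value is flagged undetected and quantified as 0.
    """

    spike_copies: float
    efficiency: float = 1.9
    efficiency_accept_range: tuple[float, float] = (1.85, 2.03)
    undetected_ct_cutoff: float = 38.0

    def __post_init__(self) -> None:
        if not (self.spike_copies > 0 and math.isfinite(self.spike_copies)):
            raise ConfigError(f"spike_copies must be positive, got {self.spike_copies}")
        if not (1.0 < self.efficiency <= 2.0):
            raise ConfigError(
                f"efficiency must be in (1, 2], got {self.efficiency}"
            )
        lo, hi = self.efficiency_accept_range
        if lo > hi:
            raise ConfigError("efficiency_accept_range lower bound exceeds upper")


def quantify_sample(ct_gene: float, ct_spike: float, config: QuantConfig) -> float:
    """Absolute copies for one sample from mean gene and spike Ct values.

    Strictly decreasing in ``ct_gene`` and increasing in ``ct_spike``;
    a one-cycle decrease of ``ct_gene`` multiplies the result by exactly
    the configured efficiency.
    """
    for name, ct in (("ct_gene", ct_gene), ("ct_spike", ct_spike)):
        if not (math.isfinite(ct) and ct > 0):
            raise InvalidMeasurementError(f"{name} must be finite and positive, got {ct!r}")
    return config.spike_copies * config.efficiency ** (ct_spike - ct_gene)


def aggregate_technical_replicates(records: Iterable[CtRecord]) -> tuple[float, float]:
    """Mean Ct and its standard error for one gene/time/repeat group.

    SEM uses the sample SD (n-1 denominator) over sqrt(n). A single
    replicate yields ``nan`` as the flagged-undefined SEM.
    """
    records = list(records)
    if not records:
        raise GroupingError("no replicates to aggregate")
    keys = {(r.gene_id, r.time, r.repeat_id) for r in records}
    if len(keys) > 1:
        raise GroupingError(f"mixed replicate groups: {sorted(keys)}")
    cts = np.array([r.ct for r in records], dtype=float)
    mean = float(cts.mean())
    if len(cts) < 2:
        return mean, float("nan")
    return mean, float(cts.std(ddof=1) / math.sqrt(len(cts)))


def technical_error(sem_gene: float, sem_spike: float) -> float:
    """Combined technical error: root of summed squared SEMs.

    Symmetric in its arguments and never below either input (a norm).
    """
    if sem_gene < 0 or sem_spike < 0:
        raise ValueError("SEMs must be non-negative")
    return math.hypot(sem_gene, sem_spike)


def screen_primer_efficiency(efficiency: float, config: QuantConfig) -> bool:
    """Accept a primer pair iff its measured efficiency lies in the closed
    acceptance interval (default [1.85, 2.03])."""
    if not (efficiency > 0):
        raise ValueError(f"efficiency must be positive, got {efficiency!r}")
    lo, hi = config.efficiency_accept_range
    return lo <= efficiency <= hi


def _records_from_frame(df: pd.DataFrame) -> pd.DataFrame:
    required = {"gene_id", "time", "repeat_id", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise GroupingError(f"Ct table missing columns: {sorted(missing)}")
    out = df.copy()
    if "tech_rep" not in out.columns:
        out["tech_rep"] = 0
    return out


def build_profiles(ct_table: pd.DataFrame, config: QuantConfig) -> list[ExpressionProfile]:
    """Convert a tidy Ct table into absolute expression profiles.

    The table needs columns ``gene_id,time,repeat_id,tech_rep,ct`` with
    spike-in rows carrying ``gene_id == "SPIKE"``. One profile is produced
    per (gene, repeat), times sorted ascending; levels come from
    :func:`quantify_sample` applied to technical-replicate mean Cts and
    technical errors from delta-method propagation of the two Ct SEMs.

    Raises
    ------
    MissingSpikeInError
        If any (time, repeat) sample present in the gene rows has no
        spike-in rows; the offending samples are named.
    """
    df = _records_from_frame(ct_table)
    spikes = df[df["gene_id"] == SPIKE_ID]
    genes = df[df["gene_id"] != SPIKE_ID]
    if genes.empty:
        raise GroupingError("Ct table contains no gene rows")

    spike_stats: dict[tuple[float, str], tuple[float, float]] = {}
    for (time, rep), grp in spikes.groupby(["time", "repeat_id"], sort=False):
        cts = grp["ct"].to_numpy(dtype=float)
        sem = float(cts.std(ddof=1) / math.sqrt(len(cts))) if len(cts) > 1 else float("nan")
        spike_stats[(float(time), str(rep))] = (float(cts.mean()), sem)

    needed = {(float(t), str(r)) for t, r in genes[["time", "repeat_id"]].itertuples(index=False)}
    missing = sorted(needed - set(spike_stats))
    if missing:
        raise MissingSpikeInError(
            "missing spike-in rows for samples (time, repeat): " + ", ".join(map(str, missing))
        )

    ln_eff = math.log(config.efficiency)
    profiles: list[ExpressionProfile] = []
    for (gene, rep), grp in genes.groupby(["gene_id", "repeat_id"], sort=True):
        rows = []
        for time, tgrp in grp.groupby("time", sort=True):
            cts = tgrp["ct"].to_numpy(dtype=float)
            if np.any(~np.isfinite(cts)) or np.any(cts <= 0):
                raise InvalidMeasurementError(
                    f"non-finite or non-positive Ct for {gene} at t={time}, repeat {rep}"
                )
            mean_ct = float(cts.mean())
            sem_ct = float(cts.std(ddof=1) / math.sqrt(len(cts))) if len(cts) > 1 else float("nan")
            ct_sp, sem_sp = spike_stats[(float(time), str(rep))]
            if mean_ct > config.undetected_ct_cutoff:
                rows.append((float(time), 0.0, float("nan")))
                continue
            level = quantify_sample(mean_ct, ct_sp, config)
            # Delta method on copies = spike * eff**(ct_sp - ct_gene):
            # |d level / d ct| = level * ln(eff) for either Ct.
            if math.isnan(sem_ct) or math.isnan(sem_sp):
                err = float("nan")
            else:
                err = technical_error(level * ln_eff * sem_ct, level * ln_eff * sem_sp)
            rows.append((float(time), level, err))
        rows.sort(key=lambda r: r[0])
        times, levels, errs = (np.array(col, dtype=float) for col in zip(*rows))
        profiles.append(ExpressionProfile(str(gene), str(rep), times, levels, errs))
    if any(np.isnan(p.tech_errors).all() and len(p) > 0 for p in profiles):
        warnings.warn("some profiles have no technical error estimates (single technical replicate)")
    return profiles
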