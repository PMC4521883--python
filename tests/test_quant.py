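"""Spike-in quantification: formula, aggregation, error propagation, screening."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import devochron as dc
from devochron.errors import (
    ConfigError,
    GroupingError,
    InvalidMeasurementError,
    MissingSpikeInError,
)


class TestQuantifySample:
    @pytest.mark.parametrize(
        "ct_gene, ct_spike, spike, expected",
        [
            (20.0, 20.0, 2.6e8, 2.6e8),          # equal Ct => equal copy number
            (21.0, 20.0, 1000.0, 1000.0 / 1.9),  # one cycle more => /efficiency
            (20.0, 22.0, 1000.0, 3610.0),        # 1000 * 1.9**2
        ],
    )
    def test_formula(self, ct_gene, ct_spike, spike, expected):
        cfg = dc.QuantConfig(spike_copies=spike)
        assert dc.quantify_sample(ct_gene, ct_spike, cfg) == pytest.approx(expected, rel=1e-12)

    def test_one_cycle_shift_multiplies_by_efficiency(self, quant_config):
        base = dc.quantify_sample(25.0, 20.0, quant_config)
        shifted = dc.quantify_sample(24.0, 20.0, quant_config)
        assert shifted / base == pytest.approx(quant_config.efficiency, rel=1e-12)

    @given(
        level=st.floats(1e-3, 1e9),
        spike=st.floats(1.0, 1e9),
        ct_spike=st.floats(5.0, 35.0),
    )
    def test_round_trip_inversion(self, level, spike, ct_spike):
        """Inverting the formula for Ct_gene recovers any positive level."""
        cfg = dc.QuantConfig(spike_copies=spike)
        ct_gene = ct_spike - math.log(level / spike) / math.log(cfg.efficiency)
        if ct_gene <= 0:
            return
        assert dc.quantify_sample(ct_gene, ct_spike, cfg) == pytest.approx(level, rel=1e-9)

    @pytest.mark.parametrize("bad", [float("nan"), float("inf"), -1.0, 0.0])
    def test_invalid_ct_rejected(self, bad, quant_config):
        with pytest.raises(InvalidMeasurementError):
            dc.quantify_sample(bad, 20.0, quant_config)

    def test_bad_efficiency_rejected(self):
        with pytest.raises(ConfigError):
            dc.QuantConfig(spike_copies=1e7, efficiency=1.0)
        with pytest.raises(ConfigError):
            dc.QuantConfig(spike_copies=-5.0)


class TestAggregateTechnicalReplicates:
    @staticmethod
    def _records(cts):
        return [dc.CtRecord("gene", 10.0, "R1", i, ct) for i, ct in enumerate(cts)]

    @pytest.mark.parametrize(
        "cts, mean, sem",
        [
            ([20.0, 20.0, 20.0], 20.0, 0.0),
            ([19.0, 20.0, 21.0], 20.0, 1.0 / math.sqrt(3)),
        ],
    )
    def test_mean_and_sem(self, cts, mean, sem):
        m, s = dc.aggregate_technical_replicates(self._records(cts))
        assert m == pytest.approx(mean)
        assert s == pytest.approx(sem, abs=1e-12)

    def test_single_replicate_flagged(self):
        m, s = dc.aggregate_technical_replicates(self._records([20.0]))
        assert m == 20.0 and math.isnan(s)

    def test_mixed_groups_rejected(self):
        recs = self._records([20.0]) + [dc.CtRecord("other", 10.0, "R1", 0, 21.0)]
        with pytest.raises(GroupingError):
            dc.aggregate_technical_replicates(recs)


class TestTechnicalError:
    @pytest.mark.parametrize(
        "g, s, expected", [(0.0, 0.0, 0.0), (3.0, 4.0, 5.0), (0.2, 0.0, 0.2)]
    )
    def test_examples(self, g, s, expected):
        assert dc.technical_error(g, s) == pytest.approx(expected)

    @given(a=st.floats(0, 1e3), b=st.floats(0, 1e3), c=st.floats(0, 1e3), k=st.floats(0, 100))
    def test_norm_properties(self, a, b, c, k):
        """Triangle inequality, symmetry, homogeneity, dominance."""
        assert dc.technical_error(a, b) == dc.technical_error(b, a)
        assert dc.technical_error(a + c, b) <= dc.technical_error(a, b) + c + 1e-9
        assert dc.technical_error(k * a, k * b) == pytest.approx(k * dc.technical_error(a, b), abs=1e-6)
        assert dc.technical_error(a, b) >= max(a, b) - 1e-12

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            dc.technical_error(-0.1, 0.2)


class TestPrimerScreening:
    @pytest.mark.parametrize(
        "eff, accepted",
        [(1.85, True), (2.03, True), (1.9, True), (1.80, False), (2.04, False)],
    )
    def test_closed_interval(self, eff, accepted, quant_config):
        assert dc.screen_primer_efficiency(eff, quant_config) is accepted


class TestBuildProfiles:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(rows, columns=["gene_id", "time", "repeat_id", "tech_rep", "ct"])

    def test_simple_profile(self, quant_config):
        rows = []
        for t in (0.0, 10.0):
            rows += [("SPIKE", t, "R1", k, 20.0) for k in range(3)]
            rows += [("gA", t, "R1", k, 22.0) for k in range(3)]
        (profile,) = dc.build_profiles(self._table(rows), quant_config)
        assert len(profile) == 2
        expected = quant_config.spike_copies * 1.9 ** (20.0 - 22.0)
        assert profile.levels == pytest.approx([expected, expected])

    def test_missing_spike_named(self, quant_config):
        rows = [("SPIKE", 0.0, "R1", 0, 20.0), ("gA", 0.0, "R1", 0, 22.0),
                ("gA", 10.0, "R1", 0, 22.0)]
        with pytest.raises(MissingSpikeInError, match="10.0"):
            dc.build_profiles(self._table(rows), quant_config)

    def test_undetected_quantified_as_zero(self, quant_config):
        rows = [("SPIKE", 0.0, "R1", 0, 20.0), ("gA", 0.0, "R1", 0, 39.5),
                ("SPIKE", 1.0, "R1", 0, 20.0), ("gA", 1.0, "R1", 0, 22.0)]
        (profile,) = dc.build_profiles(self._table(rows), quant_config)
        assert profile.levels[0] == 0.0 and profile.levels[1] > 0

    def test_round_trip_against_inverted_formula(self):
        """Profiles -> Ct (algebraic inversion) -> profiles recovers levels."""
        cfg = dc.QuantConfig(spike_copies=2.6e8, undetected_ct_cutoff=60.0)
        rng = np.random.default_rng(42)
        times = np.arange(0.0, 8.0)
        levels = 10 ** rng.uniform(1, 7, size=len(times))
        expr = pd.DataFrame(
            dict(gene_id="gX", repeat_id="R1", time=times, level=levels)
        )
        ct = dc.to_ct_table(expr, cfg, ct_noise_sd=0.0)
        (profile,) = dc.build_profiles(ct, cfg)
        assert profile.levels == pytest.approx(levels, rel=1e-9)
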