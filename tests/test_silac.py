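"""Enrichment calling: parsing, normalization, the binned outlier statistic
and the published thresholds."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_force_sig_b
from phosbridge.silac import (
    apply_enrichment_filter,
    call_enrichment,
    classify_tnf_regulation,
    normalize_log_ratios,
    read_protein_groups,
    significance_b,
)
from phosbridge.types import (
    BinSpreadError,
    EmptyInputError,
    EnrichmentCall,
    EnrichmentThresholds,
    FormatError,
    ProteinGroup,
    ValidationError,
)


def _write(tmp_path, text, name="groups.tsv"):
    path = tmp_path / name
    path.write_text(text)
    return path


def _group(pid="A", peptides=3, intensity=1e7, ratio=2.5, tnf=None):
    return ProteinGroup(protein_id=pid, unique_peptides=peptides,
                        intensity=intensity, ratio_bait_vs_ctrl=ratio,
                        ratio_tnf_vs_untreated=tnf)


class TestReadProteinGroups:
    HEADER = ("protein_id\tunique_peptides\tintensity\tratio_bait_ctrl"
              "\tcontaminant\n")

    def test_plain_parse_with_absent_tnf_channels(self, tmp_path):
        path = _write(
            tmp_path,
            "id\tpep\tint\tratio\n"
            "abc\t3\t1e6\t2.0\n"
            "DEF\t5\t2e6\t0.8\n"
            "ghi\t2\t3e6\t1.1\n",
        )
        groups = read_protein_groups(
            path,
            dialect={"protein_id": "id", "unique_peptides": "pep",
                     "intensity": "int", "ratio_bait_vs_ctrl": "ratio"},
        )
        assert [g.protein_id for g in groups] == ["ABC", "DEF", "GHI"]
        assert all(g.ratio_tnf_vs_untreated is None for g in groups)

    def test_contaminant_rows_dropped(self, tmp_path):
        rows = "".join(
            f"P{i}\t3\t1e6\t1.0\t{'+' if i == 2 else ''}\n" for i in range(5)
        )
        groups = read_protein_groups(_write(tmp_path, self.HEADER + rows))
        assert len(groups) == 4
        assert "P2" not in {g.protein_id for g in groups}

    def test_zero_ratio_rejected(self, tmp_path):
        path = _write(tmp_path, self.HEADER + "A\t3\t1e6\t0\t\n")
        with pytest.raises(ValidationError):
            read_protein_groups(path)

    def test_missing_mandatory_column_named(self, tmp_path):
        path = _write(tmp_path, "protein_id\tintensity\nA\t1e6\n")
        with pytest.raises(FormatError, match="unique_peptides"):
            read_protein_groups(path)


class TestNormalize:
    def test_constant_ratios_center_to_zero(self):
        groups = [_group(pid, ratio=2.0) for pid in "ABC"]
        assert normalize_log_ratios(groups) == {"A": 0.0, "B": 0.0, "C": 0.0}

    def test_two_ratios_split_symmetrically(self):
        groups = [_group("A", ratio=1.0), _group("B", ratio=4.0)]
        out = normalize_log_ratios(groups)
        assert out["A"] == pytest.approx(-1.0)
        assert out["B"] == pytest.approx(+1.0)

    def test_single_protein_is_its_own_median(self):
        assert normalize_log_ratios([_group("A", ratio=8.0)]) == {"A": 0.0}

    def test_empty_channel_raises(self):
        with pytest.raises(EmptyInputError):
            normalize_log_ratios([_group("A")], "ratio_tnf_vs_untreated")


class TestSignificanceB:
    def test_bin_median_scores_one_half(self):
        values = {f"P{i:02d}": float(v)
                  for i, v in enumerate([-2, -1, -0.5, 0.0, 0.5, 1, 2])}
        intensities = dict.fromkeys(values, 1.0)
        sig = significance_b(values, intensities, bin_size=20)
        assert sig["P03"] == (pytest.approx(0.5), "above_median")

    def test_value_at_8413th_percentile_scores_gaussian_one_sigma(self):
        # 10001 evenly spaced values: the 84.13th percentile interpolates
        # exactly onto the datum 0.8413, giving z = 1
        values = {f"P{i:05d}": i / 10000.0 for i in range(10001)}
        intensities = dict.fromkeys(values, 1.0)
        sig = significance_b(values, intensities, bin_size=6000)
        expected = 0.5 * math.erfc(1.0 / math.sqrt(2.0))
        assert sig["P08413"][0] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.1587, abs=5e-4)

    def test_constant_bin_scores_one(self):
        values = dict.fromkeys(["A", "B", "C"], 0.7)
        sig = significance_b(values, dict.fromkeys(values, 1.0), bin_size=20)
        assert all(s == 1.0 for s, _ in sig.values())

    def test_degenerate_spread_raises(self):
        values = {"A": 0.0, "B": 0.0, "C": 0.0, "D": -1.0}
        with pytest.raises(BinSpreadError):
            significance_b(values, dict.fromkeys(values, 1.0), bin_size=20)

    @pytest.mark.parametrize("n,bin_size", [(50, 25), (700, 300), (4999, 300)])
    def test_matches_brute_force_oracle(self, n, bin_size):
        rng = np.random.default_rng(n)
        values = {f"P{i:05d}": float(v)
                  for i, v in enumerate(rng.normal(0, 1, n))}
        intensities = {pid: float(v)
                       for pid, v in zip(values, rng.uniform(1, 1e9, n))}
        ours = significance_b(values, intensities, bin_size)
        ref = brute_force_sig_b(values, intensities, bin_size)
        for pid in values:
            assert ours[pid][1] == ref[pid][1]
            assert ours[pid][0] == pytest.approx(ref[pid][0], abs=1e-9)

    def test_null_upper_tail_is_uniform(self):
        # i.i.d. Gaussian ratios, intensity-independent spread: upper-side
        # sig_b should be uniform on (0, 0.5] (Kolmogorov-Smirnov check)
        from scipy.stats import kstest

        rng = np.random.default_rng(42)
        n = 10000
        values = {f"P{i:05d}": float(v)
                  for i, v in enumerate(rng.normal(0, 1, n))}
        intensities = {pid: float(v)
                       for pid, v in zip(values, rng.uniform(1, 1e9, n))}
        sig = significance_b(values, intensities, 300)
        upper = [s for s, side in sig.values() if side == "above_median"]
        stat, p = kstest(np.array(upper) * 2.0, "uniform")
        assert p > 0.01

    def test_row_order_never_matters(self):
        rng = np.random.default_rng(7)
        n = 900
        values = {f"P{i:04d}": float(v)
                  for i, v in enumerate(rng.normal(0, 1, n))}
        # deliberate intensity ties to exercise deterministic tie-breaking
        intensities = {pid: float(rng.integers(1, 50)) for pid in values}
        base = significance_b(values, intensities, 300)
        shuffled_keys = list(values)
        rng.shuffle(shuffled_keys)
        permuted = significance_b({k: values[k] for k in shuffled_keys},
                                  {k: intensities[k] for k in shuffled_keys},
                                  300)
        assert permuted == base


class TestEnrichmentThresholds:
    SIG = {"A": (0.01, "above_median")}

    def _one_call(self, ratio, sig_b, peptides):
        group = _group("A", peptides=peptides, ratio=ratio)
        calls = apply_enrichment_filter(
            [group], {"A": (sig_b, "above_median")}
        )
        return calls[0]

    def test_clear_interactor_enriched(self):
        assert self._one_call(2.5, 0.01, 3).enriched

    def test_ratio_boundary_is_strict(self):
        assert not self._one_call(1.9, 0.001, 5).enriched

    def test_sig_b_boundary_is_strict(self):
        assert not self._one_call(5.0, 0.1, 5).enriched

    def test_single_peptide_excluded(self):
        assert not self._one_call(5.0, 0.001, 1).enriched

    def test_below_median_never_enriched(self):
        group = _group("A", ratio=2.5)
        call = apply_enrichment_filter(
            [group], {"A": (0.01, "below_median")}
        )[0]
        assert not call.enriched

    def test_missing_protein_in_sig_map_raises(self):
        with pytest.raises(ValidationError):
            apply_enrichment_filter([_group("A"), _group("B")], self.SIG)

    @settings(max_examples=40, deadline=None)
    @given(
        ratio=st.floats(1.0, 10.0),
        sig_b=st.floats(1e-6, 1.0),
        peptides=st.integers(0, 10),
        d_ratio=st.floats(0.0, 3.0),
        d_sig=st.floats(0.0, 0.09),
    )
    def test_tightening_thresholds_is_monotone(self, ratio, sig_b, peptides,
                                               d_ratio, d_sig):
        group = _group("A", peptides=peptides, ratio=ratio)
        sig = {"A": (sig_b, "above_median")}
        loose = apply_enrichment_filter(
            [group], sig, EnrichmentThresholds()
        )[0].enriched
        tight = apply_enrichment_filter(
            [group], sig,
            EnrichmentThresholds(min_ratio=1.9 + d_ratio,
                                 max_sig_b=0.1 - d_sig),
        )[0].enriched
        assert loose or not tight  # tight => loose


class TestTnfRegulation:
    def _call(self):
        return EnrichmentCall("A", 2.0, 0.01, "above_median", True)

    def test_unchanged_ratio_is_independent(self):
        group = _group("A", tnf=1.0)
        assert classify_tnf_regulation(self._call(), group,
                                       tnf_sig_b=0.01) == "tnf_independent"

    def test_strong_increase_is_positive(self):
        group = _group("A", tnf=2.5)
        assert classify_tnf_regulation(self._call(), group,
                                       tnf_sig_b=0.01) == "tnf_positive"

    def test_strong_decrease_is_negative(self):
        group = _group("A", tnf=0.4)  # 0.4 < 1/1.9
        assert classify_tnf_regulation(self._call(), group,
                                       tnf_sig_b=0.02) == "tnf_negative"

    def test_absent_channel_defaults_to_independent(self):
        group = _group("A", tnf=None)
        assert classify_tnf_regulation(self._call(), group,
                                       tnf_sig_b=None) == "tnf_independent"


def test_call_enrichment_recovers_mini_fixture_preys(mini_bundle):
    from phosbridge.examples import BAIT_PREYS

    for bait, groups in mini_bundle.protein_groups.items():
        enriched = {c.protein_id for c in call_enrichment(groups)
                    if c.enriched}
        assert enriched == set(BAIT_PREYS[bait])
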