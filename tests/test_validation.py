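"""Comparative-Ct and dual-reporter validation statistics."""

import numpy as np
import pandas as pd
import pytest

from pwas.validation import allele_activation, ddct


def ct_table(rows):
    return pd.DataFrame(rows, columns=["sample", "gene", "replicate", "ct"])


def reporter_table(rows):
    return pd.DataFrame(rows, columns=["condition", "allele", "replicate", "firefly", "renilla"])


class TestDdct:
    def test_treated_equal_control_gives_unity(self):
        table = ct_table(
            [(s, g, r, ct) for s in ("mock", "kd")
             for g, ct in (("RUNX1", 22.0), ("GAPDH", 18.0)) for r in (1, 2, 3)]
        )
        res = ddct(table, "RUNX1", "kd")
        assert res.ddct == pytest.approx(0.0)
        assert res.relative_expression == pytest.approx(1.0)

    def test_one_cycle_shift_halves_expression(self):
        table = ct_table(
            [("mock", "RUNX1", 1, 22.0), ("mock", "GAPDH", 1, 18.0),
             ("mock", "RUNX1", 2, 22.0), ("mock", "GAPDH", 2, 18.0),
             ("kd", "RUNX1", 1, 23.0), ("kd", "GAPDH", 1, 18.0),
             ("kd", "RUNX1", 2, 23.0), ("kd", "GAPDH", 2, 18.0)]
        )
        res = ddct(table, "RUNX1", "kd")
        assert res.ddct == pytest.approx(1.0)
        assert res.relative_expression == pytest.approx(0.5)

    def test_replicate_table_matches_spreadsheet_arithmetic(self):
        # hand-computed: dCt mock = mean(21.8,22.2) - mean(17.9,18.1) = 4.0
        #                dCt kd   = mean(24.5,24.9) - mean(18.0,18.2) = 6.6
        #                ddCt = 2.6 -> 2^-2.6 = 0.16493...
        table = ct_table(
            [("mock", "T", 1, 21.8), ("mock", "T", 2, 22.2),
             ("mock", "REF", 1, 17.9), ("mock", "REF", 2, 18.1),
             ("kd", "T", 1, 24.5), ("kd", "T", 2, 24.9),
             ("kd", "REF", 1, 18.0), ("kd", "REF", 2, 18.2)]
        )
        res = ddct(table, "T", "kd", reference_gene="REF")
        assert res.ddct == pytest.approx(2.6)
        assert res.relative_expression == pytest.approx(2 ** -2.6)
        # replicate-wise ddCt values: (24.5-18.0)-(21.8-17.9)=2.6 and
        # (24.9-18.2)-(22.2-18.1)=2.6 -> zero spread
        assert res.ddct_sd == pytest.approx(0.0)

    def test_machine_offset_cancels(self):
        rows = [("mock", "T", 1, 20.0), ("mock", "REF", 1, 16.0),
                ("mock", "T", 2, 20.4), ("mock", "REF", 2, 16.2),
                ("kd", "T", 1, 22.0), ("kd", "REF", 1, 16.1),
                ("kd", "T", 2, 22.2), ("kd", "REF", 2, 16.3)]
        base = ddct(ct_table(rows), "T", "kd", reference_gene="REF")
        shifted = ddct(
            ct_table([(s, g, r, ct + 3.0) for s, g, r, ct in rows]),
            "T", "kd", reference_gene="REF",
        )
        assert shifted.ddct == pytest.approx(base.ddct)
        assert shifted.relative_expression == pytest.approx(base.relative_expression)

    def test_missing_reference_gene_rejected(self):
        table = ct_table([("mock", "T", 1, 20.0), ("kd", "T", 1, 22.0)])
        with pytest.raises(ValueError, match="GAPDH"):
            ddct(table, "T", "kd")

    def test_single_replicate_warns_without_spread(self, caplog):
        table = ct_table(
            [("mock", "T", 1, 20.0), ("mock", "REF", 1, 16.0),
             ("kd", "T", 1, 22.0), ("kd", "REF", 1, 16.0)]
        )
        with caplog.at_level("WARNING"):
            res = ddct(table, "T", "kd", reference_gene="REF")
        assert res.ddct_sd is None
        assert "single replicate" in caplog.text


class TestAlleleActivation:
    @staticmethod
    def identical_table():
        rows = []
        for allele in ("A", "T"):
            for cond in ("mock", "kd"):
                for rep in (1, 2, 3):
                    rows.append((cond, allele, rep, 1000.0, 100.0))
        return reporter_table(rows)

    def test_identical_conditions_give_zero_change(self):
        res = allele_activation(self.identical_table(), "kd")
        assert res.percent_change["A"] == pytest.approx(0.0)
        assert res.percent_change["T"] == pytest.approx(0.0)

    def test_allele_swap_symmetry(self):
        rng = np.random.default_rng(8)
        rows = []
        for allele, boost in (("A", 1.16), ("T", 1.34)):
            for cond, scale in (("mock", 1.0), ("kd", boost)):
                for rep in range(3):
                    rows.append((cond, allele, rep, 1000 * scale * rng.lognormal(0, 0.05), 100.0))
        table = reporter_table(rows)
        res = allele_activation(table, "kd")
        swapped = table.assign(allele=table["allele"].map({"A": "T", "T": "A"}))
        res_sw = allele_activation(swapped, "kd")
        assert res_sw.percent_change["T"] == pytest.approx(res.percent_change["A"])
        assert res_sw.percent_change["A"] == pytest.approx(res.percent_change["T"])
        assert res_sw.p_between_alleles == pytest.approx(res.p_between_alleles)

    def test_renilla_rescaling_invariance(self):
        rng = np.random.default_rng(21)
        rows = []
        for allele, boost in (("A", 1.2), ("T", 1.5)):
            for cond, scale in (("mock", 1.0), ("kd", boost)):
                for rep in range(3):
                    rows.append((cond, allele, rep, 1000 * scale * rng.lognormal(0, 0.1),
                                 100 * rng.lognormal(0, 0.1)))
        table = reporter_table(rows)
        res = allele_activation(table, "kd")
        rescaled = table.assign(renilla=table["renilla"] * 7.5)
        res2 = allele_activation(rescaled, "kd")
        for a in ("A", "T"):
            assert res2.percent_change[a] == pytest.approx(res.percent_change[a])

    def test_recovers_true_activation_difference(self):
        """Triplicates at true means +16% and +34% are recovered within 2 sd."""
        hits = 0
        n_trials = 50
        for seed in range(n_trials):
            rng = np.random.default_rng(seed)
            rows = []
            for allele, mean_pct, sd_pct in (("A", 16.0, 7.0), ("T", 34.0, 11.0)):
                mock_act = 10.0
                for rep in range(3):
                    rows.append(("mock", allele, rep, mock_act * 100, 100.0))
                for rep in range(3):
                    pct = rng.normal(mean_pct, sd_pct)
                    rows.append(("kd", allele, rep, mock_act * (1 + pct / 100) * 100, 100.0))
            res = allele_activation(reporter_table(rows), "kd")
            ok_a = abs(res.percent_change["A"] - 16.0) <= 2 * 7.0
            ok_t = abs(res.percent_change["T"] - 34.0) <= 2 * 11.0
            hits += ok_a and ok_t
        assert hits / n_trials >= 0.9

    def test_missing_condition_rejected(self):
        table = self.identical_table()
        with pytest.raises(ValueError, match="required"):
            allele_activation(table[table["condition"] == "mock"], "kd")

    def test_single_replicate_skips_test(self, caplog):
        table = self.identical_table()
        table = table[table["replicate"] == 1]
        with caplog.at_level("WARNING"):
            res = allele_activation(table, "kd")
        assert np.isnan(res.p_between_alleles)

    def test_nonpositive_signal_rejected(self):
        table = self.identical_table()
        table.loc[0, "firefly"] = 0.0
        with pytest.raises(ValueError, match="positive"):
            allele_activation(table, "kd")
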