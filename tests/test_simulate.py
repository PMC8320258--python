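"""Generative properties of the droplet simulator."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tcrscreen.simulate import (ActivationModel, ConfigurationError,
                                DropletParams, RepertoireSpec,
                                simulate_condition, simulate_repertoire)
from tcrscreen.vdj import translate_cdr3


class TestSimulateRepertoire:
    def test_frequencies_sum_to_one(self):
        rep = simulate_repertoire(RepertoireSpec(n_clonotypes=500, seed=1))
        assert abs(sum(c.frequency for c in rep) - 1.0) < 1e-12

    def test_single_clonotype_gets_all_mass(self):
        (c,) = simulate_repertoire(RepertoireSpec(n_clonotypes=1, seed=1))
        assert c.frequency == 1.0

    def test_dual_alpha_fraction_within_binomial_ci(self):
        n = 3000
        rep = simulate_repertoire(RepertoireSpec(n_clonotypes=n, seed=2))
        observed = sum(len(c.alphas) == 2 for c in rep)
        lo, hi = stats.binom.interval(0.99, n, 1 / 3)
        assert lo <= observed <= hi

    def test_zero_dual_alpha(self):
        rep = simulate_repertoire(
            RepertoireSpec(n_clonotypes=200, dual_alpha_fraction=0.0, seed=3))
        assert all(len(c.alphas) == 1 for c in rep)

    def test_junctions_unique_in_frame_and_translatable(self):
        rep = simulate_repertoire(RepertoireSpec(n_clonotypes=300, seed=4))
        keys = [c.cdr3b_nt for c in rep]
        assert len(set(keys)) == len(keys)
        for c in rep[:50]:
            assert len(c.cdr3b_nt) % 3 == 0
            assert set(c.cdr3b_nt) <= set("ACGT")
            assert "*" not in translate_cdr3(c.cdr3b_nt)

    @pytest.mark.parametrize("kwargs", [
        {"n_clonotypes": 0},
        {"n_clonotypes": 5, "frequency_law": "zeta"},
        {"n_clonotypes": 5, "shape": -1.0},
        {"n_clonotypes": 5, "dual_alpha_fraction": 1.5},
    ])
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            RepertoireSpec(**kwargs)


NOISE_FREE = dict(doublet_rate=0.0, cdr3_error_rate=0.0,
                  ambient_marker_rate=0.0)


class TestSimulateCondition:
    def test_noise_free_single_clonotype(self):
        rep = simulate_repertoire(RepertoireSpec(n_clonotypes=1, seed=5))
        sim = simulate_condition(
            rep, DropletParams(target_recovery=10, seed=5, **NOISE_FREE),
            ActivationModel(), "stim")
        assert sim.truth["barcode"].nunique() == 10
        trb = sim.contigs[sim.contigs["chain"] == "TRB"]
        assert trb["cdr3_nt"].nunique() == 1
        assert (sim.truth["vdj_observed"] == "mixed").sum() == 0

    def test_unknown_reactive_id_rejected(self):
        rep = simulate_repertoire(RepertoireSpec(n_clonotypes=3, seed=6))
        with pytest.raises(ConfigurationError):
            simulate_condition(rep, DropletParams(target_recovery=5, seed=6),
                               ActivationModel(reactive_clonotype_ids=frozenset({99})),
                               "stim")

    def test_artifact_clonotypes_match_closed_form(self):
        """#novel β keys ≈ C·(1−(1−e)^L) within 3 binomial standard errors."""
        n_clono, e, n_cells = 50, 2e-3, 4000
        spec = RepertoireSpec(n_clonotypes=n_clono, dual_alpha_fraction=0.0,
                              cdr3b_length_range=(36, 36), seed=7)
        rep = simulate_repertoire(spec)
        sim = simulate_condition(
            rep, DropletParams(target_recovery=n_cells, doublet_rate=0.0,
                               cdr3_error_rate=e, ambient_marker_rate=0.0,
                               seed=7),
            ActivationModel(), "stim")
        planted = {c.cdr3b_nt for c in rep}
        trb = sim.contigs[sim.contigs["chain"] == "TRB"]
        observed = (~trb["cdr3_nt"].isin(planted)).sum()
        p_hit = 1 - (1 - e) ** 36
        expect = n_cells * p_hit
        se = np.sqrt(n_cells * p_hit * (1 - p_hit))
        assert abs(observed - expect) <= 3 * se

    def test_negative_control_ambient_tail(self):
        """Without reactive clonotypes, <0.1% of barcodes cross the IFN-γ cutoff.

        Ambient counts are Poisson(0.05); P(X ≥ 5) ≈ 2.6e-9, so even one
        activated barcode in 6000 would be extraordinary.
        """
        rep = simulate_repertoire(RepertoireSpec(n_clonotypes=100, seed=8))
        sim = simulate_condition(rep, DropletParams(seed=8),
                                 ActivationModel(), "control")
        frac = (sim.markers["IFNG"] >= 5).mean()
        assert frac < 0.001

    def test_identical_seed_identical_output(self):
        rep = simulate_repertoire(RepertoireSpec(n_clonotypes=20, seed=9))
        model = ActivationModel(reactive_clonotype_ids=frozenset({0, 1}))
        runs = [simulate_condition(rep, DropletParams(target_recovery=300,
                                                      seed=9), model, "stim")
                for _ in range(2)]
        pd.testing.assert_frame_equal(runs[0].contigs, runs[1].contigs)
        pd.testing.assert_frame_equal(runs[0].markers, runs[1].markers)
        pd.testing.assert_frame_equal(runs[0].truth, runs[1].truth)

    def test_noise_free_partition_equals_planted(self):
        """Called clonotypes reproduce the planted partition exactly."""
        from tcrscreen.vdj import call_clonotypes, group_cells
        from tcrscreen.vdj import filter_productive, read_contigs

        rep = simulate_repertoire(RepertoireSpec(n_clonotypes=30, seed=10))
        sim = simulate_condition(
            rep, DropletParams(target_recovery=200, seed=10, **NOISE_FREE),
            ActivationModel(), "stim")
        key_by_cid = {str(c.cid): c.cdr3b_nt for c in rep}
        planted = {}
        for r in sim.truth.itertuples(index=False):
            planted.setdefault(key_by_cid[r.clonotype_ids], set()).add(r.barcode)
        cells = group_cells(filter_productive(
            _records_from_frame(sim.contigs)))
        called = {c.key: c.barcodes for c in call_clonotypes(cells)}
        assert called == planted


def _records_from_frame(df):
    from tcrscreen.vdj import ContigRecord
    return [
        ContigRecord(barcode=r.barcode, chain=r.chain, v_gene=r.v_gene,
                     j_gene=r.j_gene, cdr3_aa=r.cdr3, cdr3_nt=r.cdr3_nt,
                     umis=int(r.umis), productive=r.productive == "True",
                     contig_id=r.contig_id)
        for r in df.itertuples(index=False)
    ]
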