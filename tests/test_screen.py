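"""Activation join, autoreactive removal, candidate extraction and ranking."""

import pytest

from tcrscreen.markers import ActivationThresholds, MarkerProfile
from tcrscreen.screen import (ActivatedCell, extract_candidates,
                              join_condition, rank_candidates,
                              remove_autoreactive)
from tcrscreen.vdj import filter_productive, group_cells

from conftest import contig

THR = ActivationThresholds()

K1, K2, K3 = "TGTGCTTTC", "TGTAAATTC", "TGTCCCTTC"


def make_cells(spec):
    """spec: list of (barcode, beta_key or None, [alpha keys])."""
    contigs = []
    for bc, beta, alphas in spec:
        if beta is not None:
            contigs.append(contig(barcode=bc, cdr3_nt=beta,
                                  contig_id=f"{bc}_b"))
        for i, a in enumerate(alphas):
            contigs.append(contig(barcode=bc, chain="TRA", cdr3_nt=a,
                                  contig_id=f"{bc}_a{i}"))
    return group_cells(filter_productive(contigs))


def activated(bc, cond="PP-1", key=None, status="paired", ifng=20, il2=0):
    return ActivatedCell(barcode=bc, condition=cond, ifng=ifng, il2=il2,
                         lineage="CD8", clonotype_key=key, vdj_status=status)


class TestJoinCondition:
    def test_only_activated_barcodes_returned(self):
        cells = make_cells([("b1-1", K1, [K2]), ("b2-1", K1, [K2])])
        profiles = [MarkerProfile("b1-1", ifng=20),
                    MarkerProfile("b2-1", ifng=1)]
        out, log = join_condition(cells, profiles, THR, "PP-1")
        assert [a.barcode for a in out] == ["b1-1"]
        assert out[0].clonotype_key == K1 and out[0].vdj_status == "paired"
        assert log.n_activated == 1

    def test_marker_only_barcode_is_undetectable(self):
        out, log = join_condition([], [MarkerProfile("b1-1", ifng=20)],
                                  THR, "PP-1")
        assert out[0].vdj_status == "undetectable"
        assert out[0].clonotype_key is None
        assert log.n_marker_only == 1

    def test_il2_only_cell_counted_as_activated_and_logged(self):
        out, log = join_condition([], [MarkerProfile("b1-1", il2=9)],
                                  THR, "PP-1")
        assert len(out) == 1 and log.n_il2_only == 1 and log.n_ifng_pos == 0

    def test_contig_only_barcode_logged_not_activated(self):
        cells = make_cells([("b1-1", K1, [])])
        out, log = join_condition(cells, [], THR, "PP-1")
        assert out == [] and log.n_contig_only == 1


class TestRemoveAutoreactive:
    def test_clonotype_activated_in_control_removed_everywhere(self):
        act = {
            "DMSO": [activated("b1-1", "DMSO", K1)],
            "PP-1": [activated("b2-1", "PP-1", K1),
                     activated("b3-1", "PP-1", K2),
                     activated("b4-1", "PP-1", K3)],
        }
        removed = remove_autoreactive(act, "DMSO")
        assert removed == {K1}
        cells = make_cells([("b2-1", K1, [K3]), ("b3-1", K2, [K3]),
                            ("b4-1", K3, [K2])])
        cands = extract_candidates(act["PP-1"], cells, "PP-1", removed)
        assert {c.clonotype_key for c in cands} == {K2, K3}

    def test_quiet_control_removes_nothing(self):
        act = {"DMSO": [], "PP-1": [activated("b1-1", "PP-1", K1)]}
        assert remove_autoreactive(act, "DMSO") == set()

    def test_missing_control_warns_and_skips(self, caplog):
        act = {"PP-1": [activated("b1-1", "PP-1", K1)]}
        with caplog.at_level("WARNING"):
            removed = remove_autoreactive(act, None)
        assert removed == set()
        assert any("skipped" in r.message for r in caplog.records)

    def test_removal_is_idempotent(self):
        act = {"DMSO": [activated("b1-1", "DMSO", K1)], "PP-1": []}
        assert remove_autoreactive(act, "DMSO") == \
               remove_autoreactive(act, "DMSO")


class TestExtractCandidates:
    def test_four_cells_one_shared_candidate(self):
        cells = make_cells([(f"b{i}-1", K1, [K2]) for i in range(4)])
        acts = [activated(f"b{i}-1", key=K1) for i in range(4)]
        (c,) = extract_candidates(acts, cells, "PP-1")
        assert c.support == 4 and c.klass == "shared"

    def test_single_cell_unique_candidate(self):
        cells = make_cells([("b1-1", K1, [K2])])
        (c,) = extract_candidates([activated("b1-1", key=K1)], cells, "PP-1")
        assert c.klass == "unique" and c.support == 1

    def test_mixed_and_undetectable_never_candidates(self):
        cells = make_cells([("b1-1", K1, []), ("b1-1", K2, []),
                            ("b2-1", None, [K3])])
        acts = [activated("b1-1", status="mixed"),
                activated("b2-1", status="undetectable")]
        assert extract_candidates(acts, cells, "PP-1") == []

    def test_alpha_variants_capped_at_two_most_supported(self):
        spec = [("b1-1", K1, [K2, K3]), ("b2-1", K1, [K2]),
                ("b3-1", K1, ["TGTGGGTTC"])]
        cells = make_cells(spec)
        acts = [activated(f"b{i}-1", key=K1) for i in (1, 2, 3)]
        (c,) = extract_candidates(acts, cells, "PP-1")
        assert len(c.alphas) == 2
        assert c.alphas[0][2] == K2  # carried by two cells

    def test_conservation_of_candidate_counts(self):
        """#shared + #unique = #distinct non-excluded activated paired keys."""
        spec = [("b1-1", K1, [K2]), ("b2-1", K1, [K2]), ("b3-1", K2, [K3]),
                ("b4-1", K3, [K1])]
        cells = make_cells(spec)
        acts = [activated(bc, key=key) for bc, key, _ in spec]
        cands = extract_candidates(acts, cells, "PP-1", exclude_keys={K3})
        assert len(cands) == 2
        assert sum(c.klass == "shared" for c in cands) + \
               sum(c.klass == "unique" for c in cands) == 2


class TestRankCandidates:
    def _cand(self, key, support, ifng):
        from tcrscreen.screen import CandidateTCR
        return CandidateTCR(clonotype_key=key, condition="PP-1",
                            beta=("V", "J", key, "X"), alphas=[("V", "J", K2, "X")],
                            support=support, ifng_total=ifng, il2_total=0)

    def test_shared_before_unique_then_support_then_ifng(self):
        cands = [self._cand("a", 1, 40), self._cand("b", 2, 5),
                 self._cand("c", 1, 12), self._cand("d", 3, 1)]
        ordered = rank_candidates(cands)
        assert [c.clonotype_key for c in ordered] == ["d", "b", "a", "c"]
        assert [c.rank for c in ordered] == [1, 2, 3, 4]

    def test_fixture_ordering_matches_independent_sort_oracle(self, suite_run):
        cc1 = suite_run["results"]["CC1"]
        pp3 = [c for c in cc1.candidates if c.condition == "PP-3"]
        oracle = sorted(pp3, key=lambda c: (c.klass != "shared", -c.support,
                                            -c.ifng_total, c.clonotype_key))
        assert [c.clonotype_key for c in sorted(pp3, key=lambda c: c.rank)] \
               == [c.clonotype_key for c in oracle]

    def test_fixture_shared_set_matches_truth_oracle(self, suite_run):
        """Shared candidates == planted reactive clonotypes with ≥2
        responders carrying an intact observed receptor."""
        from tcrscreen.pipeline import TruthData
        for name in ("M1", "M2", "CC1"):
            truth = TruthData.load(suite_run["work_dir"] / name / "truth")
            bc = truth.barcodes
            own = bc[(bc["response"] == "ifng")
                     & (bc["observed_key"] != "")
                     & (bc["vdj_observed"] == "paired")
                     & (bc["artifact"] == "")]
            counts = own.groupby(["condition", "observed_key"]).size()
            expected = {
                (cond, key) for (cond, key), n in counts.items()
                if n >= 2 and key in truth.reactive_keys
            }
            observed = {
                (c.condition, c.clonotype_key)
                for c in suite_run["results"][name].candidates
                if c.klass == "shared"
            }
            assert observed == expected
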