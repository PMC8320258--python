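"""Contig reading, chain pairing and CDR3β-nt clonotype calling."""

import random
from collections import defaultdict

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tcrscreen.vdj import (FormatError, call_clonotypes, filter_productive,
                           group_cells, read_contigs, write_contigs)

from conftest import contig


def _write_csv(path, rows):
    header = ("barcode,is_cell,contig_id,chain,v_gene,j_gene,"
              "cdr3,cdr3_nt,umis,productive\n")
    path.write_text(header + "".join(rows))


class TestReadContigs:
    def test_single_valid_trb_row(self, tmp_path):
        p = tmp_path / "c.csv"
        _write_csv(p, ["bc1-1,True,bc1-1_c0,TRB,TRBV9,TRBJ1-1,CAF,TGTGCTTTC,3,True\n"])
        recs = read_contigs(p)
        assert len(recs) == 1 and recs[0].cdr3_nt == "TGTGCTTTC"

    def test_non_cell_and_foreign_chains_dropped(self, tmp_path):
        p = tmp_path / "c.csv"
        _write_csv(p, [
            "bc1-1,False,c0,TRB,TRBV9,TRBJ1-1,CAF,TGTGCTTTC,3,True\n",
            "bc2-1,True,c1,IGH,IGHV1,IGHJ1,CAF,TGTGCTTTC,3,True\n",
            "bc3-1,True,c2,TRA,TRAV1,TRAJ4,CAF,TGTGCTTTC,3,True\n",
        ])
        recs = read_contigs(p)
        assert [r.barcode for r in recs] == ["bc3-1"]

    def test_unproductive_retained_at_read_excluded_by_filter(self, tmp_path):
        p = tmp_path / "c.csv"
        _write_csv(p, ["bc1-1,True,c0,TRB,TRBV9,TRBJ1-1,CAF,TGTGCTTTC,3,False\n"])
        recs = read_contigs(p)
        assert len(recs) == 1 and not recs[0].productive
        assert filter_productive(recs) == []

    def test_missing_column_named_in_error(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("barcode,chain\nx,TRB\n")
        with pytest.raises(FormatError, match="cdr3_nt|is_cell|contig_id"):
            read_contigs(p)

    def test_fixture_file_round_trips(self, suite_run, tmp_path):
        src = suite_run["work_dir"] / "M1" / "TMG-1" / "contigs.csv"
        out = tmp_path / "again.csv"
        write_contigs(read_contigs(src), out)
        pd.testing.assert_frame_equal(pd.read_csv(src), pd.read_csv(out))


class TestFilterProductive:
    def test_duplicate_keeps_highest_umis(self):
        a = contig(umis=3, contig_id="c1")
        b = contig(umis=7, contig_id="c2")
        kept = filter_productive([a, b])
        assert len(kept) == 1 and kept[0].umis == 7

    def test_empty_input(self):
        assert filter_productive([]) == []


class TestGroupCells:
    @pytest.mark.parametrize("contigs, status, n_alpha", [
        # one β plus two distinct α chains: a dual-α cell, cleanly paired
        ([contig(chain="TRB"), contig(chain="TRA", cdr3_nt="TGTAAATTC", contig_id="a1"),
          contig(chain="TRA", cdr3_nt="TGTCCCTTC", contig_id="a2")], "paired", 2),
        # two distinct productive β junctions: mixed
        ([contig(cdr3_nt="TGTGCTTTC", contig_id="b1"),
          contig(cdr3_nt="TGTGGGTTC", contig_id="b2")], "mixed", 0),
        # α only: β undetectable
        ([contig(chain="TRA")], "undetectable", 1),
        # two β contigs with the identical junction collapse to one: paired
        ([contig(cdr3_nt="TGTGCTTTC", contig_id="b1"),
          contig(cdr3_nt="TGTGCTTTC", contig_id="b2", umis=2)], "paired", 0),
    ])
    def test_status_assignment(self, contigs, status, n_alpha):
        cells = group_cells(filter_productive(contigs))
        assert len(cells) == 1
        assert cells[0].status == status
        assert len(cells[0].alpha_contigs) == n_alpha


class TestCallClonotypes:
    def test_matches_brute_force_grouping(self):
        keys = ["TGTGCTTTC", "TGTAAATTC", "TGTCCCTTC", "TGTGGGTTC"]
        rng = random.Random(0)
        contigs = [contig(barcode=f"bc{i}-1", cdr3_nt=rng.choice(keys),
                          contig_id=f"bc{i}_c0") for i in range(10)]
        cells = group_cells(filter_productive(contigs))
        called = {c.key: c.barcodes for c in call_clonotypes(cells)}
        brute = defaultdict(set)
        for c in contigs:
            brute[c.cdr3_nt].add(c.barcode)
        assert called == dict(brute)

    def test_invariant_to_row_order(self):
        contigs = [contig(barcode=f"bc{i}-1", cdr3_nt=k, contig_id=f"c{i}")
                   for i, k in enumerate(["TGTGCTTTC"] * 3 + ["TGTAAATTC"] * 2)]
        shuffled = list(reversed(contigs))
        a = call_clonotypes(group_cells(filter_productive(contigs)))
        b = call_clonotypes(group_cells(filter_productive(shuffled)))
        assert [(c.key, sorted(c.barcodes)) for c in a] == \
               [(c.key, sorted(c.barcodes)) for c in b]

    def test_silent_nucleotide_change_splits_clonotypes(self):
        # TGC and TGT both encode cysteine: same protein, distinct clonotypes
        a = contig(barcode="bc1-1", cdr3_nt="TGTGCTTTC")
        b = contig(barcode="bc2-1", cdr3_nt="TGCGCTTTC")
        assert a.cdr3_aa == b.cdr3_aa
        called = call_clonotypes(group_cells(filter_productive([a, b])))
        assert len(called) == 2

    def test_shared_beta_distinct_alphas_one_clonotype(self):
        cells = group_cells(filter_productive([
            contig(barcode="bc1-1", contig_id="b1"),
            contig(barcode="bc1-1", chain="TRA", cdr3_nt="TGTAAATTC", contig_id="a1"),
            contig(barcode="bc2-1", contig_id="b2"),
            contig(barcode="bc2-1", chain="TRA", cdr3_nt="TGTCCCTTC", contig_id="a2"),
        ]))
        called = call_clonotypes(cells)
        assert len(called) == 1 and len(called[0].alpha_variants) == 2

    @given(st.lists(st.tuples(st.integers(0, 30), st.integers(0, 5)),
                    max_size=60))
    @settings(derandomize=True, deadline=None, max_examples=50)
    def test_partition_property(self, assignments):
        """Every paired cell lands in exactly one clonotype; counts conserve."""
        keys = [f"TGT{'GCT' * (k % 3 + 1)}TTC" for k in range(6)]
        contigs = [contig(barcode=f"bc{bc}-1", cdr3_nt=keys[k % 6],
                          contig_id=f"bc{bc}_c{i}")
                   for i, (bc, k) in enumerate(assignments)]
        cells = group_cells(filter_productive(contigs))
        called = call_clonotypes(cells)
        n_paired = sum(c.status == "paired" for c in cells)
        assert sum(c.count for c in called) == n_paired
        all_bcs = [b for c in called for b in c.barcodes]
        assert len(all_bcs) == len(set(all_bcs))
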