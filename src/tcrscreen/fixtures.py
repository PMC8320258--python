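"""Six planted validation specimens (M1–M3 melanoma, CC1–CC3 colorectal).

Each fixture is a fully rendered specimen — per-condition contig CSVs and
marker matrices plus a ground-truth directory — whose planted structure
mirrors the counts the screen is expected to recover: how many cells
activate per condition, which clonotypes are reactive or autoreactive,
which candidates are shared versus unique, and which were taken forward to
wet-lab testing.  Pooled over the suite the plants give 19 shared
candidates (all truly reactive) and 23 tested unique candidates of which 9
are reactive — unique calls are diluted by two planted artifact
mechanisms: CDR3 sequencing errors that spawn singleton clonotypes, and
doublets in which the responding cell's TCR dropped out so the bystander's
receptor inherits the activation signal.

Artifact and capture-failure events are placed explicitly (not drawn from
the stochastic droplet model) so every planted count is exactly
recoverable; the stochastic processes themselves are exercised by the
generic simulator in :mod:`tcrscreen.simulate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from tcrscreen.markers import write_marker_matrix
from tcrscreen.simulate import (
    NT, TRAV_GENES, TRAJ_GENES, TRBV_GENES, TRBJ_GENES, CODONS,
    AlphaChain, draw_responder_ifng, draw_responder_il2, random_barcodes,
    random_cdr3_nt, ActivationModel,
)
from tcrscreen.vdj import CONTIG_COLUMNS, translate_cdr3

FIXTURE_NAMES = ("M1", "M2", "M3", "CC1", "CC2", "CC3")

#: documented per-fixture seeds (combined with a user seed if given)
FIXTURE_SEEDS = {"M1": 11, "M2": 22, "M3": 33, "CC1": 44, "CC2": 55, "CC3": 66}

MARKERS = ("IFNG", "IL2", "CD4", "CD8A", "CD8B")
AMBIENT_RATE = 0.05


@dataclass
class PlannedClonotype:
    cid: str
    reactive: bool = False
    autoreactive: bool = False
    cognate: str = ""
    n_alpha: int = 1
    lineage: str = "CD8"
    pair_of: str | None = None   # nearly-identical receptor pair partner
    # filled at render time
    cdr3b_nt: str = ""
    v_gene: str = ""
    j_gene: str = ""
    alphas: list = field(default_factory=list)


@dataclass
class PlannedCell:
    condition: str
    cid: str
    response: str = ""            # '', 'ifng', 'il2'
    observed: str = "paired"      # paired | tra_only | markers_only | mixed
    artifact: str = ""            # '', 'cdr3_error', 'doublet_dropout', 'doublet'
    partner: str | None = None
    ifng: int | None = None       # explicit burst override
    il2: int | None = None
    tag: str = ""                 # referenced by the tested list
    markers_present: bool = True


@dataclass
class FixturePlan:
    name: str
    conditions: list[str]
    negative_control: str
    cancer_type: str              # melanoma -> IL-2 may coexpress with IFN-γ
    clonotypes: dict[str, PlannedClonotype] = field(default_factory=dict)
    cells: list[PlannedCell] = field(default_factory=list)
    tested: list[tuple[str, str]] = field(default_factory=list)  # (condition, tag/cid)
    background_cids: list[str] = field(default_factory=list)

    def add_clonotype(self, cid: str, **kw) -> str:
        self.clonotypes[cid] = PlannedClonotype(cid=cid, **kw)
        return cid

    def add_cells(self, cid: str, condition: str, n_respond: int = 0,
                  n_quiet: int = 0) -> None:
        for _ in range(n_respond):
            self.cells.append(PlannedCell(condition=condition, cid=cid,
                                          response="ifng"))
        for _ in range(n_quiet):
            self.cells.append(PlannedCell(condition=condition, cid=cid))

    def add_hidden_responders(self, cid: str, condition: str, n: int,
                              observed: str = "markers_only",
                              partner: str | None = None) -> None:
        """Responding cells whose own TCR is not cleanly observable."""
        for _ in range(n):
            self.cells.append(PlannedCell(
                condition=condition, cid=cid, response="ifng",
                observed=observed, partner=partner,
                artifact="doublet" if observed == "mixed" else "",
            ))

    def add_artifact(self, condition: str, source_cid: str, mode: str,
                     tag: str, partner: str | None = None, tested: bool = False,
                     ifng: int | None = None) -> None:
        """An activated barcode whose observed receptor is an artifact."""
        self.cells.append(PlannedCell(
            condition=condition, cid=source_cid, response="ifng",
            artifact=mode, partner=partner, tag=tag, ifng=ifng,
        ))
        if tested:
            self.tested.append((condition, tag))

    def mark_tested(self, condition: str, cid: str) -> None:
        self.tested.append((condition, cid))


def _background_sizes(rng: np.random.Generator, total: int,
                      max_size: int = 90) -> list[int]:
    """Clonotype sizes ≥2 drawn zipf-like, summing exactly to ``total``."""
    sizes: list[int] = []
    remaining = total
    while remaining > 0:
        s = int(min(rng.zipf(2.0) + 1, max_size, remaining))
        if remaining - s == 1:
            s = s + 1 if s < max_size else s - 1
        sizes.append(s)
        remaining -= s
    return sizes


def _add_background(plan: FixturePlan, rng: np.random.Generator,
                    total_retained: int, n_singletons: int) -> None:
    """Quiet polyclonal infiltrate: ``total_retained`` cells in clonotypes of
    size ≥2 (kept by singleton removal) plus once-detected clonotypes."""
    sizes = _background_sizes(rng, total_retained)
    conds = plan.conditions
    for i, s in enumerate(sizes):
        cid = f"{plan.name}_bg{i:04d}"
        plan.add_clonotype(cid, lineage=str(rng.choice(["CD4", "CD8"])),
                           n_alpha=int(1 + (rng.random() < 1 / 3)))
        plan.background_cids.append(cid)
        split = rng.multinomial(s, np.full(len(conds), 1 / len(conds)))
        for cond, k in zip(conds, split):
            plan.add_cells(cid, cond, n_quiet=int(k))
    for i in range(n_singletons):
        cid = f"{plan.name}_sg{i:03d}"
        plan.add_clonotype(cid, lineage=str(rng.choice(["CD4", "CD8"])))
        plan.add_cells(cid, str(rng.choice(conds)), n_quiet=1)


def _pick_partners(plan: FixturePlan, rng: np.random.Generator,
                   n: int) -> list[str]:
    """Distinct bystander clonotypes for doublet-dropout artifacts."""
    pool = list(plan.background_cids)
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in idx]


# ---------------------------------------------------------------------------
# fixture plans


def _plan_m1(rng: np.random.Generator) -> FixturePlan:
    # TMG-screened melanoma specimen: 26 IFN-γ+ cells under the cognate
    # minigene, 6 candidate receptors (2 shared, 4 unique, all validated),
    # top clonotype 15 cells (5 responding) = 0.30% of 5,000 retained cells.
    p = FixturePlan("M1", ["TMG-1", "TMG-2"], "TMG-2", "melanoma")
    reactive = []
    for i, (n_cells, n_resp) in enumerate(
            [(15, 5), (8, 4), (2, 1), (2, 1), (2, 1), (2, 1)], start=1):
        cid = p.add_clonotype(f"M1_R{i}", reactive=True, cognate="TMG-1",
                              n_alpha=2 if i == 1 else 1,
                              lineage="CD8" if i % 2 else "CD4")
        reactive.append(cid)
        if i <= 2:
            p.add_cells(cid, "TMG-1", n_respond=n_resp,
                        n_quiet=n_cells - n_resp)
        else:
            # unique candidates: one activated + one quiet cell split across
            # conditions so the merged count (2) survives singleton removal
            p.add_cells(cid, "TMG-1", n_respond=1)
            p.add_cells(cid, "TMG-2", n_quiet=1)
        p.mark_tested("TMG-1", cid)
    _add_background(p, rng, total_retained=5000 - 31, n_singletons=40)
    # 13 further responders whose TCR failed capture (undetectable or mixed)
    p.add_hidden_responders("M1_R3", "TMG-1", 4, observed="markers_only")
    p.add_hidden_responders("M1_R4", "TMG-1", 3, observed="tra_only")
    p.add_hidden_responders("M1_R5", "TMG-1", 3, observed="markers_only")
    for partner in _pick_partners(p, rng, 3):
        p.add_hidden_responders("M1_R6", "TMG-1", 1, observed="mixed",
                                partner=partner)
    return p


def _plan_m2(rng: np.random.Generator) -> FixturePlan:
    # Peptide-pool melanoma specimen with one autoreactive clonotype that
    # fires in every condition including the DMSO control.  PP-1: 4 shared
    # + 5 unique; PP-6: 5 shared + 7 unique; only shared receptors tested.
    p = FixturePlan("M2", ["PP-1", "PP-2", "PP-6", "DMSO"], "DMSO", "melanoma")
    auto = p.add_clonotype("M2_AUTO", autoreactive=True, n_alpha=2,
                           lineage="CD4")
    for cond, n in [("DMSO", 4), ("PP-1", 6), ("PP-2", 7), ("PP-6", 5)]:
        p.add_cells(auto, cond, n_respond=n)
    for i, (n_resp, n_quiet) in enumerate([(4, 2), (3, 1), (2, 0), (2, 0)],
                                          start=1):
        cid = p.add_clonotype(f"M2_S1-{i}", reactive=True, cognate="PP-1")
        p.add_cells(cid, "PP-1", n_respond=n_resp, n_quiet=n_quiet)
        p.mark_tested("PP-1", cid)
    # nearly identical pair: S6-1b's β differs by two amino acids, its α by
    # one silent nucleotide — distinct clonotypes under nt identity
    s61a = p.add_clonotype("M2_S6-1a", reactive=True, cognate="PP-6",
                           n_alpha=1)
    s61b = p.add_clonotype("M2_S6-1b", reactive=True, cognate="PP-6",
                           pair_of=s61a)
    p.add_cells(s61a, "PP-6", n_respond=5)
    p.add_cells(s61b, "PP-6", n_respond=3)
    p.mark_tested("PP-6", s61a)
    p.mark_tested("PP-6", s61b)
    for i in (2, 3, 4):
        cid = p.add_clonotype(f"M2_S6-{i}", reactive=True, cognate="PP-6")
        p.add_cells(cid, "PP-6", n_respond=2)
        p.mark_tested("PP-6", cid)
    _add_background(p, rng, total_retained=1100, n_singletons=20)
    partners = _pick_partners(p, rng, 5)
    for k in range(3):
        p.add_artifact("PP-1", "M2_S1-1", "cdr3_error", tag=f"M2_u1_{k}")
    for k, partner in enumerate(partners[:2]):
        p.add_artifact("PP-1", "M2_S1-2", "doublet_dropout",
                       tag=f"M2_u1d_{k}", partner=partner)
    for k in range(4):
        p.add_artifact("PP-6", "M2_S6-1a", "cdr3_error", tag=f"M2_u6_{k}")
    for k, partner in enumerate(partners[2:]):
        p.add_artifact("PP-6", "M2_S6-2", "doublet_dropout",
                       tag=f"M2_u6d_{k}", partner=partner)
    p.add_hidden_responders(auto, "PP-2", 2, observed="markers_only")
    return p


def _plan_m3(rng: np.random.Generator) -> FixturePlan:
    # PP-1: 3 shared + 5 unique, all eight tested; one unique is real.
    p = FixturePlan("M3", ["PP-1", "DMSO"], "DMSO", "melanoma")
    for i, n_resp in enumerate([3, 2, 2], start=1):
        cid = p.add_clonotype(f"M3_S{i}", reactive=True, cognate="PP-1")
        p.add_cells(cid, "PP-1", n_respond=n_resp)
        p.mark_tested("PP-1", cid)
    u4 = p.add_clonotype("M3_U4", reactive=True, cognate="PP-1", n_alpha=2)
    p.add_cells(u4, "PP-1", n_respond=1, n_quiet=1)
    p.mark_tested("PP-1", u4)
    _add_background(p, rng, total_retained=900, n_singletons=15)
    for k in range(2):
        p.add_artifact("PP-1", "M3_S1", "cdr3_error", tag=f"M3_u{k}",
                       tested=True)
    for k, partner in enumerate(_pick_partners(p, rng, 2)):
        p.add_artifact("PP-1", "M3_S2", "doublet_dropout", tag=f"M3_ud{k}",
                       partner=partner, tested=True)
    return p


def _plan_cc1(rng: np.random.Generator) -> FixturePlan:
    # Unscreened colorectal specimen, three pools at once.  PP-2: 17 IFN-γ+
    # cells (2 shared + 11 unique) and one IL-2-only cell; PP-3: 37 IFN-γ+
    # cells (2 shared + 25 unique).  All four shared plus the top seven
    # unique candidates (by IFN-γ) were tested; two uniques are real.
    p = FixturePlan("CC1", ["PP-1", "PP-2", "PP-3", "DMSO"], "DMSO",
                    "colorectal")
    for cond, i, n_resp in [("PP-2", 1, 3), ("PP-2", 2, 2),
                            ("PP-3", 1, 4), ("PP-3", 2, 3)]:
        cid = p.add_clonotype(f"CC1_{cond}_S{i}", reactive=True, cognate=cond,
                              n_alpha=2 if n_resp >= 3 else 1)
        p.add_cells(cid, cond, n_respond=n_resp)
        p.mark_tested(cond, cid)
    u23 = p.add_clonotype("CC1_U2-3", reactive=True, cognate="PP-2")
    p.add_cells(u23, "PP-2", n_quiet=1)
    p.cells.append(PlannedCell(condition="PP-2", cid=u23, response="ifng",
                               ifng=int(rng.integers(45, 66))))
    p.mark_tested("PP-2", u23)
    u36 = p.add_clonotype("CC1_U3-6", reactive=True, cognate="PP-3")
    p.add_cells(u36, "PP-3", n_quiet=1)
    p.cells.append(PlannedCell(condition="PP-3", cid=u36, response="ifng",
                               ifng=int(rng.integers(45, 66))))
    p.mark_tested("PP-3", u36)
    _add_background(p, rng, total_retained=1200, n_singletons=25)
    partners = _pick_partners(p, rng, 4)
    # tested artifact uniques ride high IFN-γ so the top-7 rule selects them
    for k in range(2):
        p.add_artifact("PP-2", "CC1_PP-2_S1", "cdr3_error", tag=f"CC1_t2_{k}",
                       tested=True, ifng=int(rng.integers(45, 66)))
    p.add_artifact("PP-2", "CC1_PP-2_S2", "doublet_dropout", tag="CC1_t2d",
                   partner=partners[0], tested=True,
                   ifng=int(rng.integers(45, 66)))
    for k in range(1):
        p.add_artifact("PP-3", "CC1_PP-3_S1", "cdr3_error", tag=f"CC1_t3_{k}",
                       tested=True, ifng=int(rng.integers(45, 66)))
    p.add_artifact("PP-3", "CC1_PP-3_S2", "doublet_dropout", tag="CC1_t3d",
                   partner=partners[1], tested=True,
                   ifng=int(rng.integers(45, 66)))
    # untested artifact uniques (lower IFN-γ): 7 in PP-2, 22 in PP-3
    for k in range(7):
        p.add_artifact("PP-2", "CC1_PP-2_S1", "cdr3_error", tag=f"CC1_x2_{k}",
                       ifng=int(rng.integers(8, 21)))
    for k in range(20):
        p.add_artifact("PP-3", "CC1_PP-3_S1", "cdr3_error", tag=f"CC1_x3_{k}",
                       ifng=int(rng.integers(8, 21)))
    for k, partner in enumerate(partners[2:]):
        p.add_artifact("PP-3", "CC1_PP-3_S2", "doublet_dropout",
                       tag=f"CC1_x3d_{k}", partner=partner,
                       ifng=int(rng.integers(8, 21)))
    # capture failures: 1 in PP-2 (17 = 16 paired + 1), 5 in PP-3 (37 = 32+5)
    p.add_hidden_responders("CC1_PP-2_S1", "PP-2", 1, observed="markers_only")
    p.add_hidden_responders("CC1_PP-3_S1", "PP-3", 3, observed="markers_only")
    p.add_hidden_responders("CC1_PP-3_S2", "PP-3", 1, observed="tra_only")
    p.add_hidden_responders("CC1_PP-3_S2", "PP-3", 1, observed="mixed",
                            partner=_pick_partners(p, rng, 1)[0])
    # the one IL-2-only activated cell (undetectable TCR)
    p.cells.append(PlannedCell(condition="PP-2", cid="CC1_PP-2_S2",
                               response="il2", observed="markers_only",
                               il2=40))
    return p


def _plan_cc2(rng: np.random.Generator) -> FixturePlan:
    # One shared receptor plus four tested uniques; the reactive unique is a
    # true singleton, so its merged frequency is not calculable.
    p = FixturePlan("CC2", ["PP-2", "DMSO"], "DMSO", "colorectal")
    c1 = p.add_clonotype("CC2_S1", reactive=True, cognate="PP-2", n_alpha=2)
    p.add_cells(c1, "PP-2", n_respond=2, n_quiet=1)
    p.mark_tested("PP-2", c1)
    v1 = p.add_clonotype("CC2_U2-2", reactive=True, cognate="PP-2")
    p.add_cells(v1, "PP-2", n_respond=1)
    p.mark_tested("PP-2", v1)
    _add_background(p, rng, total_retained=800, n_singletons=15)
    for k in range(2):
        p.add_artifact("PP-2", "CC2_S1", "cdr3_error", tag=f"CC2_u{k}",
                       tested=True)
    p.add_artifact("PP-2", "CC2_S1", "doublet_dropout", tag="CC2_ud",
                   partner=_pick_partners(p, rng, 1)[0], tested=True)
    return p


def _plan_cc3(rng: np.random.Generator) -> FixturePlan:
    # No shared receptor; three tested uniques, one of them a real singleton.
    p = FixturePlan("CC3", ["PP-2", "DMSO"], "DMSO", "colorectal")
    w1 = p.add_clonotype("CC3_U2-2", reactive=True, cognate="PP-2")
    p.add_cells(w1, "PP-2", n_respond=1)
    p.mark_tested("PP-2", w1)
    _add_background(p, rng, total_retained=700, n_singletons=12)
    p.add_artifact("PP-2", "CC3_U2-2", "cdr3_error", tag="CC3_u0",
                   tested=True)
    p.add_artifact("PP-2", "CC3_U2-2", "doublet_dropout", tag="CC3_ud",
                   partner=_pick_partners(p, rng, 1)[0], tested=True)
    return p


_PLANNERS = {"M1": _plan_m1, "M2": _plan_m2, "M3": _plan_m3,
             "CC1": _plan_cc1, "CC2": _plan_cc2, "CC3": _plan_cc3}


# ---------------------------------------------------------------------------
# rendering


def _assign_sequences(plan: FixturePlan, rng: np.random.Generator) -> None:
    used: set[str] = set()

    def fresh_cdr3() -> str:
        while True:
            s = random_cdr3_nt(rng, int(rng.integers(10, 16)))
            if s not in used:
                used.add(s)
                return s

    for c in plan.clonotypes.values():
        if c.pair_of:
            base = plan.clonotypes[c.pair_of]
            c.cdr3b_nt = _substitute_aa(rng, base.cdr3b_nt, n_sub=2, used=used)
            c.v_gene, c.j_gene = base.v_gene, base.j_gene
            c.alphas = [AlphaChain(base.alphas[0].v_gene,
                                   base.alphas[0].j_gene,
                                   _silent_variant(rng, base.alphas[0].cdr3_nt))]
        else:
            c.cdr3b_nt = fresh_cdr3()
            c.v_gene = str(rng.choice(TRBV_GENES))
            c.j_gene = str(rng.choice(TRBJ_GENES))
            c.alphas = [
                AlphaChain(str(rng.choice(TRAV_GENES)),
                           str(rng.choice(TRAJ_GENES)), fresh_cdr3())
                for _ in range(c.n_alpha)
            ]
    plan._used_keys = used  # shared with artifact-key generation


def _substitute_aa(rng: np.random.Generator, nt: str, n_sub: int,
                   used: set[str]) -> str:
    """Replace ``n_sub`` internal codons with different-amino-acid codons."""
    while True:
        codons = [nt[i:i + 3] for i in range(0, len(nt), 3)]
        pos = rng.choice(range(1, len(codons) - 1), size=n_sub, replace=False)
        for i in pos:
            old_aa = translate_cdr3(codons[i])
            choices = [c for c in CODONS if translate_cdr3(c) != old_aa]
            codons[i] = choices[int(rng.integers(len(choices)))]
        out = "".join(codons)
        if out not in used:
            used.add(out)
            return out


def _silent_variant(rng: np.random.Generator, nt: str) -> str:
    """Single synonymous nucleotide change (same protein, new nt key)."""
    codons = [nt[i:i + 3] for i in range(0, len(nt), 3)]
    order = rng.permutation(len(codons))
    for i in order:
        aa = translate_cdr3(codons[i])
        syn = [c for c in CODONS if translate_cdr3(c) == aa and c != codons[i]]
        if syn:
            codons[int(i)] = syn[int(rng.integers(len(syn)))]
            return "".join(codons)
    raise RuntimeError("no synonymous variant possible")  # pragma: no cover


def _error_key(rng: np.random.Generator, nt: str, used: set[str]) -> str:
    """One substitution that keeps the junction stop-free and yields a new key."""
    while True:
        i = int(rng.integers(len(nt)))
        new = str(rng.choice(NT[NT != nt[i]]))
        out = nt[:i] + new + nt[i + 1:]
        if "*" not in translate_cdr3(out) and out not in used:
            used.add(out)
            return out


def render_fixture(plan: FixturePlan, rng: np.random.Generator,
                   out_dir: Path) -> None:
    _assign_sequences(plan, rng)
    used_keys: set[str] = plan._used_keys
    model = ActivationModel()
    il2_coexpr = 0.5 if plan.cancer_type == "melanoma" else 0.0

    cells_by_cond: dict[str, list[PlannedCell]] = {c: [] for c in plan.conditions}
    for cell in plan.cells:
        cells_by_cond[cell.condition].append(cell)

    tag_to_key: dict[tuple[str, str], str] = {}
    truth_rows = []
    for cond in plan.conditions:
        cells = cells_by_cond[cond]
        barcodes = random_barcodes(rng, len(cells))
        contig_rows = []
        marker_index, marker_data = [], []
        for bc, cell in zip(barcodes, cells):
            clono = plan.clonotypes[cell.cid]
            partner = plan.clonotypes[cell.partner] if cell.partner else None
            observed_key = ""
            k = 0

            def emit(chain, v, j, nt):
                nonlocal k
                umis = 2 + int(rng.poisson(4)) if chain == "TRB" \
                    else 1 + int(rng.poisson(2))
                contig_rows.append({
                    "barcode": bc, "is_cell": "True",
                    "contig_id": f"{bc}_contig_{k}", "chain": chain,
                    "v_gene": v, "j_gene": j, "cdr3": translate_cdr3(nt),
                    "cdr3_nt": nt, "umis": umis, "productive": "True",
                })
                k += 1

            vdj_observed = "paired"
            if cell.artifact == "cdr3_error":
                observed_key = _error_key(rng, clono.cdr3b_nt, used_keys)
                emit("TRB", clono.v_gene, clono.j_gene, observed_key)
                for a in clono.alphas:
                    emit("TRA", a.v_gene, a.j_gene, a.cdr3_nt)
            elif cell.artifact == "doublet_dropout":
                observed_key = partner.cdr3b_nt
                emit("TRB", partner.v_gene, partner.j_gene, partner.cdr3b_nt)
                for a in partner.alphas:
                    emit("TRA", a.v_gene, a.j_gene, a.cdr3_nt)
            elif cell.observed == "paired":
                observed_key = clono.cdr3b_nt
                emit("TRB", clono.v_gene, clono.j_gene, clono.cdr3b_nt)
                for a in clono.alphas:
                    emit("TRA", a.v_gene, a.j_gene, a.cdr3_nt)
            elif cell.observed == "tra_only":
                vdj_observed = "undetectable"
                a = clono.alphas[0]
                emit("TRA", a.v_gene, a.j_gene, a.cdr3_nt)
            elif cell.observed == "markers_only":
                vdj_observed = "undetectable"
            elif cell.observed == "mixed":
                vdj_observed = "mixed"
                emit("TRB", clono.v_gene, clono.j_gene, clono.cdr3b_nt)
                for a in clono.alphas:
                    emit("TRA", a.v_gene, a.j_gene, a.cdr3_nt)
                emit("TRB", partner.v_gene, partner.j_gene, partner.cdr3b_nt)
                for a in partner.alphas:
                    emit("TRA", a.v_gene, a.j_gene, a.cdr3_nt)

            counts = {f: int(rng.poisson(AMBIENT_RATE)) for f in MARKERS}
            lineages = [clono.lineage] + ([partner.lineage] if partner else [])
            for lin in lineages:
                if lin == "CD4":
                    counts["CD4"] += int(rng.poisson(4))
                else:
                    counts["CD8A"] += int(rng.poisson(2))
                    counts["CD8B"] += int(rng.poisson(2))
            if cell.response == "ifng":
                counts["IFNG"] += (cell.ifng if cell.ifng is not None
                                   else int(draw_responder_ifng(rng, model)[0]))
                if cell.il2 is not None:
                    counts["IL2"] += cell.il2
                elif rng.random() < il2_coexpr:
                    counts["IL2"] += int(draw_responder_il2(rng, model)[0])
            elif cell.response == "il2":
                counts["IL2"] += cell.il2 if cell.il2 is not None else 40
            if cell.markers_present:
                marker_index.append(bc)
                marker_data.append([counts[f] for f in MARKERS])

            if cell.tag:
                tag_to_key[(cond, cell.tag)] = observed_key
            clono_ids = cell.cid + (f";{cell.partner}" if cell.partner else "")
            truth_rows.append({
                "barcode": bc, "condition": cond, "clonotype_ids": clono_ids,
                "response": cell.response, "vdj_observed": vdj_observed,
                "artifact": cell.artifact, "observed_key": observed_key,
            })

        cond_dir = out_dir / cond
        cond_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(contig_rows, columns=CONTIG_COLUMNS).to_csv(
            cond_dir / "contigs.csv", index=False, lineterminator="\n")
        counts_df = pd.DataFrame(marker_data, index=pd.Index(marker_index,
                                                             name="barcode"),
                                 columns=list(MARKERS))
        write_marker_matrix(counts_df, cond_dir / "markers")

    _write_truth(plan, tag_to_key, truth_rows, out_dir)
    _write_config(plan, out_dir)


def _write_truth(plan: FixturePlan, tag_to_key, truth_rows, out_dir: Path):
    truth_dir = out_dir / "truth"
    truth_dir.mkdir(parents=True, exist_ok=True)
    clono_rows = [{
        "cid": c.cid, "cdr3b_nt": c.cdr3b_nt, "cdr3b_aa": translate_cdr3(c.cdr3b_nt),
        "v_gene": c.v_gene, "j_gene": c.j_gene, "lineage": c.lineage,
        "n_alpha": len(c.alphas),
        "alpha_cdr3_nts": ";".join(a.cdr3_nt for a in c.alphas),
        "reactive": c.reactive, "autoreactive": c.autoreactive,
        "cognate_condition": c.cognate,
    } for c in plan.clonotypes.values()]
    pd.DataFrame(clono_rows).to_csv(truth_dir / "clonotypes.tsv", sep="\t",
                                    index=False, lineterminator="\n")
    pd.DataFrame(truth_rows).to_csv(truth_dir / "barcodes.tsv", sep="\t",
                                    index=False, lineterminator="\n")
    tested_rows = []
    for cond, ref in plan.tested:
        if (cond, ref) in tag_to_key:
            key = tag_to_key[(cond, ref)]
        else:
            key = plan.clonotypes[ref].cdr3b_nt
        tested_rows.append({"condition": cond, "cdr3b_nt": key, "ref": ref})
    pd.DataFrame(tested_rows, columns=["condition", "cdr3b_nt", "ref"]).to_csv(
        truth_dir / "tested.tsv", sep="\t", index=False, lineterminator="\n")


def _write_config(plan: FixturePlan, out_dir: Path):
    cfg = {
        "name": plan.name,
        "negative_control": plan.negative_control,
        "cancer_type": plan.cancer_type,
        "thresholds": {"ifng_min": 5, "il2_min": 5, "lineage_min": 2},
        "conditions": [
            {"label": c, "contigs": f"{c}/contigs.csv", "markers": f"{c}/markers"}
            for c in plan.conditions
        ],
        "truth": "truth",
    }
    (out_dir / "config.yaml").write_text(
        yaml.safe_dump(cfg, sort_keys=False), encoding="utf-8")


def make_fixture(name: str, out_dir: str | Path,
                 seed: int | None = None) -> Path:
    """Render one named fixture into ``out_dir`` and return its path.

    Without an explicit seed the documented per-fixture seed is used, which
    pins the exact byte content; the planted counts themselves are
    seed-invariant by construction.
    """
    if name not in _PLANNERS:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    if seed is None:
        seed = FIXTURE_SEEDS[name]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    plan = _PLANNERS[name](rng)
    render_fixture(plan, rng, out_dir)
    return out_dir
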