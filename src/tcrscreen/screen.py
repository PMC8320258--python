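"""The activation screen: join markers to clonotyped cells and call candidates.

Per stimulation condition, barcodes whose IFN-γ or IL-2 counts clear the
activation thresholds are matched to their V(D)J cells by barcode.  Any
clonotype that also activates in the unstimulated negative control is
autoreactive and removed everywhere.  Each remaining clonotype with at least
one activated, cleanly paired cell becomes a candidate receptor, classified
*shared* (≥2 activated cells) or *unique* (exactly one) and ranked.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import pandas as pd

from tcrscreen.markers import ActivationThresholds, MarkerProfile, activation_call, lineage_call
from tcrscreen.vdj import CellVDJ

logger = logging.getLogger(__name__)


@dataclass
class ActivatedCell:
    """One barcode passing the activation call in one condition."""

    barcode: str
    condition: str
    ifng: int
    il2: int
    lineage: str
    clonotype_key: str | None
    vdj_status: str  # paired / undetectable / mixed

    @property
    def il2_only(self) -> bool:
        return self.il2 > 0 and self.ifng == 0


@dataclass
class JoinLog:
    """Exclusion bookkeeping for one condition's marker/VDJ join."""

    condition: str
    n_activated: int = 0
    n_ifng_pos: int = 0
    n_il2_only: int = 0
    n_mixed: int = 0
    n_undetectable: int = 0
    n_marker_only: int = 0
    n_contig_only: int = 0


@dataclass
class CandidateTCR:
    """A paired αβ receptor proposed from activated cells of one condition."""

    clonotype_key: str
    condition: str
    beta: tuple[str, str, str, str]             # (v, j, cdr3_nt, cdr3_aa)
    alphas: list[tuple[str, str, str, str]]     # one or two chains
    support: int
    ifng_total: int
    il2_total: int
    klass: str = ""
    rank: int = 0

    def __post_init__(self):
        if not self.klass:
            self.klass = "shared" if self.support >= 2 else "unique"


@dataclass
class ScreenResult:
    """Outcome of the screen over all conditions of one specimen."""

    activated: dict[str, list[ActivatedCell]]
    candidates: list[CandidateTCR]
    removed_autoreactive: list[str]
    logs: dict[str, JoinLog] = field(default_factory=dict)


def join_condition(cells: list[CellVDJ], profiles: list[MarkerProfile],
                   thresholds: ActivationThresholds, condition: str,
                   ) -> tuple[list[ActivatedCell], JoinLog]:
    """Return the activated cells of one condition, annotated with their VDJ.

    Exactly the barcodes with a positive IFN-γ or IL-2 call are returned.
    Marker-positive barcodes with no contig record are kept as
    ``undetectable`` (they are real activated cells whose TCR failed
    capture); contig-only barcodes have no marker evidence and are dropped
    from the activated set.  Both are counted in the log.
    """
    cell_by_bc = {c.barcode: c for c in cells}
    profile_bcs = {p.barcode for p in profiles}
    log = JoinLog(condition=condition)
    log.n_contig_only = sum(1 for b in cell_by_bc if b not in profile_bcs)
    out: list[ActivatedCell] = []
    for p in sorted(profiles, key=lambda p: p.barcode):
        ifng_pos, il2_pos = activation_call(p, thresholds)
        if not (ifng_pos or il2_pos):
            continue
        cell = cell_by_bc.get(p.barcode)
        if cell is None:
            status, key = "undetectable", None
            log.n_marker_only += 1
        else:
            status, key = cell.status, cell.beta_key
        ac = ActivatedCell(
            barcode=p.barcode, condition=condition, ifng=p.ifng, il2=p.il2,
            lineage=lineage_call(p, thresholds),
            clonotype_key=key, vdj_status=status,
        )
        out.append(ac)
        log.n_activated += 1
        log.n_ifng_pos += int(ifng_pos)
        log.n_il2_only += int(il2_pos and not ifng_pos)
        log.n_mixed += int(status == "mixed")
        log.n_undetectable += int(status == "undetectable")
    logger.info(
        "%s: %d activated (%d IFN-g+, %d IL-2 only; %d mixed, %d undetectable)",
        condition, log.n_activated, log.n_ifng_pos, log.n_il2_only,
        log.n_mixed, log.n_undetectable,
    )
    return out, log


def remove_autoreactive(activated: dict[str, list[ActivatedCell]],
                        negative_control: str | None,
                        ) -> set[str]:
    """Clonotype keys activated in the negative control (to be excluded).

    Removal is clonotype-level: one activated cell in the unstimulated
    control disqualifies the whole clonotype in every condition.  Without a
    negative-control condition nothing is removed (warning logged).
    """
    if negative_control is None or negative_control not in activated:
        logger.warning("no negative-control condition; autoreactive removal skipped")
        return set()
    removed = {
        ac.clonotype_key
        for ac in activated[negative_control]
        if ac.clonotype_key is not None
    }
    if removed:
        logger.info("removed %d autoreactive clonotype(s)", len(removed))
    return removed


def extract_candidates(activated: list[ActivatedCell], cells: list[CellVDJ],
                       condition: str, exclude_keys: set[str] = frozenset(),
                       ) -> list[CandidateTCR]:
    """One candidate per clonotype with ≥1 activated paired cell.

    Support counts distinct activated paired cells of the clonotype in this
    condition; α chains are the up-to-two most-supported variants among
    those cells (count of carrying cells, then total UMIs, then sequence).
    Mixed and undetectable activated cells can never seed a candidate.
    """
    cell_by_bc = {c.barcode: c for c in cells}
    per_key: dict[str, list[ActivatedCell]] = defaultdict(list)
    for ac in activated:
        if ac.condition != condition or ac.vdj_status != "paired":
            continue
        if ac.clonotype_key is None or ac.clonotype_key in exclude_keys:
            continue
        per_key[ac.clonotype_key].append(ac)
    out = []
    for key in sorted(per_key):
        members = per_key[key]
        alpha_cells: Counter = Counter()
        alpha_umis: Counter = Counter()
        beta = None
        best_umis = -1
        for ac in members:
            cell = cell_by_bc[ac.barcode]
            b = cell.beta_contigs[0]
            if b.umis > best_umis:
                best_umis = b.umis
                beta = (b.v_gene, b.j_gene, b.cdr3_nt, b.cdr3_aa)
            for a in cell.alpha_contigs:
                var = (a.v_gene, a.j_gene, a.cdr3_nt, a.cdr3_aa)
                alpha_cells[var] += 1
                alpha_umis[var] += a.umis
        ranked_alphas = sorted(
            alpha_cells,
            key=lambda v: (-alpha_cells[v], -alpha_umis[v], v[2]),
        )[:2]
        out.append(CandidateTCR(
            clonotype_key=key, condition=condition, beta=beta,
            alphas=ranked_alphas, support=len(members),
            ifng_total=sum(ac.ifng for ac in members),
            il2_total=sum(ac.il2 for ac in members),
        ))
    return out


def rank_candidates(candidates: list[CandidateTCR]) -> list[CandidateTCR]:
    """Total order: shared before unique; then support, summed IFN-γ, key."""
    ordered = sorted(
        candidates,
        key=lambda c: (c.klass != "shared", -c.support, -c.ifng_total,
                       c.clonotype_key),
    )
    for i, c in enumerate(ordered, start=1):
        c.rank = i
    return ordered


def run_screen(cells_by_condition: dict[str, list[CellVDJ]],
               profiles_by_condition: dict[str, list[MarkerProfile]],
               thresholds: ActivationThresholds,
               negative_control: str | None) -> ScreenResult:
    """Join, autoreactive removal, candidate extraction and ranking."""
    activated: dict[str, list[ActivatedCell]] = {}
    logs: dict[str, JoinLog] = {}
    for cond in cells_by_condition:
        activated[cond], logs[cond] = join_condition(
            cells_by_condition[cond], profiles_by_condition[cond],
            thresholds, cond,
        )
    removed = remove_autoreactive(activated, negative_control)
    candidates: list[CandidateTCR] = []
    for cond in cells_by_condition:
        if cond == negative_control:
            continue
        candidates.extend(extract_candidates(
            activated[cond], cells_by_condition[cond], cond, removed,
        ))
    return ScreenResult(
        activated=activated,
        candidates=rank_candidates(candidates),
        removed_autoreactive=sorted(removed),
        logs=logs,
    )


def activated_to_frame(activated: dict[str, list[ActivatedCell]]) -> pd.DataFrame:
    rows = [{
        "condition": ac.condition, "barcode": ac.barcode, "ifng": ac.ifng,
        "il2": ac.il2, "lineage": ac.lineage,
        "clonotype_key": ac.clonotype_key or "",
        "vdj_status": ac.vdj_status,
    } for cond in sorted(activated) for ac in activated[cond]]
    return pd.DataFrame(rows, columns=[
        "condition", "barcode", "ifng", "il2", "lineage",
        "clonotype_key", "vdj_status",
    ])


def candidates_to_frame(candidates: list[CandidateTCR]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        a1 = c.alphas[0] if c.alphas else ("", "", "", "")
        a2 = c.alphas[1] if len(c.alphas) > 1 else ("", "", "", "")
        rows.append({
            "rank": c.rank, "condition": c.condition, "klass": c.klass,
            "support": c.support,
            "beta_v": c.beta[0], "beta_j": c.beta[1],
            "beta_cdr3_nt": c.beta[2], "beta_cdr3_aa": c.beta[3],
            "alpha1_v": a1[0], "alpha1_j": a1[1],
            "alpha1_cdr3_nt": a1[2], "alpha1_cdr3_aa": a1[3],
            "alpha2_v": a2[0], "alpha2_j": a2[1],
            "alpha2_cdr3_nt": a2[2], "alpha2_cdr3_aa": a2[3],
            "ifng_total": c.ifng_total, "il2_total": c.il2_total,
        })
    return pd.DataFrame(rows, columns=[
        "rank", "condition", "klass", "support",
        "beta_v", "beta_j", "beta_cdr3_nt", "beta_cdr3_aa",
        "alpha1_v", "alpha1_j", "alpha1_cdr3_nt", "alpha1_cdr3_aa",
        "alpha2_v", "alpha2_j", "alpha2_cdr3_nt", "alpha2_cdr3_aa",
        "ifng_total", "il2_total",
    ])
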