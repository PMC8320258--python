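"""Seeded droplet simulator for stimulated T-cell specimens.

Emulates what the analysis consumes per stimulation condition: a V(D)J
contig annotation table and a five-marker UMI matrix over droplet barcodes,
plus a ground-truth table.  The generative model is a clonotype repertoire
with a configurable frequency law (tumor infiltrates are highly diverse,
with very few cells per clonotype), dual-α cells (up to about one third of
mature T cells carry two functional α chains), doublets (two whole cells
merged into one barcode), per-nucleotide CDR3 sequencing errors (the origin
of singleton artifact clonotypes), Poisson ambient marker background, and a
negative-binomial burst of IFN-γ (optionally IL-2) in the responding
fraction of reactive clonotypes.  Autoreactive clonotypes respond in every
condition, including the unstimulated control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from tcrscreen.vdj import CONTIG_COLUMNS, translate_cdr3

NT = np.array(list("ACGT"))

#: the 61 sense codons (stop codons excluded so junctions stay productive)
CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]

TRBV_GENES = [f"TRBV{i}" for i in (2, 4, 5, 6, 7, 9, 11, 12, 19, 20, 27, 28, 30)]
TRBJ_GENES = [f"TRBJ{i}-{j}" for i in (1, 2) for j in (1, 2, 3, 5)]
TRAV_GENES = [f"TRAV{i}" for i in (1, 3, 8, 12, 13, 17, 21, 22, 26, 27, 29, 35, 38)]
TRAJ_GENES = [f"TRAJ{i}" for i in (4, 6, 9, 13, 20, 23, 28, 31, 37, 42, 45, 49)]

#: responders never fall below this IFN-γ UMI count (left-truncated burst)
RESPONDER_IFNG_FLOOR = 10
RESPONDER_IL2_FLOOR = 5


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class RepertoireSpec:
    """Parameters of a simulated clonotype repertoire."""

    n_clonotypes: int
    frequency_law: str = "power_law"   # or "log_normal"
    shape: float = 1.5                 # power-law exponent / log-normal sigma
    dual_alpha_fraction: float = 1 / 3
    cdr3b_length_range: tuple[int, int] = (30, 45)   # nt, multiples of 3
    seed: int = 0

    def __post_init__(self):
        if self.n_clonotypes < 1:
            raise ConfigurationError("n_clonotypes must be >= 1")
        if self.frequency_law not in ("power_law", "log_normal"):
            raise ConfigurationError(f"unknown frequency law {self.frequency_law!r}")
        if self.shape <= 0:
            raise ConfigurationError("shape parameter must be positive")
        if not 0 <= self.dual_alpha_fraction <= 1:
            raise ConfigurationError("dual_alpha_fraction must be in [0, 1]")
        lo, hi = self.cdr3b_length_range
        if lo % 3 or hi % 3 or lo < 9 or hi < lo:
            raise ConfigurationError("cdr3b_length_range must be in-frame nt lengths")


@dataclass(frozen=True)
class DropletParams:
    """Chip loading and droplet noise parameters."""

    n_cells_loaded: int = 10_000
    target_recovery: int = 6_000
    doublet_rate: float = 0.04
    cdr3_error_rate: float = 5e-4      # per nt per contig
    ambient_marker_rate: float = 0.05  # mean spurious UMIs / marker / barcode
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.doublet_rate < 1:
            raise ConfigurationError("doublet_rate must be in [0, 1)")
        if self.target_recovery > self.n_cells_loaded:
            raise ConfigurationError("target_recovery exceeds n_cells_loaded")


@dataclass(frozen=True)
class ActivationModel:
    """Which clonotypes respond in a condition, and how strongly."""

    reactive_clonotype_ids: frozenset = frozenset()
    responder_fraction: float = 1 / 3
    ifng_high_mean: float = 50.0
    ifng_dispersion: float = 2.0
    ifng_background_mean: float = 0.0
    il2_coexpression_prob: float = 0.5
    il2_high_mean: float = 30.0
    autoreactive_clonotype_ids: frozenset = frozenset()

    def __post_init__(self):
        if self.ifng_high_mean <= self.ifng_background_mean:
            raise ConfigurationError("ifng_high_mean must exceed background")


@dataclass
class AlphaChain:
    v_gene: str
    j_gene: str
    cdr3_nt: str

    @property
    def cdr3_aa(self) -> str:
        return translate_cdr3(self.cdr3_nt)


@dataclass
class SimClonotype:
    cid: int | str
    cdr3b_nt: str
    v_gene: str
    j_gene: str
    alphas: list[AlphaChain]
    frequency: float = 0.0
    lineage: str = "CD8"

    @property
    def cdr3b_aa(self) -> str:
        return translate_cdr3(self.cdr3b_nt)


@dataclass
class SimulatedCondition:
    """In-memory output of one condition's run."""

    condition: str
    contigs: pd.DataFrame   # contig CSV dialect
    markers: pd.DataFrame   # barcode x (IFNG, IL2, CD4, CD8A, CD8B)
    truth: pd.DataFrame     # barcode, clonotype_ids, response, vdj_observed


def random_cdr3_nt(rng: np.random.Generator, n_codons: int) -> str:
    """In-frame junction: canonical C...F motif, no stop codons."""
    inner = rng.choice(len(CODONS), size=max(n_codons - 2, 0))
    return "TGT" + "".join(CODONS[i] for i in inner) + "TTC"


def mutate_cdr3(rng: np.random.Generator, nt: str, rate: float) -> str:
    """Independent per-nucleotide substitution at the given rate."""
    if rate <= 0:
        return nt
    seq = np.array(list(nt))
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        seq[i] = rng.choice(NT[NT != seq[i]])
    return "".join(seq)


def random_barcodes(rng: np.random.Generator, n: int) -> list[str]:
    """Distinct 16-nt droplet barcodes with the standard ``-1`` suffix."""
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        draw = rng.integers(0, 4, size=(n - len(out), 16))
        for row in draw:
            bc = "".join(NT[row])
            if bc not in seen:
                seen.add(bc)
                out.append(bc + "-1")
    return out


def _frequencies(spec: RepertoireSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_clonotypes
    if spec.frequency_law == "power_law":
        raw = np.arange(1, n + 1, dtype=float) ** (-spec.shape)
    else:
        raw = np.sort(rng.lognormal(mean=0.0, sigma=spec.shape, size=n))[::-1]
    return raw / raw.sum()


def simulate_repertoire(spec: RepertoireSpec) -> list[SimClonotype]:
    """Draw a clonotype repertoire with unique in-frame CDR3β junctions."""
    rng = np.random.default_rng(spec.seed)
    freqs = _frequencies(spec, rng)
    lo, hi = (x // 3 for x in spec.cdr3b_length_range)
    dual = rng.random(spec.n_clonotypes) < spec.dual_alpha_fraction
    lineages = rng.choice(["CD4", "CD8"], size=spec.n_clonotypes)
    seen: set[str] = set()
    out = []
    for i in range(spec.n_clonotypes):
        while True:
            cdr3b = random_cdr3_nt(rng, int(rng.integers(lo, hi + 1)))
            if cdr3b not in seen:
                seen.add(cdr3b)
                break
        alphas = [
            AlphaChain(
                v_gene=str(rng.choice(TRAV_GENES)),
                j_gene=str(rng.choice(TRAJ_GENES)),
                cdr3_nt=random_cdr3_nt(rng, int(rng.integers(lo, hi + 1))),
            )
            for _ in range(2 if dual[i] else 1)
        ]
        out.append(SimClonotype(
            cid=i, cdr3b_nt=cdr3b,
            v_gene=str(rng.choice(TRBV_GENES)), j_gene=str(rng.choice(TRBJ_GENES)),
            alphas=alphas, frequency=float(freqs[i]), lineage=str(lineages[i]),
        ))
    return out


def draw_responder_ifng(rng: np.random.Generator, model: ActivationModel,
                        size: int = 1) -> np.ndarray:
    """Left-truncated negative-binomial IFN-γ burst for responding cells."""
    n = model.ifng_dispersion
    p = n / (n + model.ifng_high_mean)
    return np.maximum(rng.negative_binomial(n, p, size=size),
                      RESPONDER_IFNG_FLOOR)


def draw_responder_il2(rng: np.random.Generator, model: ActivationModel,
                       size: int = 1) -> np.ndarray:
    n = model.ifng_dispersion
    p = n / (n + model.il2_high_mean)
    return np.maximum(rng.negative_binomial(n, p, size=size),
                      RESPONDER_IL2_FLOOR)


def lineage_counts(rng: np.random.Generator, lineage: str) -> dict[str, int]:
    """Own-lineage marker UMIs (Poisson); other-lineage genes stay ambient."""
    if lineage == "CD4":
        return {"CD4": int(rng.poisson(4))}
    return {"CD8A": int(rng.poisson(2)), "CD8B": int(rng.poisson(2))}


def simulate_condition(repertoire: Sequence[SimClonotype],
                       droplet: DropletParams,
                       activation: ActivationModel,
                       condition_label: str,
                       seed: int | None = None) -> SimulatedCondition:
    """Simulate one stimulation condition end to end.

    Emits ``target_recovery`` barcodes.  Doublet barcodes merge the contigs
    and marker counts of two independently drawn cells.  Every contig's
    CDR3 is mutated per-nucleotide at ``cdr3_error_rate``.  Identical
    inputs and seed give byte-identical outputs.
    """
    by_cid = {c.cid: c for c in repertoire}
    for cid in activation.reactive_clonotype_ids | activation.autoreactive_clonotype_ids:
        if cid not in by_cid:
            raise ConfigurationError(f"activation references unknown clonotype {cid!r}")
    rng = np.random.default_rng(droplet.seed if seed is None else seed)
    freqs = np.array([c.frequency for c in repertoire])
    freqs = freqs / freqs.sum()

    n_droplets = droplet.target_recovery
    n_doublets = int(round(n_droplets * droplet.doublet_rate))
    barcodes = random_barcodes(rng, n_droplets)
    doublet_flags = np.zeros(n_droplets, dtype=bool)
    if n_doublets:
        doublet_flags[rng.choice(n_droplets, size=n_doublets, replace=False)] = True

    hot = activation.reactive_clonotype_ids | activation.autoreactive_clonotype_ids
    contig_rows, marker_rows, truth_rows = [], [], []
    for bc, is_doublet in zip(barcodes, doublet_flags):
        cells = [repertoire[i] for i in
                 rng.choice(len(repertoire), size=2 if is_doublet else 1, p=freqs)]
        counts = {f: int(rng.poisson(droplet.ambient_marker_rate))
                  for f in ("IFNG", "IL2", "CD4", "CD8A", "CD8B")}
        if activation.ifng_background_mean > 0:
            counts["IFNG"] += int(rng.poisson(activation.ifng_background_mean))
        responded = False
        observed_beta_keys = set()
        k = 0
        for cell in cells:
            responds = (cell.cid in hot
                        and rng.random() < activation.responder_fraction)
            if responds:
                responded = True
                counts["IFNG"] += int(draw_responder_ifng(rng, activation)[0])
                if rng.random() < activation.il2_coexpression_prob:
                    counts["IL2"] += int(draw_responder_il2(rng, activation)[0])
            for gene, extra in lineage_counts(rng, cell.lineage).items():
                counts[gene] += extra
            beta_nt = mutate_cdr3(rng, cell.cdr3b_nt, droplet.cdr3_error_rate)
            observed_beta_keys.add(beta_nt)
            contig_rows.append(_contig_row(bc, k, "TRB", cell.v_gene, cell.j_gene,
                                           beta_nt, 2 + int(rng.poisson(4))))
            k += 1
            for a in cell.alphas:
                alpha_nt = mutate_cdr3(rng, a.cdr3_nt, droplet.cdr3_error_rate)
                contig_rows.append(_contig_row(bc, k, "TRA", a.v_gene, a.j_gene,
                                               alpha_nt, 1 + int(rng.poisson(2))))
                k += 1
        marker_rows.append({"barcode": bc, **counts})
        truth_rows.append({
            "barcode": bc,
            "condition": condition_label,
            "clonotype_ids": ";".join(str(c.cid) for c in cells),
            "response": "ifng" if responded else "",
            "vdj_observed": "mixed" if len(observed_beta_keys) > 1 else "paired",
            "artifact": "doublet" if is_doublet else "",
        })

    contigs = pd.DataFrame(contig_rows, columns=CONTIG_COLUMNS)
    markers = pd.DataFrame(marker_rows).set_index("barcode")
    truth = pd.DataFrame(truth_rows)
    return SimulatedCondition(condition=condition_label, contigs=contigs,
                              markers=markers, truth=truth)


def _contig_row(bc: str, k: int, chain: str, v: str, j: str,
                cdr3_nt: str, umis: int) -> dict:
    return {
        "barcode": bc, "is_cell": "True", "contig_id": f"{bc}_contig_{k}",
        "chain": chain, "v_gene": v, "j_gene": j,
        "cdr3": translate_cdr3(cdr3_nt), "cdr3_nt": cdr3_nt,
        "umis": umis, "productive": "True",
    }
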