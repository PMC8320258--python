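"""Specimen-level orchestration and evaluation against planted truth.

``run_specimen`` executes the deterministic analysis chain — read contigs →
pair chains → call clonotypes → read markers → activation join →
autoreactive removal → candidate extraction/ranking → merged frequencies —
and writes every intermediate table.  ``evaluate_candidates`` scores a
candidate list against a fixture's planted truth, honoring the planted
tested-subset (all shared candidates were tested; unique candidates only as
listed), and ``summarize_suite`` pools per-specimen summaries into the
headline reliability split of shared versus unique calls.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from tcrscreen.frequency import (FrequencyTable, annotate_candidates,
                                 compute_frequencies, merge_conditions)
from tcrscreen.markers import ActivationThresholds, read_marker_matrix
from tcrscreen.screen import (CandidateTCR, ScreenResult, activated_to_frame,
                              candidates_to_frame, run_screen)
from tcrscreen.vdj import (call_clonotypes, clonotypes_to_frame,
                           filter_productive, group_cells, read_contigs)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """An analysis stage failed; carries the stage name and file context."""


@dataclass
class ConditionInput:
    label: str
    contigs: Path
    markers: Path


@dataclass
class SpecimenConfig:
    name: str
    conditions: list[ConditionInput]
    negative_control: str | None = None
    thresholds: ActivationThresholds = field(default_factory=ActivationThresholds)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SpecimenConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        base = path.parent
        thr = raw.get("thresholds", {})
        return cls(
            name=raw.get("name", base.name),
            conditions=[
                ConditionInput(label=c["label"], contigs=base / c["contigs"],
                               markers=base / c["markers"])
                for c in raw["conditions"]
            ],
            negative_control=raw.get("negative_control"),
            thresholds=ActivationThresholds(
                ifng_min=int(thr.get("ifng_min", 5)),
                il2_min=int(thr.get("il2_min", 5)),
                lineage_min=int(thr.get("lineage_min", 2)),
            ),
        )


@dataclass
class SpecimenResult:
    name: str
    screen: ScreenResult
    clonotypes: dict[str, list]          # per-condition clonotype lists
    cells: dict[str, list]               # per-condition CellVDJ lists
    frequencies: FrequencyTable
    candidate_frequencies: pd.DataFrame

    @property
    def candidates(self) -> list[CandidateTCR]:
        return self.screen.candidates


def run_specimen(config: SpecimenConfig,
                 out_dir: str | Path | None = None) -> SpecimenResult:
    """Run the full screen over one specimen; optionally write all tables."""
    cells_by_cond, profiles_by_cond, clono_by_cond = {}, {}, {}
    for cond in config.conditions:
        try:
            contigs = read_contigs(cond.contigs)
        except Exception as exc:
            raise StageError(f"read_contigs[{cond.label}] {cond.contigs}: {exc}") from exc
        cells = group_cells(filter_productive(contigs))
        cells_by_cond[cond.label] = cells
        clono_by_cond[cond.label] = call_clonotypes(cells)
        try:
            profiles_by_cond[cond.label] = read_marker_matrix(cond.markers)
        except Exception as exc:
            raise StageError(f"read_markers[{cond.label}] {cond.markers}: {exc}") from exc

    screen = run_screen(cells_by_cond, profiles_by_cond, config.thresholds,
                        config.negative_control)
    merged = merge_conditions(clono_by_cond)
    freq = compute_frequencies(merged)
    cand_freq = annotate_candidates(freq, screen.candidates)
    result = SpecimenResult(
        name=config.name, screen=screen, clonotypes=clono_by_cond,
        cells=cells_by_cond, frequencies=freq,
        candidate_frequencies=cand_freq,
    )
    if out_dir is not None:
        _write_specimen(result, Path(out_dir))
    return result


def _write_specimen(result: SpecimenResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    activated_to_frame(result.screen.activated).to_csv(
        out_dir / "activated_cells.tsv", sep="\t", index=False,
        lineterminator="\n")
    candidates_to_frame(result.screen.candidates).to_csv(
        out_dir / "candidates.tsv", sep="\t", index=False, lineterminator="\n")
    pd.DataFrame({"clonotype_key": result.screen.removed_autoreactive}).to_csv(
        out_dir / "autoreactive.tsv", sep="\t", index=False,
        lineterminator="\n")
    for cond, clonos in sorted(result.clonotypes.items()):
        clonotypes_to_frame(clonos).to_csv(
            out_dir / f"clonotypes_{cond}.tsv", sep="\t", index=False,
            lineterminator="\n")
    result.frequencies.table.to_csv(out_dir / "frequencies.tsv", sep="\t",
                                    index=False, lineterminator="\n")
    result.candidate_frequencies.to_csv(out_dir / "candidate_frequencies.tsv",
                                        sep="\t", index=False,
                                        lineterminator="\n")
    summary = {
        "specimen": result.name,
        "n_candidates": len(result.candidates),
        "n_shared": sum(c.klass == "shared" for c in result.candidates),
        "n_unique": sum(c.klass == "unique" for c in result.candidates),
        "n_autoreactive_removed": len(result.screen.removed_autoreactive),
        "retained_cells": result.frequencies.retained_total,
        "dropped_singletons": result.frequencies.dropped_singletons,
        "exclusions": {
            cond: {"mixed": log.n_mixed, "undetectable": log.n_undetectable,
                   "il2_only": log.n_il2_only, "activated": log.n_activated,
                   "ifng_pos": log.n_ifng_pos}
            for cond, log in sorted(result.screen.logs.items())
        },
    }
    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# truth + evaluation


@dataclass
class TruthData:
    """Planted ground truth of one fixture, as loaded from its truth dir."""

    clonotypes: pd.DataFrame
    barcodes: pd.DataFrame
    tested: set[tuple[str, str]]     # (condition, clonotype key)

    @classmethod
    def load(cls, truth_dir: str | Path) -> "TruthData":
        truth_dir = Path(truth_dir)
        clono = pd.read_csv(truth_dir / "clonotypes.tsv", sep="\t",
                            keep_default_na=False)
        bcs = pd.read_csv(truth_dir / "barcodes.tsv", sep="\t",
                          keep_default_na=False)
        tested = pd.read_csv(truth_dir / "tested.tsv", sep="\t",
                             keep_default_na=False)
        return cls(
            clonotypes=clono, barcodes=bcs,
            tested={(r.condition, r.cdr3b_nt)
                    for r in tested.itertuples(index=False)},
        )

    @property
    def reactive_keys(self) -> set[str]:
        df = self.clonotypes
        return set(df.loc[df["reactive"] & ~df["autoreactive"], "cdr3b_nt"])

    @property
    def autoreactive_keys(self) -> set[str]:
        df = self.clonotypes
        return set(df.loc[df["autoreactive"].astype(bool), "cdr3b_nt"])

    def responder_count(self, condition: str, marker: str = "ifng") -> int:
        df = self.barcodes
        return int(((df["condition"] == condition)
                    & (df["response"] == marker)).sum())


@dataclass
class ValidationSummary:
    """Reliability of shared vs unique candidate calls for tested receptors."""

    name: str
    n_shared_tested: int = 0
    n_shared_reactive: int = 0
    n_unique_tested: int = 0
    n_unique_reactive: int = 0

    @property
    def shared_precision(self) -> float | None:
        if self.n_shared_tested == 0:
            return None
        return 100.0 * self.n_shared_reactive / self.n_shared_tested

    @property
    def unique_precision(self) -> float | None:
        if self.n_unique_tested == 0:
            return None
        return 100.0 * self.n_unique_reactive / self.n_unique_tested

    @property
    def total_reactive(self) -> int:
        return self.n_shared_reactive + self.n_unique_reactive

    def as_dict(self) -> dict:
        fmt = lambda p: "NA" if p is None else round(p)
        return {
            "specimen": self.name,
            "n_shared_tested": self.n_shared_tested,
            "n_shared_reactive": self.n_shared_reactive,
            "shared_precision_pct": fmt(self.shared_precision),
            "n_unique_tested": self.n_unique_tested,
            "n_unique_reactive": self.n_unique_reactive,
            "unique_precision_pct": fmt(self.unique_precision),
            "total_reactive": self.total_reactive,
        }

    def report_line(self) -> str:
        fmt = lambda p: "NA" if p is None else f"{p:.0f}%"
        return (f"{self.name}: shared {self.n_shared_reactive}/"
                f"{self.n_shared_tested} ({fmt(self.shared_precision)}), "
                f"unique {self.n_unique_reactive}/{self.n_unique_tested} "
                f"({fmt(self.unique_precision)}), "
                f"total reactive {self.total_reactive}")


def evaluate_candidates(candidates: list[CandidateTCR], truth: TruthData,
                        name: str = "") -> ValidationSummary:
    """Score candidates against planted truth over the tested subset.

    A candidate is reactive iff its clonotype key belongs to a planted
    reactive (and not autoreactive) clonotype.  Only candidates in the
    planted tested list enter the precision denominators, mirroring a
    screen in which every shared receptor but only selected unique
    receptors go to wet-lab validation.
    """
    s = ValidationSummary(name=name)
    for c in candidates:
        if (c.condition, c.clonotype_key) not in truth.tested:
            continue
        reactive = c.clonotype_key in truth.reactive_keys
        if c.klass == "shared":
            s.n_shared_tested += 1
            s.n_shared_reactive += int(reactive)
        else:
            s.n_unique_tested += 1
            s.n_unique_reactive += int(reactive)
    return s


def summarize_suite(summaries: list[ValidationSummary]) -> ValidationSummary:
    """Pool per-specimen summaries by summation."""
    pooled = ValidationSummary(name="pooled")
    for s in summaries:
        pooled.n_shared_tested += s.n_shared_tested
        pooled.n_shared_reactive += s.n_shared_reactive
        pooled.n_unique_tested += s.n_unique_tested
        pooled.n_unique_reactive += s.n_unique_reactive
    return pooled


def run_suite(fixture_names=None, work_dir: str | Path = None,
              out_dir: str | Path | None = None, seed: int | None = None,
              ) -> tuple[list["ValidationSummary"], ValidationSummary,
                         dict[str, SpecimenResult]]:
    """Simulate, screen and validate a set of fixtures end to end."""
    # imported here: fixtures depend on the analysis modules above
    from tcrscreen.fixtures import FIXTURE_NAMES, FIXTURE_SEEDS, make_fixture

    if fixture_names is None:
        fixture_names = FIXTURE_NAMES
    work_dir = Path(work_dir)
    summaries, results = [], {}
    for name in fixture_names:
        fx_seed = None
        if seed is not None:
            fx_seed = (FIXTURE_SEEDS[name] * 100_003 + seed) % (2 ** 31)
        fx_dir = make_fixture(name, work_dir / name, seed=fx_seed)
        config = SpecimenConfig.from_yaml(fx_dir / "config.yaml")
        res = run_specimen(
            config, out_dir=None if out_dir is None else Path(out_dir) / name)
        truth = TruthData.load(fx_dir / "truth")
        summaries.append(evaluate_candidates(res.candidates, truth, name=name))
        results[name] = res
    pooled = summarize_suite(summaries)
    if out_dir is not None:
        report = {"specimens": [s.as_dict() for s in summaries],
                  "pooled": pooled.as_dict()}
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        (Path(out_dir) / "summary.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n")
    return summaries, pooled, results
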