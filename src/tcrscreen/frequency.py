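"""Merged clonotype frequencies with singleton removal.

To estimate how large the identified clonotypes are within the whole
infiltrate, all conditions of a specimen are pooled (barcodes namespaced by
condition), and clonotypes observed exactly once across the merge are
discarded before computing frequencies — single-observation clonotypes are
dominated by sequencing errors and doublet chimeras, so they would inflate
the denominator with artifacts.  Frequencies are fractions of the retained
(non-singleton) cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from tcrscreen.screen import CandidateTCR
from tcrscreen.vdj import Clonotype

logger = logging.getLogger(__name__)


class DataError(ValueError):
    pass


@dataclass
class FrequencyTable:
    """Per-clonotype merged counts and frequencies over retained cells."""

    table: pd.DataFrame          # columns: key, count, frequency
    retained_total: int
    dropped_singletons: int

    def frequency_of(self, key: str) -> float | None:
        hit = self.table.loc[self.table["key"] == key, "frequency"]
        return None if hit.empty else float(hit.iloc[0])


def merge_conditions(tables: dict[str, list[Clonotype]]) -> pd.DataFrame:
    """Sum per-clonotype cell counts across the conditions of one specimen.

    Barcodes are namespaced ``condition:barcode`` before pooling; a
    duplicate namespaced barcode indicates corrupt input and raises
    :class:`DataError`.
    """
    counts: dict[str, int] = {}
    seen: set[str] = set()
    for cond in sorted(tables):
        for clono in tables[cond]:
            for bc in clono.barcodes:
                namespaced = f"{cond}:{bc}"
                if namespaced in seen:
                    raise DataError(f"duplicate barcode {namespaced}")
                seen.add(namespaced)
            counts[clono.key] = counts.get(clono.key, 0) + clono.count
    df = pd.DataFrame(
        {"key": list(counts), "count": list(counts.values())},
        columns=["key", "count"],
    )
    if len(df):
        df = df.sort_values(["count", "key"], ascending=[False, True],
                            ignore_index=True)
    return df


def compute_frequencies(merged: pd.DataFrame,
                        drop_singletons: bool = True) -> FrequencyTable:
    """Drop once-detected clonotypes and normalize counts to frequencies."""
    if merged.empty:
        raise DataError("merged clonotype table is empty")
    if drop_singletons:
        retained = merged[merged["count"] >= 2].copy()
        dropped = int((merged["count"] == 1).sum())
    else:
        retained = merged.copy()
        dropped = 0
    total = int(retained["count"].sum())
    if total == 0:
        logger.warning("all clonotypes were singletons; empty frequency table")
        retained["frequency"] = pd.Series(dtype=float)
        return FrequencyTable(table=retained, retained_total=0,
                              dropped_singletons=dropped)
    retained["frequency"] = retained["count"] / total
    return FrequencyTable(table=retained.reset_index(drop=True),
                          retained_total=total, dropped_singletons=dropped)


def annotate_candidates(freq: FrequencyTable,
                        candidates: list[CandidateTCR]) -> pd.DataFrame:
    """Per-candidate merged frequency report (deduplicated by clonotype key).

    Candidates whose clonotype was removed as a singleton get frequency
    ``NA`` — once-detected clonotypes have no calculable frequency.  The
    final row sums the frequency of all candidate clonotypes.
    """
    rows = []
    seen: set[str] = set()
    total = 0.0
    for c in candidates:
        if c.clonotype_key in seen:
            continue
        seen.add(c.clonotype_key)
        f = freq.frequency_of(c.clonotype_key)
        if f is not None:
            total += f
        rows.append({
            "key": c.clonotype_key,
            "klass": c.klass,
            "condition": c.condition,
            "frequency": float("nan") if f is None else f,
            "frequency_pct": "NA" if f is None else f"{100 * f:.2f}",
        })
    rows.append({
        "key": "TOTAL", "klass": "", "condition": "",
        "frequency": total, "frequency_pct": f"{100 * total:.2f}",
    })
    return pd.DataFrame(rows, columns=[
        "key", "klass", "condition", "frequency", "frequency_pct",
    ])
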