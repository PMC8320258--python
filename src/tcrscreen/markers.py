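"""Per-barcode activation-marker UMI counts and positivity rules.

The screen quantifies five PCR-enriched transcripts per droplet: the
activation cytokines IFN-γ (IFNG) and IL-2 (IL2), and the lineage markers
CD4, CD8A and CD8B.  Counts are raw targeted-enrichment UMIs; no
normalization is applied.  Lineage positivity uses the standard rule of
two or more UMIs; the "high IFN-γ / IL-2" activation cutoffs are
configurable (default 5 UMIs, which separates responders from ambient
background by an order of magnitude in the simulated specimens).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

MARKER_FEATURES = ("IFNG", "IL2", "CD4", "CD8A", "CD8B")


class FormatError(ValueError):
    pass


@dataclass(frozen=True)
class MarkerProfile:
    """UMI counts of the five enriched markers for one barcode."""

    barcode: str
    ifng: int = 0
    il2: int = 0
    cd4: int = 0
    cd8a: int = 0
    cd8b: int = 0


@dataclass(frozen=True)
class ActivationThresholds:
    """Inclusive UMI cutoffs for positivity calls.

    ``lineage_min`` defaults to 2 (the two-or-more-UMI rule); the cytokine
    cutoffs are a documented package default.
    """

    ifng_min: int = 5
    il2_min: int = 5
    lineage_min: int = 2

    def __post_init__(self):
        if min(self.ifng_min, self.il2_min, self.lineage_min) < 1:
            raise ValueError("thresholds must be >= 1")


def read_marker_matrix(path: str | Path) -> list[MarkerProfile]:
    """Read marker UMI counts from a matrix directory or long-form CSV.

    A directory must contain ``matrix.mtx`` (features × barcodes,
    MatrixMarket coordinate), ``barcodes.tsv`` and ``features.tsv``.
    A file is read as CSV with columns barcode, feature, umi_count.
    Duplicate (barcode, feature) entries are summed with a warning;
    a feature outside the five-marker panel raises :class:`FormatError`.
    """
    path = Path(path)
    if path.is_dir():
        long = _read_mtx_dir(path)
    else:
        long = pd.read_csv(path, dtype={"barcode": str, "feature": str})
        missing = {"barcode", "feature", "umi_count"} - set(long.columns)
        if missing:
            raise FormatError(f"marker CSV missing columns: {sorted(missing)}")
    unknown = set(long["feature"]) - set(MARKER_FEATURES)
    if unknown:
        raise FormatError(f"unknown marker feature(s): {sorted(unknown)}")
    if long.duplicated(["barcode", "feature"]).any():
        logger.warning("duplicate (barcode, feature) entries summed in %s", path)
        long = long.groupby(["barcode", "feature"], as_index=False)["umi_count"].sum()
    wide = long.pivot_table(index="barcode", columns="feature",
                            values="umi_count", aggfunc="sum", fill_value=0)
    for f in MARKER_FEATURES:
        if f not in wide.columns:
            wide[f] = 0
    barcodes = getattr(long, "attrs", {}).get("all_barcodes")
    if barcodes is None:
        barcodes = list(wide.index)
    profiles = []
    for bc in sorted(barcodes):
        if bc in wide.index:
            row = wide.loc[bc]
            profiles.append(MarkerProfile(
                barcode=bc, ifng=int(row["IFNG"]), il2=int(row["IL2"]),
                cd4=int(row["CD4"]), cd8a=int(row["CD8A"]), cd8b=int(row["CD8B"]),
            ))
        else:
            profiles.append(MarkerProfile(barcode=bc))
    return profiles


def _read_mtx_dir(path: Path) -> pd.DataFrame:
    mat = scipy.io.mmread(path / "matrix.mtx").tocoo()
    # mmread keeps duplicate coordinate entries; collapse them by summation
    mat.sum_duplicates()
    features = (path / "features.tsv").read_text().split()
    barcodes = (path / "barcodes.tsv").read_text().split()
    if mat.shape != (len(features), len(barcodes)):
        raise FormatError(
            f"matrix shape {mat.shape} does not match "
            f"{len(features)} features x {len(barcodes)} barcodes"
        )
    long = pd.DataFrame({
        "barcode": [barcodes[j] for j in mat.col],
        "feature": [features[i] for i in mat.row],
        "umi_count": mat.data.astype(int),
    })
    long.attrs["all_barcodes"] = barcodes
    return long


def write_marker_matrix(counts: pd.DataFrame, out_dir: str | Path) -> None:
    """Write a barcode × marker count table as MatrixMarket + sidecar lists.

    ``counts`` is indexed by barcode with the five marker columns; the
    on-disk orientation is features × barcodes, 10x style.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts = counts.reindex(columns=list(MARKER_FEATURES), fill_value=0)
    mat = scipy.sparse.coo_matrix(
        counts.to_numpy(dtype=int, na_value=0).T,
        shape=(len(MARKER_FEATURES), len(counts)))
    scipy.io.mmwrite(out_dir / "matrix.mtx", mat, field="integer")
    (out_dir / "features.tsv").write_text("\n".join(MARKER_FEATURES) + "\n")
    (out_dir / "barcodes.tsv").write_text("\n".join(counts.index) + "\n")


def write_marker_csv(counts: pd.DataFrame, path: str | Path) -> None:
    """Long-form CSV alternative (barcode, feature, umi_count; zeros omitted)."""
    long = (counts.reindex(columns=list(MARKER_FEATURES), fill_value=0)
            .rename_axis("barcode").reset_index()
            .melt(id_vars="barcode", var_name="feature", value_name="umi_count"))
    long = long[long["umi_count"] > 0].sort_values(["barcode", "feature"])
    long.to_csv(path, index=False, lineterminator="\n")


def lineage_call(profile: MarkerProfile,
                 thresholds: ActivationThresholds = ActivationThresholds()) -> str:
    """CD4/CD8 lineage of a cell from its marker counts.

    CD4-positive iff cd4 ≥ lineage_min; CD8-positive iff cd8a + cd8b ≥
    lineage_min (combined, the permissive reading of the two-UMI rule).
    """
    cd4_pos = profile.cd4 >= thresholds.lineage_min
    cd8_pos = (profile.cd8a + profile.cd8b) >= thresholds.lineage_min
    if cd4_pos and cd8_pos:
        return "double_positive"
    if cd4_pos:
        return "CD4"
    if cd8_pos:
        return "CD8"
    return "unassigned"


def activation_call(profile: MarkerProfile,
                    thresholds: ActivationThresholds = ActivationThresholds(),
                    ) -> tuple[bool, bool]:
    """(ifng_pos, il2_pos) flags; thresholds are inclusive."""
    return profile.ifng >= thresholds.ifng_min, profile.il2 >= thresholds.il2_min
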