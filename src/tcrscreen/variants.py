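"""Hard filter for somatic variant candidates feeding the neoantigen screen.

Upstream exome alignment and calling are out of scope; this module applies
the screen's post-call hard criteria to a tumor/normal variant table: total read
depth ≥ 10 in both tumor and normal, variant allele frequency ≥ 10%, and
≥ 4 tumor reads supporting the variant.  All four thresholds are inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

MIN_TUMOR_DEPTH = 10
MIN_NORMAL_DEPTH = 10
MIN_VAF = 0.10
MIN_VARIANT_READS = 4

#: annotation effects counted as non-synonymous for the optional flag
NONSYN_EFFECTS = {
    "missense", "nonsense", "frameshift", "nonstop",
    "splice_site", "inframe_indel", "start_lost",
}


class DataError(ValueError):
    pass


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int                 # 1-based
    ref: str
    alt: str
    tumor_depth: int
    normal_depth: int
    tumor_variant_reads: int
    vaf: float               # fraction in [0, 1]
    annotation: str = ""     # free text, e.g. "GENE|missense"

    def __post_init__(self):
        if min(self.tumor_depth, self.normal_depth, self.tumor_variant_reads) < 0:
            raise DataError(f"negative read count at {self.chrom}:{self.pos}")
        if not 0.0 <= self.vaf <= 1.0:
            raise DataError(f"VAF out of [0,1] at {self.chrom}:{self.pos}")
        if self.tumor_variant_reads > self.tumor_depth:
            raise DataError(
                f"variant reads exceed tumor depth at {self.chrom}:{self.pos}")


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read a TSV with named columns into :class:`VariantRecord` rows.

    VAF columns in percent (any value > 1) are auto-normalized to
    fractions with a logged notice, since caller outputs vary.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt", "tumor_depth", "normal_depth",
                "tumor_variant_reads", "vaf"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"variant table missing columns: {sorted(missing)}")
    vaf = df["vaf"].astype(float)
    if (vaf > 1).any():
        logger.info("VAF column appears to be in percent; dividing by 100")
        vaf = vaf / 100.0
    return [
        VariantRecord(
            chrom=str(r.chrom), pos=int(r.pos), ref=r.ref, alt=r.alt,
            tumor_depth=int(r.tumor_depth), normal_depth=int(r.normal_depth),
            tumor_variant_reads=int(r.tumor_variant_reads),
            vaf=float(v),
            annotation=str(getattr(r, "annotation", "") or ""),
        )
        for r, v in zip(df.itertuples(index=False), vaf)
    ]


def is_nonsynonymous(record: VariantRecord) -> bool:
    text = record.annotation.lower()
    return any(effect in text for effect in NONSYN_EFFECTS)


def apply_filter(records: list[VariantRecord], nonsyn_only: bool = False,
                 ) -> tuple[list[VariantRecord],
                            list[tuple[VariantRecord, list[str]]]]:
    """Partition records into (passed, failed-with-reasons).

    A record passes iff every criterion holds; failures list every violated
    criterion, so the reject table is self-explanatory.
    """
    passed, failed = [], []
    for r in records:
        reasons = []
        if r.tumor_depth < MIN_TUMOR_DEPTH:
            reasons.append(f"tumor_depth<{MIN_TUMOR_DEPTH}")
        if r.normal_depth < MIN_NORMAL_DEPTH:
            reasons.append(f"normal_depth<{MIN_NORMAL_DEPTH}")
        if r.vaf < MIN_VAF:
            reasons.append(f"vaf<{MIN_VAF}")
        if r.tumor_variant_reads < MIN_VARIANT_READS:
            reasons.append(f"variant_reads<{MIN_VARIANT_READS}")
        if nonsyn_only and not is_nonsynonymous(r):
            reasons.append("not_nonsynonymous")
        if reasons:
            failed.append((r, reasons))
        else:
            passed.append(r)
    return passed, failed


def write_filter_results(passed, failed, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cols = ["chrom", "pos", "ref", "alt", "tumor_depth", "normal_depth",
            "tumor_variant_reads", "vaf", "annotation"]

    def frame(records):
        return pd.DataFrame(
            [{c: getattr(r, c) for c in cols} for r in records], columns=cols)

    frame(passed).to_csv(out_dir / "passed.tsv", sep="\t", index=False,
                         lineterminator="\n")
    rej = frame([r for r, _ in failed])
    rej["reasons"] = [";".join(reasons) for _, reasons in failed]
    rej.to_csv(out_dir / "rejected.tsv", sep="\t", index=False,
               lineterminator="\n")
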