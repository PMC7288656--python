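"""Sequencing depth-of-coverage and allele-coverage-ratio QC.

DOC per call is ref depth + alt depth. ACR is the minor/major depth ratio
of a heterozygous call; a locus with no heterozygotes has an undefined
mean ACR. Calls are flagged against a detection threshold (default 20
reads) and an interpretation threshold (default 30 reads); a call exactly
at a threshold passes it (DOC >= threshold).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from aisnp.genotype_io import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

DETECTION_THRESHOLD = 20
INTERPRETATION_THRESHOLD = 30


@dataclass
class AlleleDepthTable:
    """Long-format per-call allele depths: (sample, rsid) -> ref/alt depth."""

    samples: list[str]
    rsids: list[str]
    ref_depth: np.ndarray
    alt_depth: np.ndarray

    def __post_init__(self) -> None:
        self.ref_depth = np.asarray(self.ref_depth, dtype=np.int64)
        self.alt_depth = np.asarray(self.alt_depth, dtype=np.int64)
        n = len(self.samples)
        if not (len(self.rsids) == len(self.ref_depth) == len(self.alt_depth) == n):
            raise ValueError("allele-depth columns have inconsistent lengths")
        if (self.ref_depth < 0).any() or (self.alt_depth < 0).any():
            raise ValueError("negative depths")
        if len(set(zip(self.samples, self.rsids))) != n:
            raise ValueError("duplicate (sample, locus) records")

    def __len__(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.samples,
                "rsid": self.rsids,
                "ref_depth": self.ref_depth,
                "alt_depth": self.alt_depth,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AlleleDepthTable":
        return cls(
            samples=df["sample"].astype(str).tolist(),
            rsids=df["rsid"].astype(str).tolist(),
            ref_depth=df["ref_depth"].to_numpy(),
            alt_depth=df["alt_depth"].to_numpy(),
        )


def read_depths_tsv(path: str | Path) -> AlleleDepthTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "rsid": str})
    required = {"sample", "rsid", "ref_depth", "alt_depth"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return AlleleDepthTable.from_frame(df)


def write_depths_tsv(adt: AlleleDepthTable, path: str | Path) -> None:
    adt.to_frame().to_csv(path, sep="\t", index=False)


def compute_doc(adt: AlleleDepthTable) -> pd.DataFrame:
    """Per-locus mean and minimum depth of coverage.

    A locus with no records is simply absent from the result.
    """
    if len(adt) == 0:
        raise ValueError("empty allele-depth table")
    df = adt.to_frame()
    df["doc"] = df["ref_depth"] + df["alt_depth"]
    out = df.groupby("rsid", sort=False)["doc"].agg(
        mean_doc="mean", min_doc="min", n_calls="size"
    )
    return out.reset_index()


def compute_acr(adt: AlleleDepthTable, gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus mean allele coverage ratio over heterozygous calls.

    ACR per het call = min(ref, alt) / max(ref, alt). Loci with no usable
    heterozygotes get mean_acr NaN (undefined). Het calls with zero total
    depth are excluded with a warning.
    """
    sample_idx = {s: i for i, s in enumerate(gm.samples)}
    locus_idx = {loc.rsid: j for j, loc in enumerate(gm.loci)}
    acr_by_locus: dict[str, list[float]] = {loc.rsid: [] for loc in gm.loci}
    for sample, rsid, r, a in zip(
        adt.samples, adt.rsids, adt.ref_depth, adt.alt_depth
    ):
        i = sample_idx.get(sample)
        j = locus_idx.get(rsid)
        if i is None or j is None:
            continue
        if gm.codes[i, j] != 1:
            continue
        hi = max(int(r), int(a))
        if hi == 0:
            log.warning("het call %s@%s has zero depth; excluded", sample, rsid)
            continue
        acr_by_locus[rsid].append(min(int(r), int(a)) / hi)
    rows = []
    for loc in gm.loci:
        vals = acr_by_locus[loc.rsid]
        rows.append(
            {
                "rsid": loc.rsid,
                "mean_acr": float(np.mean(vals)) if vals else np.nan,
                "n_het": len(vals),
            }
        )
    return pd.DataFrame(rows)


def summarize_coverage(adt: AlleleDepthTable, gm: GenotypeMatrix) -> pd.DataFrame:
    """Join DOC and ACR summaries into one per-locus table."""
    doc = compute_doc(adt)
    acr = compute_acr(adt, gm)
    return doc.merge(acr, on="rsid", how="outer")


def flag_low_coverage(
    adt: AlleleDepthTable,
    detection_threshold: int = DETECTION_THRESHOLD,
    interpretation_threshold: int = INTERPRETATION_THRESHOLD,
) -> pd.DataFrame:
    """Label each call pass / below-interpretation / below-detection.

    Pass means DOC >= interpretation threshold (a call exactly at the
    threshold passes).
    """
    if detection_threshold <= 0 or interpretation_threshold <= 0:
        raise ValueError("thresholds must be positive")
    df = adt.to_frame()
    doc = df["ref_depth"] + df["alt_depth"]
    df["doc"] = doc
    df["flag"] = np.where(
        doc < detection_threshold,
        "below-detection",
        np.where(doc < interpretation_threshold, "below-interpretation", "pass"),
    )
    return df[["sample", "rsid", "doc", "flag"]]
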