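"""Genotype, manifest and allele-frequency table I/O.

Genotypes are stored as alt-allele dosage codes (0, 1, 2) with ``MISSING``
(-1) for no-calls; half-calls (e.g. ``0/.``) are treated as missing for the
whole genotype since the dosage is undefined. Positions are 1-based as in
VCF. Alleles are taken exactly as written in the input — no strand flipping
or allele harmonization is attempted, and a ref/alt mismatch between a
panel definition and a VCF record is a hard error.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

log = logging.getLogger(__name__)

#: Sentinel dosage code for a missing genotype call.
MISSING: int = -1

_VALID_CODES = frozenset({0, 1, 2, MISSING})

GroupLevel = Literal["population", "super", "pooled"]


class GenotypeIOError(ValueError):
    """Malformed genotype, manifest or frequency-table input."""


@dataclass(frozen=True)
class Locus:
    """A biallelic SNP with its panel identity.

    ``pos`` is 1-based. ``ref_allele`` and ``alt_allele`` must differ.
    """

    rsid: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise GenotypeIOError(
                f"locus {self.rsid}: ref and alt allele are both {self.ref_allele!r}"
            )


@dataclass
class GenotypeMatrix:
    """Individuals x loci alt-allele dosages.

    ``codes`` has shape (n_samples, n_loci) with entries in {0, 1, 2,
    MISSING}.
    """

    samples: list[str]
    loci: list[Locus]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int16)
        if self.codes.shape != (len(self.samples), len(self.loci)):
            raise GenotypeIOError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        if len(set(self.samples)) != len(self.samples):
            raise GenotypeIOError("duplicate sample identifiers")
        bad = set(np.unique(self.codes)) - _VALID_CODES
        if bad:
            raise GenotypeIOError(f"invalid genotype codes: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def rsids(self) -> list[str]:
        return [loc.rsid for loc in self.loci]

    def subset_samples(self, keep: Sequence[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.samples)}
        rows = [index[s] for s in keep]
        return GenotypeMatrix(list(keep), self.loci, self.codes[rows])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.loci == other.loci
            and np.array_equal(self.codes, other.codes)
        )


@dataclass
class PopulationManifest:
    """Maps samples to populations and populations to super-populations."""

    sample_to_population: dict[str, str]
    population_to_super: dict[str, str]

    def population_of(self, sample: str) -> str:
        return self.sample_to_population[sample]

    def super_of(self, sample: str) -> str:
        return self.population_to_super[self.sample_to_population[sample]]

    def group_of(self, sample: str, level: GroupLevel) -> str:
        if level == "population":
            return self.population_of(sample)
        if level == "super":
            return self.super_of(sample)
        if level == "pooled":
            return "ALL"
        raise GenotypeIOError(f"unknown grouping level {level!r}")

    def validate_against(self, gm: GenotypeMatrix) -> None:
        missing = [s for s in gm.samples if s not in self.sample_to_population]
        if missing:
            raise GenotypeIOError(f"samples without population label: {missing}")
        orphans = {
            p
            for p in self.sample_to_population.values()
            if p not in self.population_to_super
        }
        if orphans:
            raise GenotypeIOError(
                f"populations without super-population: {sorted(orphans)}"
            )


@dataclass
class AlleleFrequencyTable:
    """Per (group, locus) alt-allele frequency and chromosome counts.

    ``alt_freq`` is NaN where a group has zero non-missing calls at a
    locus (the undefined-cell flag).
    """

    groups: list[str]
    loci: list[Locus]
    alt_freq: np.ndarray  # (n_groups, n_loci), NaN = undefined
    n_chrom: np.ndarray  # (n_groups, n_loci), int

    def __post_init__(self) -> None:
        self.alt_freq = np.asarray(self.alt_freq, dtype=float)
        self.n_chrom = np.asarray(self.n_chrom, dtype=np.int64)
        shape = (len(self.groups), len(self.loci))
        if self.alt_freq.shape != shape or self.n_chrom.shape != shape:
            raise GenotypeIOError("frequency table dimensions inconsistent")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.alt_freq, initial=0.0) < 0 or np.nanmax(
                self.alt_freq, initial=0.0
            ) > 1:
                raise GenotypeIOError("alt_freq outside [0, 1]")

    @property
    def rsids(self) -> list[str]:
        return [loc.rsid for loc in self.loci]

    def group_index(self, label: str) -> int:
        try:
            return self.groups.index(label)
        except ValueError:
            raise GenotypeIOError(f"unknown group {label!r}") from None

    def row(self, label: str) -> np.ndarray:
        return self.alt_freq[self.group_index(label)]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_genotypes_vcf(
    path: str | Path,
    panel: Sequence[Locus] | None = None,
    multiallelic: Literal["skip", "error"] = "skip",
) -> tuple[GenotypeMatrix, list[Locus]]:
    """Read diploid GT calls from a VCF into a :class:`GenotypeMatrix`.

    Returns the matrix and the list of panel loci absent from the file
    (empty when ``panel`` is None). Multiallelic records are skipped with a
    warning (or rejected) per ``multiallelic``. Missing and half calls
    become ``MISSING``.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad input
        raise GenotypeIOError(f"cannot parse VCF {path}: {exc}") from exc

    panel_by_id = {loc.rsid: loc for loc in panel} if panel is not None else None
    samples = list(vcf.samples)
    loci: list[Locus] = []
    rows: list[np.ndarray] = []

    for variant in vcf:
        if len(variant.ALT) != 1:
            if multiallelic == "error":
                raise GenotypeIOError(
                    f"multiallelic record at {variant.CHROM}:{variant.POS}"
                )
            log.warning(
                "skipping multiallelic record %s:%s", variant.CHROM, variant.POS
            )
            continue
        rsid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        if panel_by_id is not None:
            want = panel_by_id.get(rsid)
            if want is None:
                continue
            if (want.ref_allele, want.alt_allele) != (variant.REF, variant.ALT[0]):
                raise GenotypeIOError(
                    f"allele mismatch at {rsid}: panel {want.ref_allele}/"
                    f"{want.alt_allele} vs VCF {variant.REF}/{variant.ALT[0]}"
                )
            locus = want
        else:
            locus = Locus(rsid, str(variant.CHROM), variant.POS, variant.REF,
                          variant.ALT[0])
        calls = np.full(len(samples), MISSING, dtype=np.int16)
        for i, gt in enumerate(variant.genotypes):
            alleles = gt[:-1]  # last element is the phase flag
            if len(alleles) != 2 or any(a < 0 for a in alleles):
                continue  # half call or no call -> MISSING
            calls[i] = int(alleles[0]) + int(alleles[1])
        loci.append(locus)
        rows.append(calls)

    if panel is not None:
        found = {loc.rsid for loc in loci}
        absent = [loc for loc in panel if loc.rsid not in found]
        # preserve panel order in the output matrix
        order = {loc.rsid: j for j, loc in enumerate(loci)}
        keep = [loc for loc in panel if loc.rsid in found]
        if rows:
            codes = np.stack(rows, axis=1)[:, [order[l.rsid] for l in keep]]
        else:
            codes = np.empty((len(samples), 0), dtype=np.int16)
        return GenotypeMatrix(samples, keep, codes), absent

    codes = (
        np.stack(rows, axis=1) if rows else np.empty((len(samples), 0), np.int16)
    )
    return GenotypeMatrix(samples, loci, codes), []


def write_genotypes_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT-only calls."""
    code_to_gt = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = sorted({loc.chrom for loc in gm.loci})
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for j, loc in enumerate(gm.loci):
            gts = "\t".join(code_to_gt[int(c)] for c in gm.codes[:, j])
            fh.write(
                f"{loc.chrom}\t{loc.pos}\t{loc.rsid}\t{loc.ref_allele}\t"
                f"{loc.alt_allele}\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# TSV genotype matrix (documented dialect: tab-separated, NA for missing)
# ---------------------------------------------------------------------------

def read_genotypes_tsv(
    path: str | Path, panel: Sequence[Locus] | None = None
) -> GenotypeMatrix:
    """Read the TSV genotype dialect: header = rsids, first column = sample.

    Cells must be 0, 1, 2 or NA. If ``panel`` is given it supplies locus
    coordinates for the header rsids; otherwise placeholder coordinates are
    used.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise GenotypeIOError(f"{path}: empty file")
        cols = header.split("\t")
        rsids = cols[1:]
        if not rsids:
            raise GenotypeIOError(f"{path}: no locus columns")
        samples: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(cols):
                raise GenotypeIOError(
                    f"{path}:{lineno}: expected {len(cols)} columns, got {len(parts)}"
                )
            samples.append(parts[0])
            row = []
            for rsid, cell in zip(rsids, parts[1:]):
                if cell == "NA":
                    row.append(MISSING)
                elif cell in ("0", "1", "2"):
                    row.append(int(cell))
                else:
                    raise GenotypeIOError(
                        f"{path}:{lineno}: bad cell {cell!r} in column {rsid}"
                    )
            rows.append(row)
    if not samples:
        raise GenotypeIOError(f"{path}: no samples")
    if panel is not None:
        by_id = {loc.rsid: loc for loc in panel}
        try:
            loci = [by_id[r] for r in rsids]
        except KeyError as exc:
            raise GenotypeIOError(f"{path}: rsid {exc} not in panel") from None
    else:
        loci = [Locus(r, "0", j + 1, "A", "G") for j, r in enumerate(rsids)]
    return GenotypeMatrix(samples, loci, np.array(rows, dtype=np.int16))


def write_genotypes_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(gm.rsids) + "\n")
        for i, s in enumerate(gm.samples):
            cells = [
                "NA" if c == MISSING else str(int(c)) for c in gm.codes[i]
            ]
            fh.write(s + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Manifest and panel files
# ---------------------------------------------------------------------------

def read_manifest_tsv(path: str | Path) -> PopulationManifest:
    """Read a manifest TSV with columns sample, population, super_population."""
    s2p: dict[str, str] = {}
    p2s: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["sample", "population", "super_population"]:
            raise GenotypeIOError(
                f"{path}: expected header sample/population/super_population"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise GenotypeIOError(f"{path}:{lineno}: expected 3 columns")
            sample, pop, sup = parts[:3]
            s2p[sample] = pop
            if pop in p2s and p2s[pop] != sup:
                raise GenotypeIOError(
                    f"{path}:{lineno}: population {pop} mapped to two "
                    f"super-populations"
                )
            p2s[pop] = sup
    return PopulationManifest(s2p, p2s)


def write_manifest_tsv(manifest: PopulationManifest, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tpopulation\tsuper_population\n")
        for sample, pop in manifest.sample_to_population.items():
            fh.write(f"{sample}\t{pop}\t{manifest.population_to_super[pop]}\n")


def read_panel_tsv(path: str | Path) -> list[Locus]:
    """Read a panel TSV with columns rsid, chrom, pos, ref, alt."""
    loci = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:5] != ["rsid", "chrom", "pos", "ref", "alt"]:
            raise GenotypeIOError(f"{path}: expected header rsid/chrom/pos/ref/alt")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            rsid, chrom, pos, ref, alt = line.split("\t")[:5]
            loci.append(Locus(rsid, chrom, int(pos), ref, alt))
    return loci


def write_panel_tsv(loci: Sequence[Locus], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("rsid\tchrom\tpos\tref\talt\n")
        for loc in loci:
            fh.write(
                f"{loc.rsid}\t{loc.chrom}\t{loc.pos}\t{loc.ref_allele}\t"
                f"{loc.alt_allele}\n"
            )


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

def allele_frequencies(
    gm: GenotypeMatrix,
    manifest: PopulationManifest,
    level: GroupLevel = "population",
) -> AlleleFrequencyTable:
    """Alt-allele frequencies per group at the requested grouping level.

    For each group and locus: alt_freq = (sum of codes) / (2 * non-missing
    calls), n_chrom = 2 * non-missing. Cells with zero non-missing calls
    get alt_freq NaN.
    """
    manifest.validate_against(gm)
    labels = [manifest.group_of(s, level) for s in gm.samples]
    groups = sorted(set(labels))
    n_g, n_l = len(groups), gm.n_loci
    alt_freq = np.full((n_g, n_l), np.nan)
    n_chrom = np.zeros((n_g, n_l), dtype=np.int64)
    codes = gm.codes
    observed = codes != MISSING
    label_arr = np.array(labels)
    for gi, g in enumerate(groups):
        rows = label_arr == g
        obs = observed[rows]
        alt = np.where(obs, codes[rows], 0).sum(axis=0)
        n = obs.sum(axis=0)
        n_chrom[gi] = 2 * n
        with np.errstate(invalid="ignore", divide="ignore"):
            alt_freq[gi] = np.where(n > 0, alt / (2 * n), np.nan)
    return AlleleFrequencyTable(groups, list(gm.loci), alt_freq, n_chrom)


def pool_groups(
    aft: AlleleFrequencyTable,
    target: str,
    weighted: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Split a frequency table into (target, pooled-rest) frequency vectors.

    The rest pool is chromosome-count weighted by default (equivalent to
    pooling the raw samples); ``weighted=False`` takes the unweighted mean
    of the non-target group frequencies instead.
    """
    if len(aft.groups) < 2:
        raise GenotypeIOError("pooling requires at least 2 groups")
    ti = aft.group_index(target)
    rest = [i for i in range(len(aft.groups)) if i != ti]
    f = aft.alt_freq[rest]
    n = aft.n_chrom[rest].astype(float)
    n = np.where(np.isnan(f), 0.0, n)  # undefined cells carry no chromosomes
    if weighted:
        counts = np.where(np.isnan(f), 0.0, f) * n
        denom = n.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            pooled = np.where(denom > 0, counts.sum(axis=0) / denom, np.nan)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            pooled = np.nanmean(f, axis=0)
    return aft.alt_freq[ti].copy(), pooled


def write_frequency_table_tsv(aft: AlleleFrequencyTable, path: str | Path) -> None:
    """Write a frequency table as TSV: rsid, then per group freq and n_chrom."""
    with open(path, "w") as fh:
        cols = ["rsid"]
        for g in aft.groups:
            cols += [f"{g}_alt_freq", f"{g}_n_chrom"]
        fh.write("\t".join(cols) + "\n")
        for j, rsid in enumerate(aft.rsids):
            cells = [rsid]
            for gi in range(len(aft.groups)):
                f = aft.alt_freq[gi, j]
                cells.append("NA" if np.isnan(f) else f"{f:.10g}")
                cells.append(str(int(aft.n_chrom[gi, j])))
            fh.write("\t".join(cells) + "\n")


def read_frequency_table_tsv(
    path: str | Path, panel: Sequence[Locus] | None = None
) -> AlleleFrequencyTable:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "rsid":
            raise GenotypeIOError(f"{path}: expected rsid header column")
        groups = [c[: -len("_alt_freq")] for c in header[1::2]]
        rsids: list[str] = []
        freq_rows: list[list[float]] = []
        chrom_rows: list[list[int]] = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                continue
            rsids.append(parts[0])
            freq_rows.append(
                [np.nan if c == "NA" else float(c) for c in parts[1::2]]
            )
            chrom_rows.append([int(c) for c in parts[2::2]])
    if panel is not None:
        by_id = {loc.rsid: loc for loc in panel}
        loci = [by_id[r] for r in rsids]
    else:
        loci = [Locus(r, "0", j + 1, "A", "G") for j, r in enumerate(rsids)]
    return AlleleFrequencyTable(
        groups,
        loci,
        np.array(freq_rows, dtype=float).T,
        np.array(chrom_rows, dtype=np.int64).T,
    )


def concat_matrices(parts: Iterable[GenotypeMatrix]) -> GenotypeMatrix:
    """Stack genotype matrices sample-wise; loci must match exactly."""
    parts = list(parts)
    first = parts[0]
    for p in parts[1:]:
        if p.loci != first.loci:
            raise GenotypeIOError("cannot concatenate matrices with different loci")
    samples = [s for p in parts for s in p.samples]
    codes = np.concatenate([p.codes for p in parts], axis=0)
    return GenotypeMatrix(samples, first.loci, codes)
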