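"""Data model and I/O for targeted bisulfite-sequencing methylation data.

The pipeline's entry point is per-CpG read counts in the Bismark coverage
dialect (one tab-separated file per subject: chromosome, start, end,
methylation percentage, methylated count, unmethylated count), together with
a sample sheet of phenotypes and a registry of named genomic intervals on
hg38 chr8.  Coordinates are 1-based and both-ends inclusive throughout.

*OPRK1* lies on the reverse strand, so "upstream" in gene terms means a
*higher* genomic coordinate; CG site identifiers increase 5'->3' along the
gene, i.e. with *decreasing* genomic position.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUP_LABELS = ("BPD", "HC")

#: Symptom / trauma scale columns of the sample sheet (mean scores).
SCALE_COLUMNS = (
    "BSL23",
    "ZAN_BPD",
    "DES",
    "BIS",
    "BIS_motor",
    "BIS_attentional",
    "BIS_nonplanning",
    "CTQ",
    "CTQ_EA",
    "CTQ_PA",
    "CTQ_SA",
    "CTQ_EN",
    "CTQ_PN",
)

SITE_ANNOTATIONS = ("promoter", "intron1", "intron2", "exon", "upstream", "other")


class ValidationError(ValueError):
    """Input violates a documented contract."""


class CoverageParseError(ValueError):
    """A coverage file row could not be parsed."""


class UndefinedRateError(ValueError):
    """Methylation rate requested for a zero-coverage cell."""


@dataclass(frozen=True)
class CpGSite:
    """A single CG dinucleotide, identified by label and hg38 position."""

    site_id: str
    chromosome: str
    position: int
    annotation: str = "other"

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise ValidationError(f"site {self.site_id}: position must be positive")
        if self.annotation not in SITE_ANNOTATIONS:
            raise ValidationError(
                f"site {self.site_id}: unknown annotation {self.annotation!r}"
            )


@dataclass(frozen=True)
class GenomicRegion:
    """A named 1-based, both-ends-inclusive genomic interval."""

    name: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"region {self.name}: start > end")
        if self.start <= 0:
            raise ValidationError(f"region {self.name}: coordinates must be positive")

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end

    def member_sites(self, sites: Iterable[CpGSite]) -> list[CpGSite]:
        return [s for s in sites if s.chromosome == self.chromosome and self.contains(s.position)]


def region_length(region: GenomicRegion, convention: str = "inclusive") -> int:
    """Region length in bp under ``inclusive`` (end-start+1) or ``difference``
    (end-start) convention.

    Published region sizes mix the two conventions (the CpG-island sizes are
    inclusive, the DMR size is a coordinate difference), so the registry
    stores raw coordinates and the caller picks the convention per region.
    """
    if convention == "inclusive":
        return region.end - region.start + 1
    if convention == "difference":
        return region.end - region.start
    raise ValidationError(f"unknown length convention {convention!r}")


# ---------------------------------------------------------------------------
# Default registry: a priori regions of the OPRK1 promoter window (hg38).
# ---------------------------------------------------------------------------

CHROMOSOME = "chr8"

#: 10 kb target window: 5 kb either side of the translation start (chr8:53251036).
TARGET_WINDOW = GenomicRegion("window", CHROMOSOME, 53246080, 53256098)
CGI1 = GenomicRegion("CGI-1", CHROMOSOME, 53251468, 53251883)
CGI2 = GenomicRegion("CGI-2", CHROMOSOME, 53250744, 53251285)
EH1 = GenomicRegion("EH1", CHROMOSOME, 53253201, 53254400)
PROMOTER = GenomicRegion("promoter", CHROMOSOME, 53250800, 53252001)
DMR_REGION = GenomicRegion("DMR", CHROMOSOME, 53252014, 53252198)

#: Regions the group comparison is run on a priori.
A_PRIORI_REGIONS = (CGI1, CGI2, EH1)

DEFAULT_REGISTRY = (TARGET_WINDOW, CGI1, CGI2, EH1, PROMOTER, DMR_REGION)


def assign_sites_to_regions(
    sites: Sequence[CpGSite], registry: Sequence[GenomicRegion]
) -> dict[str, list[str]]:
    """Map each site_id to the names of the registry regions containing it.

    Membership is inclusive at both interval ends and independent of the
    order regions are listed in.
    """
    chroms = {r.chromosome for r in registry}
    if registry and any(s.chromosome not in chroms for s in sites):
        bad = next(s for s in sites if s.chromosome not in chroms)
        raise ValidationError(
            f"site {bad.site_id} on {bad.chromosome} does not match registry "
            f"chromosome(s) {sorted(chroms)}"
        )
    out: dict[str, list[str]] = {}
    for s in sites:
        out[s.site_id] = sorted(
            r.name for r in registry if r.chromosome == s.chromosome and r.contains(s.position)
        )
    return out


# ---------------------------------------------------------------------------
# Count matrix
# ---------------------------------------------------------------------------


def site_rate(methylated: int, unmethylated: int) -> float:
    """Methylation rate methylated/(methylated+unmethylated), in [0, 1]."""
    if methylated < 0 or unmethylated < 0:
        raise ValidationError("counts must be non-negative")
    total = methylated + unmethylated
    if total == 0:
        raise UndefinedRateError("zero coverage: rate undefined, mask the cell")
    return methylated / total


@dataclass
class MethylationCountMatrix:
    """Subjects x CpG sites matrix of (methylated, unmethylated) read counts.

    ``mask`` flags valid cells; masked cells are excluded from every
    downstream sum and mean.  Rates are defined only where coverage > 0.
    """

    subjects: list[str]
    sites: list[CpGSite]
    meth: np.ndarray  # (n_subjects, n_sites) int
    unmeth: np.ndarray  # (n_subjects, n_sites) int
    mask: np.ndarray = None  # (n_subjects, n_sites) bool, True = valid

    def __post_init__(self) -> None:
        self.meth = np.asarray(self.meth, dtype=np.int64)
        self.unmeth = np.asarray(self.unmeth, dtype=np.int64)
        shape = (len(self.subjects), len(self.sites))
        if self.meth.shape != shape or self.unmeth.shape != shape:
            raise ValidationError(f"count arrays must have shape {shape}")
        if (self.meth < 0).any() or (self.unmeth < 0).any():
            raise ValidationError("negative read counts")
        if self.mask is None:
            self.mask = np.ones(shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != shape:
                raise ValidationError(f"mask must have shape {shape}")
        if len(set(self.subjects)) != len(self.subjects):
            raise ValidationError("duplicate subject ids")
        if len({s.site_id for s in self.sites}) != len(self.sites):
            raise ValidationError("duplicate site ids")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def coverage(self) -> np.ndarray:
        return self.meth + self.unmeth

    def rates(self) -> np.ndarray:
        """Per-cell methylation rate; NaN where masked or zero coverage."""
        cov = self.coverage().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(cov > 0, self.meth / np.where(cov > 0, cov, 1), np.nan)
        r = np.where(self.mask & (cov > 0), r, np.nan)
        return r

    def site_index(self, site_id: str) -> int:
        for i, s in enumerate(self.sites):
            if s.site_id == site_id:
                return i
        raise KeyError(site_id)

    def subset_sites(self, keep: Sequence[int]) -> "MethylationCountMatrix":
        keep = list(keep)
        return MethylationCountMatrix(
            subjects=list(self.subjects),
            sites=[self.sites[i] for i in keep],
            meth=self.meth[:, keep].copy(),
            unmeth=self.unmeth[:, keep].copy(),
            mask=self.mask[:, keep].copy(),
        )


@dataclass
class FilterReport:
    """Bookkeeping from the coverage filter."""

    min_coverage: int
    min_per_group: int
    n_cells: int
    n_masked_low_coverage: int
    n_sites_in: int
    n_sites_dropped: int
    dropped_site_ids: list[str] = field(default_factory=list)
    everything_masked: bool = False

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def apply_coverage_filter(
    matrix: MethylationCountMatrix,
    min_coverage: int = 25,
    groups: Mapping[str, str] | None = None,
    min_per_group: int = 3,
) -> tuple[MethylationCountMatrix, FilterReport]:
    """Mask cells with fewer than ``min_coverage`` reads; drop thin sites.

    The filter is applied per subject-site cell because the downstream
    per-site model is coverage-aware.  When ``groups`` maps subject -> group
    label, a site is dropped entirely if fewer than ``min_per_group``
    unmasked subjects remain in either group.
    """
    if min_coverage < 1:
        raise ValidationError("min_coverage must be >= 1")
    cov = matrix.coverage()
    low = matrix.mask & (cov < min_coverage)
    new_mask = matrix.mask & (cov >= min_coverage)

    keep_idx: list[int] = []
    dropped: list[str] = []
    if groups is not None:
        glab = np.array([groups[s] for s in matrix.subjects])
        for j, site in enumerate(matrix.sites):
            ok = True
            for g in GROUP_LABELS:
                if int(new_mask[glab == g, j].sum()) < min_per_group:
                    ok = False
                    break
            if ok:
                keep_idx.append(j)
            else:
                dropped.append(site.site_id)
    else:
        keep_idx = list(range(matrix.n_sites))

    out = MethylationCountMatrix(
        subjects=list(matrix.subjects),
        sites=[matrix.sites[i] for i in keep_idx],
        meth=matrix.meth[:, keep_idx].copy(),
        unmeth=matrix.unmeth[:, keep_idx].copy(),
        mask=new_mask[:, keep_idx].copy(),
    )
    report = FilterReport(
        min_coverage=min_coverage,
        min_per_group=min_per_group,
        n_cells=int(matrix.mask.sum()),
        n_masked_low_coverage=int(low.sum()),
        n_sites_in=matrix.n_sites,
        n_sites_dropped=len(dropped),
        dropped_site_ids=dropped,
        everything_masked=not bool(out.mask.any()),
    )
    if report.everything_masked:
        logger.warning("coverage filter masked every cell")
    return out, report


# ---------------------------------------------------------------------------
# Coverage-file I/O (Bismark coverage dialect)
# ---------------------------------------------------------------------------


def read_coverage_file(
    path: str | Path,
    subject_id: str | None = None,
    window: GenomicRegion | None = None,
) -> dict[tuple[str, int], tuple[int, int]]:
    """Read one subject's Bismark-style coverage file.

    Returns ``{(chromosome, position): (methylated, unmethylated)}``.  The
    percentage column is ignored on read.  Rows outside ``window`` (if
    given) are dropped with a logged count.
    """
    path = Path(path)
    out: dict[tuple[str, int], tuple[int, int]] = {}
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise CoverageParseError(
                    f"{path}:{lineno}: expected 6 tab-separated fields, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                pos = int(fields[1])
                end = int(fields[2])
                meth = int(fields[4])
                unmeth = int(fields[5])
            except ValueError as exc:
                raise CoverageParseError(f"{path}:{lineno}: {exc}") from exc
            if meth < 0 or unmeth < 0:
                raise ValidationError(f"{path}:{lineno}: negative read count")
            if pos <= 0 or end < pos:
                raise ValidationError(f"{path}:{lineno}: bad coordinates {pos}-{end}")
            if window is not None and not (
                chrom == window.chromosome and window.contains(pos)
            ):
                n_dropped += 1
                continue
            out[(chrom, pos)] = (meth, unmeth)
    if n_dropped:
        logger.info("%s: dropped %d rows outside target window", path, n_dropped)
    if not out:
        logger.warning("%s: no usable rows (empty coverage vector)", path)
    return out


def write_coverage_file(
    path: str | Path, counts: Mapping[tuple[str, int], tuple[int, int]]
) -> None:
    """Write counts in the 6-column Bismark coverage dialect."""
    with open(path, "w") as fh:
        for (chrom, pos), (meth, unmeth) in sorted(counts.items(), key=lambda kv: kv[0]):
            total = meth + unmeth
            pct = 100.0 * meth / total if total else 0.0
            fh.write(f"{chrom}\t{pos}\t{pos}\t{pct:.6g}\t{meth}\t{unmeth}\n")


# ---------------------------------------------------------------------------
# Sample sheet and registry I/O
# ---------------------------------------------------------------------------


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a phenotype table (one row per subject).

    Required columns: subject_id, group, age, bmi; scale columns optional
    with missing values allowed (complete-case analysis happens per model).
    """
    required = ["subject_id", "group", "age", "bmi"]
    for col in required:
        if col not in df.columns:
            raise ValidationError(f"sample sheet missing column {col!r}")
    if df["subject_id"].duplicated().any():
        raise ValidationError("duplicate subject ids in sample sheet")
    bad_group = ~df["group"].isin(GROUP_LABELS)
    if bad_group.any():
        raise ValidationError(
            f"unknown group labels: {sorted(df.loc[bad_group, 'group'].unique())}"
        )
    if (df["age"] <= 0).any() or (df["bmi"] <= 0).any():
        raise ValidationError("age and BMI must be positive")
    for col in SCALE_COLUMNS:
        if col in df.columns and (df[col].dropna() < 0).any():
            raise ValidationError(f"scale {col} has negative values")
    return df


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_phenotypes(df)


def write_sample_sheet(df: pd.DataFrame, path: str | Path) -> None:
    validate_phenotypes(df).to_csv(path, index=False)


REGISTRY_FLAG = "#coords=1-based-inclusive"


def write_region_registry(regions: Sequence[GenomicRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(REGISTRY_FLAG + "\n")
        for r in regions:
            fh.write(f"{r.chromosome}\t{r.start}\t{r.end}\t{r.name}\n")


def read_region_registry(path: str | Path) -> list[GenomicRegion]:
    """Read a BED-like registry; the 1-based-inclusive flag line is required
    so half-open BED intervals cannot be ingested silently."""
    regions = []
    with open(path) as fh:
        first = fh.readline().strip()
        if first != REGISTRY_FLAG:
            raise ValidationError(
                f"{path}: registry must declare {REGISTRY_FLAG!r} on its first line"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise CoverageParseError(f"{path}:{lineno}: expected 4 fields")
            chrom, start, end, name = fields
            regions.append(GenomicRegion(name, chrom, int(start), int(end)))
    return regions


def matrix_from_coverage_dir(
    counts_dir: str | Path,
    subjects: Sequence[str],
    sites: Sequence[CpGSite],
    window: GenomicRegion | None = None,
) -> MethylationCountMatrix:
    """Assemble a count matrix from one coverage file per subject
    (``<subject_id>.cov``); positions absent from a file get zero coverage
    and a masked cell."""
    counts_dir = Path(counts_dir)
    n, m = len(subjects), len(sites)
    meth = np.zeros((n, m), dtype=np.int64)
    unmeth = np.zeros((n, m), dtype=np.int64)
    mask = np.zeros((n, m), dtype=bool)
    key = {(s.chromosome, s.position): j for j, s in enumerate(sites)}
    for i, subj in enumerate(subjects):
        vec = read_coverage_file(counts_dir / f"{subj}.cov", subj, window=window)
        for k, (me, un) in vec.items():
            j = key.get(k)
            if j is None:
                continue
            meth[i, j] = me
            unmeth[i, j] = un
            mask[i, j] = me + un > 0
    return MethylationCountMatrix(list(subjects), list(sites), meth, unmeth, mask)


def write_wide_counts(matrix: MethylationCountMatrix, path: str | Path) -> None:
    """Wide TSV: one row per site, paired meth/unmeth columns per subject;
    masked cells written as 'NA/NA'."""
    cols: dict[str, list] = {
        "site_id": [s.site_id for s in matrix.sites],
        "chromosome": [s.chromosome for s in matrix.sites],
        "position": [s.position for s in matrix.sites],
    }
    for i, subj in enumerate(matrix.subjects):
        me = matrix.meth[i].astype(object).copy()
        un = matrix.unmeth[i].astype(object).copy()
        me[~matrix.mask[i]] = "NA"
        un[~matrix.mask[i]] = "NA"
        cols[f"{subj}.meth"] = me
        cols[f"{subj}.unmeth"] = un
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
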