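"""Shared domain types and strict readers/writers for every table in the pipeline.

Coordinate convention: all positions are 1-based and inclusive (VCF style)
everywhere in the package; the BED export in :mod:`nilqtl.markers` is the
single 0-based half-open surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = "NA"
GENOTYPE_ALPHABET = frozenset({"B", "G", MISSING})

#: canonical kinetic/fermentation trait names, as reported
TRAIT_NAMES = (
    "CO2max",
    "LP",
    "T35",
    "T50",
    "T70",
    "rate50_70",
    "RS",
    "ethanol",
)

_ROMAN = {
    "I": 1, "II": 2, "III": 3, "IV": 4, "V": 5, "VI": 6, "VII": 7,
    "VIII": 8, "IX": 9, "X": 10, "XI": 11, "XII": 12, "XIII": 13,
    "XIV": 14, "XV": 15, "XVI": 16,
}


class SchemaError(ValueError):
    """A table violated its declared schema."""


def chrom_sort_key(chrom: str) -> tuple:
    """Sort key placing roman-numeral chromosomes I..XVI in karyotype order.

    Non-roman names (e.g. ``chrIV`` stripped first, arbitrary contigs) sort
    after the numerals, lexicographically.
    """
    name = chrom[3:] if chrom.startswith("chr") else chrom
    if name in _ROMAN:
        return (0, _ROMAN[name], "")
    return (1, 0, chrom)


@dataclass(frozen=True, order=False)
class GenomePosition:
    """A 1-based genomic coordinate."""

    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise SchemaError("chromosome name must be non-empty")
        if self.pos < 1:
            raise SchemaError(f"position must be >= 1, got {self.pos}")

    def sort_key(self) -> tuple:
        return (*chrom_sort_key(self.chrom), self.pos)

    def __lt__(self, other: "GenomePosition") -> bool:
        return self.sort_key() < other.sort_key()


@dataclass(frozen=True)
class SnpRecord:
    """A bi-allelic SNP call for one strain against the reference."""

    position: GenomePosition
    ref_allele: str
    alt_allele: str
    quality: float
    genotype_quality: float
    zygosity: str  # "hom" | "het"

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise SchemaError("ref and alt alleles must differ")
        if self.quality < 0:
            raise SchemaError("quality must be >= 0")
        if self.zygosity not in ("hom", "het"):
            raise SchemaError(f"zygosity must be hom/het, got {self.zygosity!r}")


def make_marker_id(chrom: str, pos: int) -> str:
    """Marker naming convention ``<chrom>_<floor(pos/1000)>`` (e.g. IV_953)."""
    return f"{chrom}_{pos // 1000}"


@dataclass(frozen=True)
class Marker:
    """A validated bi-allelic marker with parental allele assignment."""

    id: str
    position: GenomePosition
    allele_b: str
    allele_g: str


@dataclass
class MarkerPanel:
    """An ordered collection of markers with unique ids."""

    markers: list[Marker] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [m.id for m in self.markers]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(f"duplicate marker ids in panel: {dup}")

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.markers]

    def by_id(self, marker_id: str) -> Marker:
        for m in self.markers:
            if m.id == marker_id:
                return m
        raise KeyError(marker_id)

    def sorted(self) -> "MarkerPanel":
        return MarkerPanel(sorted(self.markers, key=lambda m: m.position.sort_key()))


class GenotypeMatrix:
    """Segregant x marker genotype calls over the alphabet {B, G, NA}.

    Backed by a pandas DataFrame (index: segregant ids, columns: marker ids,
    values: "B"/"G"/NaN for missing).
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.index.duplicated().any():
            raise SchemaError("duplicate segregant ids")
        if frame.columns.duplicated().any():
            raise SchemaError("duplicate marker ids")
        values = frame.to_numpy(dtype=object)
        for i, seg in enumerate(frame.index):
            for j, mk in enumerate(frame.columns):
                v = values[i, j]
                if pd.isna(v) or v == MISSING:
                    values[i, j] = np.nan
                elif v not in ("B", "G"):
                    raise SchemaError(
                        f"invalid genotype call {v!r} at segregant {seg!r}, marker {mk!r}"
                    )
        self.frame = pd.DataFrame(values, index=frame.index, columns=frame.columns)

    @property
    def segregants(self) -> list[str]:
        return list(self.frame.index)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frame.shape

    def calls(self, marker_id: str) -> pd.Series:
        return self.frame[marker_id]

    def b_mask(self) -> pd.DataFrame:
        """Boolean frame: True where the call is B (NaN-safe, missing=False)."""
        return self.frame.eq("B")

    def called_mask(self) -> pd.DataFrame:
        return self.frame.notna()

    def subset(self, segregants: Sequence[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(self.frame.loc[list(segregants)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return self.frame.fillna(MISSING).equals(other.frame.fillna(MISSING))


class PhenotypeTable:
    """Long-format phenotype observations: (segregant, trait, replicate, value).

    Replicates share a row per observation; :meth:`trait_means` collapses them
    to per-segregant means, the unit used by the linkage scan.
    """

    REQUIRED_COLUMNS = ("segregant", "trait", "replicate", "value")

    def __init__(self, frame: pd.DataFrame):
        missing_cols = set(self.REQUIRED_COLUMNS) - set(frame.columns)
        if missing_cols:
            raise SchemaError(f"phenotype table missing columns: {sorted(missing_cols)}")
        frame = frame.loc[:, list(self.REQUIRED_COLUMNS)].copy()
        frame["value"] = pd.to_numeric(frame["value"], errors="raise")
        self._validate_ranges(frame)
        self.frame = frame.reset_index(drop=True)

    @staticmethod
    def _validate_ranges(frame: pd.DataFrame) -> None:
        vals = frame.dropna(subset=["value"])
        rs = vals.loc[vals["trait"] == "RS", "value"]
        if (rs < 0).any():
            raise SchemaError("RS values must be >= 0")
        times = vals.loc[vals["trait"].isin(["LP", "T35", "T50", "T70"]), "value"]
        if (times < 0).any():
            raise SchemaError("time traits must be >= 0")
        co2 = vals.loc[vals["trait"] == "CO2max", "value"]
        if (co2 <= 0).any():
            raise SchemaError("CO2max must be > 0 where present")

    @property
    def traits(self) -> list[str]:
        return sorted(self.frame["trait"].unique())

    @property
    def segregants(self) -> list[str]:
        return list(pd.unique(self.frame["segregant"]))

    def trait_means(self, trait: str) -> pd.Series:
        """Per-segregant replicate-mean values for one trait."""
        sub = self.frame[self.frame["trait"] == trait]
        if sub.empty:
            raise KeyError(f"trait {trait!r} not present")
        return sub.groupby("segregant", sort=False)["value"].mean()

    def trait_wide(self) -> pd.DataFrame:
        """Segregant x trait frame of replicate means."""
        return self.frame.pivot_table(
            index="segregant", columns="trait", values="value", aggfunc="mean"
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhenotypeTable):
            return NotImplemented
        a = self.frame.sort_values(list(self.REQUIRED_COLUMNS)).reset_index(drop=True)
        b = other.frame.sort_values(list(self.REQUIRED_COLUMNS)).reset_index(drop=True)
        return np.allclose(a["value"], b["value"], equal_nan=True) and (
            a.drop(columns="value").equals(b.drop(columns="value"))
        )


@dataclass
class FermentationCurve:
    """Cumulative CO2 release (g/L) over time (h) for one fermentation."""

    times: np.ndarray
    co2: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.co2 = np.asarray(self.co2, dtype=float)
        if self.times.shape != self.co2.shape:
            raise SchemaError("times and co2 must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise SchemaError("times must be strictly increasing")
        if not np.all(np.isfinite(self.co2)):
            raise SchemaError("co2 values must be finite")


# ---------------------------------------------------------------------------
# genotype matrix I/O
# ---------------------------------------------------------------------------

def read_genotype_matrix(path: str | Path) -> GenotypeMatrix:
    """Read a TSV genotype matrix (rows: segregants, columns: markers).

    Cells must be in {B, G, NA}; the header row carries marker ids and the
    first column segregant ids. ``#`` comment lines are ignored.
    """
    frame = pd.read_csv(
        path, sep="\t", comment="#", index_col=0, dtype=str, keep_default_na=False
    )
    frame = frame.mask(frame.isin([MISSING, ""]))
    return GenotypeMatrix(frame)


def write_genotype_matrix(matrix: GenotypeMatrix, path: str | Path) -> None:
    out = matrix.frame.fillna(MISSING)
    out.index.name = "segregant"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# SNP table I/O (VCF 4.x subset or TSV)
# ---------------------------------------------------------------------------

_TSV_SNP_COLUMNS = ["chrom", "pos", "ref", "alt", "qual", "gq", "zygosity"]


def _looks_like_vcf(path: Path) -> bool:
    if path.suffix.lower() == ".vcf":
        return True
    with open(path) as fh:
        first = fh.readline()
    return first.startswith("##fileformat=VCF")


def _sorted_records(records: list[SnpRecord], source: str) -> list[SnpRecord]:
    keys = [r.position.sort_key() for r in records]
    if keys != sorted(keys):
        log.warning("SNP table %s was not coordinate-sorted; sorting", source)
        records = sorted(records, key=lambda r: r.position.sort_key())
    return records


def read_snp_table(path: str | Path) -> list[SnpRecord]:
    """Read SNPs from a single-sample VCF 4.x subset or a 7-column TSV.

    Records are returned in ascending (chrom, pos) order; unsorted input is
    sorted with a logged warning. 1-based positions are preserved.
    """
    path = Path(path)
    if _looks_like_vcf(path):
        return _read_vcf(path)
    frame = pd.read_csv(path, sep="\t", comment="#")
    missing = set(_TSV_SNP_COLUMNS) - set(frame.columns)
    if missing:
        raise SchemaError(f"SNP TSV missing columns: {sorted(missing)}")
    records = [
        SnpRecord(
            position=GenomePosition(str(row.chrom), int(row.pos)),
            ref_allele=str(row.ref),
            alt_allele=str(row.alt),
            quality=float(row.qual),
            genotype_quality=float(row.gq),
            zygosity=str(row.zygosity),
        )
        for row in frame.itertuples()
    ]
    return _sorted_records(records, str(path))


def _read_vcf(path: Path) -> list[SnpRecord]:
    import pysam

    records: list[SnpRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise SchemaError(
                    f"multi-allelic or ALT-less record at {rec.chrom}:{rec.pos}"
                )
            gq = float("nan")
            zygosity = "hom"
            if samples:
                sample = rec.samples[samples[0]]
                if "GQ" in sample and sample["GQ"] is not None:
                    gq = float(sample["GQ"])
                gt = sample.get("GT")
                if gt is not None and None not in gt and len(set(gt)) > 1:
                    zygosity = "het"
            records.append(
                SnpRecord(
                    position=GenomePosition(rec.chrom, rec.pos),
                    ref_allele=rec.ref,
                    alt_allele=rec.alts[0],
                    quality=float(rec.qual if rec.qual is not None else 0.0),
                    genotype_quality=gq,
                    zygosity=zygosity,
                )
            )
    return _sorted_records(records, str(path))


def write_snp_table(records: Iterable[SnpRecord], path: str | Path) -> None:
    """Write SNP records as the 7-column TSV understood by :func:`read_snp_table`."""
    rows = [
        {
            "chrom": r.position.chrom,
            "pos": r.position.pos,
            "ref": r.ref_allele,
            "alt": r.alt_allele,
            "qual": r.quality,
            "gq": r.genotype_quality,
            "zygosity": r.zygosity,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_TSV_SNP_COLUMNS).to_csv(path, sep="\t", index=False)


def write_vcf(records: Iterable[SnpRecord], path: str | Path, sample: str = "strain") -> None:
    """Write records as a minimal single-sample VCF 4.2 (uncompressed text)."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">',
    ]
    chroms = []
    for r in records if isinstance(records, list) else list(records):
        if r.position.chrom not in chroms:
            chroms.append(r.position.chrom)
    records = list(records)
    for chrom in chroms:
        lines.append(f"##contig=<ID={chrom}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample
    )
    for r in records:
        gt = "1/1" if r.zygosity == "hom" else "0/1"
        gq = int(round(r.genotype_quality)) if np.isfinite(r.genotype_quality) else "."
        lines.append(
            f"{r.position.chrom}\t{r.position.pos}\t.\t{r.ref_allele}\t"
            f"{r.alt_allele}\t{r.quality:g}\t.\t.\tGT:GQ\t{gt}:{gq}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# marker panel I/O
# ---------------------------------------------------------------------------

def write_marker_panel(panel: MarkerPanel, path: str | Path) -> None:
    rows = [
        {
            "marker": m.id,
            "chrom": m.position.chrom,
            "pos": m.position.pos,
            "allele_b": m.allele_b,
            "allele_g": m.allele_g,
        }
        for m in panel
    ]
    pd.DataFrame(rows, columns=["marker", "chrom", "pos", "allele_b", "allele_g"]).to_csv(
        path, sep="\t", index=False
    )


def read_marker_panel(path: str | Path) -> MarkerPanel:
    frame = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    markers = [
        Marker(
            id=str(row.marker),
            position=GenomePosition(str(row.chrom), int(row.pos)),
            allele_b=str(row.allele_b),
            allele_g=str(row.allele_g),
        )
        for row in frame.itertuples()
    ]
    return MarkerPanel(markers)


# ---------------------------------------------------------------------------
# phenotype table I/O
# ---------------------------------------------------------------------------

def read_phenotype_table(path: str | Path) -> PhenotypeTable:
    frame = pd.read_csv(path, sep="\t", comment="#")
    return PhenotypeTable(frame)


def write_phenotype_table(table: PhenotypeTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# fermentation curve I/O
# ---------------------------------------------------------------------------

def read_curve(path: str | Path, **meta) -> FermentationCurve:
    """Read a CSV time series with columns ``time_h, co2_g_per_L``."""
    frame = pd.read_csv(path, comment="#")
    missing = {"time_h", "co2_g_per_L"} - set(frame.columns)
    if missing:
        raise SchemaError(f"curve CSV missing columns: {sorted(missing)}")
    return FermentationCurve(
        times=frame["time_h"].to_numpy(float),
        co2=frame["co2_g_per_L"].to_numpy(float),
        meta=meta,
    )


def write_curve(curve: FermentationCurve, path: str | Path) -> None:
    pd.DataFrame({"time_h": curve.times, "co2_g_per_L": curve.co2}).to_csv(
        path, index=False, float_format="%.6f"
    )


# ---------------------------------------------------------------------------
# linkage result I/O
# ---------------------------------------------------------------------------

LINKAGE_COLUMNS = [
    "marker",
    "chrom",
    "pos",
    "trait",
    "neglog10_p",
    "threshold5",
    "threshold10",
    "significant5",
    "significant10",
]


def write_linkage_table(result, path: str | Path) -> None:
    """Write a linkage scan result (anything with ``.to_frame()``) as TSV."""
    frame = result.to_frame() if hasattr(result, "to_frame") else pd.DataFrame(result)
    if frame.empty:
        raise SchemaError("refusing to write an empty linkage result")
    missing = set(LINKAGE_COLUMNS) - set(frame.columns)
    if missing:
        raise SchemaError(f"linkage frame missing columns: {sorted(missing)}")
    frame.loc[:, LINKAGE_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_linkage_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
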