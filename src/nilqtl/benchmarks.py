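"""Recomputation of published benchmark quantities from their source data.

Two groups of quantities are supported:

* supplementary-table counts (validated marker panel size, donor-inheritance
  occurrence counts in the seven extreme segregants, filtered WGS-SNP count,
  non-common tiling position count, per-segregant donor proportions), from a
  supplementary workbook that must be supplied locally;
* protein-truncation numbers from the two causal coding variants applied to
  the public reference coding sequences of OYE2 (YHR179W) and VHS1
  (YDR247W), from locally supplied FASTA files.

Neither input ships with the package: the workbook is distributed with the
original article and the reference CDS comes from the S288C genome. Both
loaders accept standard layouts and fail loudly otherwise.

Expected supplementary layout (XLSX with three sheets, or a directory with
``ngs_snps.tsv``, ``tiling_snps.tsv``, ``marker_occurrence.tsv``):

* sheet 1 / ``ngs_snps``: one row per sequencing SNP with at least
  ``qual`` and ``zygosity`` (hom/het) columns;
* sheet 2 / ``tiling_snps``: one row per tiling-predicted SNP with
  ``strain`` (B/G), ``chrom`` and ``pos``;
* sheet 3 / ``marker_occurrence``: one row per validated marker with
  ``chrom``, ``pos`` and one column per genotyped segregant holding B/G
  calls (columns whose values are all in {B, G, NA}).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import GenomePosition, GenotypeMatrix, SnpRecord
from .effects import consequence
from .markers import MatchReport, count_occurrences, filter_wgs_snps

#: printed matching counts behind the headline FDR figure
PREDICTED_NONCOMMON = 3397
CORRECTLY_ASSIGNED = 1204

OYE2_VARIANT = "c.229_230delTC"
VHS1_VARIANT = "c.1116C>A"


def tiling_fdr_percent(
    n_predicted: int = PREDICTED_NONCOMMON, n_matched: int = CORRECTLY_ASSIGNED
) -> float:
    """Array-prediction false discovery rate, percent: 100 * (1 - matched/predicted)."""
    report = MatchReport(n_predicted=n_predicted, n_matched=n_matched, window=20)
    return 100.0 * report.fdr


def load_supplementary_tables(path: str | Path) -> dict[str, pd.DataFrame]:
    """Load the three supplementary sheets from an XLSX file or TSV directory."""
    path = Path(path)
    names = ["ngs_snps", "tiling_snps", "marker_occurrence"]
    if path.is_dir():
        return {n: pd.read_csv(path / f"{n}.tsv", sep="\t") for n in names}
    sheets = pd.read_excel(path, sheet_name=[0, 1, 2])
    return dict(zip(names, (sheets[i] for i in range(3))))


def _occurrence_matrix(sheet: pd.DataFrame) -> GenotypeMatrix:
    """Transpose the marker-occurrence sheet into a segregant x marker matrix."""
    call_cols = [
        c
        for c in sheet.columns
        if sheet[c].dropna().astype(str).str.upper().isin(["B", "G", "NA"]).all()
        and sheet[c].notna().any()
        and c.lower() not in ("chrom", "pos", "marker")
    ]
    if not call_cols:
        raise ValueError("no B/G segregant call columns found in occurrence sheet")
    marker_ids = (
        sheet["marker"].astype(str)
        if "marker" in sheet.columns
        else sheet.index.astype(str)
    )
    calls = sheet[call_cols].astype(str).apply(lambda c: c.str.upper()).T
    calls.columns = marker_ids
    calls = calls.mask(calls == "NA")
    return GenotypeMatrix(calls)


def supplementary_counts(tables: dict[str, pd.DataFrame]) -> dict[str, float]:
    """Recompute the published counts from the supplementary sheets.

    Returns keys: ``wgs_snps`` (quality-filtered sequencing SNPs),
    ``noncommon_positions`` (tiling positions in exactly one parental set),
    ``validated_markers``, ``b_in_any`` (markers with donor inheritance in at
    least one genotyped segregant), ``b_in_more_than_4`` and
    ``max_b_proportion_pct``.
    """
    ngs = tables["ngs_snps"]
    records = [
        SnpRecord(
            GenomePosition(str(row.get("chrom", "NA")) or "NA", int(row.get("pos", 1))),
            "N",
            "V",
            float(row["qual"]),
            float(row.get("gq", np.inf)),
            str(row["zygosity"]).lower(),
        )
        for _, row in ngs.iterrows()
    ]
    wgs_count = len(filter_wgs_snps(records))

    tiling = tables["tiling_snps"]
    sets: dict[str, set] = {}
    for strain, group in tiling.groupby(tiling["strain"].astype(str).str.upper()):
        sets[strain] = set(zip(group["chrom"].astype(str), group["pos"].astype(int)))
    if set(sets) != {"B", "G"}:
        raise ValueError(f"expected strains B and G in tiling sheet, got {sorted(sets)}")
    noncommon = len(sets["B"] ^ sets["G"])

    occ = tables["marker_occurrence"]
    matrix = _occurrence_matrix(occ)
    per_marker, per_segregant = count_occurrences(matrix, matrix.segregants)
    return {
        "wgs_snps": wgs_count,
        "noncommon_positions": noncommon,
        "validated_markers": int(matrix.shape[1]),
        "b_in_any": int((per_marker["b_count"] >= 1).sum()),
        "b_in_more_than_4": int((per_marker["b_count"] > 4).sum()),
        "max_b_proportion_pct": round(float(per_segregant.max()) * 100, 1),
    }


def _read_first_fasta(path: str | Path) -> str:
    from Bio import SeqIO

    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq).upper()


def truncation_benchmarks(
    oye2_cds_path: str | Path, vhs1_cds_path: str | Path
) -> dict[str, float]:
    """Apply the two causal variants to the reference coding sequences.

    Returns ``oye2_stop_codon_index`` and ``oye2_reference_length`` for the
    two-base deletion, and ``vhs1_mutant_length`` / ``vhs1_reference_length``
    for the nonsense substitution, all recomputed by translation.
    """
    oye2 = consequence(_read_first_fasta(oye2_cds_path), OYE2_VARIANT)
    vhs1 = consequence(_read_first_fasta(vhs1_cds_path), VHS1_VARIANT)
    if oye2.category != "frameshift":
        raise ValueError(f"OYE2 variant classified {oye2.category}, expected frameshift")
    if vhs1.category != "nonsense":
        raise ValueError(f"VHS1 variant classified {vhs1.category}, expected nonsense")
    return {
        "oye2_stop_codon_index": oye2.stop_codon_index,
        "oye2_reference_length": oye2.reference_length,
        "oye2_p_notation": oye2.p_notation,
        "vhs1_mutant_length": vhs1.mutant_length,
        "vhs1_reference_length": vhs1.reference_length,
        "vhs1_p_notation": vhs1.p_notation,
    }
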