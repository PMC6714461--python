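"""Building the validated bi-allelic marker panel.

Covers the selective-genotyping support chain: z-score signal segmentation
into SNP predictions, quality filtering of sequencing SNPs, window matching
of predictions against sequencing (with FDR), parental-origin assignment,
occurrence counting in extreme segregants, clustering of introgressed
regions, and read-per-kb deletion flagging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    GenomePosition,
    GenotypeMatrix,
    Marker,
    MarkerPanel,
    SnpRecord,
    chrom_sort_key,
    make_marker_id,
)

log = logging.getLogger(__name__)

DEFAULT_Z_THRESHOLD = 2.5
DEFAULT_MIN_RUN = 10
DEFAULT_MATCH_WINDOW = 20
DEFAULT_MAX_GAP = 50_000
DEFAULT_RATIO_THRESHOLD = 0.1
COVERAGE_PSEUDOCOUNT = 0.5


@dataclass
class SignalTrack:
    """Per-position z-scored hybridization signal on one chromosome."""

    chrom: str
    positions: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.z = np.asarray(self.z, dtype=float)
        if self.positions.shape != self.z.shape:
            raise ValueError("positions and z must have equal length")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("position grid must be strictly increasing")


@dataclass(frozen=True)
class PredictionRecord:
    """One predicted SNP region: peak position plus the supporting run."""

    position: GenomePosition
    peak_z: float
    span_start: int
    span_end: int  # inclusive, 1-based

    def __post_init__(self) -> None:
        if self.span_end - self.span_start + 1 < 1:
            raise ValueError("region span must cover >= 1 position")


@dataclass
class MatchReport:
    """Outcome of window-matching predictions against sequencing SNPs."""

    n_predicted: int
    n_matched: int
    window: int
    matches: list[tuple[PredictionRecord, SnpRecord, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_matched > self.n_predicted:
            raise ValueError("matched count cannot exceed predicted count")

    @property
    def fdr(self) -> Optional[float]:
        """Fraction of predictions not confirmed; None when nothing predicted."""
        if self.n_predicted == 0:
            return None
        return 1.0 - self.n_matched / self.n_predicted

    def summary(self) -> dict:
        return {
            "n_predicted": self.n_predicted,
            "n_matched": self.n_matched,
            "window": self.window,
            "fdr": self.fdr,
        }


@dataclass
class IntrogressedRegion:
    chrom: str
    start: int
    end: int
    member_ids: list[str]
    max_occurrence: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start must be <= end")
        if not self.member_ids:
            raise ValueError("region must have members")


# ---------------------------------------------------------------------------
# signal segmentation
# ---------------------------------------------------------------------------

def call_snp_regions(
    track: SignalTrack,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    min_run: int = DEFAULT_MIN_RUN,
) -> list[PredictionRecord]:
    """Call SNP predictions as maximal runs of consecutive grid positions
    with ``z > z_threshold`` spanning at least ``min_run`` positions.

    The prediction position is the run's signal argmax (first maximum on
    ties). Consecutive means adjacent on the 1-bp sense: a gap in the
    position grid breaks a run.
    """
    if len(track.positions) == 0:
        return []
    above = track.z > z_threshold
    predictions: list[PredictionRecord] = []
    run_start = None
    for i in range(len(above) + 1):
        contiguous = (
            i < len(above)
            and above[i]
            and (run_start is None or track.positions[i] == track.positions[i - 1] + 1)
        )
        if contiguous:
            if run_start is None:
                run_start = i
            continue
        if run_start is not None:
            run = slice(run_start, i)
            length = track.positions[i - 1] - track.positions[run_start] + 1
            if length >= min_run:
                peak = run_start + int(np.argmax(track.z[run]))
                predictions.append(
                    PredictionRecord(
                        position=GenomePosition(track.chrom, int(track.positions[peak])),
                        peak_z=float(track.z[peak]),
                        span_start=int(track.positions[run_start]),
                        span_end=int(track.positions[i - 1]),
                    )
                )
            run_start = None
        # a kept above-threshold point that broke contiguity starts a new run
        if i < len(above) and above[i]:
            run_start = i
    return predictions


# ---------------------------------------------------------------------------
# WGS SNP filtering
# ---------------------------------------------------------------------------

def filter_wgs_snps(
    records: Iterable[SnpRecord],
    min_qual: float = 30.0,
    min_gq: float = 20.0,
    require_hom: bool = True,
) -> list[SnpRecord]:
    """Keep records with QUAL >= min_qual, GQ >= min_gq and (optionally)
    homozygous genotype; input order is preserved."""
    kept = []
    for r in records:
        if r.quality < min_qual:
            continue
        if np.isfinite(r.genotype_quality) and r.genotype_quality < min_gq:
            continue
        if require_hom and r.zygosity != "hom":
            continue
        kept.append(r)
    return kept


# ---------------------------------------------------------------------------
# prediction / sequencing reconciliation
# ---------------------------------------------------------------------------

def match_predictions(
    predictions: Sequence[PredictionRecord],
    wgs_snps: Sequence[SnpRecord],
    window: int = DEFAULT_MATCH_WINDOW,
) -> MatchReport:
    """One-to-one matching of predictions to sequencing SNPs within a window.

    Predictions are swept in coordinate order and each is greedily assigned
    the lowest-position unconsumed SNP on the same chromosome with
    ``|delta| <= window`` (ties toward lower position by construction). For
    this interval structure the sweep attains maximum matching cardinality.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    preds = sorted(predictions, key=lambda p: p.position.sort_key())
    snps = sorted(wgs_snps, key=lambda s: s.position.sort_key())
    if preds == [] :
        return MatchReport(n_predicted=0, n_matched=0, window=window)

    by_chrom: dict[str, list[SnpRecord]] = {}
    for s in snps:
        by_chrom.setdefault(s.position.chrom, []).append(s)

    matches: list[tuple[PredictionRecord, SnpRecord, int]] = []
    cursor: dict[str, int] = {c: 0 for c in by_chrom}
    for p in preds:
        chrom = p.position.chrom
        if chrom not in by_chrom:
            continue
        pool = by_chrom[chrom]
        i = cursor[chrom]
        # skip SNPs that can no longer match any later prediction on this sweep
        while i < len(pool) and pool[i].position.pos < p.position.pos - window:
            i += 1
        cursor[chrom] = i
        if i < len(pool) and abs(pool[i].position.pos - p.position.pos) <= window:
            matches.append((p, pool[i], abs(pool[i].position.pos - p.position.pos)))
            cursor[chrom] = i + 1
    return MatchReport(
        n_predicted=len(preds), n_matched=len(matches), window=window, matches=matches
    )


def match_report_frame(report: MatchReport) -> pd.DataFrame:
    rows = [
        {
            "chrom": p.position.chrom,
            "predicted_pos": p.position.pos,
            "snp_pos": s.position.pos,
            "distance": d,
        }
        for p, s, d in report.matches
    ]
    return pd.DataFrame(rows, columns=["chrom", "predicted_pos", "snp_pos", "distance"])


# ---------------------------------------------------------------------------
# parental origin
# ---------------------------------------------------------------------------

def assign_parental_origin(
    positions: Iterable[GenomePosition],
    parent_b_snps: Sequence[SnpRecord],
    parent_g_snps: Sequence[SnpRecord],
) -> MarkerPanel:
    """Build the B/G marker panel from candidate positions.

    A position carried as a non-reference SNP by exactly one parent becomes a
    marker: that parent's alt allele on its side, the shared reference allele
    on the other. Positions variant in both or neither parent are dropped
    with a log message (not discriminating).
    """
    b_by_pos = {(s.position.chrom, s.position.pos): s for s in parent_b_snps}
    g_by_pos = {(s.position.chrom, s.position.pos): s for s in parent_g_snps}
    markers: list[Marker] = []
    n_dropped = 0
    for pos in positions:
        key = (pos.chrom, pos.pos)
        in_b, in_g = key in b_by_pos, key in g_by_pos
        if in_b == in_g:  # both or neither
            n_dropped += 1
            continue
        snp = b_by_pos[key] if in_b else g_by_pos[key]
        allele_b = snp.alt_allele if in_b else snp.ref_allele
        allele_g = snp.ref_allele if in_b else snp.alt_allele
        markers.append(
            Marker(
                id=make_marker_id(pos.chrom, pos.pos),
                position=pos,
                allele_b=allele_b,
                allele_g=allele_g,
            )
        )
    if n_dropped:
        log.info("dropped %d non-discriminating candidate positions", n_dropped)
    # the kb-based naming can collide for nearby positions: disambiguate
    seen: dict[str, int] = {}
    unique: list[Marker] = []
    for m in markers:
        if m.id in seen:
            seen[m.id] += 1
            m = Marker(f"{m.id}.{seen[m.id]}", m.position, m.allele_b, m.allele_g)
        else:
            seen[m.id] = 0
        unique.append(m)
    return MarkerPanel(unique).sorted()


# ---------------------------------------------------------------------------
# occurrence counting in extreme segregants
# ---------------------------------------------------------------------------

def count_occurrences(
    matrix: GenotypeMatrix,
    selected: Sequence[str],
    min_count: int = 4,
) -> tuple[pd.DataFrame, pd.Series]:
    """Count B-allele inheritance of each marker across selected segregants.

    Returns ``(per_marker, per_segregant)``: per-marker B counts with a
    ``candidate`` flag for counts strictly greater than ``min_count``, and the
    per-segregant B-proportion (B calls over called markers).
    """
    sub = matrix.subset(selected)
    b = sub.b_mask()
    called = sub.called_mask()
    per_marker = pd.DataFrame(
        {
            "b_count": b.sum(axis=0).astype(int),
            "n_called": called.sum(axis=0).astype(int),
        }
    )
    per_marker["candidate"] = per_marker["b_count"] > min_count
    per_segregant = b.sum(axis=1) / called.sum(axis=1)
    per_segregant.name = "b_proportion"
    return per_marker, per_segregant


# ---------------------------------------------------------------------------
# region clustering
# ---------------------------------------------------------------------------

def cluster_regions(
    panel: MarkerPanel,
    marker_ids: Sequence[str],
    max_gap: int = DEFAULT_MAX_GAP,
    occurrences: Optional[pd.Series] = None,
) -> list[IntrogressedRegion]:
    """Single-linkage clustering of flagged markers along each chromosome.

    Same-chromosome markers whose inter-marker gap is <= ``max_gap`` merge
    into one region; region bounds are min/max member positions.
    """
    flagged = sorted(
        (panel.by_id(i) for i in marker_ids), key=lambda m: m.position.sort_key()
    )
    regions: list[IntrogressedRegion] = []
    for m in flagged:
        if (
            regions
            and regions[-1].chrom == m.position.chrom
            and m.position.pos - regions[-1].end <= max_gap
        ):
            regions[-1].end = m.position.pos
            regions[-1].member_ids.append(m.id)
        else:
            regions.append(
                IntrogressedRegion(
                    chrom=m.position.chrom,
                    start=m.position.pos,
                    end=m.position.pos,
                    member_ids=[m.id],
                )
            )
    if occurrences is not None:
        for r in regions:
            r.max_occurrence = int(max(occurrences.get(i, 0) for i in r.member_ids))
    return regions


def regions_to_bed(regions: Sequence[IntrogressedRegion], path: str | Path) -> None:
    """Write regions as BED (the package's only 0-based half-open output)."""
    lines = [
        f"{r.chrom}\t{r.start - 1}\t{r.end}\tn_markers={len(r.member_ids)};max_occ={r.max_occurrence}"
        for r in sorted(regions, key=lambda r: (chrom_sort_key(r.chrom), r.start))
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# coverage-based deletion detection
# ---------------------------------------------------------------------------

def detect_coverage_deletions(
    coverage: pd.DataFrame,
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
    pseudocount: float = COVERAGE_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Flag genes deleted in strain A relative to strain B by read-per-kb ratio.

    Expects columns ``gene, chrom, start, end, rpk_a, rpk_b``; a gene is
    flagged when ``(rpk_a + eps) / (rpk_b + eps) <= ratio_threshold``.
    Contiguous flagged genes (in coordinate order per chromosome) share a
    ``block`` id; unflagged genes carry block ``-1``.
    """
    required = {"gene", "chrom", "start", "end", "rpk_a", "rpk_b"}
    missing = required - set(coverage.columns)
    if missing:
        raise ValueError(f"coverage table missing columns: {sorted(missing)}")
    if (coverage[["rpk_a", "rpk_b"]] < 0).any().any():
        raise ValueError("coverage must be >= 0")
    out = coverage.copy()
    out["ratio"] = (out["rpk_a"] + pseudocount) / (out["rpk_b"] + pseudocount)
    out["deleted_in_a"] = out["ratio"] <= ratio_threshold
    out = out.sort_values(
        ["chrom", "start"], key=lambda c: c.map(chrom_sort_key) if c.name == "chrom" else c
    ).reset_index(drop=True)
    block = -np.ones(len(out), dtype=int)
    current = -1
    prev_flag, prev_chrom = False, None
    for i, row in out.iterrows():
        if row["deleted_in_a"]:
            if not (prev_flag and row["chrom"] == prev_chrom):
                current += 1
            block[i] = current
        prev_flag, prev_chrom = bool(row["deleted_in_a"]), row["chrom"]
    out["block"] = block
    return out
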