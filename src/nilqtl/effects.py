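"""Protein-level consequences of small coding-sequence variants.

Variants are expressed in CDS space with c.-style notation (substitution,
deletion, insertion), applied to a reference coding sequence, and classified
by comparing the reference and mutant translations: synonymous, missense,
nonsense (premature stop from a substitution), frameshift, or no_stop.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

STOP = "*"

_SUB_RE = re.compile(r"^c\.(\d+)([ACGT]+)>([ACGT]+)$")
_DEL_RE = re.compile(r"^c\.(\d+)(?:_(\d+))?del([ACGT]*)$")
_INS_RE = re.compile(r"^c\.(\d+)_(\d+)ins([ACGT]+)$")


@dataclass(frozen=True)
class CdsVariant:
    """A small variant in 1-based coding-sequence coordinates."""

    kind: str  # substitution | deletion | insertion
    start: int
    end: int  # inclusive; for insertions, the base after the insertion point
    ref: str
    alt: str

    @property
    def notation(self) -> str:
        if self.kind == "substitution":
            return f"c.{self.start}{self.ref}>{self.alt}"
        if self.kind == "deletion":
            span = f"{self.start}" if self.start == self.end else f"{self.start}_{self.end}"
            return f"c.{span}del{self.ref}"
        return f"c.{self.start}_{self.end}ins{self.alt}"

    @classmethod
    def parse(cls, notation: str) -> "CdsVariant":
        """Parse a c.-style variant string (e.g. ``c.229_230delTC``)."""
        text = notation.strip()
        if m := _SUB_RE.match(text):
            pos, ref, alt = int(m.group(1)), m.group(2), m.group(3)
            if len(ref) != len(alt):
                raise ValueError(f"substitution alleles must have equal length: {text}")
            return cls("substitution", pos, pos + len(ref) - 1, ref, alt)
        if m := _DEL_RE.match(text):
            start = int(m.group(1))
            end = int(m.group(2)) if m.group(2) else start
            ref = m.group(3)
            if ref and len(ref) != end - start + 1:
                raise ValueError(f"deleted bases inconsistent with span: {text}")
            return cls("deletion", start, end, ref, "")
        if m := _INS_RE.match(text):
            start, end, alt = int(m.group(1)), int(m.group(2)), m.group(3)
            if end != start + 1:
                raise ValueError(f"insertion must sit between adjacent bases: {text}")
            return cls("insertion", start, end, "", alt)
        raise ValueError(f"unrecognized variant notation: {notation!r}")

    @property
    def length_change(self) -> int:
        if self.kind == "deletion":
            return -(self.end - self.start + 1)
        if self.kind == "insertion":
            return len(self.alt)
        return 0


@dataclass(frozen=True)
class ProteinConsequence:
    category: str  # synonymous | missense | nonsense | frameshift | no_stop
    p_notation: str
    mutant_length: int  # residues strictly before the (new) stop
    reference_length: int
    truncation: int  # residues lost relative to the reference
    stop_codon_index: Optional[int] = None  # 1-based codon index of the new stop


def _check_cds(cds: str) -> str:
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    if not cds.startswith("ATG"):
        raise ValueError("CDS must start with ATG")
    if cds[-3:] not in ("TAA", "TAG", "TGA"):
        raise ValueError("CDS must end with a stop codon")
    return cds


def _shift_3prime(cds: str, variant: CdsVariant) -> CdsVariant:
    """Right-align (3'-rule) an indel within a repeat before annotation."""
    if variant.kind == "deletion":
        start, end = variant.start, variant.end
        while end < len(cds) and cds[end] == cds[start - 1]:
            start += 1
            end += 1
        return CdsVariant("deletion", start, end, cds[start - 1 : end], "")
    if variant.kind == "insertion":
        start, ins = variant.start, variant.alt
        while start < len(cds) and cds[start] == ins[0]:
            ins = ins[1:] + ins[0]
            start += 1
        return CdsVariant("insertion", start, start + 1, "", ins)
    return variant


def apply_variant(cds: str, variant: CdsVariant | str) -> str:
    """Apply a CDS-space variant; the stated ref bases must match the CDS."""
    if isinstance(variant, str):
        variant = CdsVariant.parse(variant)
    cds = cds.upper()
    if variant.end > len(cds) and variant.kind != "insertion":
        raise ValueError(f"variant span {variant.start}_{variant.end} outside CDS")
    if variant.kind == "substitution":
        found = cds[variant.start - 1 : variant.end]
        if found != variant.ref:
            raise ValueError(
                f"reference mismatch at c.{variant.start}: expected "
                f"{variant.ref!r}, found {found!r}"
            )
        return cds[: variant.start - 1] + variant.alt + cds[variant.end :]
    if variant.kind == "deletion":
        found = cds[variant.start - 1 : variant.end]
        if variant.ref and found != variant.ref:
            raise ValueError(
                f"reference mismatch at c.{variant.start}_{variant.end}: expected "
                f"{variant.ref!r}, found {found!r}"
            )
        return cds[: variant.start - 1] + cds[variant.end :]
    # insertion between start and end
    return cds[: variant.start] + variant.alt + cds[variant.start :]


def translate(dna: str) -> tuple[str, bool]:
    """Standard-code translation from position 1 up to (excluding) the first
    stop codon. Returns ``(peptide, has_stop)``."""
    dna = dna.upper()
    if len(dna) < 3:
        raise ValueError("need at least one codon")
    usable = dna[: len(dna) - len(dna) % 3]
    full = str(Seq(usable).translate())
    stop = full.find(STOP)
    if stop == -1:
        return full, False
    return full[:stop], True


def consequence(cds: str, variant: CdsVariant | str) -> ProteinConsequence:
    """Classify a CDS variant by comparing reference and mutant translations."""
    if isinstance(variant, str):
        variant = CdsVariant.parse(variant)
    cds = _check_cds(cds)
    if variant.kind in ("deletion", "insertion"):
        variant = _shift_3prime(cds, variant)
    mutant = apply_variant(cds, variant)
    ref_protein, _ = translate(cds)
    mut_protein, mut_has_stop = translate(mutant)
    ref_len = len(ref_protein)
    mut_len = len(mut_protein)
    truncation = ref_len - mut_len
    stop_index = mut_len + 1 if mut_has_stop else None

    if mut_protein == ref_protein and mut_has_stop and variant.length_change == 0:
        return ProteinConsequence("synonymous", "p.=", mut_len, ref_len, 0, stop_index)

    frameshift = variant.length_change % 3 != 0
    if frameshift:
        first = _first_difference(ref_protein, mut_protein)
        aa = seq3(ref_protein[first]) if first < ref_len else "Ter"
        ter = f"Ter{stop_index}" if mut_has_stop else "Ter?"
        notation = f"p.{aa}{first + 1}fs{ter}"
        category = "frameshift" if mut_has_stop else "no_stop"
        return ProteinConsequence(category, notation, mut_len, ref_len, truncation, stop_index)

    if not mut_has_stop:
        return ProteinConsequence(
            "no_stop", f"p.Ter{ref_len + 1}ext?", mut_len, ref_len, truncation, None
        )

    if variant.kind == "substitution" and mut_len < ref_len:
        # premature stop introduced by a substitution
        k = mut_len + 1
        aa = seq3(ref_protein[k - 1])
        return ProteinConsequence("nonsense", f"p.{aa}{k}*", mut_len, ref_len, truncation, k)

    first = _first_difference(ref_protein, mut_protein)
    if first >= min(ref_len, mut_len) and ref_len == mut_len:
        return ProteinConsequence("synonymous", "p.=", mut_len, ref_len, 0, stop_index)
    aa_ref = seq3(ref_protein[first]) if first < ref_len else "Ter"
    aa_mut = seq3(mut_protein[first]) if first < mut_len else "Ter"
    return ProteinConsequence(
        "missense", f"p.{aa_ref}{first + 1}{aa_mut}", mut_len, ref_len, truncation, stop_index
    )


def _first_difference(a: str, b: str) -> int:
    for i, (x, y) in enumerate(zip(a, b)):
        if x != y:
            return i
    return min(len(a), len(b))
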