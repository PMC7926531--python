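"""SNP calling from aligned consensus sequences and coding-effect annotation.

The workflow mirrors a Sanger candidate-gene study: per-sample consensus
sequences (heterozygous positions as two-fold IUPAC codes) are compared
column-by-column against the reference region, calls are lifted between
assemblies by a verified constant offset, mapped into the coding sequence
of a gene model, and classified as intronic / synonymous / missense /
nonsense.

The gene model is CDS-only: an ordered list of exon intervals, in
*transcript* order, whose concatenated length equals the CDS length.  For
a minus-strand gene, transcript order means decreasing genomic
coordinates, and the CDS index increases as the genomic coordinate
decreases within each exon; substituted bases are complemented before
being placed into the codon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
from Bio.Seq import Seq

from .errors import DegenerateStatisticError, ValidationError

#: two-fold IUPAC ambiguity codes, the Sanger-consensus encoding of
#: heterozygous sites.
IUPAC_HET = {
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

EFFECT_CLASSES = ("intronic", "synonymous", "missense", "nonsense")


@dataclass(frozen=True)
class GeneModel:
    """A CDS-only gene model: exons in transcript order plus the CDS text.

    ``exons`` are 1-based inclusive genomic intervals.  ``cds_sequence``
    is given in coding orientation (i.e. already reverse-complemented for
    a minus-strand gene) and must tile the exons exactly.
    """

    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_sequence: str
    require_start: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        object.__setattr__(self, "exons", tuple((int(s), int(e)) for s, e in self.exons))
        object.__setattr__(self, "cds_sequence", self.cds_sequence.upper())
        for s, e in self.exons:
            if not (1 <= s <= e):
                raise ValidationError(f"invalid exon interval ({s}, {e})")
        spans = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValidationError("exon intervals overlap")
        exon_len = sum(e - s + 1 for s, e in self.exons)
        if exon_len != len(self.cds_sequence):
            raise ValidationError(
                f"exon lengths ({exon_len}) do not tile the CDS ({len(self.cds_sequence)})"
            )
        if len(self.cds_sequence) % 3 != 0:
            raise ValidationError("CDS length must be divisible by 3")
        if self.require_start and not self.cds_sequence.startswith("ATG"):
            raise ValidationError("CDS does not begin with a start codon")
        # transcript order must run 5'->3' on the coding strand
        starts = [s for s, _ in self.exons]
        ordered = starts == sorted(starts) if self.strand == "+" else starts == sorted(starts, reverse=True)
        if len(self.exons) > 1 and not ordered:
            raise ValidationError("exons are not in transcript order for this strand")

    @property
    def span(self) -> tuple[int, int]:
        return (min(s for s, _ in self.exons), max(e for _, e in self.exons))

    @property
    def protein(self) -> str:
        return str(Seq(self.cds_sequence).translate())


@dataclass(frozen=True)
class VariantCall:
    """A diallelic substitution call on the reference plus strand."""

    chromosome: str
    position: int
    ref_base: str
    alt_base: str
    zygosity: str  # hom_ref / het / hom_alt

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValidationError("ref and alt base identical")
        if self.zygosity not in ("hom_ref", "het", "hom_alt"):
            raise ValidationError(f"invalid zygosity {self.zygosity!r}")


@dataclass(frozen=True)
class CodingEffect:
    region: str  # intron / exon
    effect_class: str  # intronic / synonymous / missense / nonsense
    cds_position: int | None = None
    codon_index: int | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None


@dataclass(frozen=True)
class AssemblyOffset:
    """Signed constant such that position_old = position_new + offset."""

    offset: int


# ---------------------------------------------------------------------------
# SNP calling
# ---------------------------------------------------------------------------

def call_snps(sample_seq: str, ref_seq: str, ref_start: int,
              chromosome: str = "5") -> list[VariantCall]:
    """Column-wise SNP calls from a pre-aligned, indel-free sample sequence.

    Both sequences must be equal length and in plus-strand orientation.
    A plain base mismatch yields a homozygous-alt call; a two-fold IUPAC
    code whose decoding contains the reference base yields a heterozygous
    call.  An ambiguity code with neither decoded base equal to the
    reference cannot be represented as a diallelic call and is an error.
    ``N`` in either sequence skips the column.
    """
    sample_seq = sample_seq.upper()
    ref_seq = ref_seq.upper()
    if len(sample_seq) != len(ref_seq):
        raise ValidationError(
            f"sample length {len(sample_seq)} != reference length {len(ref_seq)}; "
            "inputs must be pre-aligned and indel-free"
        )
    calls = []
    for i, (s, r) in enumerate(zip(sample_seq, ref_seq)):
        if s == r or s == "N" or r == "N":
            continue
        pos = ref_start + i
        if s in IUPAC_HET:
            decoded = IUPAC_HET[s]
            if r not in decoded:
                raise ValidationError(
                    f"position {pos}: ambiguity code {s} decodes to "
                    f"{'/'.join(sorted(decoded))}, neither matching reference {r}"
                )
            (alt,) = decoded - {r}
            calls.append(VariantCall(chromosome, pos, r, alt, "het"))
        elif s in _COMPLEMENT:
            calls.append(VariantCall(chromosome, pos, r, s, "hom_alt"))
        else:
            raise ValidationError(f"position {pos}: unsupported symbol {s!r} in sample")
    return calls


# ---------------------------------------------------------------------------
# assembly lift-over
# ---------------------------------------------------------------------------

def infer_offset(pairs: Sequence[tuple[int, int]]) -> AssemblyOffset:
    """Infer the constant coordinate offset between two assemblies.

    Takes (position_new, position_old) pairs; the offset from the first
    pair must hold exactly for every other pair, otherwise the shift is
    not a simple translation and lift-over is refused.
    """
    if not pairs:
        raise ValidationError("need at least one coordinate pair")
    offset = pairs[0][1] - pairs[0][0]
    offenders = [(v4, v3) for v4, v3 in pairs if v3 - v4 != offset]
    if offenders:
        raise ValidationError(
            f"coordinate offset is not constant: first pair implies {offset:+d}, "
            f"violated by pairs {offenders}"
        )
    return AssemblyOffset(offset)


def liftover(position: int, offset: AssemblyOffset) -> int:
    """Translate a coordinate by the verified constant offset."""
    out = position + offset.offset
    if out < 1:
        raise ValidationError(f"lifted coordinate {out} is not a valid 1-based position")
    return out


# ---------------------------------------------------------------------------
# genomic <-> CDS coordinate mapping
# ---------------------------------------------------------------------------

INTRONIC = "intronic"


def genomic_to_cds(position: int, model: GeneModel) -> int | str:
    """Map a genomic position to a 1-based CDS position, or ``"intronic"``.

    Positions outside the gene span raise.  On the minus strand the CDS
    index counts from the transcript 5' end, i.e. it increases as the
    genomic coordinate decreases within each exon.
    """
    lo, hi = model.span
    if not (lo <= position <= hi):
        raise ValidationError(f"position {position} outside gene span [{lo}, {hi}]")
    offset = 0
    for s, e in model.exons:
        if s <= position <= e:
            if model.strand == "+":
                return offset + (position - s + 1)
            return offset + (e - position + 1)
        offset += e - s + 1
    return INTRONIC


def cds_to_genomic(cds_position: int, model: GeneModel) -> int:
    """Inverse of :func:`genomic_to_cds` for exonic positions."""
    if not (1 <= cds_position <= len(model.cds_sequence)):
        raise ValidationError(f"CDS position {cds_position} out of range")
    offset = 0
    for s, e in model.exons:
        length = e - s + 1
        if cds_position <= offset + length:
            within = cds_position - offset  # 1-based within exon
            if model.strand == "+":
                return s + within - 1
            return e - within + 1
        offset += length
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# coding-effect classification
# ---------------------------------------------------------------------------

def coding_effect(model: GeneModel, call: VariantCall) -> CodingEffect:
    """Classify a substitution call against a gene model.

    Intronic positions get the intronic class.  For exonic positions the
    affected codon is translated before and after the substitution with
    the standard nuclear code; for a minus-strand gene the called bases
    are complemented into coding orientation first.  A reference base that
    disagrees with the model CDS at the mapped position is an error.
    """
    cds_pos = genomic_to_cds(call.position, model)
    if cds_pos == INTRONIC:
        return CodingEffect(region="intron", effect_class="intronic")
    ref_coding = call.ref_base if model.strand == "+" else _COMPLEMENT[call.ref_base]
    alt_coding = call.alt_base if model.strand == "+" else _COMPLEMENT[call.alt_base]
    model_base = model.cds_sequence[cds_pos - 1]
    if model_base != ref_coding:
        raise ValidationError(
            f"reference base {call.ref_base} at position {call.position} maps to "
            f"coding base {ref_coding}, but the model CDS has {model_base} at CDS "
            f"position {cds_pos}"
        )
    codon_index = (cds_pos - 1) // 3 + 1
    codon_start = (codon_index - 1) * 3
    codon = model.cds_sequence[codon_start: codon_start + 3]
    within = cds_pos - 1 - codon_start
    mutant_codon = codon[:within] + alt_coding + codon[within + 1:]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(mutant_codon).translate())
    if alt_aa == "*":
        effect = "nonsense"
    elif alt_aa == ref_aa:
        effect = "synonymous"
    else:
        effect = "missense"
    return CodingEffect(region="exon", effect_class=effect, cds_position=cds_pos,
                        codon_index=codon_index, ref_aa=ref_aa, alt_aa=alt_aa)


# ---------------------------------------------------------------------------
# variant report
# ---------------------------------------------------------------------------

def annotate_variants(model: GeneModel, calls: Sequence[VariantCall],
                      offset: AssemblyOffset | None = None,
                      known_sites: set[int] | None = None) -> pd.DataFrame:
    """Tabulate calls with lift-over, region, residue and effect columns.

    ``known_sites`` is a user-supplied set of genomic positions already
    present in a variation database; calls outside it are flagged novel.
    """
    rows = []
    for call in sorted(calls, key=lambda c: c.position):
        eff = coding_effect(model, call)
        rows.append({
            "chromosome": call.chromosome,
            "position": call.position,
            "position_lifted": liftover(call.position, offset) if offset else pd.NA,
            "ref": call.ref_base,
            "alt": call.alt_base,
            "zygosity": call.zygosity,
            "region": eff.region,
            "cds_position": eff.cds_position if eff.cds_position else pd.NA,
            "residue": eff.codon_index if eff.codon_index else pd.NA,
            "ref_aa": eff.ref_aa or "",
            "alt_aa": eff.alt_aa or "",
            "effect": eff.effect_class,
            "known": (call.position in known_sites) if known_sites is not None else pd.NA,
        })
    return pd.DataFrame(rows, columns=[
        "chromosome", "position", "position_lifted", "ref", "alt", "zygosity",
        "region", "cds_position", "residue", "ref_aa", "alt_aa", "effect", "known",
    ])
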