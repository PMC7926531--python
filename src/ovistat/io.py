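"""Core domain types and file readers/writers.

The pipeline works on four kinds of input: a diallelic genotype table
(animals x loci, unordered allele pairs), phenotype records (animal id,
parity, litter size), a locus metadata table (dual-assembly coordinates,
alleles, gene region), and FASTA sequences.  All tabular formats are
headered delimited text (comma by default, tab selectable); lines starting
with ``#`` are treated as comments so that reports can carry provenance
headers and still round-trip.

Genotypes are stored as unordered allele pairs: Sanger sequencing of
diploids cannot phase, so ``"GA"`` and ``"AG"`` denote the same genotype
and are normalized to a canonical (alphabetically sorted) two-character
string.  Missing genotypes are written as ``"NN"`` and held internally as
``None``; they are excluded locus-wise from every downstream count.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ValidationError

MISSING_TOKEN = "NN"

#: nucleotide symbols accepted when reading analysis sequences: the four
#: bases, N, gap, and the two-fold IUPAC ambiguity codes used for
#: heterozygous positions in Sanger consensus sequences.
IUPAC_ALPHABET = frozenset("ACGTN-RYSWKM")

VALID_BASES = frozenset("ACGT")
VALID_REGIONS = ("intron", "exon")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Locus:
    """A diallelic marker with dual-assembly coordinates.

    Positions are 1-based inclusive genomic coordinates, following the
    GenBank convention.  ``position_v3`` (the older assembly) is optional.
    """

    id: str
    chromosome: str
    position_v4: int
    ref_allele: str
    alt_allele: str
    region: str = "intron"
    position_v3: int | None = None
    known_in_db: bool = True

    def __post_init__(self) -> None:
        if self.ref_allele not in VALID_BASES or self.alt_allele not in VALID_BASES:
            raise ValidationError(
                f"locus {self.id}: alleles must be A/C/G/T, got "
                f"{self.ref_allele!r}/{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValidationError(f"locus {self.id}: ref and alt allele identical")
        if self.position_v4 < 1:
            raise ValidationError(f"locus {self.id}: position_v4 must be >= 1")
        if self.position_v3 is not None and self.position_v3 < 1:
            raise ValidationError(f"locus {self.id}: position_v3 must be >= 1")
        if self.region not in VALID_REGIONS:
            raise ValidationError(
                f"locus {self.id}: region must be one of {VALID_REGIONS}"
            )

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset((self.ref_allele, self.alt_allele))


def normalize_genotype(raw: str, locus: Locus | None = None) -> str | None:
    """Normalize a two-character genotype string to unordered canonical form.

    ``"GA"`` and ``"AG"`` map to the same string.  The missing token (or an
    empty cell) maps to ``None``.  When ``locus`` is given, alleles outside
    its allele set raise :class:`ValidationError`.
    """
    raw = raw.strip().upper()
    if raw in ("", MISSING_TOKEN, "NA", "."):
        return None
    if len(raw) != 2:
        raise ValidationError(f"genotype {raw!r} is not a two-allele string")
    if locus is not None:
        bad = set(raw) - locus.alleles
        if bad:
            raise ValidationError(
                f"genotype {raw!r} contains allele(s) {sorted(bad)} outside the "
                f"allele set {{{locus.ref_allele},{locus.alt_allele}}} of locus {locus.id}"
            )
    elif not set(raw) <= VALID_BASES:
        raise ValidationError(f"genotype {raw!r} contains non-ACGT symbols")
    return "".join(sorted(raw))


@dataclass
class GenotypeTable:
    """Animals x loci matrix of unordered genotype pairs.

    ``genotypes`` is an object array of shape (n_samples, n_loci) holding
    canonical genotype strings or ``None`` for missing.
    """

    sample_ids: list[str]
    loci: list[Locus]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise ValidationError(f"duplicate sample id(s): {dupes}")
        if len({l.id for l in self.loci}) != len(self.loci):
            raise ValidationError("duplicate locus ids")
        self.genotypes = np.asarray(self.genotypes, dtype=object)
        if self.genotypes.shape != (len(self.sample_ids), len(self.loci)):
            raise ValidationError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.loci)} loci"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def locus_index(self, locus_id: str) -> int:
        for i, loc in enumerate(self.loci):
            if loc.id == locus_id:
                return i
        raise ValidationError(f"locus {locus_id!r} not in table")

    def locus(self, locus_id: str) -> Locus:
        return self.loci[self.locus_index(locus_id)]

    def column(self, locus_id: str) -> np.ndarray:
        """Genotype column (canonical strings / None) for one locus."""
        return self.genotypes[:, self.locus_index(locus_id)]

    def genotype_of(self, sample_id: str, locus_id: str) -> str | None:
        i = self.sample_ids.index(sample_id)
        return self.genotypes[i, self.locus_index(locus_id)]

    def to_dataframe(self) -> pd.DataFrame:
        data = np.where(self.genotypes == None, MISSING_TOKEN, self.genotypes)  # noqa: E711
        return pd.DataFrame(data, index=pd.Index(self.sample_ids, name="animal_id"),
                            columns=[l.id for l in self.loci])


@dataclass(frozen=True)
class PhenotypeRecord:
    """One litter-size record: animal, parity (1-based level), litter size."""

    animal_id: str
    parity: int
    litter_size: float

    def __post_init__(self) -> None:
        if self.parity < 1:
            raise ValidationError(f"{self.animal_id}: parity must be >= 1")
        if self.litter_size < 1:
            raise ValidationError(f"{self.animal_id}: litter_size must be >= 1")


@dataclass
class Dataset:
    """Genotypes plus phenotype records for the same cohort."""

    genotypes: GenotypeTable
    phenotypes: list[PhenotypeRecord]

    def __post_init__(self) -> None:
        known = set(self.genotypes.sample_ids)
        orphans = sorted({p.animal_id for p in self.phenotypes} - known)
        if orphans:
            raise ValidationError(
                f"phenotype records refer to unknown animal id(s): {orphans[:5]}"
            )


# ---------------------------------------------------------------------------
# tabular readers / writers
# ---------------------------------------------------------------------------

def read_genotype_table(path: str | Path, locus_meta: Sequence[Locus],
                        delimiter: str = ",") -> GenotypeTable:
    """Read a genotype CSV: first column animal id, one column per locus id.

    Cells are two-character allele pairs or the missing token; heterozygote
    order is normalized away.  Every header locus id must appear in
    ``locus_meta`` and alleles must belong to that locus's allele set.
    """
    df = pd.read_csv(path, sep=delimiter, comment="#", dtype=str).fillna("")
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected an id column plus locus columns")
    meta = {l.id: l for l in locus_meta}
    locus_ids = list(df.columns[1:])
    unknown = [lid for lid in locus_ids if lid not in meta]
    if unknown:
        raise ValidationError(f"{path}: unknown locus id(s) in header: {unknown}")
    loci = [meta[lid] for lid in locus_ids]
    sample_ids = [str(s) for s in df.iloc[:, 0]]
    geno = np.empty((len(sample_ids), len(loci)), dtype=object)
    for j, loc in enumerate(loci):
        for i, raw in enumerate(df.iloc[:, j + 1]):
            geno[i, j] = normalize_genotype(str(raw), loc)
    return GenotypeTable(sample_ids, loci, geno)


def write_genotype_table(table: GenotypeTable, path: str | Path,
                         delimiter: str = ",", header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        table.to_dataframe().to_csv(fh, sep=delimiter)


def read_phenotypes(path: str | Path, delimiter: str = ",") -> list[PhenotypeRecord]:
    """Read phenotype records (animal_id, parity, litter_size).

    Repeated animal ids are expected — each parity contributes one record.
    Malformed rows raise :class:`ValidationError` naming the line number.
    """
    records: list[PhenotypeRecord] = []
    with open(path) as fh:
        lines = [(i + 1, ln.rstrip("\n")) for i, ln in enumerate(fh)]
    body = [(n, ln) for n, ln in lines if ln.strip() and not ln.lstrip().startswith("#")]
    if not body:
        raise ValidationError(f"{path}: empty phenotype file")
    header_no, header = body[0]
    cols = [c.strip().lower() for c in header.split(delimiter)]
    required = ["animal_id", "parity", "litter_size"]
    if cols[: len(required)] != required:
        raise ValidationError(
            f"{path}: line {header_no}: header must start with {required}, got {cols}"
        )
    for n, ln in body[1:]:
        parts = [p.strip() for p in ln.split(delimiter)]
        if len(parts) < 3:
            raise ValidationError(f"{path}: line {n}: expected 3 fields, got {len(parts)}")
        animal, parity_s, litter_s = parts[0], parts[1], parts[2]
        try:
            parity = int(parity_s)
            litter = float(litter_s)
        except ValueError as exc:
            raise ValidationError(f"{path}: line {n}: {exc}") from None
        if not litter.is_integer():
            raise ValidationError(
                f"{path}: line {n}: litter_size must be a positive integer, got {litter_s!r}"
            )
        litter = int(litter)
        try:
            records.append(PhenotypeRecord(animal, parity, litter))
        except ValidationError as exc:
            raise ValidationError(f"{path}: line {n}: {exc}") from None
    return records


def write_phenotypes(records: Iterable[PhenotypeRecord], path: str | Path,
                     delimiter: str = ",", header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write(delimiter.join(["animal_id", "parity", "litter_size"]) + "\n")
        for r in records:
            litter = int(r.litter_size) if float(r.litter_size).is_integer() else r.litter_size
            fh.write(delimiter.join([r.animal_id, str(r.parity), str(litter)]) + "\n")


_LOCUS_COLS = ["id", "chromosome", "position_v4", "position_v3",
               "ref_allele", "alt_allele", "region", "known_in_db"]


def read_locus_table(path: str | Path, delimiter: str = ",") -> list[Locus]:
    df = pd.read_csv(path, sep=delimiter, comment="#", dtype=str).fillna("")
    missing = [c for c in _LOCUS_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: locus table missing column(s) {missing}")
    loci = []
    for _, row in df.iterrows():
        v3 = row["position_v3"].strip()
        loci.append(Locus(
            id=row["id"], chromosome=row["chromosome"],
            position_v4=int(row["position_v4"]),
            position_v3=int(v3) if v3 else None,
            ref_allele=row["ref_allele"].strip().upper(),
            alt_allele=row["alt_allele"].strip().upper(),
            region=row["region"].strip().lower(),
            known_in_db=str(row["known_in_db"]).strip().lower() in ("1", "true", "yes"),
        ))
    return loci


def write_locus_table(loci: Iterable[Locus], path: str | Path,
                      delimiter: str = ",", header_comment: str | None = None) -> None:
    rows = [{
        "id": l.id, "chromosome": l.chromosome, "position_v4": l.position_v4,
        "position_v3": "" if l.position_v3 is None else l.position_v3,
        "ref_allele": l.ref_allele, "alt_allele": l.alt_allele,
        "region": l.region, "known_in_db": l.known_in_db,
    } for l in loci]
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        pd.DataFrame(rows, columns=_LOCUS_COLS).to_csv(fh, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as (name, uppercase sequence) pairs.

    Sequences are restricted to nucleotides, N, gaps, and the two-fold
    IUPAC ambiguity codes used for heterozygous consensus positions;
    anything else (e.g. ``X``) is rejected.  Duplicate names and empty
    files are errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValidationError(f"{path}: no FASTA records found")
    names = [r.id for r in records]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValidationError(f"{path}: duplicate sequence name(s): {dupes}")
    out = []
    for r in records:
        seq = str(r.seq).upper()
        bad = set(seq) - IUPAC_ALPHABET
        if bad:
            raise ValidationError(
                f"{path}: sequence {r.id!r} contains invalid symbol(s) {sorted(bad)}"
            )
        out.append((r.id, seq))
    return out


def write_fasta(seqs: Iterable[tuple[str, str]], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs]
    SeqIO.write(records, str(path), "fasta")
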