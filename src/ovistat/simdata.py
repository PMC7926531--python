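"""Synthetic-data generators with known ground truth for every stage.

Three generators emulate a candidate-gene study cohort:

* genotypes — independent diallelic loci drawn from the F-adjusted
  Hardy–Weinberg trinomial (p^2 + Fpq, 2pq(1-F), q^2 + Fpq), where F is an
  inbreeding-like disequilibrium coefficient; F = 0 gives exact HWE and
  F = 1 removes heterozygotes.  A clone option copies a genotype column to
  exercise the concordant-locus screen.
* litter sizes — the forward direction of the fixed-effects model
  y = mu + parity + g1 + g2 + interaction + N(0, sigma), two records per
  ewe (parities 1 and 2); an integer mode rounds half-away-from-zero and
  clamps to the biologically plausible 1..4 lambs.
* gene sequences — a reference region with a valid CDS (no internal
  stops), per-sample consensus sequences carrying planted hom/het
  variants (heterozygotes as IUPAC codes), and a ground-truth manifest in
  which the expected coding effect is derived by brute-force translation
  of the whole mutant CDS (an independent path from the per-codon
  annotation logic).

Defaults mirror the study conditions: a cohort of 154 ewes, allele
frequencies spanning roughly 0.007–0.71, and litter sizes 1–3.  Seeds are
mandatory so every output is reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .annotation import GeneModel, cds_to_genomic, genomic_to_cds, INTRONIC, _COMPLEMENT
from .errors import ValidationError
from .io import GenotypeTable, Locus, PhenotypeRecord

_IUPAC_FOR_PAIR = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}

#: reference allele frequencies of the nine study-like markers (eight
#: candidate-gene SNPs plus the fecundity locus), used as the default
#: simulated cohort.
DEFAULT_LOCUS_FREQS = (0.994, 0.994, 0.955, 0.286, 0.955, 0.286, 0.844, 0.844, 0.682)


@dataclass(frozen=True)
class GenoSimParams:
    """Cohort size, per-locus (p, F) pairs, and the RNG seed."""

    n_animals: int = 154
    loci: tuple[tuple[float, float], ...] = tuple((p, 0.0) for p in DEFAULT_LOCUS_FREQS)
    seed: int = 0
    clones: tuple[tuple[int, int], ...] = ()  # (target_index, source_index)

    def genotype_probs(self, p: float, F: float) -> tuple[float, float, float]:
        q = 1.0 - p
        probs = (p * p + F * p * q, 2 * p * q * (1 - F), q * q + F * p * q)
        if min(probs) < -1e-12:
            raise ValidationError(
                f"invalid genotype probabilities {probs} for p={p}, F={F}"
            )
        return tuple(max(x, 0.0) for x in probs)


@dataclass(frozen=True)
class PhenoSimParams:
    """Forward parameters of the litter-size model."""

    mu: float = 1.6
    parity_effects: tuple[float, ...] = (0.0, 0.1)  # two parities
    g1_effects: dict = field(default_factory=dict)  # genotype -> offset
    g2_effects: dict = field(default_factory=dict)
    interaction_effects: dict = field(default_factory=dict)  # (g1, g2) -> offset
    sigma: float = 0.6
    integer_mode: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValidationError("sigma must be non-negative")


def simulate_genotypes(params: GenoSimParams) -> GenotypeTable:
    """Draw a genotype table from independent F-adjusted HWE trinomials."""
    rng = np.random.default_rng(params.seed)
    loci = []
    alleles = ("A", "G")
    for i, (p, F) in enumerate(params.loci):
        loci.append(Locus(id=f"locus_{i + 1}", chromosome="5",
                          position_v4=1000 + i, ref_allele=alleles[0],
                          alt_allele=alleles[1]))
    sample_ids = [f"ewe{i + 1:03d}" for i in range(params.n_animals)]
    geno = np.empty((params.n_animals, len(loci)), dtype=object)
    genotype_strings = ("AA", "AG", "GG")
    for j, (p, F) in enumerate(params.loci):
        probs = params.genotype_probs(p, F)
        draws = rng.choice(3, size=params.n_animals, p=probs)
        for i, d in enumerate(draws):
            geno[i, j] = genotype_strings[d]
    for target, source in params.clones:
        geno[:, target] = geno[:, source]
    return GenotypeTable(sample_ids, loci, geno)


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def simulate_phenotypes(table: GenotypeTable, g1: str, g2: str,
                        params: PhenoSimParams) -> list[PhenotypeRecord]:
    """Two litter-size records per animal from the fixed-effects model.

    Genotype effect maps must cover every genotype present in the table at
    the chosen loci.  In integer mode, values are rounded half away from
    zero and clamped to [1, 4].
    """
    rng = np.random.default_rng(params.seed)
    g1_col = dict(zip(table.sample_ids, table.column(g1)))
    g2_col = dict(zip(table.sample_ids, table.column(g2)))
    records = []
    for animal in table.sample_ids:
        a, b = g1_col[animal], g2_col[animal]
        if a is None or b is None:
            continue
        for parity_idx, parity_eff in enumerate(params.parity_effects, start=1):
            try:
                y = (params.mu + parity_eff + params.g1_effects[a]
                     + params.g2_effects[b]
                     + params.interaction_effects.get((a, b), 0.0))
            except KeyError as exc:
                raise ValidationError(f"no simulated effect for genotype level {exc}") from None
            y += rng.normal(0.0, params.sigma) if params.sigma > 0 else 0.0
            if params.integer_mode:
                y = float(min(max(_round_half_away(y), 1), 4))
            else:
                y = max(y, 1.0)  # litter sizes are at least one lamb
            records.append(PhenotypeRecord(animal, parity_idx, y))
    return records


def genotype_table_from_counts(counts_by_locus: dict, n_animals: int | None = None,
                               loci: list[Locus] | None = None) -> GenotypeTable:
    """Deterministically realize a genotype table with exact genotype counts.

    ``counts_by_locus`` maps locus id -> (n_refref, n_refalt, n_altalt);
    animals beyond a locus's total count are left untyped.  Useful for
    reconstructing a table from a published count/frequency table.
    """
    totals = [sum(c) for c in counts_by_locus.values()]
    n = n_animals or max(totals)
    if max(totals) > n:
        raise ValidationError("counts exceed the number of animals")
    if loci is None:
        loci = [Locus(id=lid, chromosome="5", position_v4=1000 + k,
                      ref_allele="A", alt_allele="G")
                for k, lid in enumerate(counts_by_locus)]
    by_id = {l.id: l for l in loci}
    sample_ids = [f"ewe{i + 1:03d}" for i in range(n)]
    geno = np.full((n, len(counts_by_locus)), None, dtype=object)
    for j, (lid, (n_rr, n_ra, n_aa)) in enumerate(counts_by_locus.items()):
        loc = by_id[lid]
        gts = ["".join(sorted(loc.ref_allele * 2))] * n_rr \
            + ["".join(sorted(loc.ref_allele + loc.alt_allele))] * n_ra \
            + ["".join(sorted(loc.alt_allele * 2))] * n_aa
        for i, g in enumerate(gts):
            geno[i, j] = g
    return GenotypeTable(sample_ids, list(by_id[l] for l in counts_by_locus), geno)


# ---------------------------------------------------------------------------
# gene-region simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedVariant:
    """Ground truth for one planted substitution (plus-strand bases)."""

    position: int
    ref: str
    alt: str
    zygosity: str  # het / hom_alt
    region: str  # intron / exon
    effect: str  # intronic / synonymous / missense / nonsense


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Random CDS with a start codon and no internal stops."""
    stops = {"TAA", "TAG", "TGA"}
    bases = "ACGT"
    codons = ["ATG"]
    for _ in range(n_codons - 2):
        while True:
            c = "".join(rng.choice(list(bases), 3))
            if c not in stops:
                codons.append(c)
                break
    codons.append("TAA")
    return "".join(codons)


def simulate_gene(exons: tuple[tuple[int, int], ...], strand: str,
                  planted: tuple[tuple[int, str, str], ...], seed: int,
                  gene_start: int | None = None, gene_end: int | None = None,
                  chromosome: str = "5",
                  sample_name: str = "sample1") -> tuple[GeneModel, str, dict, list]:
    """Build a gene model, reference region and one mutated sample sequence.

    ``exons`` are genomic intervals in transcript order; their total
    length must be a multiple of 3.  ``planted`` lists
    ``(genomic position, alt plus-strand base, zygosity)`` substitutions
    applied to the sample.  Returns ``(model, ref_region, samples,
    manifest)`` where ``ref_region`` is the plus-strand reference text of
    the gene span, ``samples`` maps the sample name to its consensus
    sequence (IUPAC codes at heterozygous sites), and ``manifest`` is the
    list of :class:`PlantedVariant` ground truths.  Expected coding
    effects in the manifest come from translating the full mutant CDS and
    diffing proteins, independent of the per-codon annotation path.
    """
    rng = np.random.default_rng(seed)
    lo = min(s for s, _ in exons) if gene_start is None else gene_start
    hi = max(e for _, e in exons) if gene_end is None else gene_end
    exon_len = sum(e - s + 1 for s, e in exons)
    if exon_len % 3 != 0:
        raise ValidationError("total exon length must be a multiple of 3")

    cds = _random_cds(rng, exon_len // 3)
    region = list(rng.choice(list("ACGT"), hi - lo + 1))
    # place the CDS into the region (reverse-complemented for minus strand)
    model = GeneModel(chromosome=chromosome, strand=strand, exons=tuple(exons),
                      cds_sequence=cds, require_start=True)
    for cds_pos in range(1, len(cds) + 1):
        g = cds_to_genomic(cds_pos, model)
        base = cds[cds_pos - 1]
        region[g - lo] = base if strand == "+" else _COMPLEMENT[base]
    ref_region = "".join(region)

    sample = list(ref_region)
    manifest: list[PlantedVariant] = []
    transition = {"A": "G", "G": "A", "C": "T", "T": "C"}
    for pos, alt, zygosity in planted:
        if not (lo <= pos <= hi):
            raise ValidationError(f"planted variant at {pos} outside gene span [{lo}, {hi}]")
        ref_base = ref_region[pos - lo]
        if alt is None:  # default to the transition partner, never the reference
            alt = transition[ref_base]
        if alt == ref_base:
            raise ValidationError(f"planted alt at {pos} equals the reference base {ref_base}")
        if zygosity == "het":
            sample[pos - lo] = _IUPAC_FOR_PAIR[frozenset((ref_base, alt))]
        elif zygosity == "hom_alt":
            sample[pos - lo] = alt
        else:
            raise ValidationError(f"invalid zygosity {zygosity!r}")
        cds_pos = genomic_to_cds(pos, model)
        if cds_pos == INTRONIC:
            manifest.append(PlantedVariant(pos, ref_base, alt, zygosity,
                                           "intron", "intronic"))
        else:
            alt_coding = alt if strand == "+" else _COMPLEMENT[alt]
            mutant_cds = cds[: cds_pos - 1] + alt_coding + cds[cds_pos:]
            ref_prot = str(Seq(cds).translate())
            alt_prot = str(Seq(mutant_cds).translate())
            codon_index = (cds_pos - 1) // 3 + 1
            if alt_prot[codon_index - 1] == "*" and ref_prot[codon_index - 1] != "*":
                effect = "nonsense"
            elif alt_prot == ref_prot:
                effect = "synonymous"
            else:
                effect = "missense"
            manifest.append(PlantedVariant(pos, ref_base, alt, zygosity, "exon", effect))
    return model, ref_region, {sample_name: "".join(sample)}, manifest
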