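import numpy as np
import pytest

from ovistat import Dataset, GeneModel, GenotypeTable, Locus
from ovistat.simdata import (
    GenoSimParams,
    PhenoSimParams,
    genotype_table_from_counts,
    simulate_genotypes,
    simulate_phenotypes,
)

# Genotype counts of the nine study markers, reconstructed as
# round(published genotype frequency x 154 animals).
STUDY_COUNTS = {
    "g.41769606T>G": (152, 2, 0),
    "g.41769574G>A": (152, 2, 0),
    "g.41769567T>C": (140, 14, 0),
    "g.41769246A>G": (12, 64, 78),
    "g.41769223C>G": (140, 14, 0),
    "g.41769002A>G": (12, 64, 78),
    "g.41768501A>G": (110, 40, 4),
    "g.41768485G>A": (110, 40, 4),
    "FecB": (64, 82, 8),
}

# the published 3-dp He / Ne / PIC triples for the same markers
STUDY_DIVERSITY = {
    "g.41769606T>G": (0.013, 1.013, 0.013),
    "g.41769574G>A": (0.013, 1.013, 0.013),
    "g.41769567T>C": (0.087, 1.095, 0.083),
    "g.41769246A>G": (0.408, 1.690, 0.325),
    "g.41769223C>G": (0.087, 1.095, 0.083),
    "g.41769002A>G": (0.408, 1.690, 0.325),
    "g.41768501A>G": (0.263, 1.357, None),  # PIC rounding-path ambiguous
    "g.41768485G>A": (0.263, 1.357, None),
    "FecB": (0.434, 1.766, 0.340),
}


@pytest.fixture(scope="session")
def study_table() -> GenotypeTable:
    """Genotype table realizing the reconstructed study counts exactly."""
    return genotype_table_from_counts(STUDY_COUNTS, n_animals=154)


@pytest.fixture
def toy_minus_gene() -> GeneModel:
    """Minus-strand two-exon toy gene.

    Transcript order: exon1 genomic [21, 26], exon2 genomic [11, 16]
    (coordinates decrease along the transcript).  CDS: ATG GTC TTT TAA.
    """
    return GeneModel(chromosome="5", strand="-", exons=((21, 26), (11, 16)),
                     cds_sequence="ATGGTCTTTTAA")


def simulated_dataset(seed, g1_effects=None, g2_effects=None, sigma=0.6,
                      n=154, integer_mode=False, mu=2.5):
    """Study-sized cohort: two loci at the study allele frequencies, two
    parity records per ewe from the fixed-effects litter-size model."""
    gtab = simulate_genotypes(GenoSimParams(
        n_animals=n, loci=((0.844, 0.0), (0.682, 0.0)), seed=seed))
    params = PhenoSimParams(
        mu=mu,
        g1_effects=g1_effects or {"AA": 0.0, "AG": 0.0, "GG": 0.0},
        g2_effects=g2_effects or {"AA": 0.0, "AG": 0.0, "GG": 0.0},
        sigma=sigma, integer_mode=integer_mode, seed=seed + 500_000)
    phenos = simulate_phenotypes(gtab, "locus_1", "locus_2", params)
    return Dataset(gtab, phenos)


def make_table(columns: dict, sample_prefix: str = "s") -> GenotypeTable:
    """Small genotype table from {locus_id: [genotype or None, ...]}."""
    n = len(next(iter(columns.values())))
    loci = [Locus(id=lid, chromosome="5", position_v4=100 + k,
                  ref_allele="A", alt_allele="G")
            for k, lid in enumerate(columns)]
    geno = np.empty((n, len(columns)), dtype=object)
    for j, vals in enumerate(columns.values()):
        for i, v in enumerate(vals):
            geno[i, j] = "".join(sorted(v)) if v is not None else None
    return GenotypeTable([f"{sample_prefix}{i}" for i in range(n)], loci, geno)
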