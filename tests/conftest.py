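import pytest

from homogene import (GenomeSequences, IntronEvidence, derive_target,
                      extract_evidence, generate_reference, load_reference,
                      simulate_spliced_sam)

# A tiny hand-built two-exon gene: ATG GTT | intron | TGG TAA -> protein MVW.
HAND_EXON1 = "ATGGTT"
HAND_EXON2 = "TGGTAA"
HAND_INTRON = "GT" + "C" * 36 + "AG"   # 40 nt, canonical


@pytest.fixture(scope="session")
def hand_gene_plus():
    contig = "TTTTT" + HAND_EXON1 + HAND_INTRON + HAND_EXON2 + "TTTTT"
    genome = GenomeSequences({"ctg": contig})
    gff = "\n".join([
        "##gff-version 3",
        "ctg\ttest\tgene\t6\t57\t.\t+\t.\tID=geneA",
        "ctg\ttest\tmRNA\t6\t57\t.\t+\t.\tID=geneA.t1;Parent=geneA",
        "ctg\ttest\tCDS\t6\t11\t.\t+\t0\tID=c1;Parent=geneA.t1",
        "ctg\ttest\tCDS\t52\t57\t.\t+\t0\tID=c2;Parent=geneA.t1",
    ]) + "\n"
    return genome, gff


@pytest.fixture(scope="session")
def hand_gene_minus(hand_gene_plus):
    """The same gene on the reverse-complemented contig."""
    from homogene.genome_io import reverse_complement
    genome, _ = hand_gene_plus
    contig = genome["ctg"]
    L = len(contig)
    rc = GenomeSequences({"ctg": reverse_complement(contig)})
    # original CDS [5,11) and [51,57) map to [L-11,L-5) and [L-57,L-51)
    gff = "\n".join([
        "##gff-version 3",
        "ctg\ttest\tgene\t1\t62\t.\t-\t.\tID=geneA",
        "ctg\ttest\tmRNA\t1\t62\t.\t-\t.\tID=geneA.t1;Parent=geneA",
        f"ctg\ttest\tCDS\t{L - 11 + 1}\t{L - 5}\t.\t-\t0\tID=c1;Parent=geneA.t1",
        f"ctg\ttest\tCDS\t{L - 57 + 1}\t{L - 51}\t.\t-\t0\tID=c2;Parent=geneA.t1",
    ]) + "\n"
    return rc, gff


@pytest.fixture(scope="session")
def small_reference():
    """Seeded 6-gene reference used across module tests."""
    return generate_reference(n_genes=6, seed=11)


@pytest.fixture(scope="session")
def small_refs(small_reference):
    return small_reference[1]


@pytest.fixture(scope="session")
def small_round_trip(small_reference):
    """Diverged target + simulated evidence for the small reference."""
    genome, refs = small_reference
    target, truth = derive_target(genome, refs, aa_identity=0.9, seed=12)
    sam = simulate_spliced_sam(truth, target, reads_per_intron=2, read_len=50, seed=13)
    introns, coverage = extract_evidence(sam, with_coverage=True)
    return {"genome": genome, "refs": refs, "target": target, "truth": truth,
            "sam": sam, "introns": introns, "coverage": coverage}


@pytest.fixture(scope="session")
def true_introns(small_reference):
    """Evidence introns exactly matching the reference annotation."""
    _, refs = small_reference
    return [IntronEvidence(r.seq_id, s, e, r.strand, 3)
            for r in refs for s, e in r.intron_intervals()]


@pytest.fixture()
def loaded_hand_gene(hand_gene_plus):
    genome, gff = hand_gene_plus
    return genome, load_reference(genome, gff)
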