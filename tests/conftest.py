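"""Shared fixtures and independent oracles.

The retranslation oracle deliberately avoids every code path of the
annotator under test: it mutates the raw locus string, re-splices with
Biopython, translates the whole protein and diffs it against the wild
type.  The geometric oracle re-derives splice/UTR/intron classes from
the exon intervals alone.
"""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq

from mybpc_landscape.consequence_engine import GeneModel
from mybpc_landscape.synthetic_data import make_gene_model
from mybpc_landscape.variant_io import VariantRecord


@pytest.fixture
def toy_model() -> GeneModel:
    """Single-exon plus-strand toy gene: CDS = ATG GAA TGG TAA."""
    seq = "AAAA" + "ATGGAATGGTAA" + "TTTT"
    model = GeneModel(
        gene_symbol="TOY",
        transcript_id="ENSTTOY00000000001",
        chrom="chrT",
        strand="+",
        exons=((1, len(seq)),),
        cds_start=5,
        cds_end=16,
        sequence=seq,
        seq_offset=1,
    )
    model.validate()
    return model


@pytest.fixture
def toy_model_minus(toy_model: GeneModel) -> GeneModel:
    """The same toy gene laid down on the minus strand of the genome."""
    seq = str(Seq(toy_model.sequence).reverse_complement())
    L = len(seq)
    model = GeneModel(
        gene_symbol="TOY",
        transcript_id="ENSTTOY00000000001",
        chrom="chrT",
        strand="-",
        exons=((1, L),),
        cds_start=L - toy_model.cds_end + 1,
        cds_end=L - toy_model.cds_start + 1,
        sequence=seq,
        seq_offset=1,
    )
    model.validate()
    return model


def random_models(n: int, seed: int, **kwargs):
    """Random valid gene models over both strands, 2-6 exons."""
    rng = np.random.default_rng(seed)
    models = []
    for i in range(n):
        models.append(
            make_gene_model(
                n_exons=int(rng.integers(2, 7)),
                cds_length_codons=int(rng.integers(40, 120)),
                strand="+-"[int(rng.integers(0, 2))],
                seed=int(rng.integers(0, 2**31 - 1)),
                flank=120,
                intron_min=30,
                intron_max=90,
                **kwargs,
            )
        )
    return models


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def retranslate_oracle(model: GeneModel, v: VariantRecord):
    """Category/protein_pos/aa_change of an SNV by whole-protein diff.

    Returns (category, protein_pos, aa_change) for coding SNVs, or None
    when the substituted base is not part of the spliced CDS.
    """
    assert v.is_snv
    mutant_seq = list(model.sequence)
    idx = v.pos - model.seq_offset
    assert mutant_seq[idx] == v.ref
    mutant_seq[idx] = v.alt
    mutant = GeneModel(
        gene_symbol=model.gene_symbol,
        transcript_id=model.transcript_id,
        chrom=model.chrom,
        strand=model.strand,
        exons=model.exons,
        cds_start=model.cds_start,
        cds_end=model.cds_end,
        sequence="".join(mutant_seq),
        seq_offset=model.seq_offset,
    )
    wt_cds = _splice(model)
    mut_cds = _splice(mutant)
    if wt_cds == mut_cds:
        return None
    wt_prot = str(Seq(wt_cds).translate())
    mut_prot = str(Seq(mut_cds).translate())
    if wt_prot == mut_prot:
        # find the substituted codon for the protein position
        i = next(j for j in range(len(wt_cds)) if wt_cds[j] != mut_cds[j])
        return ("synonymous", i // 3 + 1, (wt_prot[i // 3], mut_prot[i // 3]))
    i = next(j for j in range(len(wt_prot)) if wt_prot[j] != mut_prot[j])
    wt_aa, mut_aa = wt_prot[i], mut_prot[i]
    if i == 0:
        category = "start_loss"
    elif mut_aa == "*":
        category = "truncation"
    elif wt_aa == "*":
        category = "stop_loss"
    else:
        category = "missense"
    return (category, i + 1, (wt_aa, mut_aa))


def _splice(model: GeneModel) -> str:
    """Spliced strand-oriented CDS, rebuilt from scratch with Biopython."""
    lo = model.seq_offset
    chunks = []
    for s, e in model.exons:
        cs, ce = max(s, model.cds_start), min(e, model.cds_end)
        if cs <= ce:
            chunks.append(model.sequence[cs - lo: ce - lo + 1])
    cds = "".join(chunks)
    if model.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return cds


def geometric_noncoding_oracle(model: GeneModel, pos: int) -> str:
    """Independent splice/UTR/intron/flank classification from intervals."""
    exons = model.exons
    in_exon = any(s <= pos <= e for s, e in exons)
    if in_exon:  # caller only passes non-CDS positions, so exonic == UTR
        if model.strand == "+":
            return "5_prime_UTR_variant" if pos < model.cds_start else "3_prime_UTR_variant"
        return "5_prime_UTR_variant" if pos > model.cds_end else "3_prime_UTR_variant"
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        if e1 < pos < s2:
            near_left = pos - e1 <= 2
            near_right = s2 - pos <= 2
            if model.strand == "+":
                if near_left:
                    return "splice_donor_variant"
                if near_right:
                    return "splice_acceptor_variant"
            else:
                if near_right:
                    return "splice_donor_variant"
                if near_left:
                    return "splice_acceptor_variant"
            return "intron_variant"
    upstream = pos < exons[0][0] if model.strand == "+" else pos > exons[-1][1]
    return "upstream_gene_variant" if upstream else "downstream_gene_variant"


def random_snvs(model: GeneModel, n: int, seed: int) -> list[VariantRecord]:
    """Uniform random SNVs across the locus span (any region)."""
    rng = np.random.default_rng(seed)
    lo, hi = model.span
    out = []
    for _ in range(n):
        pos = int(rng.integers(lo + 1, hi))
        ref = model.base(pos)
        alt = "ACGT"[int(rng.integers(0, 4))]
        while alt == ref:
            alt = "ACGT"[int(rng.integers(0, 4))]
        out.append(VariantRecord(model.chrom, pos, ref, alt))
    return out
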