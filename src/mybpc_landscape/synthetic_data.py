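"""Synthetic gene models, domain architectures and variant cohorts.

The generator emulates what a gnomAD download plus a VEP run hands the
pipeline: a multi-exon gene on either strand, a cohort of SNVs and small
indels with a configurable mutation model (transition:transversion ratio,
optional CpG elevation, indel length distribution), VEP ``--tab`` and VCF
serialisations, and per-variant ground truth recorded at generation time,
before the internal annotator sees anything.

Two sampling regimes:

* **undirected** — positions uniform (genomic or coding), alternate
  alleles drawn from the mutation model; category proportions emerge.
* **directed** — ``category_proportions`` set: the category is drawn
  first, then transition-vs-transversion with ``P(ts) = R/(R+1)``, then a
  candidate site of that class from the category's exhaustive pool.  This
  keeps the realised transition fraction an exact Bernoulli(R/(R+1)) per
  SNV regardless of the category mix, so both the configured proportions
  and the configured Ts/Tv are recoverable from one cohort.

Directed cohorts emit every variant key (chrom, pos, ref, alt) exactly
once, so the cleaning cascade's dedup stage is the identity on them and
configured proportions survive it.  Undirected cohorts model a mutation
process and may contain recurrent alleles.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .consequence_engine import (
    GENETIC_CODE,
    STOP_CODONS,
    TRANSITIONS,
    GeneModel,
    annotate_variant,
    complement,
    translate_codon,
)
from .landscape_stats import DomainArchitecture, Region, map_to_domain
from .variant_io import TranscriptAnnotation, VariantRecord, write_vcf

log = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

DEFAULT_INDEL_LENGTHS = {1: 0.45, 2: 0.20, 3: 0.12, 4: 0.10, 5: 0.07, 6: 0.06}

#: Coding-category profile matching the observed MYBPC landscape
#: (missense-dominated, ~30% synonymous, few percent truncating).
DEFAULT_CODING_PROPORTIONS = {
    "missense": 0.63,
    "synonymous": 0.30,
    "frameshift": 0.015,
    "truncation": 0.015,
    "inframe_indel": 0.02,
    "splice": 0.02,
}


@dataclass
class MutationModel:
    """Mutation process parameters for a simulated cohort.

    ``cpg_multiplier`` elevates C→T (and G→A on the other strand) at CpG
    dinucleotides; 1.0 disables it, 8.0 is a realistic human germline
    value.  ``category_proportions`` switches on directed sampling (see
    module docstring); ``noncoding_fraction`` only applies there.
    """

    n_variants: int = 1000
    snv_fraction: float = 0.9
    ts_tv_ratio: float = 2.0
    cpg_multiplier: float = 1.0
    indel_length_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_INDEL_LENGTHS)
    )
    positional_model: str = "uniform_genomic"
    seed: int = 0
    category_proportions: Optional[dict[str, float]] = None
    noncoding_fraction: float = 0.75
    damaging_prob: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.snv_fraction <= 1.0:
            raise ValueError("snv_fraction must be in [0,1]")
        if self.ts_tv_ratio <= 0:
            raise ValueError("ts_tv_ratio must be positive")
        if self.cpg_multiplier < 1.0:
            raise ValueError("cpg_multiplier must be >= 1")
        total = sum(self.indel_length_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("indel length probabilities must sum to 1")
        if any(not 1 <= k <= 6 for k in self.indel_length_distribution):
            raise ValueError("indel lengths must be 1..6")
        if self.positional_model not in ("uniform_genomic", "uniform_coding"):
            raise ValueError(f"unknown positional_model {self.positional_model!r}")
        if self.category_proportions is not None:
            s = sum(self.category_proportions.values())
            if abs(s - 1.0) > 1e-6:
                raise ValueError(f"category proportions sum to {s}, expected 1")
        if not 0.0 <= self.noncoding_fraction < 1.0:
            raise ValueError("noncoding_fraction must be in [0,1)")


@dataclass
class GroundTruth:
    """Generation-time truth, independent of the annotator's answers."""

    configured: dict = field(default_factory=dict)
    entries: list[dict] = field(default_factory=list)

    def category_counts(self) -> Counter:
        return Counter(e["category"] for e in self.entries)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"configured": self.configured, "entries": self.entries}, fh, indent=1)


# ---------------------------------------------------------------------------
# Gene model generation
# ---------------------------------------------------------------------------

_SENSE_CODONS = sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def make_gene_model(
    n_exons: int,
    cds_length_codons: int,
    strand: str = "+",
    seed: int = 0,
    *,
    gene_symbol: str = "SYNGENE",
    transcript_id: str = "ENSTSYN00000000001",
    chrom: str = "chrS",
    utr5: int = 60,
    utr3: int = 120,
    intron_min: int = 80,
    intron_max: int = 400,
    flank: int = 1000,
    seq_offset: int = 100_001,
) -> GeneModel:
    """Random valid gene model: ATG start, clean ORF, single terminal stop.

    The transcript (5'UTR + CDS + 3'UTR) is cut into ``n_exons`` pieces at
    random points (each exon >= 20 nt), introns get GT..AG ends, and on the
    minus strand the whole locus is laid down reverse-complemented so the
    genomic plus-strand sequence is the mirror of the transcript.
    Deterministic given ``seed``.
    """
    if n_exons < 1:
        raise ValueError("n_exons must be >= 1")
    if cds_length_codons < 2:
        raise ValueError("cds_length_codons must be >= 2")
    rng = np.random.default_rng(seed)

    n_internal = cds_length_codons - 2
    internal = "".join(
        np.array(_SENSE_CODONS)[rng.integers(0, len(_SENSE_CODONS), size=n_internal)]
    )
    stop = ["TAA", "TAG", "TGA"][rng.integers(0, 3)]
    cds = "ATG" + internal + stop
    transcript = _random_seq(rng, utr5) + cds + _random_seq(rng, utr3)

    min_exon = 20
    if len(transcript) < n_exons * min_exon:
        raise ValueError(
            f"transcript of {len(transcript)} nt cannot be cut into {n_exons} exons of >= {min_exon} nt"
        )
    while True:
        cuts = np.sort(rng.choice(np.arange(1, len(transcript)), size=n_exons - 1, replace=False))
        sizes = np.diff(np.concatenate([[0], cuts, [len(transcript)]]))
        if (sizes >= min_exon).all():
            break
    intron_lengths = rng.integers(intron_min, intron_max + 1, size=n_exons - 1)

    # Lay the locus down in transcript orientation first.
    pieces: list[str] = [_random_seq(rng, flank)]
    exon_bounds_tx: list[tuple[int, int]] = []  # 1-based within locus, tx orientation
    cursor = flank
    offset_in_tx = 0
    for i, size in enumerate(sizes):
        exon_bounds_tx.append((cursor + 1, cursor + int(size)))
        pieces.append(transcript[offset_in_tx: offset_in_tx + int(size)])
        cursor += int(size)
        offset_in_tx += int(size)
        if i < n_exons - 1:
            ilen = int(intron_lengths[i])
            intron = "GT" + _random_seq(rng, ilen - 4) + "AG"
            pieces.append(intron)
            cursor += ilen
    pieces.append(_random_seq(rng, flank))
    locus_tx = "".join(pieces)

    # Transcript coordinates of the CDS ends, mapped to locus positions.
    cds_tx_lo, cds_tx_hi = utr5 + 1, utr5 + len(cds)

    def tx_to_locus(tx_pos: int) -> int:
        consumed = 0
        for (s, e) in exon_bounds_tx:
            size = e - s + 1
            if tx_pos <= consumed + size:
                return s + (tx_pos - consumed - 1)
            consumed += size
        raise AssertionError("transcript position outside exons")

    cds_lo_locus = tx_to_locus(cds_tx_lo)
    cds_hi_locus = tx_to_locus(cds_tx_hi)

    if strand == "+":
        sequence = locus_tx
        exons = tuple(exon_bounds_tx)
        cds_start, cds_end = cds_lo_locus, cds_hi_locus
    elif strand == "-":
        L = len(locus_tx)
        sequence = complement(locus_tx)[::-1]
        mirror = lambda p: L - p + 1  # noqa: E731
        exons = tuple(sorted((mirror(e), mirror(s)) for s, e in exon_bounds_tx))
        cds_start, cds_end = mirror(cds_hi_locus), mirror(cds_lo_locus)
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")

    exons = tuple((s + seq_offset - 1, e + seq_offset - 1) for s, e in exons)
    model = GeneModel(
        gene_symbol=gene_symbol,
        transcript_id=transcript_id,
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds_start=cds_start + seq_offset - 1,
        cds_end=cds_end + seq_offset - 1,
        sequence=sequence,
        seq_offset=seq_offset,
    )
    model.validate()
    assert model.cds_sequence == cds
    return model


def write_gene_model(model: GeneModel, tsv_path: str | Path, fasta_path: str | Path) -> None:
    """Serialise as GFF3-like TSV (feature table) + FASTA locus sequence."""
    with open(tsv_path, "w") as fh:
        fh.write("# feature\tstart\tend\tstrand\n")
        fh.write(
            f"gene\t{model.gene_span[0]}\t{model.gene_span[1]}\t{model.strand}"
            f"\t{model.gene_symbol}\t{model.transcript_id}\t{model.chrom}\t{model.seq_offset}\n"
        )
        for s, e in model.exons:
            fh.write(f"exon\t{s}\t{e}\t{model.strand}\n")
        fh.write(f"CDS\t{model.cds_start}\t{model.cds_end}\t{model.strand}\n")
    with open(fasta_path, "w") as fh:
        fh.write(f">{model.chrom}:{model.seq_offset} {model.gene_symbol}\n")
        for i in range(0, len(model.sequence), 80):
            fh.write(model.sequence[i: i + 80] + "\n")


def read_gene_model(tsv_path: str | Path, fasta_path: str | Path) -> GeneModel:
    exons: list[tuple[int, int]] = []
    cds_start = cds_end = None
    meta: dict = {}
    with open(tsv_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            feature = parts[0]
            if feature == "gene":
                meta = {
                    "strand": parts[3],
                    "gene_symbol": parts[4],
                    "transcript_id": parts[5],
                    "chrom": parts[6],
                    "seq_offset": int(parts[7]),
                }
            elif feature == "exon":
                exons.append((int(parts[1]), int(parts[2])))
            elif feature == "CDS":
                cds_start, cds_end = int(parts[1]), int(parts[2])
    with open(fasta_path) as fh:
        seq_lines = [l.strip() for l in fh if not l.startswith(">")]
    model = GeneModel(
        gene_symbol=meta["gene_symbol"],
        transcript_id=meta["transcript_id"],
        chrom=meta["chrom"],
        strand=meta["strand"],
        exons=tuple(sorted(exons)),
        cds_start=cds_start,
        cds_end=cds_end,
        sequence="".join(seq_lines),
        seq_offset=meta["seq_offset"],
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Domain architecture generation
# ---------------------------------------------------------------------------

def make_architecture(
    protein_length: int,
    n_domains: int,
    include_c0: bool = False,
    seed: int = 0,
    *,
    protein_name: str = "synMyBP-C",
) -> DomainArchitecture:
    """Random MyBP-C-like architecture: [C0] PA C1 M C2..Cn with linker gaps.

    Fibronectin type III class is assigned to C6, C7 and C9 when present
    (the cardiac/skeletal layout); every other C domain is Ig-like, PA is
    the proline/alanine-rich region and M the phosphorylatable motif.
    """
    if n_domains < 1:
        raise ValueError("n_domains must be >= 1")
    rng = np.random.default_rng(seed)
    names: list[tuple[str, str]] = []
    if include_c0:
        names.append(("C0", "Ig"))
    names.append(("PA", "PA_rich"))
    names.append(("C1", "Ig"))
    names.append(("M", "M_domain"))
    for i in range(2, n_domains + 1):
        cls = "Fn3" if i in (6, 7, 9) else "Ig"
        names.append((f"C{i}", cls))

    sizes = []
    for _name, cls in names:
        if cls == "Ig":
            sizes.append(int(rng.integers(85, 106)))
        elif cls == "Fn3":
            sizes.append(int(rng.integers(90, 111)))
        elif cls == "PA_rich":
            sizes.append(int(rng.integers(25, 46)))
        else:  # M_domain
            sizes.append(int(rng.integers(60, 101)))
    gaps = [int(g) for g in rng.integers(3, 13, size=len(names) + 1)]
    needed = sum(sizes) + sum(gaps)
    if needed > protein_length:
        # shrink proportionally but never below a minimal fold/gap size
        factor = protein_length / needed
        sizes = [max(30, int(s * factor)) for s in sizes]
        gaps = [max(1, int(g * factor)) for g in gaps]
        if sum(sizes) + sum(gaps) > protein_length:
            raise ValueError(
                f"protein of {protein_length} aa cannot hold {len(names)} regions "
                f"(minimum {sum(sizes) + sum(gaps)} aa)"
            )
    start = 1 + gaps[0]
    regions = []
    for (name, cls), size, gap in zip(names, sizes, gaps[1:]):
        regions.append(Region(name, cls, start, start + size - 1))
        start += size + int(gap)
    return DomainArchitecture(protein_name, protein_length, regions)


# ---------------------------------------------------------------------------
# Variant simulation
# ---------------------------------------------------------------------------

def _is_transition(ref: str, alt: str) -> bool:
    return TRANSITIONS[ref] == alt


def _is_cpg_deamination(model: GeneModel, pos: int, ref: str, alt: str) -> bool:
    """C→T at a CpG, or G→A at the G of a CpG (reverse-strand deamination)."""
    lo, hi = model.span
    if ref == "C" and alt == "T" and pos + 1 <= hi:
        return model.base(pos + 1) == "G"
    if ref == "G" and alt == "A" and pos - 1 >= lo:
        return model.base(pos - 1) == "C"
    return False


@dataclass
class _SnvCandidate:
    pos: int
    ref: str
    alt: str
    category: str
    protein_pos: Optional[int]
    aa_change: Optional[tuple[str, str]]
    codon_positions: tuple[int, ...]
    is_transition: bool
    is_cpg: bool


def _coding_snv_pools(model: GeneModel) -> dict[str, list[_SnvCandidate]]:
    """Exhaustive 3L enumeration of coding SNVs, bucketed by true category.

    The truth here comes straight from codon arithmetic on the spliced CDS
    (mutate one base, translate one codon) — it never calls the annotator.
    """
    cds = model.cds_sequence
    n_codons = len(cds) // 3
    index = {ci: pos for pos, ci in ((p, model.cds_index_of(p)) for p in model._index())}
    pools: dict[str, list[_SnvCandidate]] = {}
    for ci in range(len(cds)):
        gpos = index[ci]
        ref_genomic = model.base(gpos)
        codon_i, within = divmod(ci, 3)
        ref_codon = cds[codon_i * 3: codon_i * 3 + 3]
        ref_aa = translate_codon(ref_codon)
        for alt_tx in "ACGT":
            if alt_tx == cds[ci]:
                continue
            alt_codon = ref_codon[:within] + alt_tx + ref_codon[within + 1:]
            alt_aa = translate_codon(alt_codon)
            if codon_i == 0 and alt_aa != ref_aa:
                category = "start_loss"
            elif alt_aa == "*" and ref_aa != "*":
                category = "truncation" if codon_i < n_codons - 1 else "synonymous"
            elif ref_aa == "*":
                category = "synonymous" if alt_aa == "*" else "stop_loss"
            elif alt_aa == ref_aa:
                category = "synonymous"
            else:
                category = "missense"
            alt_genomic = alt_tx if model.strand == "+" else complement(alt_tx)
            cand = _SnvCandidate(
                pos=gpos,
                ref=ref_genomic,
                alt=alt_genomic,
                category=category,
                protein_pos=codon_i + 1,
                aa_change=(ref_aa, alt_aa),
                codon_positions=(within + 1,),
                is_transition=_is_transition(ref_genomic, alt_genomic),
                is_cpg=_is_cpg_deamination(model, gpos, ref_genomic, alt_genomic),
            )
            pools.setdefault(category, []).append(cand)
    return pools


def _splice_positions(model: GeneModel) -> list[int]:
    out = []
    for (_s1, e1), (s2, _e2) in zip(model.exons, model.exons[1:]):
        out.extend([e1 + 1, e1 + 2, s2 - 2, s2 - 1])
    return sorted(set(out))


def _noncoding_snv_pool(model: GeneModel) -> tuple[list[_SnvCandidate], list[_SnvCandidate]]:
    """Noncoding SNV candidates (splice ±1/2 sites excluded) by ts/tv class."""
    splice = set(_splice_positions(model))
    lo, hi = model.span
    ts_pool: list[_SnvCandidate] = []
    tv_pool: list[_SnvCandidate] = []
    for pos in range(lo + 1, hi):
        if model.is_coding(pos) or pos in splice:
            continue
        ref = model.base(pos)
        for alt in "ACGT":
            if alt == ref:
                continue
            cand = _SnvCandidate(
                pos=pos, ref=ref, alt=alt, category="noncoding",
                protein_pos=None, aa_change=None, codon_positions=(),
                is_transition=_is_transition(ref, alt),
                is_cpg=_is_cpg_deamination(model, pos, ref, alt),
            )
            (ts_pool if cand.is_transition else tv_pool).append(cand)
    return ts_pool, tv_pool


def _splice_snv_pool(model: GeneModel) -> tuple[list[_SnvCandidate], list[_SnvCandidate]]:
    ts_pool: list[_SnvCandidate] = []
    tv_pool: list[_SnvCandidate] = []
    for pos in _splice_positions(model):
        ref = model.base(pos)
        for alt in "ACGT":
            if alt == ref:
                continue
            cand = _SnvCandidate(
                pos=pos, ref=ref, alt=alt, category="splice",
                protein_pos=None, aa_change=None, codon_positions=(),
                is_transition=_is_transition(ref, alt),
                is_cpg=_is_cpg_deamination(model, pos, ref, alt),
            )
            (ts_pool if cand.is_transition else tv_pool).append(cand)
    return ts_pool, tv_pool


class _PoolSampler:
    """Weighted sampling without replacement from a candidate list."""

    def __init__(self, candidates: list[_SnvCandidate], cpg_multiplier: float):
        self.candidates = list(candidates)
        self.cpg = cpg_multiplier

    def __len__(self) -> int:
        return len(self.candidates)

    def draw(self, rng: np.random.Generator) -> _SnvCandidate:
        if self.cpg == 1.0:
            i = int(rng.integers(0, len(self.candidates)))
        else:
            weights = np.array(
                [self.cpg if c.is_cpg else 1.0 for c in self.candidates], dtype=float
            )
            weights /= weights.sum()
            i = int(rng.choice(len(self.candidates), p=weights))
        return self.candidates.pop(i)


def _truth_entry(rec: VariantRecord, cand: Optional[_SnvCandidate], category: str,
                 exon_index: Optional[int], domain: Optional[str],
                 protein_pos: Optional[int] = None,
                 aa_change: Optional[tuple[str, str]] = None) -> dict:
    return {
        "key": list(rec.key),
        "category": category,
        "codon_positions": list(cand.codon_positions) if cand else [],
        "aa_change": list(cand.aa_change) if cand and cand.aa_change else (
            list(aa_change) if aa_change else None
        ),
        "protein_pos": cand.protein_pos if cand else protein_pos,
        "exon_index": exon_index,
        "domain": domain,
        "is_snv": rec.is_snv,
        "is_transition": cand.is_transition if cand else None,
    }


def _sample_indel(
    model: GeneModel,
    rng: np.random.Generator,
    lengths: Sequence[int],
    probs: Sequence[float],
    *,
    coding: Optional[bool],
    frameshift: Optional[bool],
    used: set,
    max_tries: int = 200,
) -> Optional[tuple[VariantRecord, str, Optional[int]]]:
    """One anchored indel; returns (record, true category, protein_pos)."""
    lo, hi = model.span
    coding_positions = sorted(model._index())
    for _ in range(max_tries):
        length = int(rng.choice(lengths, p=probs))
        if frameshift is True and length % 3 == 0:
            continue
        if frameshift is False and length % 3 != 0:
            continue
        is_del = bool(rng.integers(0, 2))
        if coding:
            anchor = int(rng.choice(coding_positions))
        else:
            anchor = int(rng.integers(lo + 1, hi - length - 1))
        deleted: list[int] = []
        del_coding: list[int] = []
        if is_del:
            if anchor + length > hi:
                continue
            deleted = list(range(anchor + 1, anchor + length + 1))
            del_coding = [p for p in deleted if model.is_coding(p)]
            hits_coding = bool(del_coding)
            if coding is True and len(del_coding) != length:
                continue  # keep directed indels fully inside the CDS
            ref = model.slice(anchor, anchor + length)
            alt = ref[0]
        else:
            hits_coding = model.is_coding(anchor) and model.is_coding(anchor + 1)
            ref = model.base(anchor)
            alt = ref + _random_seq(rng, length)
        if coding is True and not hits_coding:
            continue
        if coding is False and hits_coding:
            continue
        rec = VariantRecord(model.chrom, anchor, ref, alt)
        if rec.key in used:
            continue
        if hits_coding:
            category = "frameshift" if length % 3 else "inframe_indel"
            if is_del:
                first_ci = min(model.cds_index_of(p) for p in del_coding)
            else:
                downstream = anchor + 1 if model.strand == "+" else anchor
                first_ci = model.cds_index_of(downstream)
            protein_pos = first_ci // 3 + 1
        else:
            ann_positions = deleted if is_del else [anchor, anchor + 1]
            splice = set(_splice_positions(model))
            if any(p in splice for p in ann_positions):
                category = "splice"
            else:
                category = "noncoding"
            protein_pos = None
        return rec, category, protein_pos
    return None


def _attach_predictors(
    rng: np.random.Generator, ann: TranscriptAnnotation, damaging_prob: float
) -> dict:
    """Sample SIFT/PolyPhen labels for missense annotations (not predicted)."""
    if "missense_variant" not in ann.consequence_terms:
        return {"sift_damaging": None, "polyphen_damaging": None}
    sift_damaging = bool(rng.random() < damaging_prob)
    polyphen_damaging = bool(rng.random() < damaging_prob)
    if sift_damaging:
        ann.sift = ("deleterious", round(float(rng.uniform(0.0, 0.049)), 3))
    else:
        ann.sift = ("tolerated", round(float(rng.uniform(0.05, 1.0)), 3))
    if polyphen_damaging:
        ann.polyphen = ("probably_damaging", round(float(rng.uniform(0.909, 1.0)), 3))
    elif rng.random() < 0.2:
        ann.polyphen = ("possibly_damaging", round(float(rng.uniform(0.446, 0.908)), 3))
    else:
        ann.polyphen = ("benign", round(float(rng.uniform(0.0, 0.445)), 3))
    return {"sift_damaging": sift_damaging, "polyphen_damaging": polyphen_damaging}


def simulate_variants(
    model: GeneModel,
    mm: MutationModel,
    arch: Optional[DomainArchitecture] = None,
) -> tuple[list[VariantRecord], GroundTruth]:
    """Draw a cohort of annotated variants plus generation-time ground truth.

    Records come back annotated by the internal annotator; the
    :class:`GroundTruth` category/protein fields are computed during
    generation from codon arithmetic and never read back from those
    annotations.  Deterministic given ``mm.seed``; keys are unique in
    directed mode (``category_proportions`` set).
    """
    rng = np.random.default_rng(mm.seed)
    truth = GroundTruth(
        configured={
            "n_variants": mm.n_variants,
            "snv_fraction": mm.snv_fraction,
            "ts_tv_ratio": mm.ts_tv_ratio,
            "cpg_multiplier": mm.cpg_multiplier,
            "positional_model": mm.positional_model,
            "category_proportions": mm.category_proportions,
            "noncoding_fraction": (
                mm.noncoding_fraction if mm.category_proportions else None
            ),
            "seed": mm.seed,
        }
    )
    records: list[VariantRecord] = []
    used: set = set()
    p_ts = mm.ts_tv_ratio / (mm.ts_tv_ratio + 1.0)
    lengths = sorted(mm.indel_length_distribution)
    length_probs = [mm.indel_length_distribution[k] for k in lengths]

    def finalize(rec: VariantRecord, cand: Optional[_SnvCandidate], category: str,
                 protein_pos: Optional[int] = None) -> None:
        ann = annotate_variant(model, rec)
        pred = _attach_predictors(rng, ann, mm.damaging_prob)
        rec.annotations.append(ann)
        pp = cand.protein_pos if cand else protein_pos
        domain = None
        if arch is not None and pp is not None and 1 <= pp <= arch.length_aa:
            domain = map_to_domain(pp, arch)
        entry = _truth_entry(
            rec, cand, category, model.exon_index_of(rec.pos), domain, protein_pos=pp
        )
        entry.update(pred)
        truth.entries.append(entry)
        used.add(rec.key)
        records.append(rec)

    if mm.category_proportions is not None:
        _simulate_directed(model, mm, rng, p_ts, lengths, length_probs, used, finalize)
    else:
        _simulate_undirected(model, mm, rng, lengths, length_probs, used, finalize)

    return records, truth


def _simulate_directed(model, mm, rng, p_ts, lengths, length_probs, used, finalize) -> None:
    coding_pools = _coding_snv_pools(model)
    samplers: dict[tuple[str, bool], _PoolSampler] = {}
    for cat, pool in coding_pools.items():
        for is_ts in (True, False):
            samplers[(cat, is_ts)] = _PoolSampler(
                [c for c in pool if c.is_transition is is_ts], mm.cpg_multiplier
            )
    for cat, (ts_pool, tv_pool) in (
        ("splice", _splice_snv_pool(model)),
        ("noncoding", _noncoding_snv_pool(model)),
    ):
        samplers[(cat, True)] = _PoolSampler(ts_pool, mm.cpg_multiplier)
        samplers[(cat, False)] = _PoolSampler(tv_pool, mm.cpg_multiplier)

    cats = sorted(mm.category_proportions)
    cat_probs = np.array([mm.category_proportions[c] for c in cats])
    cat_probs = cat_probs / cat_probs.sum()

    for _ in range(mm.n_variants):
        if rng.random() < mm.noncoding_fraction:
            category = "noncoding"
        else:
            category = cats[int(rng.choice(len(cats), p=cat_probs))]
        if category in ("frameshift", "inframe_indel"):
            got = _sample_indel(
                model, rng, lengths, length_probs,
                coding=True, frameshift=(category == "frameshift"), used=used,
            )
            if got is None:
                log.warning("could not place a %s indel; skipping draw", category)
                continue
            rec, true_cat, protein_pos = got
            finalize(rec, None, true_cat, protein_pos)
            continue
        is_ts = bool(rng.random() < p_ts)
        sampler = samplers.get((category, is_ts))
        if sampler is None or len(sampler) == 0:
            sampler = samplers.get((category, not is_ts))
        if sampler is None or len(sampler) == 0:
            log.warning("pool for category %s exhausted; skipping draw", category)
            continue
        cand = sampler.draw(rng)
        rec = VariantRecord(model.chrom, cand.pos, cand.ref, cand.alt)
        finalize(rec, cand, cand.category)


def _simulate_undirected(model, mm, rng, lengths, length_probs, used, finalize) -> None:
    lo, hi = model.span
    coding_positions = sorted(model._index())
    coding_pools = _coding_snv_pools(model)
    coding_lookup: dict[tuple[int, str], _SnvCandidate] = {
        (c.pos, c.alt): c for pool in coding_pools.values() for c in pool
    }
    splice = set(_splice_positions(model))

    # CpG elevation raises the SITE's mutation rate, so position sampling is
    # weighted by each position's total substitution weight, not uniform.
    if mm.positional_model == "uniform_coding":
        positions = np.array(coding_positions)
    else:
        positions = np.arange(lo + 1, hi)
    base_w = 2.0 * mm.ts_tv_ratio + 2.0
    pos_weights = np.full(len(positions), base_w)
    if mm.cpg_multiplier != 1.0:
        seq = model.sequence
        off = model.seq_offset
        for i, pos in enumerate(positions):
            b = seq[pos - off]
            if (b == "C" and pos + 1 <= hi and seq[pos + 1 - off] == "G") or (
                b == "G" and pos - 1 >= lo and seq[pos - 1 - off] == "C"
            ):
                pos_weights[i] = 2.0 * mm.ts_tv_ratio * mm.cpg_multiplier + 2.0
    pos_cum = np.cumsum(pos_weights)

    for _ in range(mm.n_variants):
        if rng.random() < mm.snv_fraction:
            # Recurrent alleles are allowed here: rejecting used keys would
            # deplete the (smaller) transition pool faster and bias the
            # realised Ts/Tv below the configured ratio on small loci.
            idx = int(np.searchsorted(pos_cum, rng.random() * pos_cum[-1]))
            pos = int(positions[idx])
            ref = model.base(pos)
            alts = [b for b in "ACGT" if b != ref]
            weights = []
            for alt in alts:
                w = 2.0 * mm.ts_tv_ratio if _is_transition(ref, alt) else 1.0
                if _is_cpg_deamination(model, pos, ref, alt):
                    w *= mm.cpg_multiplier
                weights.append(w)
            w = np.array(weights) / sum(weights)
            alt = alts[int(rng.choice(3, p=w))]
            rec = VariantRecord(model.chrom, pos, ref, alt)
            cand = coding_lookup.get((pos, alt))
            if cand is not None:
                finalize(rec, cand, cand.category)
            else:
                category = "splice" if pos in splice else "noncoding"
                finalize(rec, _snv_stub(model, pos, ref, alt, category), category)
        else:
            scope_coding = mm.positional_model == "uniform_coding"
            got = _sample_indel(
                model, rng, lengths, length_probs,
                coding=True if scope_coding else None, frameshift=None, used=used,
            )
            if got is None:
                log.warning("could not place an indel; skipping draw")
                continue
            rec, category, protein_pos = got
            finalize(rec, None, category, protein_pos)


def _snv_stub(model, pos, ref, alt, category) -> _SnvCandidate:
    return _SnvCandidate(
        pos=pos, ref=ref, alt=alt, category=category,
        protein_pos=None, aa_change=None, codon_positions=(),
        is_transition=_is_transition(ref, alt),
        is_cpg=_is_cpg_deamination(model, pos, ref, alt),
    )


# ---------------------------------------------------------------------------
# VEP --tab serialisation (the dialect variant_io reads back)
# ---------------------------------------------------------------------------

_VEP_COLUMNS = [
    "#Uploaded_variation", "Location", "Allele", "SYMBOL", "Gene", "Feature",
    "Consequence", "EXON", "Protein_position", "Amino_acids", "Codons",
    "Existing_variation", "SIFT", "PolyPhen",
]


def _fmt_predictor(value: Optional[tuple[str, float]]) -> str:
    if value is None:
        return "-"
    label, score = value
    return f"{label}({score:g})"


def write_vep_table(
    records: Sequence[VariantRecord], path: str | Path, *, n_exons: Optional[int] = None
) -> None:
    """Write one row per (variant, annotation) in the VEP ``--tab`` dialect.

    Codon fields use VEP case markup (``gGg/gAg``); synonymous amino-acid
    fields collapse to the single letter, as VEP prints them.
    """
    with open(path, "w") as fh:
        fh.write("## ENSEMBL VARIANT EFFECT PREDICTOR (synthetic emulation)\n")
        fh.write("## Output produced by mybpc-landscape synthetic_data\n")
        fh.write("\t".join(_VEP_COLUMNS) + "\n")
        for rec in records:
            uploaded = f"{rec.chrom}_{rec.pos}_{rec.ref}/{rec.alt}"
            location = f"{rec.chrom}:{rec.pos}"
            anns = rec.annotations or [None]
            for ann in anns:
                if ann is None:
                    row = [uploaded, location, rec.alt] + ["-"] * 11
                    fh.write("\t".join(row) + "\n")
                    continue
                if ann.exon_index is None:
                    exon = "-"
                elif n_exons is not None:
                    exon = f"{ann.exon_index}/{n_exons}"
                else:
                    exon = str(ann.exon_index)
                if ann.aa_change is None:
                    aa = "-"
                elif ann.aa_change[0] == ann.aa_change[1]:
                    aa = ann.aa_change[0]
                else:
                    aa = f"{ann.aa_change[0]}/{ann.aa_change[1]}"
                codons = "/".join(ann.codon_change) if ann.codon_change else "-"
                row = [
                    uploaded,
                    location,
                    rec.alt,
                    ann.gene_symbol or "-",
                    ann.gene_symbol or "-",
                    ann.transcript_id or "-",
                    ",".join(ann.consequence_terms),
                    exon,
                    str(ann.protein_pos) if ann.protein_pos is not None else "-",
                    aa,
                    codons,
                    rec.rs_id or "-",
                    _fmt_predictor(ann.sift),
                    _fmt_predictor(ann.polyphen),
                ]
                fh.write("\t".join(row) + "\n")


__all__ = [
    "MutationModel",
    "GroundTruth",
    "DEFAULT_CODING_PROPORTIONS",
    "make_gene_model",
    "make_architecture",
    "simulate_variants",
    "write_vep_table",
    "write_vcf",
    "write_gene_model",
    "read_gene_model",
]
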