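"""Genetic-code arithmetic and consequence classification.

This module is the in-repo stand-in for VEP: it maps Sequence-Ontology
consequence terms onto the analysis categories, computes which codon
position a substitution hits, translates codons (NCBI table 1), and
annotates variants against a :class:`GeneModel` by splicing the CDS,
reverse-complementing on the minus strand, substituting and translating.

Coordinates are 1-based inclusive at every public boundary (VCF/UniProt
convention); interval arithmetic inside is 0-based half-open.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio.Data import CodonTable
from Bio.Seq import Seq

from .variant_io import TranscriptAnnotation, VariantRecord

log = logging.getLogger(__name__)

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# Standard nuclear genetic code (NCBI translation table 1).
_TABLE = CodonTable.unambiguous_dna_by_id[1]
GENETIC_CODE: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    GENETIC_CODE[_stop] = "*"

STOP_CODONS = frozenset(_TABLE.stop_codons)
AMINO_ACIDS = sorted(set(_TABLE.forward_table.values()))
TRANSITIONS = {"A": "G", "G": "A", "C": "T", "T": "C"}


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """Translate one codon; returns ``*`` for a stop.

    Raises ``ValueError`` on anything that is not three of {A,C,G,T}.
    """
    codon = codon.upper()
    try:
        return GENETIC_CODE[codon]
    except KeyError:
        raise ValueError(f"not a valid codon: {codon!r}") from None


def translate_cds(cds: str) -> str:
    """Translate a CDS (length multiple of 3), keeping internal ``*``."""
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    return str(Seq(cds).translate())


class ConsequenceCategory(str, enum.Enum):
    """Analysis buckets for consequence terms.

    ``truncation`` is stop-gain only; frameshifts are a separate bucket
    even though both shorten the protein.  ``noncoding`` covers intronic,
    UTR and up/downstream annotations.
    """

    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    TRUNCATION = "truncation"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    SPLICE = "splice"
    START_LOSS = "start_loss"
    STOP_LOSS = "stop_loss"
    PROTEIN_ALTERING_OTHER = "protein_altering_other"
    NONCODING = "noncoding"


CODING_CATEGORIES = tuple(c for c in ConsequenceCategory if c is not ConsequenceCategory.NONCODING)

#: Term -> category, listed most-severe first (Ensembl-style severity).
#: classify_terms resolves multi-term annotations by the first hit in this
#: order.  splice_region_variant deliberately ranks below synonymous: it is
#: a positional modifier and must not mask a coding call.
_TERM_PRIORITY: list[tuple[str, ConsequenceCategory]] = [
    ("start_lost", ConsequenceCategory.START_LOSS),
    ("stop_gained", ConsequenceCategory.TRUNCATION),
    ("frameshift_variant", ConsequenceCategory.FRAMESHIFT),
    ("stop_lost", ConsequenceCategory.STOP_LOSS),
    ("splice_donor_variant", ConsequenceCategory.SPLICE),
    ("splice_acceptor_variant", ConsequenceCategory.SPLICE),
    ("inframe_insertion", ConsequenceCategory.INFRAME_INDEL),
    ("inframe_deletion", ConsequenceCategory.INFRAME_INDEL),
    ("missense_variant", ConsequenceCategory.MISSENSE),
    ("protein_altering_variant", ConsequenceCategory.PROTEIN_ALTERING_OTHER),
    ("synonymous_variant", ConsequenceCategory.SYNONYMOUS),
    ("stop_retained_variant", ConsequenceCategory.SYNONYMOUS),
    ("splice_region_variant", ConsequenceCategory.NONCODING),
    ("5_prime_UTR_variant", ConsequenceCategory.NONCODING),
    ("3_prime_UTR_variant", ConsequenceCategory.NONCODING),
    ("intron_variant", ConsequenceCategory.NONCODING),
    ("upstream_gene_variant", ConsequenceCategory.NONCODING),
    ("downstream_gene_variant", ConsequenceCategory.NONCODING),
    ("intergenic_variant", ConsequenceCategory.NONCODING),
]
_TERM_RANK = {term: i for i, (term, _) in enumerate(_TERM_PRIORITY)}
_TERM_CATEGORY = dict(_TERM_PRIORITY)


def classify_terms(terms: Sequence[str]) -> ConsequenceCategory:
    """Map a (possibly multi-term) consequence list onto one category.

    The highest-priority recognised term wins.  Unrecognised-only lists
    fall back to ``protein_altering_other`` with a logged warning.
    """
    if not terms:
        raise ValueError("terms must be non-empty")
    known = [t for t in terms if t in _TERM_RANK]
    if not known:
        log.warning("no recognised consequence term in %r", list(terms))
        return ConsequenceCategory.PROTEIN_ALTERING_OTHER
    best = min(known, key=_TERM_RANK.__getitem__)
    return _TERM_CATEGORY[best]


def classify_annotation(ann: TranscriptAnnotation) -> ConsequenceCategory:
    return classify_terms(ann.consequence_terms)


# ---------------------------------------------------------------------------
# Codon changes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonChange:
    """A reference/alternate codon pair plus the 1-based changed positions."""

    ref_codon: str
    alt_codon: str
    changed_positions: frozenset[int]

    def __post_init__(self) -> None:
        if len(self.ref_codon) != 3 or len(self.alt_codon) != 3:
            raise ValueError("codons must have length 3")
        true_diff = frozenset(
            i + 1 for i in range(3) if self.ref_codon[i].upper() != self.alt_codon[i].upper()
        )
        if not true_diff:
            raise ValueError("codons must differ at >= 1 position")
        if self.changed_positions != true_diff:
            raise ValueError(
                f"changed_positions {set(self.changed_positions)} inconsistent with "
                f"base differences {set(true_diff)}"
            )

    @classmethod
    def from_codons(cls, ref_codon: str, alt_codon: str) -> "CodonChange":
        diff = frozenset(
            i + 1 for i in range(3) if ref_codon[i].upper() != alt_codon[i].upper()
        )
        return cls(ref_codon, alt_codon, diff)

    @classmethod
    def from_vep_markup(cls, ref_codon: str, alt_codon: str) -> "CodonChange":
        """Parse VEP case markup (``gGg/gAg``): uppercase = substituted.

        The uppercase positions are cross-checked against the literal base
        difference; inconsistency raises ``ValueError``.
        """
        has_markup = any(c.islower() for c in ref_codon + alt_codon)
        upper = frozenset(i + 1 for i in range(3) if ref_codon[i].isupper() or alt_codon[i].isupper())
        change = cls.from_codons(ref_codon, alt_codon)
        if has_markup and upper != change.changed_positions:
            raise ValueError(
                f"VEP case markup {ref_codon}/{alt_codon} marks positions {set(upper)} "
                f"but bases differ at {set(change.changed_positions)}"
            )
        return change


def codon_position_of_change(change: CodonChange) -> frozenset[int]:
    """Which of codon positions {1,2,3} a substitution touches."""
    return change.changed_positions


def vep_codon_markup(ref_codon: str, alt_codon: str) -> tuple[str, str]:
    """Render a codon pair in VEP case markup (changed bases uppercase)."""
    ref_out = []
    alt_out = []
    for r, a in zip(ref_codon.upper(), alt_codon.upper()):
        if r == a:
            ref_out.append(r.lower())
            alt_out.append(a.lower())
        else:
            ref_out.append(r)
            alt_out.append(a)
    return "".join(ref_out), "".join(alt_out)


# ---------------------------------------------------------------------------
# Nonsense accessibility of the genetic code
# ---------------------------------------------------------------------------

def enumerate_single_substitutions() -> Iterable[tuple[str, str, int, str, str]]:
    """Yield (codon, alt_codon, position 1..3, ref_aa, alt_aa) for all 64x9."""
    for codon in GENETIC_CODE:
        ref_aa = GENETIC_CODE[codon]
        for i in range(3):
            for base in _BASES:
                if base == codon[i]:
                    continue
                alt_codon = codon[:i] + base + codon[i + 1:]
                yield codon, alt_codon, i + 1, ref_aa, GENETIC_CODE[alt_codon]


def stop_accessibility() -> dict[str, tuple[int, int]]:
    """Per amino acid: (single substitutions reaching a stop, total substitutions).

    Exhaustive over all 64 codons x 9 single-base changes, aggregated over
    each amino acid's codons.  This is the mechanistic null for why Trp and
    Tyr dominate premature-stop spectra: both reach a stop in 2 of the 9
    single-base changes of each of their codons.
    """
    out: dict[str, list[int]] = {aa: [0, 0] for aa in AMINO_ACIDS}
    for _codon, _alt, _pos, ref_aa, alt_aa in enumerate_single_substitutions():
        if ref_aa == "*":
            continue
        out[ref_aa][1] += 1
        if alt_aa == "*":
            out[ref_aa][0] += 1
    return {aa: (n_stop, n_total) for aa, (n_stop, n_total) in out.items()}


# ---------------------------------------------------------------------------
# Gene model
# ---------------------------------------------------------------------------

class AnnotationRangeError(ValueError):
    """Variant lies outside the gene model's sequence span."""


@dataclass
class GeneModel:
    """Transcript structure over a locus sequence.

    ``exons`` are genomic 1-based inclusive intervals in ascending order;
    ``cds_start``/``cds_end`` bound the coding span in genomic coordinates
    regardless of strand; ``sequence`` is the plus-strand locus sequence
    whose first base sits at genomic coordinate ``seq_offset``.
    """

    gene_symbol: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int
    sequence: str
    seq_offset: int = 1
    _cds_index: dict[int, int] = field(default=None, repr=False, compare=False)  # type: ignore[assignment]
    _cds_seq: str = field(default=None, repr=False, compare=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.exons = tuple((int(s), int(e)) for s, e in self.exons)
        for (s, e) in self.exons:
            if s > e:
                raise ValueError(f"exon {s}-{e} is inverted")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 >= s2:
                raise ValueError("exons must be sorted and non-overlapping")

    # -- spans ------------------------------------------------------------

    @property
    def span(self) -> tuple[int, int]:
        return (self.seq_offset, self.seq_offset + len(self.sequence) - 1)

    @property
    def gene_span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def base(self, pos: int) -> str:
        lo, hi = self.span
        if not lo <= pos <= hi:
            raise AnnotationRangeError(f"position {pos} outside locus span {lo}-{hi}")
        return self.sequence[pos - self.seq_offset]

    def slice(self, start: int, end: int) -> str:
        """Plus-strand sequence of the 1-based inclusive interval."""
        return "".join(self.base(p) for p in range(start, end + 1))

    # -- exon / CDS indexing ----------------------------------------------

    @property
    def tx_exons(self) -> tuple[tuple[int, int], ...]:
        """Exons in transcription order."""
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))

    def exon_index_of(self, pos: int) -> Optional[int]:
        """1-based exon ordinal in transcription order, or None if intronic."""
        for i, (s, e) in enumerate(self.tx_exons, start=1):
            if s <= pos <= e:
                return i
        return None

    def _index(self) -> dict[int, int]:
        if self._cds_index is None:
            positions: list[int] = []
            for (s, e) in self.tx_exons:
                lo = max(s, self.cds_start)
                hi = min(e, self.cds_end)
                if lo > hi:
                    continue
                rng = range(lo, hi + 1) if self.strand == "+" else range(hi, lo - 1, -1)
                positions.extend(rng)
            self._cds_index = {pos: i for i, pos in enumerate(positions)}
            bases = (
                self.base(p) if self.strand == "+" else complement(self.base(p))
                for p in positions
            )
            self._cds_seq = "".join(bases)
        return self._cds_index

    @property
    def cds_sequence(self) -> str:
        """Spliced, strand-oriented coding sequence (starts ATG, ends stop)."""
        self._index()
        return self._cds_seq

    @property
    def protein(self) -> str:
        return translate_cds(self.cds_sequence)[:-1]

    def cds_index_of(self, pos: int) -> Optional[int]:
        """0-based position within the spliced CDS, or None if non-coding."""
        return self._index().get(pos)

    def is_coding(self, pos: int) -> bool:
        return pos in self._index()

    def validate(self) -> None:
        cds = self.cds_sequence
        if len(cds) < 6 or len(cds) % 3:
            raise ValueError(f"spliced CDS length {len(cds)} invalid (need multiple of 3, >= 6)")
        if not cds.startswith("ATG"):
            raise ValueError("spliced CDS must begin with ATG")
        if cds[-3:] not in STOP_CODONS:
            raise ValueError("spliced CDS must end with a stop codon")
        span_lo, span_hi = self.span
        if self.exons[0][0] < span_lo or self.exons[-1][1] > span_hi:
            raise ValueError("exons extend beyond the locus sequence")
        union_ok = any(s <= self.cds_start <= e for s, e in self.exons) and any(
            s <= self.cds_end <= e for s, e in self.exons
        )
        if not union_ok:
            raise ValueError("CDS bounds must lie within exons")

    # -- positional classification ----------------------------------------

    def splice_site_term(self, pos: int) -> Optional[str]:
        """splice_donor/splice_acceptor for the first/last 2 intronic bases."""
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            intron_lo, intron_hi = e1 + 1, s2 - 1
            if not intron_lo <= pos <= intron_hi:
                continue
            at_low_edge = pos - intron_lo < 2
            at_high_edge = intron_hi - pos < 2
            if not (at_low_edge or at_high_edge):
                return None
            # Donor = intron end adjacent to the transcription-upstream exon.
            if self.strand == "+":
                return "splice_donor_variant" if at_low_edge else "splice_acceptor_variant"
            return "splice_donor_variant" if at_high_edge else "splice_acceptor_variant"
        return None

    def is_intronic(self, pos: int) -> bool:
        lo, hi = self.gene_span
        return lo <= pos <= hi and self.exon_index_of(pos) is None

    def noncoding_term(self, pos: int) -> str:
        """SO term for a non-CDS position (splice > UTR > intron > flank)."""
        splice = self.splice_site_term(pos)
        if splice is not None:
            return splice
        if self.exon_index_of(pos) is not None:
            if self.strand == "+":
                return "5_prime_UTR_variant" if pos < self.cds_start else "3_prime_UTR_variant"
            return "5_prime_UTR_variant" if pos > self.cds_end else "3_prime_UTR_variant"
        if self.is_intronic(pos):
            return "intron_variant"
        lo, hi = self.gene_span
        if self.strand == "+":
            return "upstream_gene_variant" if pos < lo else "downstream_gene_variant"
        return "upstream_gene_variant" if pos > hi else "downstream_gene_variant"


# ---------------------------------------------------------------------------
# The annotator
# ---------------------------------------------------------------------------

_NONCODING_PRIORITY = [
    "splice_donor_variant",
    "splice_acceptor_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "intron_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
]


def _substitution_annotation(
    model: GeneModel, v: VariantRecord, changed: list[int]
) -> TranscriptAnnotation:
    """Same-length substitution with every changed base inside the CDS."""
    cds = model.cds_sequence
    sub: dict[int, str] = {}
    for gpos in changed:
        offset = gpos - v.pos
        alt_base = v.alt[offset]
        ci = model.cds_index_of(gpos)
        sub[ci] = alt_base if model.strand == "+" else complement(alt_base)
    codon_indices = sorted({ci // 3 for ci in sub})
    mutant = list(cds)
    for ci, b in sub.items():
        mutant[ci] = b
    mutant = "".join(mutant)

    n_codons = len(cds) // 3
    first = codon_indices[0]
    ref_codon = cds[first * 3: first * 3 + 3]
    alt_codon = mutant[first * 3: first * 3 + 3]
    aa_pairs = []
    for ci in codon_indices:
        aa_pairs.append((translate_cds(cds[ci * 3: ci * 3 + 3]), translate_cds(mutant[ci * 3: ci * 3 + 3])))

    if 0 in codon_indices and aa_pairs[codon_indices.index(0)][0] != aa_pairs[codon_indices.index(0)][1]:
        term = "start_lost"
    elif any(r != a and a == "*" for r, a in aa_pairs):
        term = "stop_gained"
    elif any(r == "*" and a != "*" for r, a in aa_pairs):
        term = "stop_lost"
    elif all(r == a for r, a in aa_pairs):
        term = "stop_retained_variant" if first == n_codons - 1 else "synonymous_variant"
    else:
        term = "missense_variant"

    codon_change = None
    aa_change = None
    if len(codon_indices) == 1:
        codon_change = vep_codon_markup(ref_codon, alt_codon)
        aa_change = aa_pairs[0]
    return TranscriptAnnotation(
        transcript_id=model.transcript_id,
        gene_symbol=model.gene_symbol,
        consequence_terms=[term],
        exon_index=model.exon_index_of(changed[0]),
        codon_change=codon_change,
        protein_pos=first + 1,
        aa_change=aa_change,
    )


def _noncoding_annotation(model: GeneModel, positions: Sequence[int]) -> TranscriptAnnotation:
    terms = {model.noncoding_term(p) for p in positions if not model.is_coding(p)}
    term = min(terms, key=_NONCODING_PRIORITY.index)
    anchor = positions[0]
    return TranscriptAnnotation(
        transcript_id=model.transcript_id,
        gene_symbol=model.gene_symbol,
        consequence_terms=[term],
        exon_index=model.exon_index_of(anchor),
    )


def _indel_annotation(model: GeneModel, v: VariantRecord) -> TranscriptAnnotation:
    """Anchored VCF-style indel (shared leading base)."""
    dlen = len(v.alt) - len(v.ref)
    deleted = list(range(v.pos + 1, v.pos + len(v.ref)))  # empty for pure insertion
    if dlen < 0:
        coding_hit = [p for p in deleted if model.is_coding(p)]
        affected = deleted
    else:
        # Insertion between pos and pos+1: coding when both flanks are coding.
        coding_hit = (
            [v.pos] if model.is_coding(v.pos) and model.is_coding(v.pos + 1) else []
        )
        affected = [v.pos, v.pos + 1]

    if coding_hit:
        if dlen % 3 != 0:
            term = "frameshift_variant"
        else:
            term = "inframe_insertion" if dlen > 0 else "inframe_deletion"
        if dlen < 0:
            first_ci = min(model.cds_index_of(p) for p in coding_hit)
        else:
            downstream = v.pos + 1 if model.strand == "+" else v.pos
            first_ci = model.cds_index_of(downstream)
        codon_i = first_ci // 3
        cds = model.cds_sequence
        ref_aa = translate_cds(cds[codon_i * 3: codon_i * 3 + 3])
        aa_change = (ref_aa, "X") if term == "frameshift_variant" else None
        return TranscriptAnnotation(
            transcript_id=model.transcript_id,
            gene_symbol=model.gene_symbol,
            consequence_terms=[term],
            exon_index=model.exon_index_of(coding_hit[0] if dlen < 0 else v.pos),
            protein_pos=codon_i + 1,
            aa_change=aa_change,
        )
    return _noncoding_annotation(model, affected)


def annotate_variant(model: GeneModel, v: VariantRecord) -> TranscriptAnnotation:
    """Annotate one variant against a gene model (the internal VEP stand-in).

    SNVs and same-codon MNVs in the CDS get codon change, protein position
    and amino-acid change by splicing, substituting and translating; CDS
    indels classify as frameshift or in-frame by length; intronic SNVs in
    the first/last two bases of an intron become splice donor/acceptor
    calls (strand-aware); everything else falls through to UTR, intron or
    up/downstream terms.

    Raises :class:`AnnotationRangeError` when the variant lies outside the
    model's sequence span, ``ValueError`` when REF disagrees with it.
    """
    lo, hi = model.span
    if not (lo <= v.pos and v.pos + len(v.ref) - 1 <= hi):
        raise AnnotationRangeError(
            f"{v.chrom}:{v.pos} {v.ref}>{v.alt} outside locus span {lo}-{hi}"
        )
    expected = model.slice(v.pos, v.pos + len(v.ref) - 1)
    if expected != v.ref:
        raise ValueError(
            f"REF mismatch at {v.chrom}:{v.pos}: variant says {v.ref}, model has {expected}"
        )

    if len(v.ref) == len(v.alt):
        changed = [v.pos + i for i in range(len(v.ref)) if v.ref[i] != v.alt[i]]
        if all(model.is_coding(p) for p in changed):
            return _substitution_annotation(model, v, changed)
        return _noncoding_annotation(model, changed)
    return _indel_annotation(model, v)


def annotate_records(model: GeneModel, records: Sequence[VariantRecord]) -> None:
    """Attach one internal annotation per record, in place."""
    for rec in records:
        rec.annotations.append(annotate_variant(model, rec))
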