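"""Reading, normalising, de-duplicating and filtering variant records.

The input dialects are the two files a gnomAD/VEP workflow hands you:

* the VEP ``--tab`` output (``#``-prefixed header, one row per
  variant-transcript consequence), and
* a VCF 4.x of the underlying variants (read through :mod:`pysam`).

Variant identity throughout the package is the tuple
``(chrom, pos, ref, alt)`` with VCF conventions: 1-based position,
non-empty alleles, indels anchored on a shared leading base.  rsIDs are
carried but never used for identity because aggregated databases reuse
them across alternate alleles.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pysam
import yaml

log = logging.getLogger(__name__)

_ALLELE_RE = re.compile(r"^[ACGT]+$")

SIFT_LABELS = {
    "deleterious",
    "deleterious_low_confidence",
    "tolerated",
    "tolerated_low_confidence",
}
POLYPHEN_LABELS = {"probably_damaging", "possibly_damaging", "benign", "unknown"}


@dataclass
class TranscriptAnnotation:
    """One VEP-style consequence payload for a (variant, transcript) pair.

    ``codon_change`` keeps the VEP case markup (lowercase unchanged,
    uppercase substituted bases, e.g. ``("gGg", "gAg")``).  ``aa_change``
    uses one-letter code with ``*`` for stop and ``X`` for the shifted
    tail of a frameshift.
    """

    transcript_id: str
    gene_symbol: str
    consequence_terms: list[str]
    exon_index: Optional[int] = None
    codon_change: Optional[tuple[str, str]] = None
    protein_pos: Optional[int] = None
    aa_change: Optional[tuple[str, str]] = None
    sift: Optional[tuple[str, float]] = None
    polyphen: Optional[tuple[str, float]] = None

    def __post_init__(self) -> None:
        if not self.consequence_terms:
            raise ValueError("consequence_terms must be non-empty")
        if self.codon_change is not None:
            ref_c, alt_c = self.codon_change
            if len(ref_c) != 3 or len(alt_c) != 3:
                raise ValueError(f"codons must have length 3: {self.codon_change}")
            if ref_c.upper() == alt_c.upper():
                raise ValueError(f"codon_change must differ: {self.codon_change}")
        if self.aa_change is not None and self.protein_pos is None:
            raise ValueError("aa_change requires protein_pos")

    @property
    def base_transcript_id(self) -> str:
        return strip_version(self.transcript_id)


@dataclass
class VariantRecord:
    """One normalised, biallelic variant and its per-transcript annotations."""

    chrom: str
    pos: int
    ref: str
    alt: str
    rs_id: Optional[str] = None
    annotations: list[TranscriptAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("empty alleles are forbidden (use the VCF anchor base)")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) is not a variant")
        for allele in (self.ref, self.alt):
            if not _ALLELE_RE.match(allele):
                raise ValueError(f"allele {allele!r} is not over {{A,C,G,T}}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass
class CleaningReport:
    """Audit trail of the cleaning stages; counts are non-increasing."""

    n_input: int = 0
    n_after_dedup: int = 0
    n_after_transcript_filter: int = 0
    n_after_gene_filter: int = 0
    removed_gene_symbols: dict[str, int] = field(default_factory=dict)
    n_rows_read: int = 0
    n_rows_skipped: int = 0

    def validate(self) -> None:
        counts = [
            self.n_input,
            self.n_after_dedup,
            self.n_after_transcript_filter,
            self.n_after_gene_filter,
        ]
        if any(a < b for a, b in zip(counts, counts[1:])):
            raise ValueError(f"cleaning counts must be non-increasing: {counts}")

    def to_dict(self) -> dict:
        return {
            "n_rows_read": self.n_rows_read,
            "n_rows_skipped": self.n_rows_skipped,
            "n_input": self.n_input,
            "n_after_dedup": self.n_after_dedup,
            "n_after_transcript_filter": self.n_after_transcript_filter,
            "n_after_gene_filter": self.n_after_gene_filter,
            "removed_gene_symbols": dict(self.removed_gene_symbols),
        }


def strip_version(transcript_id: str) -> str:
    """``ENST00000361466.5`` -> ``ENST00000361466``."""
    return transcript_id.split(".", 1)[0]


# ---------------------------------------------------------------------------
# VEP --tab dialect
# ---------------------------------------------------------------------------

#: Column mapping for the VEP ``--tab`` dialect this package writes and the
#: stock VEP output uses (``--sift b --polyphen b --symbol --numbers``).
DEFAULT_DIALECT: dict[str, str] = {
    "uploaded_variation": "#Uploaded_variation",
    "location": "Location",
    "allele": "Allele",
    "gene_symbol": "SYMBOL",
    "transcript": "Feature",
    "consequence": "Consequence",
    "exon": "EXON",
    "protein_position": "Protein_position",
    "amino_acids": "Amino_acids",
    "codons": "Codons",
    "existing_variation": "Existing_variation",
    "sift": "SIFT",
    "polyphen": "PolyPhen",
}

MANDATORY_DIALECT_KEYS = (
    "uploaded_variation",
    "location",
    "allele",
    "consequence",
    "transcript",
)


class DialectError(ValueError):
    """A named column required by the dialect is missing from the file."""


def load_dialect(path: str | Path) -> dict[str, str]:
    """Read a YAML column-name mapping, falling back to defaults per key."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    dialect = dict(DEFAULT_DIALECT)
    dialect.update({k: str(v) for k, v in user.items()})
    return dialect


_MISSING = {"", "-", ".", "NA"}


def _opt(value: str) -> Optional[str]:
    value = value.strip()
    return None if value in _MISSING else value


_PRED_RE = re.compile(r"^([A-Za-z_]+)\(([-0-9.eE]+)\)$")


def _parse_predictor(raw: Optional[str], vocab: set[str]) -> Optional[tuple[str, float]]:
    """Parse ``deleterious(0.02)`` / ``probably_damaging(0.98)`` fields."""
    if raw is None:
        return None
    m = _PRED_RE.match(raw)
    if m:
        label, score = m.group(1), float(m.group(2))
    else:
        label, score = raw, float("nan")
    if label not in vocab:
        log.warning("unknown predictor label %r", label)
    return (label, score)


def _parse_uploaded_variation(raw: str) -> Optional[tuple[str, int, str, str]]:
    """Parse the ``chrom_pos_ref/alt`` form VEP emits for VCF input."""
    try:
        chrom, pos_s, alleles = raw.rsplit("_", 2)
        ref, alt = alleles.split("/", 1)
        pos = int(pos_s)
    except ValueError:
        return None
    if pos < 1 or not _ALLELE_RE.match(ref) or not _ALLELE_RE.match(alt) or ref == alt:
        return None
    return chrom, pos, ref, alt


def _row_to_annotation(row: Mapping[str, str], dialect: Mapping[str, str]) -> TranscriptAnnotation:
    def col(key: str) -> Optional[str]:
        name = dialect.get(key)
        if name is None or name not in row:
            return None
        return _opt(row[name])

    terms_raw = col("consequence")
    terms = [t.strip() for t in terms_raw.split(",")] if terms_raw else []

    exon_index: Optional[int] = None
    exon_raw = col("exon")
    if exon_raw is not None:
        try:
            exon_index = int(exon_raw.split("/", 1)[0])
        except ValueError:
            log.warning("unparseable EXON field %r", exon_raw)

    codon_change = None
    codons_raw = col("codons")
    if codons_raw is not None and "/" in codons_raw:
        ref_c, alt_c = codons_raw.split("/", 1)
        if len(ref_c) == 3 and len(alt_c) == 3 and ref_c.upper() != alt_c.upper():
            codon_change = (ref_c, alt_c)

    protein_pos = None
    pp_raw = col("protein_position")
    if pp_raw is not None:
        try:
            protein_pos = int(pp_raw.split("-", 1)[0])
        except ValueError:
            log.warning("unparseable Protein_position %r", pp_raw)

    aa_change = None
    aa_raw = col("amino_acids")
    if aa_raw is not None and protein_pos is not None:
        if "/" in aa_raw:
            ref_aa, alt_aa = aa_raw.split("/", 1)
        else:
            ref_aa = alt_aa = aa_raw  # VEP prints a single letter for synonymous
        if len(ref_aa) >= 1 and len(alt_aa) >= 1:
            aa_change = (ref_aa, alt_aa)

    return TranscriptAnnotation(
        transcript_id=col("transcript") or "",
        gene_symbol=col("gene_symbol") or "",
        consequence_terms=terms or ["intergenic_variant"],
        exon_index=exon_index,
        codon_change=codon_change,
        protein_pos=protein_pos,
        aa_change=aa_change,
        sift=_parse_predictor(col("sift"), SIFT_LABELS),
        polyphen=_parse_predictor(col("polyphen"), POLYPHEN_LABELS),
    )


def read_vep_table(
    path: str | Path,
    dialect: Optional[Mapping[str, str]] = None,
    *,
    stats: Optional[dict] = None,
) -> list[VariantRecord]:
    """Read a VEP ``--tab`` file into grouped :class:`VariantRecord` objects.

    One record per distinct (chrom, pos, ref, alt); one annotation per input
    row.  Rows whose location/alleles cannot be parsed are counted and
    skipped, never silently dropped — pass ``stats`` (a dict) to receive
    ``{"rows": n, "converted": n, "skipped": n}``.

    Raises :class:`DialectError` when a mandatory column named by the
    dialect is absent from the header.
    """
    dialect = dict(dialect or DEFAULT_DIALECT)
    header: Optional[list[str]] = None
    records: dict[tuple[str, int, str, str], VariantRecord] = {}
    n_rows = n_skipped = 0

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if header is None:
                if not line.startswith("#"):
                    raise DialectError(f"{path}: expected a '#'-prefixed header line")
                header = line.split("\t")
                for key in MANDATORY_DIALECT_KEYS:
                    name = dialect.get(key)
                    if name not in header:
                        raise DialectError(
                            f"{path}: mandatory column {name!r} (dialect key {key!r}) "
                            f"missing from header"
                        )
                continue
            n_rows += 1
            fields = line.split("\t")
            row = dict(zip(header, fields))
            parsed = _parse_uploaded_variation(row.get(dialect["uploaded_variation"], ""))
            if parsed is None:
                n_skipped += 1
                log.warning("skipping unparseable row %d of %s", n_rows, path)
                continue
            chrom, pos, ref, alt = parsed
            ann = _row_to_annotation(row, dialect)
            rs_raw = _opt(row.get(dialect.get("existing_variation", ""), ""))
            key = (chrom, pos, ref, alt)
            rec = records.get(key)
            if rec is None:
                rec = VariantRecord(chrom, pos, ref, alt, rs_id=rs_raw)
                records[key] = rec
            rec.annotations.append(ann)
            if rec.rs_id is None and rs_raw is not None:
                rec.rs_id = rs_raw

    if header is None:
        raise DialectError(f"{path}: empty file (no header)")
    if n_rows == 0:
        log.warning("%s contained a header but no data rows", path)
    if stats is not None:
        stats.update({"rows": n_rows, "converted": n_rows - n_skipped, "skipped": n_skipped})
    return list(records.values())


# ---------------------------------------------------------------------------
# Cleaning stages
# ---------------------------------------------------------------------------

def _annotation_signature(ann: TranscriptAnnotation) -> tuple:
    return (
        ann.base_transcript_id,
        ann.gene_symbol,
        tuple(ann.consequence_terms),
        ann.exon_index,
        ann.codon_change,
        ann.protein_pos,
        ann.aa_change,
    )


def dedup(records: Sequence[VariantRecord]) -> tuple[list[VariantRecord], dict]:
    """Drop duplicate (chrom, pos, ref, alt) entries, merging novel annotations.

    First occurrence wins; annotations from later duplicates are appended
    only if not already present (by content).  Idempotent.
    """
    seen: dict[tuple, VariantRecord] = {}
    n_removed = 0
    for rec in records:
        kept = seen.get(rec.key)
        if kept is None:
            seen[rec.key] = replace(rec, annotations=list(rec.annotations))
        else:
            n_removed += 1
            have = {_annotation_signature(a) for a in kept.annotations}
            for ann in rec.annotations:
                if _annotation_signature(ann) not in have:
                    kept.annotations.append(ann)
                    have.add(_annotation_signature(ann))
    out = list(seen.values())
    return out, {"n_removed": n_removed, "n_after_dedup": len(out)}


def select_transcript(
    records: Sequence[VariantRecord], transcript_id: str, *, aliases: Iterable[str] = ()
) -> list[VariantRecord]:
    """Keep only annotations on ``transcript_id`` (version suffix ignored).

    Records left with no matching annotation are dropped.  ``aliases``
    admits alternative spellings of the same transcript (the cleaning
    configs ship known typos of database IDs this way).
    """
    if not transcript_id:
        raise ValueError("transcript_id must be non-empty")
    wanted = {strip_version(transcript_id)} | {strip_version(a) for a in aliases}
    out: list[VariantRecord] = []
    n_dropped = 0
    for rec in records:
        matching = [a for a in rec.annotations if a.base_transcript_id in wanted]
        if matching:
            out.append(replace(rec, annotations=matching))
        else:
            n_dropped += 1
    if not out and records:
        log.warning(
            "select_transcript(%s): no records retained out of %d", transcript_id, len(records)
        )
    return out


def filter_overlapping_genes(
    records: Sequence[VariantRecord],
    target_gene: str,
    excluded_genes: Sequence[str],
) -> tuple[list[VariantRecord], dict]:
    """Remove annotations attributed to overlapping/neighbouring genes.

    A record whose every annotation is excluded is dropped.  Returns the
    surviving records plus per-symbol removal counts.
    """
    if not target_gene:
        raise ValueError("target_gene must be non-empty")
    excluded = set(excluded_genes)
    removed: Counter[str] = Counter()
    out: list[VariantRecord] = []
    for rec in records:
        kept_anns = []
        for ann in rec.annotations:
            if ann.gene_symbol in excluded:
                removed[ann.gene_symbol] += 1
            else:
                kept_anns.append(ann)
        if kept_anns:
            out.append(replace(rec, annotations=kept_anns))
    return out, {"removed_gene_symbols": dict(removed), "n_after_gene_filter": len(out)}


def clean_variants(
    records: Sequence[VariantRecord],
    transcript_id: str,
    target_gene: str,
    excluded_genes: Sequence[str] = (),
    *,
    transcript_aliases: Iterable[str] = (),
) -> tuple[list[VariantRecord], CleaningReport]:
    """Run the full cleaning cascade: dedup -> transcript -> gene filter."""
    report = CleaningReport(n_input=len(records))
    deduped, frag = dedup(records)
    report.n_after_dedup = frag["n_after_dedup"]
    on_tx = select_transcript(deduped, transcript_id, aliases=transcript_aliases)
    report.n_after_transcript_filter = len(on_tx)
    cleaned, frag = filter_overlapping_genes(on_tx, target_gene, excluded_genes)
    report.n_after_gene_filter = frag["n_after_gene_filter"]
    report.removed_gene_symbols = frag["removed_gene_symbols"]
    report.validate()
    return cleaned, report


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read a VCF into annotation-free records, decomposing multi-allelics."""
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        for site in vf:
            rs_id = site.id if site.id not in (None, ".") else None
            for alt in site.alts or ():
                if alt is None or not _ALLELE_RE.match(alt):
                    log.warning(
                        "skipping symbolic/invalid ALT %r at %s:%d", alt, site.chrom, site.pos
                    )
                    continue
                records.append(
                    VariantRecord(site.chrom, site.pos, site.ref, alt, rs_id=rs_id)
                )
    return records


def write_vcf(records: Sequence[VariantRecord], path: str | Path) -> None:
    """Write records as a minimal, sorted VCF 4.2 (plain text)."""
    chroms: dict[str, int] = {}
    for rec in records:
        end = rec.pos + len(rec.ref)
        chroms[rec.chrom] = max(chroms.get(rec.chrom, 0), end)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=mybpc-landscape\n")
        for chrom, length in sorted(chroms.items()):
            fh.write(f"##contig=<ID={chrom},length={length + 1000}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for rec in sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt)):
            rs = rec.rs_id or "."
            fh.write(f"{rec.chrom}\t{rec.pos}\t{rs}\t{rec.ref}\t{rec.alt}\t.\tPASS\t.\n")
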