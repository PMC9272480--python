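"""Landscape summaries over cleaned, classified variant records.

Everything here consumes :class:`~mybpc_landscape.variant_io.VariantRecord`
lists that have been through the cleaning cascade, so each record usually
carries exactly one transcript annotation.  Tallies are over annotations;
grand totals always equal the number of eligible annotations (conservation
is asserted in the tests, not here).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd

from .consequence_engine import (
    CodonChange,
    ConsequenceCategory,
    GeneModel,
    classify_annotation,
)
from .variant_io import TranscriptAnnotation, VariantRecord

log = logging.getLogger(__name__)

REGION_CLASSES = ("Ig", "Fn3", "PA_rich", "M_domain", "loop", "linker")


@dataclass(frozen=True)
class Region:
    name: str
    cls: str
    start_aa: int
    end_aa: int

    def __post_init__(self) -> None:
        if self.cls not in REGION_CLASSES:
            raise ValueError(f"unknown region class {self.cls!r}")
        if not 1 <= self.start_aa <= self.end_aa:
            raise ValueError(f"bad region interval {self.start_aa}-{self.end_aa}")

    @property
    def length(self) -> int:
        return self.end_aa - self.start_aa + 1


@dataclass
class DomainArchitecture:
    """Ordered, non-overlapping amino-acid intervals (C0...C10, PA, M).

    Named regions need not tile the protein; positions between them are
    implicit linkers.  Intervals are 1-based inclusive (UniProt style).
    """

    protein_name: str
    length_aa: int
    regions: list[Region] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.regions = sorted(self.regions, key=lambda r: r.start_aa)
        for a, b in zip(self.regions, self.regions[1:]):
            if a.end_aa >= b.start_aa:
                raise ValueError(f"regions {a.name} and {b.name} overlap")
        if self.regions and self.regions[-1].end_aa > self.length_aa:
            raise ValueError("regions extend beyond the protein")

    @property
    def region_names(self) -> list[str]:
        return [r.name for r in self.regions]

    def region_of(self, protein_pos: int) -> Optional[Region]:
        for region in self.regions:
            if region.start_aa <= protein_pos <= region.end_aa:
                return region
        return None

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            [(r.name, r.cls, r.start_aa, r.end_aa) for r in self.regions],
            columns=["name", "class", "start_aa", "end_aa"],
        )
        with open(path, "w") as fh:
            fh.write(f"# protein={self.protein_name} length_aa={self.length_aa}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DomainArchitecture":
        import io

        protein_name, length_aa = "protein", 0
        with open(path) as fh:
            lines = fh.readlines()
        body = []
        for line in lines:
            if line.startswith("#"):
                for tok in line[1:].split():
                    k, _, v = tok.partition("=")
                    if k == "protein" and v:
                        protein_name = v
                    elif k == "length_aa" and v.isdigit():
                        length_aa = int(v)
            elif line.strip():
                body.append(line)
        df = pd.read_csv(io.StringIO("".join(body)), sep="\t")
        regions = [
            Region(str(r["name"]), str(r["class"]), int(r["start_aa"]), int(r["end_aa"]))
            for _, r in df.iterrows()
        ]
        if length_aa == 0 and regions:
            length_aa = regions[-1].end_aa
        return cls(protein_name, length_aa, regions)


def map_to_domain(protein_pos: int, arch: DomainArchitecture) -> str:
    """Name of the region containing ``protein_pos``; gaps map to ``linker``."""
    if not 1 <= protein_pos <= arch.length_aa:
        raise ValueError(
            f"protein position {protein_pos} outside 1..{arch.length_aa} of {arch.protein_name}"
        )
    region = arch.region_of(protein_pos)
    return region.name if region is not None else "linker"


# ---------------------------------------------------------------------------
# Category and nucleotide tallies
# ---------------------------------------------------------------------------

def iter_annotations(records: Iterable[VariantRecord]):
    for rec in records:
        for ann in rec.annotations:
            yield rec, ann


@dataclass
class CategoryTally:
    counts: dict[str, int]
    coding_proportions: dict[str, float]
    n_coding: int
    n_noncoding: int

    @property
    def noncoding_fraction(self) -> Optional[float]:
        total = self.n_coding + self.n_noncoding
        return self.n_noncoding / total if total else None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "category": cat,
                "count": self.counts.get(cat, 0),
                "coding_proportion": self.coding_proportions.get(cat),
            }
            for cat in [c.value for c in ConsequenceCategory]
        ]
        return pd.DataFrame(rows)


def tally_categories(records: Sequence[VariantRecord]) -> CategoryTally:
    """Count annotations per category; proportions over coding categories.

    The noncoding fraction is reported separately so the coding
    proportions sum to 1 regardless of how intron-heavy the input is.
    """
    counts: Counter[str] = Counter()
    for _rec, ann in iter_annotations(records):
        counts[classify_annotation(ann).value] += 1
    n_noncoding = counts.get(ConsequenceCategory.NONCODING.value, 0)
    n_coding = sum(v for k, v in counts.items() if k != ConsequenceCategory.NONCODING.value)
    proportions = (
        {k: v / n_coding for k, v in counts.items() if k != ConsequenceCategory.NONCODING.value}
        if n_coding
        else {}
    )
    return CategoryTally(dict(counts), proportions, n_coding, n_noncoding)


def tally_nucleotide_changes(
    records: Sequence[VariantRecord], per_category: bool = False
):
    """Count SNV base changes (12 ordered ref>alt cells, + strand as reported).

    With ``per_category`` the result is nested: category -> base-change
    counter.  Non-SNV records do not contribute.
    """
    if per_category:
        nested: dict[str, Counter[str]] = {}
        for rec, ann in iter_annotations(records):
            if not rec.is_snv:
                continue
            cat = classify_annotation(ann).value
            nested.setdefault(cat, Counter())[f"{rec.ref}>{rec.alt}"] += 1
        return {cat: dict(c) for cat, c in nested.items()}
    counts: Counter[str] = Counter()
    seen: set = set()
    for rec in records:
        if rec.is_snv and rec.key not in seen:
            seen.add(rec.key)
            counts[f"{rec.ref}>{rec.alt}"] += 1
    return dict(counts)


def codon_position_tally(
    records: Sequence[VariantRecord],
    categories: Sequence[str] = ("missense", "synonymous"),
) -> dict[str, Counter]:
    """Per category: which codon positions (1/2/3) substitutions hit."""
    out: dict[str, Counter] = {c: Counter() for c in categories}
    for _rec, ann in iter_annotations(records):
        cat = classify_annotation(ann).value
        if cat not in out or ann.codon_change is None:
            continue
        change = CodonChange.from_vep_markup(*ann.codon_change)
        for pos in change.changed_positions:
            out[cat][pos] += 1
    return out


# ---------------------------------------------------------------------------
# Substitution spectra
# ---------------------------------------------------------------------------

@dataclass
class SubstitutionSpectrum:
    """Counts over ordered (ref_aa -> alt_aa-or-stop) substitution pairs."""

    counts: Counter = field(default_factory=Counter)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def top_k(self, k: int) -> list[tuple[tuple[str, str], int]]:
        """Top-k pairs; ties broken lexicographically on (ref, alt)."""
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))[:k]

    def marginal_ref(self) -> dict[str, int]:
        out: Counter[str] = Counter()
        for (ref_aa, _alt_aa), n in self.counts.items():
            out[ref_aa] += n
        return dict(out)

    def marginal_alt(self) -> dict[str, int]:
        out: Counter[str] = Counter()
        for (_ref_aa, alt_aa), n in self.counts.items():
            out[alt_aa] += n
        return dict(out)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"ref_aa": r, "alt_aa": a, "count": n}
            for (r, a), n in sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        ]
        return pd.DataFrame(rows, columns=["ref_aa", "alt_aa", "count"])


def substitution_spectrum(
    records: Sequence[VariantRecord],
    category_filter: Sequence[str] = ("missense",),
) -> SubstitutionSpectrum:
    """Spectrum of amino-acid changes over annotations in the given categories."""
    wanted = set(category_filter)
    spectrum = SubstitutionSpectrum()
    for _rec, ann in iter_annotations(records):
        if classify_annotation(ann).value not in wanted:
            continue
        if ann.aa_change is None:
            continue
        ref_aa, alt_aa = ann.aa_change
        if ref_aa == alt_aa:
            continue
        spectrum.counts[(ref_aa, alt_aa)] += 1
    return spectrum


def frameshift_aa_tally(records: Sequence[VariantRecord]) -> dict[str, int]:
    """Reference amino acid at the first codon hit by each frameshift.

    Frameshift annotations lacking a protein position are counted under
    ``unknown`` with a warning.
    """
    counts: Counter[str] = Counter()
    for _rec, ann in iter_annotations(records):
        if classify_annotation(ann) is not ConsequenceCategory.FRAMESHIFT:
            continue
        if ann.protein_pos is None or ann.aa_change is None:
            log.warning("frameshift annotation without protein position: %s", ann)
            counts["unknown"] += 1
        else:
            counts[ann.aa_change[0]] += 1
    return dict(counts)


def stop_gain_sources(records: Sequence[VariantRecord]) -> dict[str, int]:
    """Reference amino acids converted to premature stops (truncations)."""
    counts: Counter[str] = Counter()
    for _rec, ann in iter_annotations(records):
        if classify_annotation(ann) is not ConsequenceCategory.TRUNCATION:
            continue
        if ann.aa_change is not None and ann.aa_change[1] == "*":
            counts[ann.aa_change[0]] += 1
    return dict(counts)


# ---------------------------------------------------------------------------
# Domain / exon distributions
# ---------------------------------------------------------------------------

def domain_distribution(
    records: Sequence[VariantRecord],
    arch: DomainArchitecture,
    normalize: bool = False,
):
    """Per-region counts of protein-positioned annotations.

    Positions outside named regions accrue to ``linker``.  With
    ``normalize`` the result maps region -> (count, count per 100 aa);
    linker length = protein length minus named-region lengths.
    """
    counts: Counter[str] = Counter()
    for _rec, ann in iter_annotations(records):
        if ann.protein_pos is None or not 1 <= ann.protein_pos <= arch.length_aa:
            continue
        counts[map_to_domain(ann.protein_pos, arch)] += 1
    if not normalize:
        return dict(counts)
    named = sum(r.length for r in arch.regions)
    lengths = {r.name: r.length for r in arch.regions}
    lengths["linker"] = max(arch.length_aa - named, 0)
    return {
        name: (n, 100.0 * n / lengths[name] if lengths.get(name) else float("nan"))
        for name, n in counts.items()
    }


def exon_distribution(
    records: Sequence[VariantRecord], model: Optional[GeneModel] = None
) -> tuple[dict[int, int], int]:
    """Per-exon annotation counts plus the excluded (non-exonic) count.

    The exon ordinal comes from the annotation when present, else from the
    gene model; annotations with neither are excluded and counted.
    """
    counts: Counter[int] = Counter()
    n_excluded = 0
    for rec, ann in iter_annotations(records):
        exon = ann.exon_index
        if exon is None and model is not None:
            exon = model.exon_index_of(rec.pos)
        if exon is None:
            n_excluded += 1
        else:
            counts[exon] += 1
    return dict(counts), n_excluded


# ---------------------------------------------------------------------------
# Pathogenicity filtering
# ---------------------------------------------------------------------------

RuleMode = Literal["sift_only", "polyphen_only", "either", "both"]

DEFAULT_SIFT_DAMAGING = frozenset({"deleterious"})
DEFAULT_POLYPHEN_DAMAGING = frozenset({"probably_damaging"})


@dataclass(frozen=True)
class PathogenicityRule:
    """Which SIFT/PolyPhen label combination counts as "likely pathogenic".

    ``both`` is the default: an annotation must carry a damaging SIFT label
    AND a damaging PolyPhen label.  Annotations lacking both predictors are
    never pathogenic under any mode.
    """

    mode: RuleMode = "both"
    sift_damaging_labels: frozenset[str] = DEFAULT_SIFT_DAMAGING
    polyphen_damaging_labels: frozenset[str] = DEFAULT_POLYPHEN_DAMAGING

    def __post_init__(self) -> None:
        if self.mode not in ("sift_only", "polyphen_only", "either", "both"):
            raise ValueError(f"unknown rule mode {self.mode!r}")


def is_likely_pathogenic(ann: TranscriptAnnotation, rule: PathogenicityRule) -> bool:
    sift_hit = ann.sift is not None and ann.sift[0] in rule.sift_damaging_labels
    polyphen_hit = ann.polyphen is not None and ann.polyphen[0] in rule.polyphen_damaging_labels
    if ann.sift is None and ann.polyphen is None:
        return False
    if rule.mode == "sift_only":
        return sift_hit
    if rule.mode == "polyphen_only":
        return polyphen_hit
    if rule.mode == "either":
        return sift_hit or polyphen_hit
    return sift_hit and polyphen_hit


def filter_likely_pathogenic(
    records: Sequence[VariantRecord], rule: PathogenicityRule
) -> list[VariantRecord]:
    """Records restricted to their likely-pathogenic annotations."""
    out = []
    for rec in records:
        kept = [a for a in rec.annotations if is_likely_pathogenic(a, rule)]
        if kept:
            out.append(
                VariantRecord(rec.chrom, rec.pos, rec.ref, rec.alt, rec.rs_id, kept)
            )
    return out


def pathogenic_distribution(
    records: Sequence[VariantRecord],
    rule: PathogenicityRule,
    arch: Optional[DomainArchitecture] = None,
    model: Optional[GeneModel] = None,
) -> tuple[dict[int, int], dict[str, int]]:
    """Exon and domain distributions of the likely-pathogenic subset."""
    subset = filter_likely_pathogenic(records, rule)
    exon_counts, _ = exon_distribution(subset, model)
    region_counts = domain_distribution(subset, arch) if arch is not None else {}
    return exon_counts, region_counts
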