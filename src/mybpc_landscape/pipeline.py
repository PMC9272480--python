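"""End-to-end runs: cleaning -> classification -> landscape tables.

``run_pipeline`` is the reusable form of the analysis: it takes a
:class:`RunConfig`, executes the cleaning cascade and every landscape
summary in order, logs per-stage counts, and returns a
:class:`ResultBundle` whose tables serialise to TSV/JSON.  ``synthetic``
mode generates its own inputs, round-trips them through the VEP-dialect
files on disk, and re-ingests them, so a synthetic run exercises exactly
the same code path as a real gnomAD/VEP export.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import landscape_stats as ls
from . import synthetic_data as syn
from . import variant_io as vio
from .consequence_engine import GeneModel
from .landscape_stats import DomainArchitecture, PathogenicityRule

log = logging.getLogger(__name__)

#: Overlapping/neighbouring gene symbols removed per target gene, as
#: annotation releases place them today.  Configuration, not constants —
#: overlap sets drift between releases.
DEFAULT_EXCLUDED_GENES: dict[str, list[str]] = {
    "MYBPC1": ["AC117505.1"],
    "MYBPC2": ["AC020909.1", "SPIB", "FAM71E1"],
    "MYBPC3": ["MADD", "SPI1"],
}

#: Longest-isoform transcripts per paralog.  MYBPC3 ships the 13-digit
#: string printed in circulation plus the canonical 15-digit Ensembl ID as
#: an alias; matching is exact after version-stripping.
DEFAULT_TRANSCRIPTS: dict[str, tuple[str, tuple[str, ...]]] = {
    "MYBPC1": ("ENST00000361466", ()),
    "MYBPC2": ("ENST00000357701", ()),
    "MYBPC3": ("ENST0000545968", ("ENST00000545968",)),
}


@dataclass
class RunConfig:
    """One pipeline run (one gene/paralog)."""

    mode: str = "synthetic"  # "real" | "synthetic"
    label: str = "SYNGENE"
    out_dir: Path = Path("results/run")
    seed: int = 0
    top_k: int = 10
    # real mode inputs
    vep_path: Optional[Path] = None
    vcf_path: Optional[Path] = None
    dialect_path: Optional[Path] = None
    architecture_path: Optional[Path] = None
    gene_model_tsv: Optional[Path] = None
    gene_model_fasta: Optional[Path] = None
    transcript_id: Optional[str] = None
    transcript_aliases: tuple[str, ...] = ()
    excluded_genes: tuple[str, ...] = ()
    # synthetic mode knobs
    n_variants: int = 10_000
    n_exons: int = 20
    cds_length_codons: int = 1274
    strand: str = "+"
    noncoding_fraction: float = 0.75
    ts_tv_ratio: float = 2.0
    cpg_multiplier: float = 1.0
    category_proportions: Optional[dict[str, float]] = None
    include_c0: bool = False
    # filtering
    rule: PathogenicityRule = field(default_factory=PathogenicityRule)

    def __post_init__(self) -> None:
        if self.mode not in ("real", "synthetic"):
            raise ValueError(f"mode must be 'real' or 'synthetic', got {self.mode!r}")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.mode == "real" and self.vep_path is None:
            raise ValueError("real mode requires vep_path")
        self.out_dir = Path(self.out_dir)


@dataclass
class ResultBundle:
    """Every table one run produces, ready to serialise."""

    label: str
    cleaning_report: vio.CleaningReport
    categories: pd.DataFrame
    noncoding_fraction: Optional[float]
    nucleotide_changes: pd.DataFrame
    codon_positions: pd.DataFrame
    spectrum_top: pd.DataFrame
    missense_per_aa: pd.DataFrame
    frameshift_per_aa: pd.DataFrame
    stopgain_sources: pd.DataFrame
    domain_counts: Optional[pd.DataFrame]
    exon_counts: pd.DataFrame
    pathogenic_exon: pd.DataFrame
    pathogenic_domain: Optional[pd.DataFrame]
    pathogenic_mode_audit: dict[str, int]

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {
            "categories": self.categories,
            "nucleotide_changes": self.nucleotide_changes,
            "codon_positions": self.codon_positions,
            "spectrum_top": self.spectrum_top,
            "missense_per_aa": self.missense_per_aa,
            "frameshift_per_aa": self.frameshift_per_aa,
            "stopgain_sources": self.stopgain_sources,
            "exon_counts": self.exon_counts,
            "pathogenic_exon": self.pathogenic_exon,
        }
        if self.domain_counts is not None:
            out["domain_counts"] = self.domain_counts
        if self.pathogenic_domain is not None:
            out["pathogenic_domain"] = self.pathogenic_domain
        return out

    def write(self, out_dir: Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables().items():
            df.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
        summary = {
            "label": self.label,
            "cleaning_report": self.cleaning_report.to_dict(),
            "noncoding_fraction": self.noncoding_fraction,
            "pathogenic_mode_audit": self.pathogenic_mode_audit,
        }
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1)


def _counter_frame(counts: dict, key: str) -> pd.DataFrame:
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], str(kv[0])))
    return pd.DataFrame(rows, columns=[key, "count"])


def _analyze(
    records: list[vio.VariantRecord],
    report: vio.CleaningReport,
    label: str,
    rule: PathogenicityRule,
    top_k: int,
    arch: Optional[DomainArchitecture],
    model: Optional[GeneModel],
) -> ResultBundle:
    tally = ls.tally_categories(records)
    log.info(
        "%s: %d records (%d coding, %d noncoding annotations)",
        label, len(records), tally.n_coding, tally.n_noncoding,
    )

    nt = _counter_frame(ls.tally_nucleotide_changes(records), "change")
    cp = ls.codon_position_tally(records)
    cp_df = pd.DataFrame(
        [
            {"category": cat, "codon_position": pos, "count": n}
            for cat, counter in cp.items()
            for pos, n in sorted(counter.items())
        ],
        columns=["category", "codon_position", "count"],
    )

    spectrum = ls.substitution_spectrum(records, ("missense",))
    top = pd.DataFrame(
        [
            {"ref_aa": r, "alt_aa": a, "count": n}
            for (r, a), n in spectrum.top_k(top_k)
        ],
        columns=["ref_aa", "alt_aa", "count"],
    )
    missense_marginal = _counter_frame(spectrum.marginal_ref(), "ref_aa")
    frameshift = _counter_frame(ls.frameshift_aa_tally(records), "ref_aa")
    stopgain = _counter_frame(ls.stop_gain_sources(records), "ref_aa")

    if arch is not None:
        dom = ls.domain_distribution(records, arch, normalize=True)
        dom_df = pd.DataFrame(
            [
                {"region": name, "count": n, "per_100_aa": rate}
                for name, (n, rate) in sorted(dom.items(), key=lambda kv: -kv[1][0])
            ],
            columns=["region", "count", "per_100_aa"],
        )
    else:
        log.warning("%s: no domain architecture; domain tables skipped", label)
        dom_df = None

    exon_counts, n_nonexonic = ls.exon_distribution(records, model)
    exon_df = pd.DataFrame(
        sorted(exon_counts.items()), columns=["exon", "count"]
    )
    log.info("%s: %d annotations outside exons", label, n_nonexonic)

    audit = {}
    for mode in ("sift_only", "polyphen_only", "either", "both"):
        mode_rule = dataclasses.replace(rule, mode=mode)
        audit[mode] = len(ls.filter_likely_pathogenic(records, mode_rule))
    log.info("%s: likely-pathogenic counts by rule mode: %s", label, audit)

    patho_exon, patho_dom = ls.pathogenic_distribution(records, rule, arch, model)
    patho_exon_df = pd.DataFrame(sorted(patho_exon.items()), columns=["exon", "count"])
    patho_dom_df = (
        _counter_frame(patho_dom, "region") if arch is not None else None
    )

    return ResultBundle(
        label=label,
        cleaning_report=report,
        categories=tally.to_frame(),
        noncoding_fraction=tally.noncoding_fraction,
        nucleotide_changes=nt,
        codon_positions=cp_df,
        spectrum_top=top,
        missense_per_aa=missense_marginal,
        frameshift_per_aa=frameshift,
        stopgain_sources=stopgain,
        domain_counts=dom_df,
        exon_counts=exon_df,
        pathogenic_exon=patho_exon_df,
        pathogenic_domain=patho_dom_df,
        pathogenic_mode_audit=audit,
    )


def run_pipeline(cfg: RunConfig) -> ResultBundle:
    """Execute ingestion -> cleaning -> classification -> landscape stats."""
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    arch: Optional[DomainArchitecture] = None
    model: Optional[GeneModel] = None

    if cfg.mode == "synthetic":
        model = syn.make_gene_model(
            cfg.n_exons, cfg.cds_length_codons, cfg.strand, cfg.seed,
            gene_symbol=cfg.label,
        )
        protein_length = cfg.cds_length_codons - 1
        arch = syn.make_architecture(
            protein_length=protein_length,
            n_domains=max(1, min(10, protein_length // 120)),
            include_c0=cfg.include_c0,
            seed=cfg.seed + 1,
        )
        mm = syn.MutationModel(
            n_variants=cfg.n_variants,
            ts_tv_ratio=cfg.ts_tv_ratio,
            cpg_multiplier=cfg.cpg_multiplier,
            category_proportions=(
                cfg.category_proportions or dict(syn.DEFAULT_CODING_PROPORTIONS)
            ),
            noncoding_fraction=cfg.noncoding_fraction,
            seed=cfg.seed + 2,
        )
        records, truth = syn.simulate_variants(model, mm, arch)
        vep_path = cfg.out_dir / "synthetic_vep.tsv"
        vcf_path = cfg.out_dir / "synthetic.vcf"
        syn.write_vep_table(records, vep_path, n_exons=model.n_exons)
        vio.write_vcf(records, vcf_path)
        truth.to_json(cfg.out_dir / "ground_truth.json")
        syn.write_gene_model(
            model, cfg.out_dir / "gene_model.tsv", cfg.out_dir / "locus.fa"
        )
        arch.to_tsv(cfg.out_dir / "architecture.tsv")
        transcript_id = model.transcript_id
        aliases: tuple[str, ...] = ()
        excluded: tuple[str, ...] = ()
        dialect = None
    else:
        vep_path = cfg.vep_path
        dialect = vio.load_dialect(cfg.dialect_path) if cfg.dialect_path else None
        transcript_id = cfg.transcript_id or DEFAULT_TRANSCRIPTS.get(
            cfg.label, (cfg.label, ())
        )[0]
        aliases = cfg.transcript_aliases or tuple(
            DEFAULT_TRANSCRIPTS.get(cfg.label, ("", ()))[1]
        )
        excluded = cfg.excluded_genes or tuple(
            DEFAULT_EXCLUDED_GENES.get(cfg.label, ())
        )
        if cfg.architecture_path:
            arch = DomainArchitecture.from_tsv(cfg.architecture_path)
        if cfg.gene_model_tsv and cfg.gene_model_fasta:
            model = syn.read_gene_model(cfg.gene_model_tsv, cfg.gene_model_fasta)

    stats: dict = {}
    records = vio.read_vep_table(vep_path, dialect, stats=stats)
    log.info(
        "%s: read %d rows (%d skipped) -> %d variant records",
        cfg.label, stats["rows"], stats["skipped"], len(records),
    )
    cleaned, report = vio.clean_variants(
        records,
        transcript_id,
        cfg.label,
        excluded,
        transcript_aliases=aliases,
    )
    report.n_rows_read = stats["rows"]
    report.n_rows_skipped = stats["skipped"]
    log.info("%s: cleaning %s", cfg.label, report.to_dict())

    bundle = _analyze(cleaned, report, cfg.label, cfg.rule, cfg.top_k, arch, model)
    bundle.write(cfg.out_dir)
    return bundle


def compare_bundles(bundles: dict[str, ResultBundle]) -> pd.DataFrame:
    """Side-by-side category table across runs (no pooled statistics)."""
    frames = []
    for label, bundle in bundles.items():
        df = bundle.categories.copy()
        df["run"] = label
        frames.append(df)
    joined = pd.concat(frames, ignore_index=True)
    return joined.pivot_table(
        index="category", columns="run", values="count", fill_value=0
    ).reset_index()


def render_figures(bundle: ResultBundle, out_dir: Path) -> list[Path]:
    """Bar-chart renderings of each table; presentation only."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def bar(df: pd.DataFrame, x: str, y: str, title: str, fname: str) -> None:
        if df is None or df.empty:
            return
        fig, ax = plt.subplots(figsize=(max(4, 0.35 * len(df)), 3.2))
        ax.bar(df[x].astype(str), df[y], color="#4878a8")
        ax.set_title(f"{bundle.label}: {title}", fontsize=10)
        ax.set_ylabel(y)
        ax.tick_params(axis="x", rotation=90, labelsize=7)
        fig.tight_layout()
        path = out_dir / fname
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    cats = bundle.categories[bundle.categories["count"] > 0]
    bar(cats, "category", "count", "consequence categories", "categories.png")
    bar(bundle.nucleotide_changes, "change", "count", "nucleotide changes", "nucleotide_changes.png")
    top = bundle.spectrum_top.copy()
    if not top.empty:
        top["substitution"] = top["ref_aa"] + ">" + top["alt_aa"]
        bar(top, "substitution", "count", "top substitutions", "spectrum_top.png")
    bar(bundle.missense_per_aa, "ref_aa", "count", "missense by amino acid", "missense_per_aa.png")
    bar(bundle.frameshift_per_aa, "ref_aa", "count", "frameshift by amino acid", "frameshift_per_aa.png")
    bar(bundle.stopgain_sources, "ref_aa", "count", "stop-gain source residues", "stopgain_sources.png")
    if bundle.domain_counts is not None:
        bar(bundle.domain_counts, "region", "count", "variants per domain", "domain_counts.png")
    bar(bundle.exon_counts, "exon", "count", "variants per exon", "exon_counts.png")
    bar(bundle.pathogenic_exon, "exon", "count", "likely-pathogenic per exon", "pathogenic_exon.png")
    if bundle.pathogenic_domain is not None:
        bar(bundle.pathogenic_domain, "region", "count", "likely-pathogenic per domain", "pathogenic_domain.png")
    return written


def load_run_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    rule_raw = raw.pop("rule", None)
    cfg = RunConfig(**raw)
    if rule_raw:
        cfg.rule = PathogenicityRule(
            mode=rule_raw.get("mode", "both"),
            sift_damaging_labels=frozenset(
                rule_raw.get("sift_damaging_labels", ["deleterious"])
            ),
            polyphen_damaging_labels=frozenset(
                rule_raw.get("polyphen_damaging_labels", ["probably_damaging"])
            ),
        )
    return cfg
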