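#!/usr/bin/env python
"""Domain/exon distributions and the likely-pathogenic subsets.

Maps each cohort's protein-positioned variants onto its domain
architecture (raw counts plus per-100-aa rates — a short domain can be a
hotspot without carrying the most variants), counts variants per exon,
then applies the SIFT+PolyPhen "likely pathogenic" screen under all four
rule modes and redoes both distributions on the surviving subset.
Tables land under results/domains/.
"""

import dataclasses
from pathlib import Path

import pandas as pd

from mybpc_landscape import landscape_stats as ls
from mybpc_landscape import synthetic_data as syn
from mybpc_landscape import variant_io as vio

SIM = Path("results/sim")
CLEAN = Path("results/clean")
OUT = Path("results/domains")


def main() -> None:
    rule = ls.PathogenicityRule()  # both-mode, deleterious + probably_damaging
    for clean_dir in sorted(CLEAN.iterdir()):
        label = clean_dir.name
        out = OUT / label
        out.mkdir(parents=True, exist_ok=True)
        records = vio.read_vep_table(clean_dir / "cleaned_vep.tsv")
        arch = ls.DomainArchitecture.from_tsv(SIM / label / "architecture.tsv")
        model = syn.read_gene_model(SIM / label / "gene_model.tsv", SIM / label / "locus.fa")

        dom = ls.domain_distribution(records, arch, normalize=True)
        pd.DataFrame(
            [{"region": k, "count": n, "per_100_aa": round(r, 2)}
             for k, (n, r) in sorted(dom.items(), key=lambda kv: -kv[1][0])]
        ).to_csv(out / "domain_counts.tsv", sep="\t", index=False)
        busiest = max(dom, key=lambda k: dom[k][0])
        densest = max(dom, key=lambda k: dom[k][1])
        print(f"\n{label}: busiest domain {busiest} ({dom[busiest][0]} variants); "
              f"densest {densest} ({dom[densest][1]:.1f}/100 aa)")

        exon_counts, n_outside = ls.exon_distribution(records, model)
        pd.DataFrame(sorted(exon_counts.items()), columns=["exon", "count"]).to_csv(
            out / "exon_counts.tsv", sep="\t", index=False)
        top_exons = sorted(exon_counts, key=exon_counts.get, reverse=True)[:3]
        print(f"  exonic annotations in {len(exon_counts)} exons "
              f"({n_outside} outside); top exons {top_exons}")

        audit = {}
        for mode in ("sift_only", "polyphen_only", "either", "both"):
            subset = ls.filter_likely_pathogenic(records, dataclasses.replace(rule, mode=mode))
            audit[mode] = len(subset)
        print(f"  likely-pathogenic by rule mode: {audit}")

        patho_exon, patho_dom = ls.pathogenic_distribution(records, rule, arch, model)
        pd.DataFrame(sorted(patho_exon.items()), columns=["exon", "count"]).to_csv(
            out / "pathogenic_exon.tsv", sep="\t", index=False)
        pd.DataFrame(
            sorted(patho_dom.items(), key=lambda kv: -kv[1]), columns=["region", "count"]
        ).to_csv(out / "pathogenic_domain.tsv", sep="\t", index=False)
        if patho_dom:
            lead = max(patho_dom, key=patho_dom.get)
            print(f"  pathogenic (both-mode) n={sum(patho_dom.values())}, "
                  f"leading domain {lead}")
    print(f"\nwrote domain/exon tables under {OUT}/")


if __name__ == "__main__":
    main()
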