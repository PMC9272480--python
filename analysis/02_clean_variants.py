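#!/usr/bin/env python
"""Clean each simulated cohort the way a gnomAD/VEP export is cleaned.

Stages (counts logged per cohort, mirroring the audit a real analysis
needs): re-ingest the VEP-dialect table, drop duplicate variant entries,
keep only the longest-isoform transcript's annotations, and remove
annotations attributed to overlapping/neighbouring genes.  Writes the
cleaned table and the CleaningReport JSON under results/clean/.
"""

import json
from pathlib import Path

from mybpc_landscape import synthetic_data as syn
from mybpc_landscape import variant_io as vio

SIM = Path("results/sim")
OUT = Path("results/clean")


def main() -> None:
    for sim_dir in sorted(SIM.iterdir()):
        label = sim_dir.name
        out = OUT / label
        out.mkdir(parents=True, exist_ok=True)
        stats: dict = {}
        records = vio.read_vep_table(sim_dir / "synthetic_vep.tsv", stats=stats)
        model = syn.read_gene_model(sim_dir / "gene_model.tsv", sim_dir / "locus.fa")
        cleaned, report = vio.clean_variants(
            records, model.transcript_id, label, excluded_genes=[]
        )
        report.n_rows_read = stats["rows"]
        report.n_rows_skipped = stats["skipped"]
        syn.write_vep_table(cleaned, out / "cleaned_vep.tsv", n_exons=model.n_exons)
        with open(out / "cleaning_report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=1)
        print(f"{label}: {stats['rows']} rows ({stats['skipped']} skipped) -> "
              f"{report.n_input} records -> {report.n_after_dedup} after dedup -> "
              f"{report.n_after_gene_filter} cleaned")
    print(f"\nwrote cleaned cohorts under {OUT}/")


if __name__ == "__main__":
    main()
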