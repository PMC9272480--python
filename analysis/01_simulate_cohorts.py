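#!/usr/bin/env python
"""Simulate three paralog-like variant cohorts with known ground truth.

Emulates what a gnomAD download plus a VEP run provides for MYBPC1/2/3:
three multi-exon genes (one on the minus strand; the cardiac-like one
with a C0 domain), each with 10,000 variants drawn from the
missense-dominated coding profile (0.63/0.30/0.03/0.02/0.02) over a
gene-specific noncoding background (90% / 75% / 62% intronic+UTR+flank),
Ts/Tv = 2.0 and 8x CpG elevation.  Writes the VEP-dialect table, VCF,
gene model, domain architecture and ground truth per cohort under
results/sim/.
"""

from collections import Counter
from pathlib import Path

from mybpc_landscape import synthetic_data as syn
from mybpc_landscape import variant_io as vio

OUT = Path("results/sim")

#: label -> (strand, include_c0, noncoding fraction, seed)
COHORTS = {
    "SYN-MYBPC1": ("+", False, 0.90, 101),
    "SYN-MYBPC2": ("-", False, 0.75, 202),
    "SYN-MYBPC3": ("+", True, 0.62, 303),
}


def main() -> None:
    for label, (strand, include_c0, noncoding, seed) in COHORTS.items():
        out = OUT / label
        out.mkdir(parents=True, exist_ok=True)
        model = syn.make_gene_model(
            n_exons=30, cds_length_codons=1274, strand=strand, seed=seed,
            gene_symbol=label, flank=2000,
        )
        arch = syn.make_architecture(1273, 10, include_c0=include_c0, seed=seed + 1,
                                     protein_name=label)
        mm = syn.MutationModel(
            n_variants=10_000,
            ts_tv_ratio=2.0,
            cpg_multiplier=8.0,
            category_proportions=dict(syn.DEFAULT_CODING_PROPORTIONS),
            noncoding_fraction=noncoding,
            seed=seed + 2,
        )
        records, truth = syn.simulate_variants(model, mm, arch)
        syn.write_vep_table(records, out / "synthetic_vep.tsv", n_exons=model.n_exons)
        vio.write_vcf(records, out / "synthetic.vcf")
        syn.write_gene_model(model, out / "gene_model.tsv", out / "locus.fa")
        arch.to_tsv(out / "architecture.tsv")
        truth.to_json(out / "ground_truth.json")

        cats = Counter(e["category"] for e in truth.entries)
        print(f"{label}: {len(records)} variants on strand {strand}, "
              f"{cats['noncoding'] / len(records):.0%} noncoding")
        print(f"  true category counts: {dict(cats.most_common())}")
    print(f"\nwrote cohorts under {OUT}/")


if __name__ == "__main__":
    main()
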