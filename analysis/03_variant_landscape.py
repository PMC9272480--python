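#!/usr/bin/env python
"""Landscape summaries per cohort: categories, nucleotides, codons, spectra.

For each cleaned cohort this computes and prints what the cross-paralog
comparison hinges on: coding category proportions (missense should
dominate at ~63%), the 12-cell nucleotide-change tally and transition
fraction, codon positions hit by synonymous vs missense substitutions
(synonymous changes should pile onto position 3), the top-10 amino-acid
substitution spectrum, and per-amino-acid missense / frameshift /
stop-gain tallies (Trp and Tyr should lead the per-codon stop-gain
ranking).  Tables land under results/landscape/.
"""

from pathlib import Path

import pandas as pd

from mybpc_landscape import landscape_stats as ls
from mybpc_landscape import variant_io as vio
from mybpc_landscape.consequence_engine import stop_accessibility

CLEAN = Path("results/clean")
OUT = Path("results/landscape")

TRANSITIONS = {"A>G", "G>A", "C>T", "T>C"}


def main() -> None:
    accessibility = stop_accessibility()
    for clean_dir in sorted(CLEAN.iterdir()):
        label = clean_dir.name
        out = OUT / label
        out.mkdir(parents=True, exist_ok=True)
        records = vio.read_vep_table(clean_dir / "cleaned_vep.tsv")

        tally = ls.tally_categories(records)
        pd.DataFrame(
            sorted(tally.counts.items()), columns=["category", "count"]
        ).to_csv(out / "categories.tsv", sep="\t", index=False)
        print(f"\n{label}: {len(records)} records, "
              f"noncoding fraction {tally.noncoding_fraction:.2f}")
        coding = {k: f"{v:.2f}" for k, v in sorted(
            tally.coding_proportions.items(), key=lambda kv: -kv[1])}
        print(f"  coding proportions: {coding}")

        nt = ls.tally_nucleotide_changes(records)
        pd.DataFrame(sorted(nt.items()), columns=["change", "count"]).to_csv(
            out / "nucleotide_changes.tsv", sep="\t", index=False)
        n_snv = sum(nt.values())
        ts = sum(v for k, v in nt.items() if k in TRANSITIONS)
        print(f"  transition fraction {ts / n_snv:.3f} over {n_snv} SNVs")

        cp = ls.codon_position_tally(records)
        rows = [{"category": c, "codon_position": p, "count": n}
                for c, counter in cp.items() for p, n in sorted(counter.items())]
        pd.DataFrame(rows).to_csv(out / "codon_positions.tsv", sep="\t", index=False)
        syn_cp = cp.get("synonymous", {})
        if syn_cp:
            third = syn_cp.get(3, 0) / sum(syn_cp.values())
            print(f"  synonymous changes at codon position 3: {third:.0%}")

        spectrum = ls.substitution_spectrum(records, ("missense",))
        spectrum.to_frame().head(10).to_csv(out / "top10_substitutions.tsv",
                                            sep="\t", index=False)
        top3 = ", ".join(f"{r}>{a} ({n})" for (r, a), n in spectrum.top_k(3))
        print(f"  top missense substitutions: {top3}")

        for name, counts in [
            ("missense_per_aa", spectrum.marginal_ref()),
            ("frameshift_per_aa", ls.frameshift_aa_tally(records)),
            ("stopgain_sources", ls.stop_gain_sources(records)),
        ]:
            pd.DataFrame(
                sorted(counts.items(), key=lambda kv: -kv[1]), columns=["ref_aa", "count"]
            ).to_csv(out / f"{name}.tsv", sep="\t", index=False)

        sg = ls.stop_gain_sources(records)
        per_codon = {
            aa: n / accessibility[aa][0] for aa, n in sg.items()
            if accessibility.get(aa, (0, 0))[0] > 0
        }
        lead = sorted(per_codon, key=per_codon.get, reverse=True)[:3]
        print(f"  stop-gain sources (raw): {dict(sorted(sg.items(), key=lambda kv: -kv[1]))}")
        print(f"  leading after nonsense-accessibility normalisation: {lead}")
    print(f"\nwrote landscape tables under {OUT}/")


if __name__ == "__main__":
    main()
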