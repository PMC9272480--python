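#!/usr/bin/env python
"""Render bar-chart equivalents of every landscape table (presentation only)."""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

SOURCES = [Path("results/landscape"), Path("results/domains")]
OUT = Path("results/figures")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    n = 0
    for source in SOURCES:
        if not source.exists():
            continue
        for tsv in sorted(source.glob("*/*.tsv")):
            df = pd.read_csv(tsv, sep="\t")
            if "count" not in df.columns or df.empty:
                continue
            label = tsv.parent.name
            x = df.columns[0]
            fig, ax = plt.subplots(figsize=(max(4, 0.3 * len(df)), 3.2))
            ax.bar(df[x].astype(str), df["count"], color="#4878a8")
            ax.set_title(f"{label}: {tsv.stem}", fontsize=10)
            ax.set_ylabel("count")
            ax.tick_params(axis="x", rotation=90, labelsize=7)
            fig.tight_layout()
            fig.savefig(OUT / f"{label}_{tsv.stem}.png", dpi=120)
            plt.close(fig)
            n += 1
    print(f"rendered {n} figures to {OUT}/")


if __name__ == "__main__":
    main()
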