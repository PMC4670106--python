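#!/usr/bin/env python
"""NB-Wald differential expression, HD vs control.

Fits the per-gene negative-binomial GLM with condition, binned age at
death, and RIN>7 as covariates and size-factor offsets, then calls DE at
FDR<0.05 and reports recovery against the simulation ground truth.
"""

import argparse
from pathlib import Path

from hdbrain import dge, io


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--prepdir", type=Path, default=Path("results/preprocess"))
    ap.add_argument("--outdir", type=Path, default=Path("results/dge"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    counts = io.read_counts(args.prepdir / "counts_preprocessed.tsv")
    samples = io.read_sample_table(args.datadir / "meta.tsv")
    table = dge.nb_wald_test(counts, samples)
    io.write_table(table.round(6), args.outdir / "de_table.tsv", index=True)

    de_genes = dge.call_de(table)
    (args.outdir / "de_genes_ranked.txt").write_text("\n".join(de_genes) + "\n")
    ranked_all = dge.rank_by_significance(table)
    (args.outdir / "all_genes_ranked.txt").write_text(
        "\n".join(ranked_all) + "\n")

    up = int((table.loc[de_genes, "lfc"] > 0).sum())
    print(f"{len(de_genes)} of {table['p'].notna().sum()} tested genes DE at "
          f"FDR<0.05 ({len(de_genes)/table['p'].notna().sum():.1%})")
    print(f"{up} up- vs {len(de_genes)-up} down-regulated "
          f"({100*up/max(len(de_genes),1):.1f}% up)")

    truth_path = args.datadir / "truth.tsv"
    if truth_path.exists():
        truth = io.read_table(truth_path, index_col=0)
        planted = set(truth.index[truth["is_de"]]) & set(counts.index)
        called = set(de_genes)
        recall = len(called & planted) / len(planted)
        fdr = len(called - planted) / max(len(called), 1)
        print(f"recovery vs ground truth: recall {recall:.2f}, "
              f"empirical FDR {fdr:.3f}")


if __name__ == "__main__":
    main()
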