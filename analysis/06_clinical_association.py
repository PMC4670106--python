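#!/usr/bin/env python
"""Clinical covariate association and the cortical-involvement confound check.

Regresses variance-stabilized expression of every gene on CAG repeat
length, CAG-adjusted residual age at onset, and the H-V striatal/cortical
involvement scores (cases only, adjusting for RIN), BH-adjusts within each
covariate, and re-models raw DE-gene counts on cortical score with the
NB-GLM stage to ask whether the DE signal merely tracks tissue involvement.
"""

import argparse
from pathlib import Path

from hdbrain import covariates, dge, io, preprocess


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--prepdir", type=Path, default=Path("results/preprocess"))
    ap.add_argument("--dgedir", type=Path, default=Path("results/dge"))
    ap.add_argument("--outdir", type=Path, default=Path("results/assoc"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    samples = io.read_sample_table(args.datadir / "meta.tsv")
    cases = samples[samples["condition"] == "HD"]
    vst = io.read_table(args.prepdir / "vst.tsv", index_col=0)[cases.index]
    rin = cases["rin"]

    onset_model = covariates.fit_onset_model(cases["age_of_onset"],
                                             cases["cag"])
    onset_resid = covariates.residual_onset(cases["age_of_onset"],
                                            cases["cag"], onset_model)
    covs = {"cag": cases["cag"], "onset_residual": onset_resid,
            "hv_striatal": cases["hv_striatal"],
            "hv_cortical": cases["hv_cortical"]}
    for name, cov in covs.items():
        table = covariates.covariate_regression(vst, cov, rin)
        io.write_table(table.round(6), args.outdir / f"assoc_{name}.tsv",
                       index=True)
        hit = table["p"].idxmin()
        print(f"{name}: min nominal p {table['p'].min():.2e} ({hit}, "
              f"beta {table.loc[hit, 'beta']:.3f}); "
              f"min adjusted p {table['padj'].min():.3f} -> "
              f"{'no' if table['padj'].min() >= 0.05 else 'some'} "
              f"genome-wide-significant associations")

    counts = io.read_counts(args.prepdir / "counts_preprocessed.tsv")
    de_genes = (args.dgedir / "de_genes_ranked.txt").read_text().split()
    factors = preprocess.size_factors(counts)
    table, confounded = covariates.confound_check(
        counts[cases.index], de_genes, cases["hv_cortical"], rin,
        size_factors=factors[cases.index])
    io.write_table(table.round(6), args.outdir / "confound_check.tsv",
                   index=True)
    print(f"confound check on {len(de_genes)} DE genes: "
          f"{'CONFOUNDED' if confounded else 'no gene'} associated with "
          f"cortical involvement after FDR adjustment "
          f"(min padj {table['padj'].min():.3f})")


if __name__ == "__main__":
    main()
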