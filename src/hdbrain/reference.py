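"""Published reference values bundled as worked-example inputs.

Three small tables from a published post-mortem HD prefrontal-cortex (BA9)
RNA-seq study of 20 HD cases and 49 controls ship with the package:

* the HD cohort clinical table (PMI, age at death, RIN, onset, duration,
  CAG repeat length, Vonsattel grade, H-V striatal/cortical scores);
* the top 20 DE genes ranked by significance;
* the top 20 DE genes ranked by DES.

They serve as ground truth for the DES arithmetic (the printed tables
include the score alongside its inputs) and for table-level descriptive
checks; they are inputs, not outputs, of this package.

The study also reports 3,004 up- vs 2,476 down-regulated genes among its
5,480 DE genes (28,087 detected) — bundled here for the up-fraction
worked example.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

UP_REGULATED_DE_GENES = 3004
DOWN_REGULATED_DE_GENES = 2476


def _load(name: str, **kwargs) -> pd.DataFrame:
    ref = resources.files("hdbrain.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def cohort_clinical() -> pd.DataFrame:
    """HD cohort clinical table (20 cases), indexed by sample id."""
    return _load("hd_cohort_clinical.tsv", index_col=0,
                 na_values=["unk"])


def top_genes_by_significance() -> pd.DataFrame:
    """Top 20 published DE genes ranked by adjusted p, with printed DES."""
    return _load("reference_top_genes_by_significance.tsv", index_col=0)


def top_genes_by_des() -> pd.DataFrame:
    """Top 20 published DE genes ranked by DES, with printed DES."""
    return _load("reference_top_genes_by_des.tsv", index_col=0)


def up_regulated_percent() -> float:
    """Percentage of DE genes up-regulated, from the published up/down counts."""
    total = UP_REGULATED_DE_GENES + DOWN_REGULATED_DE_GENES
    return 100.0 * UP_REGULATED_DE_GENES / total
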