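"""Bundled example datasets."""

from __future__ import annotations

from importlib import resources

import pandas as pd


def lld_significant_links(use_abbrev: bool = True) -> pd.DataFrame:
    """The 21 disrupted functional links reported in a late-life
    depression connectome study (disease vs. matched controls, 87-region
    Desikan parcellation, FDR level q = 0.2).

    Columns: ``region1, region2, tF`` — region names (abbreviated by
    default) and the signed FC group-difference statistic; positive means
    hyperconnectivity in the patient group.  Used as the worked example
    for the network/hub summaries.
    """
    with resources.files("mmlfdr.data").joinpath("lld_significant_links.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    if use_abbrev:
        df = df.rename(columns={"region1": "name1", "region2": "name2",
                                "abbrev1": "region1", "abbrev2": "region2"})
    return df[["region1", "region2", "tF"]]
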