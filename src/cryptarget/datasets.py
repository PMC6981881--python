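"""Packaged published reference tables: the printed duplex rows and trans-screen correlations.

``load_published_duplexes`` returns the 24 printed (miRNA, target-region,
pairing) rows for the mature miRNA novel-m3234-5p; the accompanying text
speaks of 25 targeted genes, but only 24 rows survive in the printed table,
so 24 is what ships. ``load_published_trans`` returns the nine
lincRNA-sjCRY-DASH Pearson correlations (all above 0.99).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_published_duplexes", "load_published_trans", "PUBLISHED_MIRNA_SEQ"]

PUBLISHED_MIRNA_SEQ = "UCCAGCCCGGCGUUGAUGGC"


def _load(name: str) -> pd.DataFrame:
    with resources.as_file(resources.files("cryptarget.data") / name) as path:
        return pd.read_csv(path, sep="\t")


def load_published_duplexes() -> pd.DataFrame:
    """Columns: mirna_id, target_id, target_region_3to5, pairing, mirna_seq."""
    return _load("table2_duplexes.tsv")


def load_published_trans() -> pd.DataFrame:
    """Columns: lncrna_id, classification, target_id, correlation."""
    return _load("table1_trans.tsv")
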