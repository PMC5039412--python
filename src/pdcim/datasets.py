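"""Packaged reference ranking lists used for precision evaluation.

Four published top-20 drug-disease ranking lists are shipped as small TSV
fixtures: the lists produced for the three highest-scoring module pairs on
the original SIDER/CTD corpus, and the top-20 list of the PREDICT
similarity-fusion method used as a comparison baseline. Each row carries
its curated mark (M, T, M&T, inferred or none), which is all
precision-at-n needs.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_FILES = {
    1: "reported_top20_pair1.tsv",
    2: "reported_top20_pair2.tsv",
    3: "reported_top20_pair3.tsv",
    "baseline": "reported_top20_baseline.tsv",
}


def load_reported_ranking(which) -> pd.DataFrame:
    """Load one packaged top-20 ranking list.

    Parameters
    ----------
    which : {1, 2, 3, "baseline"}
        Module-pair rank of the list, or ``"baseline"`` for the comparison
        method's list.
    """
    try:
        fname = _FILES[which]
    except KeyError:
        raise ValueError(f"which must be one of {sorted(_FILES, key=str)}") from None
    ref = resources.files("pdcim").joinpath("data", fname)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype={"curated_mark": str})
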