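"""Small packaged datasets.

``load_promdmeg_table`` returns the published set of 34 promoter-DMR ×
differentially-expressed-gene pairs from a grapevine cell-culture carbon
depletion study (gene id, chromosome, expression log2 fold change G−
vs G+, promoter-DMR methylation difference, cytosine context).  Two rows
share a gene: that gene carries two distinct promoter DMRs.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_promdmeg_table"]


def load_promdmeg_table() -> pd.DataFrame:
    with resources.files("methylflux.data").joinpath("promdmeg_34.csv").open() as fh:
        return pd.read_csv(fh)
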