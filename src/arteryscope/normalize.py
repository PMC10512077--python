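"""Upper-quartile (Q3) normalization of the filtered count matrix.

Each ROI is scaled so that its upper-quartile count over retained gene
targets lands on a common anchor — by default the geometric mean of the
per-ROI Q3 values (the platform convention), optionally a fixed anchor of 1.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
import pandas as pd


def q3_normalize(
    counts: pd.DataFrame, anchor: str = "geomean"
) -> Tuple[pd.DataFrame, pd.Series]:
    """Return (normalized matrix, per-ROI factors).

    ``counts`` must already be QC- and target-filtered (genes x ROIs, no
    negative probes). factor = Q3(ROI) / anchor; normalized = count / factor,
    so every ROI's post-normalization Q3 equals the anchor.
    """
    q3 = counts.quantile(0.75, axis=0, interpolation="linear")
    zero = q3.index[q3 <= 0]
    if len(zero):
        raise ValueError(f"ROI(s) with non-positive Q3: {list(zero)}")
    if anchor == "geomean":
        target = float(np.exp(np.log(q3).mean()))
    elif anchor == "one":
        target = 1.0
    else:
        raise ValueError(f"unknown anchor {anchor!r}; use 'geomean' or 'one'")
    factors = q3 / target
    normalized = counts.div(factors, axis=1)
    return normalized, factors.rename("factor")
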