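"""Published reference panel of colicin cross-induction response ratios.

Measured response ratios (induced RLU over non-induced control) of eight lux
reporter strains — seven carrying colicin promoters plus a promoterless
control — challenged with extracts of seven colicinogenic strains and a
colicin-free isogenic host (BZB).  Values are means with standard deviations
over replicated plate-reader experiments.

The panel is the standard worked input for :mod:`colicomp.assays`: calling
induction at the conventional response-ratio threshold of 2 yields one
induced reporter for the ColE6 extract (the divergent-promoter Lum-Ib
reporter), no calls for the toxin-free control, and 36 calls over the full
7 x 7 reporter-by-colicin block.
"""

from __future__ import annotations

import pandas as pd

from .assays import ResponseTable

__all__ = ["reference_response_panel", "REFERENCE_ASSAY_DILUTIONS"]

_COLUMNS = ["ColE2", "ColE7", "ColE6", "ColD", "ColA", "ColK", "ColIb", "BZB"]
_ROWS = [
    "Lum-E2", "Lum-E7", "Lum-E6", "Lum-D", "Lum-A", "Lum-K", "Lum-Ib", "Lum-P(-)",
]

# mean response ratios, rows = reporters, columns = inducing extracts
_MEANS = [
    [126.9, 141.8, 1.2, 42.0, 1.5, 5.2, 9.4, 1.1],
    [135.9, 140.5, 1.3, 55.5, 1.5, 2.8, 15.0, 1.0],
    [67.8, 94.3, 1.1, 36.6, 1.3, 3.4, 11.0, 1.0],
    [107.8, 117.5, 1.0, 48.0, 2.1, 2.1, 9.2, 1.0],
    [91.9, 103.0, 1.4, 56.6, 1.6, 2.2, 13.0, 1.0],
    [88.2, 109.7, 1.4, 44.0, 1.6, 3.3, 9.0, 1.0],
    [44.5, 42.4, 3.5, 11.7, 1.1, 1.7, 2.3, 0.9],
    [1.8, 1.6, 0.9, 1.8, 1.1, 1.6, 1.3, 1.0],
]

_SDS = [
    [5.9, 2.7, 0.05, 4.4, 0.1, 0.5, 0.8, 0.10],
    [9.2, 2.1, 0.2, 8.9, 0.2, 0.3, 3.2, 0.07],
    [2.2, 4.3, 0.1, 0.4, 0.1, 0.6, 0.3, 0.05],
    [5.4, 2.0, 0.05, 6.0, 0.3, 0.5, 0.4, 0.05],
    [7.4, 4.4, 0.35, 4.1, 0.2, 0.3, 1.3, 0.02],
    [4.5, 5.2, 0.5, 2.5, 0.1, 0.5, 2.4, 0.03],
    [7.0, 9.0, 0.25, 1.8, 0.2, 0.7, 0.1, 0.30],
    [0.5, 0.7, 0.04, 0.1, 0.1, 0.04, 0.15, 0.00],
]

#: Extract dilution at which each colicin was assayed (the working
#: concentration of the reporter experiment, not the spot titer).
REFERENCE_ASSAY_DILUTIONS = {
    "ColE2": 3e-6, "ColE7": 3e-3, "ColE6": 3e-5, "ColD": 3e-2,
    "ColA": 3e-2, "ColK": 8e-4, "ColIb": 4e-1, "BZB": 1.0,
}


def reference_response_panel() -> ResponseTable:
    """The published reference panel as a :class:`ResponseTable`."""
    data = pd.DataFrame(_MEANS, index=_ROWS, columns=_COLUMNS)
    sd = pd.DataFrame(_SDS, index=_ROWS, columns=_COLUMNS)
    return ResponseTable(
        data=data, sd=sd, control_column="BZB", promoterless_row="Lum-P(-)"
    )
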