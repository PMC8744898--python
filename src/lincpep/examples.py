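"""Published worked example: the six liver-cancer-specific lincRNAs.

The screen's reference publication prints a six-transcript table of
hepatocellular-carcinoma-specific lincRNAs, each with zero FPKM in normal
liver, its FPKM in the HepG2 tumor line, and its count of ORFs longer than
50 aa.  It is bundled here as a desk-checkable worked example for the
exclusivity filter.
"""

from __future__ import annotations

import pandas as pd

from .io_formats import ExpressionMatrix, SampleInfo

__all__ = ["HCC_LINCRNA_TABLE", "hcc_expression_matrix"]

#: (transcript_id, liver FPKM, HepG2 FPKM, number of ORFs > 50 aa)
HCC_LINCRNA_TABLE: tuple[tuple[str, float, float, int], ...] = (
    ("NONHSAT226968.1", 0.0, 104.9, 2),
    ("NONHSAT013026.2", 0.0, 61.3, 2),
    ("NONHSAT250607.1", 0.0, 39.3, 2),
    ("NONHSAT142412.2", 0.0, 30.5, 12),
    ("NONHSAT115455.2", 0.0, 15.0, 2),
    ("NONHSAT168790.1", 0.0, 13.7, 3),
)


def hcc_expression_matrix() -> ExpressionMatrix:
    """The published six-transcript table as a two-sample expression matrix."""
    ids = [row[0] for row in HCC_LINCRNA_TABLE]
    values = pd.DataFrame(
        {
            "liver": [row[1] for row in HCC_LINCRNA_TABLE],
            "HepG2": [row[2] for row in HCC_LINCRNA_TABLE],
        },
        index=ids,
    )
    meta = {
        "liver": SampleInfo(role="normal_tissue", tissue="liver"),
        "HepG2": SampleInfo(role="tumor", tissue="hepatoma"),
    }
    return ExpressionMatrix(values, meta)
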