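"""Published QC measurements used as worked-example estimator inputs.

These are NGS-derived percentages reported for a constructed semi-synthetic
scFv phage-display library built with non-combinatorial CDR design (the
design approach this package implements), plus the design-table totals and
the array-synthesis pool capacity of that build.  They are desk inputs for
the functional-fraction and PTM-free estimators and for the worked examples;
nothing in the package derives them.
"""

from __future__ import annotations

#: Per-region percentage of extracted CDRs that were in frame.
LIBRARY_IN_FRAME_PCT: dict[str, float] = {
    "H1": 91.3, "H2": 89.7, "H3": 90.3,
    "K1": 92.2, "K2": 91.6, "K3": 93.2,
    "L1": 91.5, "L2": 78.7, "L3": 90.7,
}

#: Per-region percentage of library CDR sequences carrying >=1 PTM motif.
LIBRARY_TOTAL_PTM_PCT: dict[str, float] = {
    "H1": 1.36, "H2": 5.44, "H3": 5.87,
    "K1": 3.60, "K2": 3.58, "K3": 2.32,
    "L1": 6.16, "L2": 10.48, "L3": 4.81,
}

#: Same quantity measured on natural human antibody CDRs, for contrast.
NATURAL_TOTAL_PTM_PCT: dict[str, float] = {
    "H1": 1.09, "H2": 36.70, "H3": 32.92,
    "K1": 12.55, "K2": 1.23, "K3": 15.56,
    "L1": 8.08, "L2": 1.13, "L3": 20.70,
}

#: Designed totals per region in that build (redundancy included).
DESIGN_TOTALS: dict[str, int] = {
    "H1": 1500, "H2": 1500, "H3": 7836,
    "K1": 1500, "K2": 1000, "K3": 1500,
    "L1": 1500, "L2": 1000, "L3": 1500,
}

#: Maximum oligonucleotides per array-synthesis pool in that build.
POOL_CAPACITY = 3918
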