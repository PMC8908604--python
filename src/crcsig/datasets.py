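"""Built-in reference inputs.

The printed cross-tabulation of a large mixed primary/metastatic colorectal
cancer cohort (2250 tumors classified into CMS1-4 plus CMS-NA) is
reconstructed here at the sample level from its published counts, so the
summary-table machinery can be exercised and checked against the printed
percentages without any external download. Only the cross-tabulated fields
are populated (class label, sex, site, primary stage); everything else is
absent. Two samples carry missing fields forced by the printed marginals:
one CMS2 sample lacks sex (F 283 + M 391 = 674 of 675) and one CMS-NA
sample lacks site information (65+240+...+107+130 = 2249 of 2250).
"""

from __future__ import annotations

import pandas as pd

from .stats import ClinicalTable

__all__ = ["reference_crosstab"]

# class -> (N, F, M, metastatic, primary, stage I, II, III, IV, stage-NA)
_REFERENCE_COUNTS = {
    "CMS1": (305, 182, 123, 65, 240, 38, 108, 69, 18, 7),
    "CMS2": (675, 283, 391, 276, 399, 84, 130, 138, 32, 15),
    "CMS3": (347, 176, 171, 39, 308, 82, 78, 105, 29, 14),
    "CMS4": (685, 316, 369, 277, 408, 38, 132, 167, 52, 19),
    "CMS-NA": (238, 109, 129, 107, 130, 24, 33, 57, 12, 4),
}

_STAGE_ORDER = ("I", "II", "III", "IV", None)


def reference_crosstab() -> tuple[ClinicalTable, pd.Series]:
    """Sample-level reconstruction of the reference cohort cross-tabulation.

    Returns a (clinical table, CMS label Series) pair whose per-class
    counts of sex, metastatic/primary site and primary stage match the
    published table exactly. Sex is assigned independently of site within
    each class (the published table reports only the class-wise margins).
    """
    rows = []
    for cls, (n, f, m, met, prim, s1, s2, s3, s4, sna) in _REFERENCE_COUNTS.items():
        site: list = ["metastatic"] * met
        for stage, count in zip(_STAGE_ORDER, (s1, s2, s3, s4, sna)):
            site += [("primary", stage)] * count
        site += [None] * (n - met - prim)  # samples with unknown site
        sex: list = ["F"] * f + ["M"] * m + [None] * (n - f - m)
        for i, (sx, st) in enumerate(zip(sex, site)):
            if isinstance(st, tuple):
                site_type, stage = st
            else:
                site_type, stage = st, None
            rows.append(
                {
                    "sample_id": f"{cls.replace('-', '')}_{i:04d}",
                    "cms": cls if cls != "CMS-NA" else "NA",
                    "sex": sx,
                    "site_type": site_type,
                    "stage": stage,
                }
            )
    df = pd.DataFrame(rows).set_index("sample_id")
    labels = df.pop("cms")
    return ClinicalTable(df=df), labels
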