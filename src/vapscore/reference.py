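"""Published ultrasound cross-tables as in-memory reference inputs.

The source study printed, for its 84 examined patients, the VAP / no-VAP
counts of every lung-ultrasound feature level.  Those counts fully
determine the per-feature contingency tables, so they serve as exact
inputs for re-deriving the odds ratios and the point table.
"""

from __future__ import annotations

import pandas as pd

from .derivation import ContingencyTable

#: Per-level 2×2 counts (level vs reference, VAP vs no-VAP) as printed.
PUBLISHED_CONTINGENCIES: dict[str, ContingencyTable] = {
    "subpleural": ContingencyTable(1, 7, 1, 7),
    "lobar": ContingencyTable(47, 21, 1, 7),
    "bilateral": ContingencyTable(7, 13, 1, 7),
    "unilateral": ContingencyTable(41, 15, 1, 7),
    "size_lt15": ContingencyTable(1, 7, 1, 7),
    "size_15_20": ContingencyTable(8, 9, 1, 7),
    "size_gt20": ContingencyTable(39, 12, 1, 7),
    "static_bronchogram": ContingencyTable(10, 19, 1, 14),
    "dynamic_bronchogram": ContingencyTable(38, 2, 1, 14),
}

#: Printed cohort size and confirmed-VAP count.
N_SUSPECTED = 108
N_CONFIRMED = 51
N_EXAMINED = 84


def reference_lus_cohort() -> pd.DataFrame:
    """An 84-patient cohort whose per-feature cross-counts equal the
    published tables exactly.

    The joint distribution of the four findings was not published; features
    are laid out independently within each outcome group, subject to the
    structural constraint that patients without a consolidation have no
    size, laterality or bronchogram.  Every single-feature contingency
    table therefore reproduces the printed counts.  Non-ultrasound columns
    hold neutral placeholder values.
    """
    def rows(vap: int, spec):
        out = []
        for ctype, size, lat, bronch, count in spec:
            for _ in range(count):
                out.append({
                    "vap_confirmed": vap,
                    "temperature_c": 37.0,
                    "wbc_per_mm3": 8000,
                    "band_forms_per_mm3": 0,
                    "pf_ratio": 300,
                    "ards": 0,
                    "secretions": "absent_minimal",
                    "radiography": "no_infiltrate",
                    "microbiology": "negative",
                    "pct_ng_ml": pd.NA,
                    "lus_performed": 1,
                    "consolidation_type": ctype,
                    "size_band": size,
                    "laterality": lat,
                    "bronchogram": bronch,
                })
        return out

    # VAP, n=49: types 1/1/47; among the 48 consolidated patients:
    # sizes 1/8/39, laterality 7/41, bronchogram 10 static / 38 dynamic.
    vap_types = ["subpleural"] + ["lobar"] * 47
    vap_sizes = ["lt15"] + ["s15to20"] * 8 + ["gt20"] * 39
    vap_lats = ["bilateral"] * 7 + ["unilateral"] * 41
    vap_bronchs = ["static"] * 10 + ["dynamic"] * 38
    vap_spec = [("none", "none", "none", "none", 1)] + [
        (t, s, l, b, 1) for t, s, l, b in zip(vap_types, vap_sizes, vap_lats, vap_bronchs)
    ]
    # no-VAP, n=35: types 7/7/21; among the 28 consolidated:
    # sizes 7/9/12, laterality 13/15, bronchogram 7 none / 19 static / 2 dynamic.
    no_types = ["subpleural"] * 7 + ["lobar"] * 21
    no_sizes = ["lt15"] * 7 + ["s15to20"] * 9 + ["gt20"] * 12
    no_lats = ["bilateral"] * 13 + ["unilateral"] * 15
    no_bronchs = ["none"] * 7 + ["static"] * 19 + ["dynamic"] * 2
    no_spec = [("none", "none", "none", "none", 7)] + [
        (t, s, l, b, 1) for t, s, l, b in zip(no_types, no_sizes, no_lats, no_bronchs)
    ]
    df = pd.DataFrame(rows(1, vap_spec) + rows(0, no_spec))
    df.insert(0, "patient_id", [f"R{i:03d}" for i in range(len(df))])
    return df
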