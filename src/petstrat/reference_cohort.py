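"""Published cohort-level summary used as a worked example and report fixture.

Whole-burden FDG-PET parameters (cohort means at baseline and at the
3-month follow-up scan, and the reported percent change) from an
18-patient cohort of advanced medullary thyroid cancer treated with
vandetanib.  The change column is defined by
((follow-up / baseline) − 1) × 100 applied to the cohort means; these rows
fix the layout of the change report and serve as an arithmetic consistency
check of the change formula.  They are cohort-specific summaries, not
reference values for the feature extractors.
"""

from __future__ import annotations

import pandas as pd

from .conventional import percent_change

#: (parameter, baseline mean, follow-up mean, reported change as printed).
#: The change is kept as a string to preserve the reported decimal precision.
COHORT_SUMMARY_ROWS: tuple[tuple[str, float, float, str], ...] = (
    ("suv_max", 7.2, 5.2, "-27.8"),
    ("suv_mean", 3.3, 2.3, "-30.3"),
    ("mtv_ml", 441.1, 340.2, "-22.9"),
    ("tlg", 25782.6, 7427.1, "-71.2"),
    ("std_dev", 1.2, 0.8, "-33.3"),
    ("kurtosis", 0.899, 0.891, "-0.89"),
    ("entropy", 4.1, 3.4, "-17.1"),
    ("homogeneity", 0.4, 0.5, "25"),
    ("busyness", 1.9, 0.5, "-73.7"),
    ("coarseness", 0.12, 0.1, "-16.6"),
    ("complexity", 83.0, 50.5, "-39.2"),
    ("contrast", 13.8, 8.5, "-38.4"),
)

#: The reported Coarseness change (−16.6) is inconsistent with the change
#: formula applied to its reported means, which yields −16.7; presumably a
#: transcription artifact in the source table.
KNOWN_INCONSISTENT_ROWS: frozenset[str] = frozenset({"coarseness"})


def _printed_decimals(text: str) -> int:
    return len(text.split(".")[1]) if "." in text else 0


def check_change_consistency() -> pd.DataFrame:
    """Recompute the change column from the reported means.

    Returns one row per parameter with the computed change rounded to the
    reported precision, the reported value, and whether they agree.
    """
    rows = []
    for name, base, fup, printed in COHORT_SUMMARY_ROWS:
        nd = _printed_decimals(printed)
        computed = round(percent_change(base, fup), nd)
        rows.append(
            {
                "parameter": name,
                "baseline_mean": base,
                "followup_mean": fup,
                "computed_change_pct": computed,
                "reported_change_pct": float(printed),
                "match": computed == float(printed),
            }
        )
    return pd.DataFrame(rows)
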