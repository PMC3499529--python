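"""Published reference values for the Eugenia uniflora leaf sRNA study.

Curated report tables from the original E. uniflora (Myrtaceae) leaf
small-RNA survey that this pipeline re-implements: per-precursor metrics for
the 25 conserved and 17 novel hairpin precursors, the library read-length
accounting, and the small-RNA categorization.  They serve as arithmetic
fixtures: the AMFE/MFEI identities, cohort averages and percentage columns
must be reproducible from these printed numbers by the package's own report
arithmetic.  Printed MFE values are treated as inputs (they came from an
external folding engine with its own parameter set).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Library-level read accounting (redundant reads, 1-44 nt, quality-filtered).
READ_ACCOUNTING = {
    "total": 14_849_131,
    "in_window": 12_759_506,   # 18-25 nt
    "below": 1_554_975,        # <18 nt
    "above": 534_650,          # >25 nt
}

#: Printed integer percentages for the accounting rows.
READ_ACCOUNTING_PERCENT = {"in_window": 86, "below": 10, "above": 4}

#: Small-RNA categorization of the 18-25 nt redundant reads.
SRNA_CATEGORIES = {
    "miRNA": 1_852_722,
    "rRNA": 765_989,
    "tRNA": 67_491,
    "snRNA": 1_555,
    "snoRNA": 859,
    "mtRNA": 159_106,
    "cpRNA": 1_046_305,
    "other": 8_865_479,
}

#: Printed two-decimal percentages for the categorization rows.
SRNA_CATEGORY_PERCENT = {
    "miRNA": 14.52, "rRNA": 6.00, "tRNA": 0.53, "snRNA": 0.01,
    "snoRNA": 0.01, "mtRNA": 1.25, "cpRNA": 8.20, "other": 69.48,
}

#: Cohort averages over the printed precursor metric columns.
COHORT_AVERAGES = {
    "conserved": {"mfe": -66.51, "gc_percent": 47.63, "mfei": -0.94, "n": 25},
    "novel": {"mfe": -137.89, "gc_percent": 42.86, "mfei": -1.05, "n": 17},
}

#: Rows whose printed AMFE is internally inconsistent with the printed
#: length and MFE (100*mfe/length differs by more than 0.01).  For
#: eun-MIR482-1 the printed MFEI does agree with the printed AMFE
#: (-61.43/53.90 -> -1.14), implying the printed length (153) is a typo for
#: 154 (9460/61.43 = 154.0); the AMFE identity is checked on the other rows.
AMFE_INCONSISTENT_ROWS = frozenset({"eun-MIR482-1"})


def load_precursor_table() -> pd.DataFrame:
    """The 42 published precursor rows (conserved + novel) as a DataFrame.

    Columns: name, contig, group, length, gc_percent, mfe, amfe, mfei,
    seq_5p, count_5p, seq_3p, count_3p, total_reads.  'ND' marks an arm with
    no sequenced read.  Decimal columns are read as strings alongside float
    views so exact decimal arithmetic is possible downstream.
    """
    with resources.files("mirseed.data").joinpath(
            "eugenia_precursors.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={
            "gc_percent": str, "mfe": str, "amfe": str, "mfei": str})
    for col in ("gc_percent", "mfe", "amfe", "mfei"):
        df[col + "_f"] = df[col].astype(float)
    return df
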