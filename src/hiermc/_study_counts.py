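"""Published per-year record counts of the study cohort the generator emulates.

The source study reports cumulative training-window totals (2007–2014,
2008–2014, …, 2014) plus a fixed 2015 test year; per-year counts below are
the differences of adjacent windows and sum exactly to every published
column total.
"""

#: year -> (stage 3, stage 4, stage 5) complete-record counts.
YEAR_STAGE_COUNTS: dict[int, tuple[int, int, int]] = {
    2007: (617, 73, 57),
    2008: (2681, 324, 132),
    2009: (4801, 519, 231),
    2010: (7463, 675, 306),
    2011: (10982, 946, 447),
    2012: (13809, 1338, 597),
    2013: (15799, 1477, 704),
    2014: (17273, 1624, 767),
    2015: (8419, 782, 375),
}

#: Total records in the raw extract, before complete-case filtering.
TOTAL_RAW_RECORDS = 120_739

#: Records dropped because at least one pertinent attribute was missing.
INCOMPLETE_RECORDS = 27_521

#: Patients contributing records to the cohort.
N_PATIENTS = 13_111

#: The seven diagnosed-condition features that directly indicate the staged
#: disease and are excluded from modelling.
DISEASE_INDICATOR_CONDITIONS = (
    "CKD stage 2",
    "CKD stage 3",
    "CKD stage 4",
    "End Stage Renal Disease",
    "Chronic Renal Failure",
    "History of renal transplant (situation)",
    "Renal Failure Syndrome",
)
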