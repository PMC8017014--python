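"""Published design tabulation of the motivating prospective cohort.

The study nested 128 matched case-control pairs (100 with metastatic
disease at diagnosis) inside a population cohort of women who donated a
blood sample 0.2-7.2 years before the case's lung-cancer diagnosis.  The
year-binned case counts below are the published design table of that
cohort; they are used as bookkeeping inputs when checking that window
definitions reproduce the stated window occupancies, and as emulation
targets for the synthetic-cohort generator.
"""

from __future__ import annotations

# Cases per whole year between blood draw and diagnosis: bins
# (0,1], (1,2], ..., (7,8] years.
ALL_CASES_BY_YEAR = (15, 17, 11, 18, 25, 26, 10, 6)
METASTATIC_CASES_BY_YEAR = (12, 14, 10, 11, 21, 19, 7, 6)

N_PAIRS = 128
N_METASTATIC = 100
N_IDENTIFIED_CASES = 134  # before laboratory-quality exclusions
DAYS_RANGE = (75.0, 2630.0)  # ~0.2 to ~7.2 years

# Day cutoffs splitting time-to-diagnosis into three near-equal-occupancy
# windows for the curve-group method; window 1 (< c1) is nearest diagnosis.
DEFAULT_CUTOFFS = (1093.0, 1783.0)

# Sliding-window size (consecutive metastatic cases) for the local-in-time
# statistics method.
DEFAULT_LITS_WINDOW = 30


def nonmetastatic_cases_by_year() -> tuple[int, ...]:
    return tuple(a - m for a, m in zip(ALL_CASES_BY_YEAR, METASTATIC_CASES_BY_YEAR))


def nearest_window_occupancy() -> dict[str, int]:
    """Occupancy of the time window nearest diagnosis (< 3 years) implied
    by the year-binned design table, plus the cohort totals."""
    meta_w1 = sum(METASTATIC_CASES_BY_YEAR[:3])
    nonmeta_w1 = sum(nonmetastatic_cases_by_year()[:3])
    return {
        "metastatic_window1": meta_w1,
        "nonmetastatic_window1": nonmeta_w1,
        "total_pairs": sum(ALL_CASES_BY_YEAR),
        "total_metastatic": sum(METASTATIC_CASES_BY_YEAR),
    }
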