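"""Published aggregate counts from a 123-patient aggressive prostate-cancer
cohort, used as worked-example inputs.

Patient-level data for that cohort are not deposited; only group-level counts
were printed.  The counts below are the raw numerators/denominators for the
HRD-score threshold table (cutoff 21) and the zero-score tally, from which the
package's statistics recompute every percentage and the chi-square test.
"""

from __future__ import annotations

__all__ = [
    "N_TOTAL",
    "N_IDCP_POS",
    "N_IDCP_NEG",
    "N_GE21_TOTAL",
    "N_GE21_IDCP_POS",
    "N_GE21_IDCP_NEG",
    "N_GE30_TOTAL",
    "N_ZERO_TOTAL",
    "N_ZERO_IDCP_POS",
    "N_ZERO_IDCP_NEG",
    "HRD21_BY_IDCP_TABLE",
]

N_TOTAL = 123
N_IDCP_POS = 77
N_IDCP_NEG = 46

N_GE21_TOTAL = 65
N_GE21_IDCP_POS = 47
N_GE21_IDCP_NEG = 18
N_GE30_TOTAL = 30

N_ZERO_TOTAL = 9
N_ZERO_IDCP_POS = 3
N_ZERO_IDCP_NEG = 6

# 2 x 2 contingency of HRD score (<21 / >=21) by IDC-P status (without / with)
HRD21_BY_IDCP_TABLE = [
    [N_IDCP_NEG - N_GE21_IDCP_NEG, N_IDCP_POS - N_GE21_IDCP_POS],  # < 21
    [N_GE21_IDCP_NEG, N_GE21_IDCP_POS],  # >= 21
]
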