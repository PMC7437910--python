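"""Published summary tables of the Egyptian water buffalo genome project.

Input data for table-derived arithmetic: the per-run sequencing statistics
of the SOLiD runs deposited under BioProject PRJNA267486 (reads and yields
before and after Q15 trimming) and the RepeatMasker repeat-content totals
(bp per family) for the cattle and Egyptian water buffalo assemblies.
"""
from __future__ import annotations

#: per-run read counts (millions) and yields (Gbp), before (q0) and after
#: (q15) quality trimming; the two mate runs carry 1 kb / 3 kb inserts
RUN_TABLE = {
    "Run1": {"reads_q0": 880, "reads_q15": 565, "yield_q0": 66.0, "yield_q15": 28.815},
    "Run2": {"reads_q0": 778, "reads_q15": 546, "yield_q0": 58.3, "yield_q15": 28.938},
    "Run3_1K": {"reads_q0": 944, "reads_q15": 517, "yield_q0": 56.64, "yield_q15": 24.299},
    "Run4_3K": {"reads_q0": 805, "reads_q15": 400, "yield_q0": 48.3, "yield_q15": 18.8},
}

#: totals over the four runs
TOTAL_READS_Q0_M = 3407
TOTAL_READS_Q15_M = 2028
TOTAL_YIELD_Q0_GB = 229.24
TOTAL_YIELD_Q15_GB = 100.852

#: estimated total scaffold length of the assembly, bp ("about 2.8 Gb")
SCAFFOLD_TOTAL_BP = 2_800_000_000

#: repeat content in bp per family (RepeatMasker), per genome
REPEAT_BP = {
    "cattle": {
        "LINE": 591_242_926,
        "LTR": 125_345_371,
        "SINE": 455_612_491,
        "Simple repeat": 20_557_705,
        "Satellite": 7_090_776,
        "ncRNA": 21_196_503,
        "Others": 55_795_102,
    },
    "buffalo": {
        "LINE": 564_818_087,
        "LTR": 115_039_365,
        "SINE": 443_033_730,
        "Simple repeat": 16_644_633,
        "Satellite": 2_966_452,
        "ncRNA": 5_714_700,
        "Others": 53_967_410,
    },
}

#: published totals of the repeat tables, for conservation checks
REPEAT_TOTAL_BP = {"cattle": 1_276_840_874, "buffalo": 1_202_184_377}

#: approximate genome lengths the repeat fractions were quoted against, bp
GENOME_LEN_BP = {"cattle": 2_800_000_000, "buffalo": 3_050_000_000}
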