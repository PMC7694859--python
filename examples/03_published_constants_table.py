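"""Reproduce a reference PI table from published indexing constants.

Uses the published all-nonsighthound LVDd constants (2.5th percentile
1.17, median 1.38, 97.5th 1.63, exponent 0.322) to print the mean and
95% interval across a body-weight grid — the kind of table a screening
cardiologist reads off during an exam.
"""

import echoref as er
from echoref.reference import ALLOMETRIC_AB, INDEX_CONSTANTS, PI_TABLE_BW_GRID

consts = er.IndexConstants("LVDd", ALLOMETRIC_AB["LVDd"][1],
                           INDEX_CONSTANTS["LVDd"])
table = er.pi_table(consts, PI_TABLE_BW_GRID)
print("LVDd (cm), mean and 95% prediction interval by body weight:")
print(table[["bw_kg", "formatted"]].to_string(index=False))
print()
print("Example reading: a 25 kg dog with LVDd above 4.6 cm is outside the")
print("95% reference band; 1.63 * 25^0.322 = 4.6 cm is the upper bound.")
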