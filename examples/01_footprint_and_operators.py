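"""Build a player's workload footprint and evaluate the classical operators.

Recreates the canonical desk example: a player with three alternating
weeks (1.5 / one-third units, each week summing to 7) followed by a
fourth week that redistributes the same 7 units into the final session.
The weekly acute load, both chronic loads and all three ACWR variants
are computed at the season's final event.
"""

import numpy as np

from fwf.features import (
    acute_workload,
    acwr_coupled,
    acwr_ewma,
    acwr_uncoupled,
    chronic_workload_21,
    chronic_workload_28,
    delta_acw,
)

THIRD = 1.0 / 3.0
week = [1.5, THIRD, 1.5, THIRD, 1.5, THIRD, 1.5]
season = week * 3 + [0, 0, 0, 0, 0, 0, 7]
j = len(season) - 1  # final event

print("weekly acute load AW(j,7)  :", acute_workload(season, j, 7))
print("chronic CW28 (coupled)     :", chronic_workload_28(season, j))
print("chronic CW21 (uncoupled)   :", round(chronic_workload_21(season, j), 4))
print("ACWR coupled               :", acwr_coupled(season, j))
print("ACWR uncoupled             :", round(acwr_uncoupled(season, j), 4))
print("ACWR EWMA (spans 7/28)     :", round(acwr_ewma(season, j), 4))
print("delta-ACW(j, tau=7)        :", delta_acw(season, j, 7))

# Interpretation: all weekly totals are 7 units, so acute equals chronic
# and every flat-window ACWR is exactly 1 — the ratio is blind to how the
# 7 units are distributed inside the week.  The differential operator
# delta-ACW(j,7) = x(j) - x(j-7) = 7 - 1.5 = 5.5 exposes the massive
# single-session spike the ratio cannot see.
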