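"""The four behavioral stress-outcome scores on hand measurements."""

from domhier import coping_score, si_ratio, vigilance_time, wound_score

si = si_ratio(time_present=38.0, time_absent=61.0)
print(f"SI ratio          = {si.si_ratio:.2f}  ({si.outcome}; "
      "susceptible means < 1: the mouse avoids the social target)")

cs = coping_score(n_escape=9, n_fight=3, n_passive=14, n_attacks=26)
print(f"coping score      = {cs:+.2f}  (active minus passive responses "
      "per attack bout; -1 all-passive, +1 all-active)")

ws = wound_score(lower_back_area=1.4, upper_back_wounds=3,
                 tail_wounds=0, abdominal_wounds=6)
print(f"wound score       = {ws}      (0-12: area-binned lower back + "
      "count-binned upper back / tail / abdomen)")

vig = vigilance_time(
    [(10, 24, True, False), (30, 35, True, True), (40, 52, True, False)],
    trial_duration_s=150,
)
print(f"vigilance         = {vig.vigilance_s:.0f} s   (oriented to the "
      "aggressor while outside the interaction zone)")
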