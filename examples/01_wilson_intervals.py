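"""Binomial proportions with continuity-corrected Wilson intervals.

Transparency dashboards report rates like "19 of 24 trials were
prospectively registered" with a 95% interval. The continuity-corrected
Wilson score interval behaves well at extreme rates and tiny denominators,
where the naive normal interval collapses or escapes [0, 1].
"""

from trialaudit import percent_round, wilson_cc_interval

cases = [
    ("DRKS trials started 2006-2008, prospectively registered", 0, 44),
    ("DRKS trials started 2017, prospectively registered", 19, 24),
    ("ClinicalTrials.gov trials started 2006, prospectively registered", 58, 178),
    ("publications reporting the TRN in the abstract", 714, 1895),
]

for label, x, n in cases:
    ci = wilson_cc_interval(x, n)
    print(
        f"{x:>4}/{n:<5} = {percent_round(x / n):>3}%  "
        f"(95% CI {percent_round(ci.lower)}% to {percent_round(ci.upper)}%)  {label}"
    )

print()
print("Note the 0/44 row: the interval is (0%, 10%), not a degenerate point —")
print("zero observed events still leave real uncertainty about the true rate.")
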