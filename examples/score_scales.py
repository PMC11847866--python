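"""Score the four instruments and band the results.

Scores an SDS depression questionnaire, bands a MINISM suicide-risk
total and a PHCSS self-concept total, and prints the clinical categories.
"""

from nssinet import band_minism, phcss_from_total, score_sds

sds = score_sds([3, 2, 3, 3, 2, 3, 3, 3, 2, 3, 3, 3, 3, 2, 3, 3, 3, 3, 3, 3])
print(f"SDS raw total {sds.raw_total} -> standard score {sds.standard_score} "
      f"({sds.band.value})")

risk = band_minism(21)
print(f"MINISM total {risk.minism_total} -> {risk.band.value} suicide risk "
      f"(high_risk flag = {risk.high_risk})")

sc = phcss_from_total(48)
print(f"PHCSS total {sc.phcss_total} -> {sc.category.value} self-concept")

# The standard score is raw x 1.25; 73+ is the severe-depression band,
# MINISM >= 17 is the high-suicide-risk group and PHCSS < 52 is low
# self-concept — the three flags the downstream analysis is built on.
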