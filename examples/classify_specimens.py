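"""Classify individual synovial-fluid specimens with the two-step rule.

Builds three archetypal specimens — a classic primary-OA profile, a
septic-arthritis profile, and a discordant "secondary OA" profile — and
prints each call with its reason code and ratio.
"""

from oadx import DecisionLimits, Specimen, classify_specimen

# COMP gate at the validated 1500 ng/mL; the ratio gate value below is
# ILLUSTRATIVE — the clinically validated ratio limit is unpublished.
limits = DecisionLimits(comp_limit=1500.0, ratio_limit=2.0)

specimens = [
    Specimen(id="primary-oa", comp=3903.5, il8=102.4, diagnosis="OA"),
    Specimen(id="septic", comp=216.0, il8=27598.8, diagnosis="NSA"),
    Specimen(id="secondary-oa", comp=2786.0, il8=1740.3, diagnosis="OA"),
]

for s in specimens:
    r = classify_specimen(s, limits)
    ratio = f"{r.ratio:.2f}" if r.ratio is not None else "n/a"
    print(f"{s.id:>13}: {r.call:<8} reason={r.reason.value:<20} ratio={ratio}")

print(
    "\nA specimen is positive only when COMP exceeds the concentration gate"
    "\nAND the COMP/IL-8 ratio exceeds the ratio gate; 'below_comp_limit'"
    "\nmeans no measurable cartilage deterioration, 'low_ratio' means"
    "\ncartilage damage in a highly inflamed joint (potential secondary OA)."
)
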