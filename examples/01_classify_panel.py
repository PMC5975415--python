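"""Classify one patient's five-marker panel with the 3-of-5 vote.

A marker is positive when it lies outside its reference range on the
malignancy side (CA 125 and beta-2 microglobulin high; transferrin, ApoA1
and prealbumin low); at least three positives flag the mass as high risk.
"""

from miascreen import MarkerPanel, MenopausalStatus, ca125_classify, mia_classify

# A postmenopausal woman: CA 125 is judged against the 35 IU/L cutoff.
panel = MarkerPanel(ca125=48.0, b2m=2.9, transferrin=1.8, apoa1=1.5, prealbumin=0.27)
status = MenopausalStatus.POSTMENOPAUSAL

result = mia_classify(panel, status)
print("per-marker calls:")
for call in result.calls:
    print(f"  {call.marker:12s} {call.value:8.2f}  {'POSITIVE' if call.positive else 'negative'}")
print(f"positive markers: {result.n_positive} of 5")
print(f"panel verdict:    {'HIGH risk of malignancy' if result.high_risk else 'low risk'}")
print(f"CA 125 alone:     {'suspicious' if ca125_classify(panel.ca125, status) else 'not suspicious'}")
# Three markers (CA 125, b2m, transferrin) are positive, so the panel is
# high risk; CA 125 alone is also above its postmenopausal cutoff.
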