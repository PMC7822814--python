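"""Convert fitted T1 relaxation times to oxygen partial pressure.

The PFCE relaxation rate R1 = 1/T1 rises linearly with dissolved oxygen,
so PO2 [mmHg] = 470.81 / T1 [s] - 200.14.
"""

from fluorox import po2_to_t1, t1_to_po2

for t1 in (1.0, 1.66, 2.18, 2.3524):
    print(f"T1 = {t1:6.4f} s  ->  PO2 = {t1_to_po2(t1):8.2f} mmHg")

# the inverse is exact: the simulator uses it to pick a T1 for a target PO2
po2 = 100.0
t1 = po2_to_t1(po2)
print(f"\ntarget PO2 = {po2} mmHg needs T1 = {t1:.5f} s "
      f"(round trip: {t1_to_po2(t1):.10f} mmHg)")

# A T1 near 1.66 s (the wildtype 30%-O2 level) maps to ~84 mmHg of oxygen;
# T1 = 2.3524 s is the calibration's zero crossing: longer T1s imply
# negative, physically impossible PO2 and get QC-flagged downstream.
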