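"""Compute one patient's severity panel from 24 h postoperative physiology.

A patient on moderate inotropic support, nearly weaned from the
ventilator, with a small postoperative creatinine rise.
"""

from vvrkit import DrugDoses, RenalPanel, VentilationParams, score_panel

doses = DrugDoses(dopamine=3.0, milrinone=0.375, norepinephrine=0.05)
vent = VentilationParams(respiratory_rate=14, pip=18, peep=5, paco2=42)
renal = RenalPanel(serum_creatinine_post=1.1, serum_creatinine_baseline=0.9,
                   age=66, weight=72, sex="male")

panel = score_panel(doses, vent, renal)
print(f"VIS    = {panel.vis:7.2f}   (weighted infusion rates)")
print(f"VI     = {panel.vi:7.2f}   (RR x driving pressure x PaCO2 / 1000)")
print(f"dCr    = {panel.delta_cr:7.2f}   mg/dL rise from baseline")
print(f"Ccr    = {panel.ccr:7.2f}   mL/min (Cockcroft-Gault)")
print(f"VVR    = {panel.vvr:7.2f}   = VI + VIS + 10 x dCr")
print(f"M-VVR  = {panel.mvvr:7.2f}   = VI + VIS + Ccr")
# Higher VVR/M-VVR means more multi-organ support; M-VVR sits near 100
# for typical renal function because Ccr enters in mL/min.
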