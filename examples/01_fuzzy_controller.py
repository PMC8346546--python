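"""The cell-decision controller on its own.

Evaluates the stock Mamdani controller for a naive MSC under three Mg2+
conditions and prints the five action intensities. Expect proliferation to
peak in the stimulatory band (around 4.5 mM) and mortality to jump in the
cytotoxic range.
"""

from fuzzymsc import default_controller

controller = default_controller()

cell = dict(maturity=0.05, dna_damage=0.0, alkalinity=0.0,
            bmp2=0.01, tgfb1=0.1, density=0.3)

print(f"{'Mg (mM)':>8} {'prolif':>8} {'mort':>8} {'migr':>8} {'earlyD':>8} {'lateD':>8}")
for mg in (0.8, 4.5, 60.0):
    out = controller.evaluate(mg=mg, **cell)
    print(f"{mg:8.1f} {out.proliferation:8.3f} {out.mortality:8.3f} "
          f"{out.migration:8.3f} {out.early_differentiation:8.3f} "
          f"{out.late_differentiation:8.3f}")

print()
print("Each column is a dimensionless action intensity in [0, 1] that the")
print("event equations scale into per-hour probabilities and rates. The")
print("stimulatory 4.5 mM condition raises proliferation and early")
print("differentiation; 60 mM (cytotoxic, alkaline) suppresses growth and")
print("drives mortality toward its maximum.")
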