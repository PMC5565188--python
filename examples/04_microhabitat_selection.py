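"""Use-versus-availability selection of deposition microhabitats.

The selection index is the percentage of disperser droppings found in a
microhabitat minus its percentage cover: positive = seeds arrive there
more often than random deposition would predict.  Uncertainty comes from
a multinomial bootstrap of the dropping counts.
"""

import seedfate as sf

dataset = sf.study_dataset()
selection = sf.microhabitat_selection(dataset.faeces, dataset.cover, n_boot=2000, seed=0)

print(f"{'microhabitat':<12} {'droppings%':>10} {'cover%':>7} {'index':>7}  95% CI")
for micro, e in selection.entries.items():
    verdict = "+" if e.positively_selected else ("-" if e.negatively_selected else "0")
    print(f"{micro:<12} {e.droppings_pct:>10.1f} {e.cover_pct:>7.1f} {e.index:>+7.1f}  "
          f"[{e.ci_low:+.1f}, {e.ci_high:+.1f}] {verdict}")
# '+' = interval above 0 (preferred), '-' = below 0 (avoided), '0' = random.
# Open ground is strongly preferred for dropping deposition; shrub canopies
# receive fewer droppings than their cover predicts.
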