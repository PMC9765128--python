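"""Split-ratio analysis: who makes and who spends the ATP?

Solves the toy network under aerobic growth on acetate and prints the
metabolite-centric flux ledger at the ATP and NADH nodes: each reaction's
absolute contribution (mmol/gDW/h) and its share of the node's turnover.
"""

import aromflux as af

model = af.make_toy_model()
condition = next(c for c in af.toy_conditions() if c.label == "acetate-aerobic")
bounded = af.apply_condition(model, condition)
solution = af.solve_fba(bounded, condition)

for node in ("atp_c", "nadh_c"):
    table = af.split_ratios(bounded, solution, node)
    print(f"\n{node}: turnover {table.turnover:.2f} mmol/gDW/h")
    print("  producers:")
    for rid, flux, pct in table.producers:
        print(f"    {rid:12s} {flux:8.2f}  ({pct:5.1f} %)")
    print("  consumers:")
    for rid, flux, pct in table.consumers:
        print(f"    {rid:12s} {flux:8.2f}  ({pct:5.1f} %)")

print("\nProducer and consumer shares each sum to 100% — at steady state the "
      "node's production equals its consumption.")
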