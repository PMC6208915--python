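"""Base-case cost-effectiveness of serum endoxifen monitoring.

Traces the lifetime of a cohort of 53-year-old women starting adjuvant
tamoxifen, with and without endoxifen monitoring, and prints the
incremental economics.
"""

import endotdm as e

params, _ = e.load_parameters()          # Table defaults
life_table = e.default_life_table()      # synthetic Dutch-female mortality

engine = e.TraceEngine(params, life_table)
no_tdm, tdm = e.build_strategies(params)

summary_no = e.summarize(engine.trace(params, no_tdm))
summary_tdm = e.summarize(engine.trace(params, tdm))
inc = e.compare(summary_tdm, summary_no, wtp=20_000)

print(f"cycles traced           : {engine.n_cycles} x {params.cycle_length:.0f} days")
print(f"no monitoring           : EUR {summary_no.total_cost:9.0f}   {summary_no.total_qalys:.3f} QALYs")
print(f"endoxifen monitoring    : EUR {summary_tdm.total_cost:9.0f}   {summary_tdm.total_qalys:.3f} QALYs")
print(f"incremental cost        : EUR {inc.delta_cost:9.1f}")
print(f"incremental QALYs       : {inc.delta_qalys:.5f}")
print(f"ICER                    : EUR {inc.icer:,.0f} per QALY ({inc.icer_label})")
print(f"NMB at WTP EUR 20,000   : EUR {inc.nmb:,.1f}")
print()
print("Monitoring moves 18% of the cohort onto the lower recurrence hazard")
print("(HR 0.74), which buys a small QALY gain and avoids enough expensive")
print("recurrent-disease time to more than repay the one or two serum tests:")
print("a negative ICER here means better outcomes at lower cost.")
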