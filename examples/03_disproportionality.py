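"""Reporting odds ratio and information component for single pairs.

The ROR flags a pair when the 95% interval's lower bound is >= 1; the IC
flags when IC025 (the lower credible bound of the shrinkage
observed-to-expected log2 ratio) is > 0.
"""

from pvmlsd import (
    ContingencyTable,
    adjusted_ror,
    contingency_table,
    crude_ror,
    default_config,
    dpa_signal,
    generate_reports,
    information_component,
)

# a textbook table: OR = (10*40)/(20*5) = 4
table = ContingencyTable(10, 20, 5, 40)
ror = crude_ror(table)
ic = information_component(table)
print(f"crude ROR  {ror.estimate:.2f}  (95% CI {ror.ci_low:.2f}–{ror.ci_high:.2f})"
      f"  signal={dpa_signal(ror)}")
print(f"IC         {ic.ic:.2f}  (IC025 {ic.ic025:.2f})  signal={dpa_signal(ic)}")

# the same statistics on a planted pair from the simulator
cfg = default_config(seed=7)
reports, truth = generate_reports(cfg)
drug, term, rr = truth.planted_pairs[0]
t = contingency_table(reports, drug, term, cfg.comparators)
print(f"\nplanted pair ({drug}, {term}), true rate ratio {rr}:")
print(f"  cells a,b,c,d = {t.a}, {t.b}, {t.c}, {t.d}")
print(f"  crude ROR     = {crude_ror(t).estimate:.2f}")
adj = adjusted_ror(reports, drug, term, cfg.comparators,
                   covariates=("sex", "age_group", "serious"))
print(f"  adjusted ROR  = {adj.estimate:.2f}  (covariate-adjusted, case/non-case logit)")
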