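"""Generate a synthetic spontaneous-reporting dataset with planted signals.

The default scenario draws 20,000 reports over one study drug, six
comparators and two therapeutic class-mates, with 30 planted drug–event
associations at rate ratio 5.  A fifth of the planted pairs is deliberately
left off the study drug's reference label — those are the "unknown true
signals" a detection method should rediscover.
"""

from pvmlsd import default_config, generate_reports

cfg = default_config(seed=7)
reports, truth = generate_reports(cfg)

n_study = sum(1 for r in reports if cfg.study_drug in r.suspected_drugs)
print(f"reports drawn:            {len(reports)}")
print(f"naming the study drug:    {n_study}")
print(f"planted associations:     {len(truth.planted_pairs)} (rate ratio 5)")
print(f"held out of the label:    {len(truth.held_out_pairs)}")
print(f"example held-out pair:    {truth.held_out_pairs[0]}")
# The held-out pairs report at five times their baseline rate but are absent
# from the study drug's label, so downstream they land in the unknown set.
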