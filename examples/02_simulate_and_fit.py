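"""Generate synthetic theatre lists and recover the effects by REML.

The generator's defaults encode a 0.39% per-position saving, a 0.98%
saving per same-procedure repetition and a 6.48% switching cost on the
log-duration scale.  The mixed model (random intercept per procedure ×
age × ASA cell) should recover all three within its confidence intervals.
"""

import theatreflow as tf

cfg = tf.GeneratorConfig(seed=7)
raw = tf.generate_dataset(cfg)
clean, summary = tf.clean_records(raw)
coded = tf.assign_list_numbers(tf.build_lists(clean))

print(f"generated {summary.n_input} rows, retained {summary.n_retained} after cleaning")
print(f"switch fraction: {100 * tf.switch_fraction(coded):.1f}%\n")

fit = tf.fit_lmm(coded, outcome="duration")
truth = tf.truth_table(cfg)
for name, true_pct in [
    ("absolute_order", truth["pct_abs"]),
    ("specific_order", truth["pct_spec"]),
    ("switch", truth["pct_switch"]),
]:
    e = fit.effects[name]
    print(
        f"{name:15s} {e.pct:+6.2f}% (95% CI {e.pct_low:+6.2f} to {e.pct_high:+6.2f})"
        f"   generating value {true_pct:+.2f}%"
    )
# Each printed interval is the model's 95% CI for the percent change in
# operating time per unit of that covariate; the generating value should
# fall inside it.
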