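"""Bias-corrected bootstrap mediation: does thalamus connectivity carry the
resilience -> processing-speed association?

Fits the three-regression path model (a, b, c, c') for each candidate
mediator (four regions plus education) and bootstraps the indirect effect
a*b with a bias-corrected 95% percentile interval.
"""

from connmed import RunConfig, run_study

cfg = RunConfig(synthetic=True, seed=0)  # n_boot defaults to 5000
res = run_study(cfg)

cols = ["m", "a", "b", "c", "c_prime", "indirect", "ci_low", "ci_high", "significant"]
print("mediation suite (X = resilience, Y = speed; standardised paths):")
print(res.mediation[cols].round(3).to_string(index=False))

row = res.mediation.set_index("m").loc["Thalamus"]
print(f"\nthalamus: indirect = {row.indirect:.3f}, "
      f"95% BC CI ({row.ci_low:.3f}, {row.ci_high:.3f}), "
      f"direct effect p = {row.p_c_prime:.3f}")
print("a significant positive indirect effect with a nonsignificant direct "
      "effect is the full-mediation pattern planted in the generator: "
      "higher resilience -> lower thalamus degree centrality -> faster "
      "processing speed.")
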