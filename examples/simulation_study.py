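"""A scaled-down run of the one- vs two-stage simulation study.

For a handful of study counts, simulates meta-analyses under the default
mechanism (log-normal study sizes floored at 20, inverse-chi-square residual
variances, tau2 = 1, beta = 0), fits both REML procedures to each dataset
and prints the relative precision gain of two- vs one-stage and the
coverage of the Kenward-Roger 95% intervals.  Gains hover around 0% and
coverage near 95% except for very few studies.
"""

import gaussmeta as gm

summaries = gm.run_simulation_study([3, 5, 10, 20], nsim=200, base_seed=2024)
print("  I   gain%  (MCSE)   cover 2-stage   cover 1-stage")
for s in summaries:
    print(f"{s.I:4d}  {s.precision_gain_pct:+.2f} ({s.precision_gain_mcse:.2f})"
          f"      {100 * s.cover['two_stage']:.1f}%"
          f"          {100 * s.cover['one_stage']:.1f}%")
print("A gain of 0% means the two procedures are equally precise; coverage "
      "is the fraction of intervals containing the true effect 0.")
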