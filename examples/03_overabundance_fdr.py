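"""Overabundance analysis: observed vs expected p-value counts and FDR.

With N features and none truly differential, p-values are uniform and
about N*alpha of them fall below any threshold alpha. Comparing the
observed count k against N*alpha gives the empirical FDR estimate
min(1, N*alpha/k), and a Monte-Carlo envelope of same-size null
experiments shows whether the observed excess is meaningful.
"""

import numpy as np

from lipidiff import fdr_estimate, format_fdr, make_overabundance_curve
from lipidiff.plotting import plot_overabundance

# With 168 tested lipids and 18 observed below p = 0.05, about 8.4 null
# discoveries are expected, so roughly half the discoveries may be false:
for alpha, k in [(0.05, 18), (0.01, 6), (0.001, 2)]:
    print(f"N=168, alpha={alpha}, observed={k}: FDR = {format_fdr(fdr_estimate(168, alpha, k))}")

# Full curve from a p-value collection with some planted signal:
rng = np.random.default_rng(1)
p_values = np.concatenate([rng.random(148), rng.random(20) * 1e-3])
curve = make_overabundance_curve(p_values, n_null_replicates=2000, seed=1)
for alpha, obs, exp, fdr in zip(
    curve.alphas, curve.observed_k, curve.expected_k, curve.fdr_estimates
):
    print(f"alpha={alpha:<7g} observed={obs:<4d} expected={exp:7.2f} FDR~{format_fdr(fdr)}")

plot_overabundance(curve, "overabundance_example.svg", title="planted signal demo")
print("wrote overabundance_example.svg")
# Observed counts far above the expected N*alpha (and above the null
# envelope) at small alpha indicate genuine differential signal.
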