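"""Adjust a small set of raw p-values with all four procedures.

Ten p-values, three of them clearly small.  BH controls the FDR at 5%;
Storey relaxes the BH thresholds by the estimated true-null proportion;
Bonferroni-E(V) caps the *expected count* of false discoveries at gamma;
Bon-EV combines the BH rejection fraction with the pi0 estimate into a
single-step pFDR rule.
"""

from bonev import (
    PValueVector,
    bh_reject,
    bonev_adjust,
    bonferroni_ev_reject,
    pi0_fixed_lambda,
    storey_reject,
)

p = [0.001, 0.004, 0.012, 0.2, 0.3, 0.55, 0.6, 0.7, 0.8, 0.9]
pvals = PValueVector([f"gene{i:02d}" for i in range(1, 11)], p)
alpha = 0.05

pi0 = pi0_fixed_lambda(pvals, lam=0.5)
print(f"pi0_hat = {pi0.pi0:.2f}  (fraction of p-values above lambda=0.5, scaled)")

bonev = bonev_adjust(pvals, alpha, pi0=pi0)
print(
    f"Bon-EV: BH rejection fraction r_hat = {bonev.rejection_fraction_hat:.2f}, "
    f"cutoff = alpha * r_hat / pi0_hat = {bonev.cutoff:.4f}"
)

for res in (
    bh_reject(pvals, alpha),
    storey_reject(pvals, alpha, pi0=pi0),
    bonferroni_ev_reject(pvals, gamma=1.0),
    bonev,
):
    print(f"{res.procedure.value:>13}: {res.n_rejected} rejected")

# The three smallest p-values are called by every procedure here; the
# Bon-EV cutoff (0.015) sits between BH's realized threshold and
# Storey's, which is what buys power without Storey's extra false calls.
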