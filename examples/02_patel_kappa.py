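"""Patel's kappa and its Dirichlet Monte-Carlo significance on 2x2 tables.

kappa measures the excess of the joint alteration probability theta1 over
the independence expectation E, normalized to [-1, 1]; significance is the
posterior probability that kappa > 0 under a flat-prior Dirichlet
posterior of the 4-cell multinomial.
"""

from coalternet import ContingencyCounts, edge_significance, patel_kappa

tables = {
    "perfect co-occurrence": (30, 0, 0, 70),
    "complementary": (0, 50, 50, 0),
    "independent": (15, 15, 15, 15),
    "moderate coupling": (20, 6, 5, 26),
}

for name, (n1, n2, n3, n4) in tables.items():
    cc = ContingencyCounts("a", "b", n1, n2, n3, n4)
    kappa = patel_kappa(cc.thetas())
    res = edge_significance(cc, seed=0, n_samples=10_000)
    print(f"{name:22s} counts={n1:2d}/{n2:2d}/{n3:2d}/{n4:2d} "
          f"kappa={kappa:+.4f}  P(kappa>0)={res.posterior_prob:.4f}  "
          f"significant={res.significant}")
# kappa hits the endpoints +1/-1 exactly on the first two tables, is ~0
# under independence, and the moderate table is flagged significant because
# >=99% of the posterior mass lies above kappa=0.
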