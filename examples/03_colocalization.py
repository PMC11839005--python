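"""Approximate-Bayes-factor colocalization of two association signals.

Simulates summary statistics for a protein and a transcript under three
causal configurations and shows how the posterior mass moves between H4
(one shared causal variant), H3 (two distinct variants) and H0 (nothing).
"""

from plasmanet import coloc_abf, simulate_summary_pair

for scenario in ("shared", "distinct", "null"):
    s1, s2 = simulate_summary_pair(scenario, region_size=50,
                                   n1=5000, n2=5000, effect_z=8.0,
                                   rng_seed=3)
    post = coloc_abf(s1, s2)
    d = post.as_dict()
    top = max(d, key=d.get)
    print(f"{scenario:12s} -> " +
          "  ".join(f"{k}={v:.3f}" for k, v in d.items()) +
          f"   (modal: {top}, colocalized: {post.colocalized})")

print("\nA shared causal variant concentrates posterior mass on PP.H4; "
      "distinct variants on PP.H3; no association on PP.H0. "
      "PP.H4 > 0.5 is the colocalization call.")
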