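"""Extract signatures by NMF, pick the rank, and name them by cosine match.

The cohort is drawn from three known signature profiles; the rank scan
should favor K=3 and each extracted profile should match its generating
reference at cosine near 1.
"""

import sigprog as sp

config = sp.SimulationConfig(seed=2, n_samples=80)
records, _, truth = sp.simulate_cohort(config)
catalog = sp.build_catalog(records)

chosen, diag = sp.select_rank(catalog, 2, 5, n_restarts=6, seed=0)
print("rank scan (error should flatten and stability peak at the true K=3):")
print(diag.round(4).to_string())
print(f"chosen K = {chosen}")

result = sp.factorize(catalog, rank=chosen, n_restarts=10, seed=0)
print(f"KL objective {result.reconstruction_error:.1f} "
      f"after {result.restarts_used} restarts")

panel = sp.make_fixture_panel()
for m in sp.match_panel(result.signatures, panel):
    tag = "novel" if m.novel else f"-> {m.assigned_name}"
    print(f"  {m.extracted_id} {tag} (cosine {m.cosine:.3f})")
# The asterisked names mark re-extracted versions of reference signatures;
# cosines >= 0.99 mean the de-novo profiles are essentially the truth.
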