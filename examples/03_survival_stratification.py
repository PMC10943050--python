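"""Stratify survival by signature exposure at the 20% threshold.

The third signature is simulated as protective (log-hazard -2.5 across
its exposure range), so samples with > 20% relative exposure should show
significantly better survival by the log-rank test.
"""

import sigprog as sp
from sigprog.simulate import simulate_exposure_survival

exposures, clinical = simulate_exposure_survival(
    n_samples=200,
    exposure_alpha=[1.0, 1.0, 1.0],
    exposure_log_hazard=[0.0, 0.0, -2.5],
    seed=3,
)

groups = sp.assign_groups(clinical)
print("five-year outcome groups:", groups["group"].value_counts().to_dict())

res = sp.stratify_by_exposure(exposures.loc["true3"], clinical, threshold=0.20)
print(f"high arm (exposure > 20%): n={res.n_high}, "
      f"median survival {res.median_high and round(res.median_high, 1)} months")
print(f"low arm:                   n={res.n_low}, "
      f"median survival {res.median_low and round(res.median_low, 1)} months")
print(f"log-rank statistic {res.logrank_statistic:.2f}, p = {res.p_value:.2e}")
# p << 0.05 confirms the protective effect; with the effect set to zero the
# same analysis rejects at the nominal 5% rate (see the test suite).
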