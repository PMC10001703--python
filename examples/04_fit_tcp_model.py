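"""Fit a logistic TCP model to simulated lesion responses.

Simulates mRECIST responses from a known dose-response model, refits it by
maximum likelihood, and reads off the 50%-TCP dose — the quantity the
selection pipeline uses as its lesion-eligibility threshold.
"""

import numpy as np

from sirtboost import LogitTCPModel, dose_at_tcp, fit_logit
from sirtboost.phantom import simulate_responses

truth = LogitTCPModel.from_threshold(292.0, slope=0.012)
rng = np.random.default_rng(0)
doses = rng.uniform(0, 700, 400)
records = simulate_responses(doses, truth, seed=1)

fit = fit_logit(records)
d50 = dose_at_tcp(fit.model, 0.5)
print(f"responders: {sum(r.responder for r in records)}/{len(records)}")
print(f"fitted b0={fit.model.b0:.3f}, b1={fit.model.b1:.5f} per Gy "
      f"(converged={fit.converged}, separation={fit.separation})")
print(f"50%-TCP dose: {d50:.1f} Gy "
      f"(truth 292.0, SE {fit.se_dose_at_tcp50():.1f} Gy)")

# The fitted threshold lands within a couple of standard errors of the
# generating 292 Gy; with small separated datasets fit_logit flags the
# separation instead and fit_logit(records, firth=True) keeps it finite.
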