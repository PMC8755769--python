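"""Generate a calibration-driven counterfactual for a normal-class query.

A small pipeline is trained end to end; a normal query is then pushed
toward the abnormal class in latent space under the TraCE objective, and
the decoded counterfactual shows increased lung opacity.
"""

import numpy as np

from tracecf.counterfactual import CFConfig, generate_trace
from tracecf.lbc import LbcConfig, class_probabilities, train_lbc
from tracecf.synthetic import generate_dataset, severity_readout
from tracecf.wae import WAEConfig, encode, train_wae

ds = generate_dataset(300, seed=5)
wae = train_wae(ds, WAEConfig(latent_dim=32, epochs=20, warmup_epochs=5,
                              batch_size=32, lr_schedule={12: 2.0, 17: 5.0}),
                seed=0)
z = encode(wae, ds.images)
model = train_lbc(z, ds.labels, "classification",
                  LbcConfig(f_hidden=(64, 64), g_hidden=(64, 64),
                            epochs=80, min_epochs=40), seed=0)

i = int(np.flatnonzero(ds.labels == 0)[0])
print(f"query: P(abnormal) = "
      f"{class_probabilities(model, z[i])[1]:.3f}, "
      f"lung opacity = {severity_readout(ds.images[i]):.3f}")

result = generate_trace(z[i], 1, model, wae, CFConfig(eta1=0.05))
p = class_probabilities(model, encode(wae, result.x_bar))[1]
print(f"counterfactual: P(abnormal) = {p:.3f}, "
      f"lung opacity = {severity_readout(result.x_bar):.3f}, "
      f"latent displacement = {result.displacement:.2f}")
print("the hypothesis flip is achieved by adding opacity in the lung fields")
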