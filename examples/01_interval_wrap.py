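"""Wrap a small trained network with parameter intervals.

Builds a 3-layer dense ReLU network, wraps it post hoc with +/-5% parameter
intervals, and propagates a batch of inputs.  The printed check shows the
central property of the construction: the interval output [lower, upper]
contains the base prediction, and indeed the output of any network whose
parameters are drawn inside the intervals.
"""

import numpy as np

from innuq import Dense, PredictionNetwork, forward_interval, wrap_network

rng = np.random.default_rng(0)
net = PredictionNetwork([
    Dense(rng.standard_normal((8, 4)) * 0.5, rng.standard_normal(8) * 0.1),
    Dense(rng.standard_normal((6, 8)) * 0.5, rng.standard_normal(6) * 0.1),
    Dense(rng.standard_normal((4, 6)) * 0.5, np.zeros(4),
          activation="identity"),
])

inn = wrap_network(net, init_width=0.05)  # +/- 5% relative interval widths
z = rng.standard_normal((3, 4))
lo, hi, pred = forward_interval(inn, z)

print("input batch shape:", z.shape)
print("mean interval width per output:", np.round((hi - lo).mean(0), 3))
print("base prediction inside interval:",
      bool(np.all(lo <= pred) and np.all(pred <= hi)))

# any parameter selection inside the intervals stays inside the bounds
inside = True
for _ in range(200):
    for lay, wb, bb in zip(net.layers, inn.weight_intervals,
                           inn.bias_intervals):
        lay.W[...] = rng.uniform(wb.lower, wb.upper)
        lay.b[...] = rng.uniform(bb.lower, bb.upper)
    out = net.forward(z)
    inside &= bool(np.all(lo <= out) and np.all(out <= hi))
print("200 random parameter selections inside interval:", inside)
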