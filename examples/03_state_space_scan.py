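"""The linear state-space scan and its four-direction 2D extension.

A scalar system h_t = 0.5 h_{t-1} + x_t, y_t = h_t on the constant input
1,1,1 produces the running geometric sums 1, 1.5, 1.75.  The 2D operator
flattens a feature map along four traversal orders; with per-direction
identity feed-through (A=0, C B=0, D=I) the merged output is exactly four
times the input — each direction contributes one copy.
"""

import numpy as np

import kneemamba as km
from kneemamba.ssm import SSMParams, TokenSequence, SCAN_ORDERS

p = SSMParams(A=[[0.5]], B=[[1.0]], C=[[1.0]], D=[[0.0]])
y = km.ssm_scan(TokenSequence(np.ones((3, 1)), (3, 1)), p)
print("scalar recurrence output:", y.tokens[:, 0])   # [1.0, 1.5, 1.75]

f = km.FeatureMap(np.array([[[1.0, 2.0], [3.0, 4.0]]]))
for order in SCAN_ORDERS:
    print(f"{order:8s} token order:", km.flatten_2d(f, order).tokens[:, 0])

identity = SSMParams(A=np.zeros((2, 2)), B=np.zeros((2, 1)),
                     C=np.zeros((1, 2)), D=np.eye(1))
out = km.ss2d(f, {o: identity for o in SCAN_ORDERS})
print("identity 4-direction merge (= 4x input):")
print(out.values[0])
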