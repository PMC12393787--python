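"""Build the four ablation variants and account for their complexity.

The grid is: plain state-space U-Net (baseline), + channel-attended skips
(ECA), + the parallel local pyramid (MPSK), and the full model.  Parameter
counts are exact; FLOPs are an analytic estimate for one 256x256 forward
pass (convolutions, linear maps and scan recurrences; normalisations and
activations omitted as lower-order terms).
"""

from kneemamba import full_reference
from kneemamba.model import build_variant, variant_grid, complexity_report

for name, cfg in variant_grid(full_reference()).items():
    rep = complexity_report(build_variant(cfg))
    print(f"{name:9s} {rep['parameters_millions']:8.4f} M params   "
          f"{rep['flops_estimate'] / 1e9:6.2f} GFLOPs @ {rep['flops_input_hw']}")
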