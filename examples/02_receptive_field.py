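"""Receptive-field and valid-size arithmetic for encoder traces.

One element of the classical U-Net's deepest encoder feature map can see
at most a 140x140 region of the input — small thyroid glands fit inside
it, but large glands and super-large nodules do not, which motivates
adding global context (ASPP/DASPP) at the bottleneck.  The valid-size
arithmetic reproduces the 572 -> 568 shrink of the first two unpadded
convolutions.
"""

from thyroseg.analysis import (
    Layer,
    receptive_field,
    sru_encoder_trace,
    unet_encoder_trace,
    valid_conv_size,
)

for name, trace in (("U-Net encoder", unet_encoder_trace()),
                    ("SRU-Net encoder", sru_encoder_trace())):
    report = receptive_field(trace)
    print(f"{name}: {len(trace)} spatial layers, "
          f"receptive field {report.receptive_field}x{report.receptive_field}, "
          f"output stride {report.jump}")

print("two unpadded 3x3 convolutions on side 572 ->",
      valid_conv_size(572, [Layer(3), Layer(3)]))
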