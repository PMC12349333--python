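# Detection-head (layer 22) published anchors at nc=60, input 640x640.
# version: 1
model,head_params,head_flops_g
baseline,762244,3.025
pfl-yolo,59861,0.405
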