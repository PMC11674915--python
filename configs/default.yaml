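input_shape:
- 224
- 224
- 3
stem_filters: 32
mim_branch_filters: 64
mim_repeats: 1
post_mim_kernel: 3
post_mim_filters: 128
dseb_filters: 64
se_ratio: 16
cm_h: 256
cm_d: 16
cm_k: 5
cm_p: 2
head_hidden_units: []
n_classes: 3
bias: true
bn_variant: stem
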