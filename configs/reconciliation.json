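{
  "target": 1650020,
  "n_matches": 0,
  "matches": [],
  "nearest_miss": {
    "config": {
      "input_shape": [
        224,
        224,
        3
      ],
      "stem_filters": 32,
      "mim_branch_filters": 64,
      "mim_repeats": 1,
      "post_mim_kernel": 3,
      "post_mim_filters": 128,
      "dseb_filters": 64,
      "se_ratio": 2,
      "cm_h": 256,
      "cm_d": 16,
      "cm_k": 5,
      "cm_p": 2,
      "head_hidden_units": [
        256
      ],
      "n_classes": 3,
      "bias": true,
      "bn_variant": "stem_postmim"
    },
    "count": 1637763,
    "delta": -12257
  }
}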