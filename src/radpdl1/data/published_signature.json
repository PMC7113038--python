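{
  "version": "published-v1",
  "intercept": -1.59423,
  "coefficients": {
    "Texture_GLCM_ASM": -8.49568,
    "Texture_GLRLM_RV": 3.58597,
    "Texture_GLRLM_RE": -5.01416,
    "Texture_GLRLM_SRHGE": 0.05253
  },
  "cutoff": -0.715
}
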