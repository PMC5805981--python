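# VKBL-model parameter template (synthetic placeholder values: all unset).
# Fill every key with the rate constants from the original VKBL model
# publication before loading with titrosc.extended_models.VkblParams.load().
V: null            # system-size analogue
tx_A_free: null    # activator transcription, own promoter free
tx_A_bound: null   # activator transcription, own promoter bound
tx_R_free: null    # inhibitor transcription, promoter free
tx_R_bound: null   # inhibitor transcription, promoter bound
tl_A: null         # activator translation rate
tl_R: null         # inhibitor translation rate
delta_mA: null     # activator mRNA degradation
delta_mR: null     # inhibitor mRNA degradation
delta_A: null      # activator degradation (free and complexed)
delta_R: null      # inhibitor degradation
k_C: null          # titration A + R -> C
kappa_A: null      # activator binding to its own promoter
theta_A: null      # unbinding from its own promoter
kappa_R: null      # activator binding to the inhibitor promoter
theta_R: null      # unbinding from the inhibitor promoter
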