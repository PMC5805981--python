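# KB-model parameter template (synthetic placeholder values: all unset).
# Fill every key with the rate constants from the original KB model
# publication before loading with titrosc.extended_models.KbParams.load().
# Loading fails until every value is set; units are mass-action
# concentration/time units consistent with the system-size analogue V.
V: null            # system-size analogue (molecules per concentration unit)
G_max: null        # number of promoter binding sites for the activator dimer
tx_A: null         # activator mRNA transcription rate (constitutive)
tx_I_free: null    # inhibitor transcription rate, promoter free (G = 0)
tx_I_bound: null   # inhibitor transcription rate, promoter bound (G >= 1)
tl_A: null         # translation rate of activator mRNA
tl_I: null         # translation rate of inhibitor mRNA
delta_rA: null     # activator mRNA degradation rate
delta_rI: null     # inhibitor mRNA degradation rate
delta_A: null      # activator monomer degradation rate
delta_A2: null     # activator homodimer degradation rate
delta_I: null      # inhibitor degradation rate
delta_AI: null     # heterodimer degradation rate
k_dim_f: null      # dimerization 2A -> A2
k_dim_r: null      # dimer dissociation A2 -> 2A
k_het_f: null      # heterodimerization A + I -> AI
k_het_r: null      # heterodimer dissociation AI -> A + I
kappa_b: null      # dimer-promoter association rate (per free site)
theta_b: null      # dimer-promoter dissociation rate (per bound site)
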