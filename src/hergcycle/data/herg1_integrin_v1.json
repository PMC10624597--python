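{
 "name": "herg1_integrin_v1",
 "comment": "Coarse-grained whole-cell network of integrin-driven hERG1 expression, trafficking and hERG1/beta1-integrin complex dynamics. Species suffixed 's' are the active (starred) forms. The transcription reaction r03 carries the gene-dosage scale constant g_dose as unit carrier for k_ie. The activator-inactivation law r19 uses the cooperative form As*(Is)^2; the ternary alternative As*Is*X is selectable in code.",
 "species": [
  {"name": "F", "role": "free fibronectin binding sites", "initial": 0.0},
  {"name": "B", "role": "inactive beta1 integrin", "initial": 0.0},
  {"name": "Bs", "role": "active (FN-bound) beta1 integrin", "initial": 0.0},
  {"name": "M", "role": "herg1 mRNA", "initial": 0.0},
  {"name": "R", "role": "ER core-glycosylated channel (135 kD band)", "initial": 0.0},
  {"name": "G", "role": "Golgi fully-glycosylated channel", "initial": 0.0},
  {"name": "Sc", "role": "surface free channel, closed state", "initial": 0.0},
  {"name": "So", "role": "surface free channel, open state", "initial": 0.0},
  {"name": "X", "role": "hERG1/beta1-integrin complex", "initial": 0.0},
  {"name": "E", "role": "endosomal channel (Rab5-positive)", "initial": 0.0},
  {"name": "A", "role": "activator module, inactive", "initial": 0.0},
  {"name": "As", "role": "activator module, active", "initial": 0.0},
  {"name": "I", "role": "inhibitor module, inactive", "initial": 0.0},
  {"name": "Is", "role": "inhibitor module, active", "initial": 0.0},
  {"name": "N", "role": "internalization module, inactive", "initial": 0.0},
  {"name": "Ns", "role": "internalization module, active", "initial": 0.0}
 ],
 "reactions": [
  {"id": "r01_integrin_activation", "reactants": {"B": 1, "F": 1}, "products": {"Bs": 1}, "modifiers": {}, "rate_constant": "kf0"},
  {"id": "r02_integrin_deactivation", "reactants": {"Bs": 1}, "products": {"B": 1, "F": 1}, "modifiers": {}, "rate_constant": "k_minus_f"},
  {"id": "r03_transcription", "reactants": {}, "products": {"M": 1}, "modifiers": {"Bs": 1}, "rate_constant": "k_ie", "scale_constants": ["g_dose"]},
  {"id": "r04_mrna_decay", "reactants": {"M": 1}, "products": {}, "modifiers": {}, "rate_constant": "k_dm"},
  {"id": "r05_translation", "reactants": {}, "products": {"R": 1}, "modifiers": {"M": 1}, "rate_constant": "k_c"},
  {"id": "r06_translation_boost", "reactants": {}, "products": {"R": 1}, "modifiers": {"M": 1, "As": 1}, "rate_constant": "k_c_plus"},
  {"id": "r07_er_to_golgi", "reactants": {"R": 1}, "products": {"G": 1}, "modifiers": {}, "rate_constant": "k_g"},
  {"id": "r08_er_to_golgi_boost", "reactants": {"R": 1}, "products": {"G": 1}, "modifiers": {"As": 1}, "rate_constant": "k_g_plus"},
  {"id": "r09_golgi_to_membrane", "reactants": {"G": 1}, "products": {"Sc": 1}, "modifiers": {}, "rate_constant": "k_tg"},
  {"id": "r10_golgi_to_membrane_boost", "reactants": {"G": 1}, "products": {"Sc": 1}, "modifiers": {"As": 1}, "rate_constant": "k_tg_plus"},
  {"id": "r11_channel_opening", "reactants": {"Sc": 1}, "products": {"So": 1}, "modifiers": {}, "rate_constant": "k_o"},
  {"id": "r12_channel_closing", "reactants": {"So": 1}, "products": {"Sc": 1}, "modifiers": {}, "rate_constant": "k_o_minus"},
  {"id": "r13_complex_formation", "reactants": {"Sc": 1, "Bs": 1}, "products": {"X": 1}, "modifiers": {}, "rate_constant": "k_on"},
  {"id": "r14_complex_dissociation", "reactants": {"X": 1}, "products": {"Sc": 1, "Bs": 1}, "modifiers": {}, "rate_constant": "k_off"},
  {"id": "r15_internalization", "reactants": {"Sc": 1}, "products": {"E": 1}, "modifiers": {"Ns": 1}, "rate_constant": "k_e"},
  {"id": "r16_recycling", "reactants": {"E": 1}, "products": {"Sc": 1}, "modifiers": {}, "rate_constant": "k_te"},
  {"id": "r17_endosomal_degradation", "reactants": {"E": 1}, "products": {}, "modifiers": {}, "rate_constant": "k_de"},
  {"id": "r18_activator_activation", "reactants": {"A": 1}, "products": {"As": 1}, "modifiers": {"X": 1}, "rate_constant": "k_a"},
  {"id": "r19_activator_inactivation", "reactants": {"As": 1}, "products": {"A": 1}, "modifiers": {"Is": 2}, "rate_constant": "k_a_minus"},
  {"id": "r20_inhibitor_activation", "reactants": {"I": 1}, "products": {"Is": 1}, "modifiers": {"X": 1}, "rate_constant": "k_i"},
  {"id": "r21_inhibitor_relaxation", "reactants": {"Is": 1}, "products": {"I": 1}, "modifiers": {}, "rate_constant": "k_ie_plus"},
  {"id": "r22_internalization_activation", "reactants": {"N": 1}, "products": {"Ns": 1}, "modifiers": {}, "rate_constant": "k_n_plus"},
  {"id": "r23_internalization_relaxation", "reactants": {"Ns": 1}, "products": {"N": 1}, "modifiers": {}, "rate_constant": "k_minus_n"},
  {"id": "r24_internalization_inhibition", "reactants": {"Ns": 1}, "products": {"N": 1}, "modifiers": {"As": 1}, "rate_constant": "k_n"},
  {"id": "r25_direct_degradation", "reactants": {"Sc": 1}, "products": {}, "modifiers": {}, "rate_constant": "k_dd"}
 ]
}
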