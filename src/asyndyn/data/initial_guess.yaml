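# Order-of-magnitude starting values and search bounds for the 20 grouped
# rate constants (units: per second, particle-number mass action).
# Reconstructed from literature anchors; k_l2a_on_dm starts at 1.2x
# k_l2a_on_12 (higher affinity of the DA-modified monomer for Lamp2a).
parameters:
  k_syn_asyn:   {value: 5.0e-3,  lower: 5.0e-4,  upper: 5.0e-2,  free: true}
  k_syn_da:     {value: 1.0e-2,  lower: 1.0e-4,  upper: 1.0e-1,  free: true}
  k_deg_da:     {value: 3.0e-5,  lower: 1.0e-6,  upper: 1.0e-3,  free: true}
  k_mod:        {value: 3.0e-9,  lower: 1.0e-11, upper: 1.0e-6,  free: true}
  k_dim_f:      {value: 5.0e-10, lower: 1.0e-12, upper: 1.0e-7,  free: true}
  k_olig_f:     {value: 2.0e-8,  lower: 1.0e-11, upper: 1.0e-5,  free: true}
  k_dim_d:      {value: 1.0e-5,  lower: 1.0e-8,  upper: 1.0e-2,  free: true}
  k_olig_d:     {value: 1.0e-5,  lower: 1.0e-8,  upper: 1.0e-2,  free: true}
  k_hmw:        {value: 1.0e-10, lower: 1.0e-13, upper: 1.0e-8,  free: true}
  k_l2a_on_12:  {value: 2.0e-8,  lower: 1.0e-10, upper: 1.0e-6,  free: true}
  k_l2a_on_olig: {value: 1.0e-8, lower: 1.0e-11, upper: 1.0e-6,  free: true}
  k_l2a_off:    {value: 1.0e-3,  lower: 1.0e-6,  upper: 1.0e-1,  free: true}
  k_l2a_intern: {value: 1.0e-3,  lower: 1.0e-6,  upper: 1.0e-1,  free: true}
  k_lys_deg:    {value: 1.0e-2,  lower: 1.0e-5,  upper: 1.0,     free: false}
  k_l2a_on_dm:  {value: 2.4e-8,  lower: 1.0e-10, upper: 1.0e-6,  free: true}
  k_auto_in:    {value: 1.0e-6,  lower: 1.0e-9,  upper: 1.0e-4,  free: true}
  k_auto_deg:   {value: 1.0e-4,  lower: 1.0e-7,  upper: 1.0e-2,  free: false}
  k_prot_on:    {value: 1.0e-9,  lower: 1.0e-12, upper: 1.0e-6,  free: true}
  k_prot_deg:   {value: 1.0e-4,  lower: 1.0e-7,  upper: 1.0e-1,  free: true}
  k_prot_hmw:   {value: 1.0e-10, lower: 1.0e-13, upper: 1.0e-8,  free: false}
initial_conditions:
  monomer_total: 2800.0
  dimer_total: 25.0
  oligomer_total: 110.0
  f_mono: 0.95
  f_di: 0.95
  lamp2a: 200.0
  proteasome: 200.0
  da: null
  hmw: 0.0
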