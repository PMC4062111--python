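parameters:
  k_syn_asyn:
    value: 0.0011758748087107977
    lower: 2.3517496174215953e-05
    upper: 0.058793740435539886
    free: true
  k_syn_da:
    value: 0.00739796567497248
    lower: 0.0001479593134994496
    upper: 0.369898283748624
    free: true
  k_deg_da:
    value: 0.00039870739699191313
    lower: 7.974147939838262e-06
    upper: 0.019935369849595656
    free: true
  k_mod:
    value: 1.1416680631908453e-06
    lower: 2.2833361263816908e-08
    upper: 5.7083403159542265e-05
    free: true
  k_dim_f:
    value: 3.214989284233082e-10
    lower: 6.429978568466164e-12
    upper: 1.607494642116541e-08
    free: true
  k_olig_f:
    value: 6.610750485122056e-08
    lower: 1.3221500970244112e-09
    upper: 3.305375242561028e-06
    free: true
  k_dim_d:
    value: 2.7734092943619703e-13
    lower: 5.546818588723941e-15
    upper: 1.3867046471809852e-11
    free: true
  k_olig_d:
    value: 3.8322035478258565e-05
    lower: 7.664407095651714e-07
    upper: 0.0019161017739129282
    free: true
  k_hmw:
    value: 2.811633662360725e-10
    lower: 5.623267324721451e-12
    upper: 1.4058168311803626e-08
    free: true
  k_l2a_on_12:
    value: 8.60512246297803e-08
    lower: 1.721024492595606e-09
    upper: 4.302561231489015e-06
    free: true
  k_l2a_on_olig:
    value: 1.2440065941276e-06
    lower: 2.4880131882552e-08
    upper: 6.220032970638e-05
    free: true
  k_l2a_off:
    value: 9.244231321136748e-05
    lower: 1.8488462642273497e-06
    upper: 0.004622115660568374
    free: true
  k_l2a_intern:
    value: 0.002901327517297907
    lower: 5.802655034595815e-05
    upper: 0.14506637586489535
    free: true
  k_lys_deg:
    value: 0.01
    lower: 0.0002
    upper: 0.5
    free: false
  k_l2a_on_dm:
    value: 1.3537302728844878e-08
    lower: 2.7074605457689756e-10
    upper: 6.768651364422439e-07
    free: true
  k_auto_in:
    value: 7.134831896650129e-16
    lower: 1.426966379330026e-17
    upper: 3.5674159483250646e-14
    free: true
  k_auto_deg:
    value: 0.0001
    lower: 2.0e-06
    upper: 0.005
    free: false
  k_prot_on:
    value: 3.4754523407646627e-15
    lower: 6.950904681529326e-17
    upper: 1.7377261703823312e-13
    free: true
  k_prot_deg:
    value: 0.0007163441305709499
    lower: 1.4326882611418999e-05
    upper: 0.035817206528547495
    free: true
  k_prot_hmw:
    value: 1.0e-10
    lower: 2.0e-12
    upper: 5.0e-09
    free: false
initial_conditions:
  monomer_total: 3399.7951302354177
  dimer_total: 43.81777483385574
  oligomer_total: 91.21008907670208
  f_mono: 1.0
  f_di: 1.0
  lamp2a: 200.0
  proteasome: 200.0
  da: null
  hmw: 0.0
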