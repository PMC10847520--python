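mesh_label,n_elements,probe,value,re_percent_printed
coarse,1500000,nostril_right_velocity,0.305,4.98
coarse,1500000,nostril_right_pressure,101312,0.16
coarse,1500000,nostril_left_velocity,0.735,0.97
coarse,1500000,nostril_left_pressure,101311,0.11
coarse,1500000,choana_velocity,0.270,2.31
coarse,1500000,choana_pressure,101302,0.02
medium,3500000,nostril_right_velocity,0.317,1.24
medium,3500000,nostril_right_pressure,101311,0.08
medium,3500000,nostril_left_velocity,0.740,0.30
medium,3500000,nostril_left_pressure,101310,0.04
medium,3500000,choana_velocity,0.275,0.51
medium,3500000,choana_pressure,101301,0.01
finest,7000000,nostril_right_velocity,0.321,
finest,7000000,nostril_right_pressure,101310,
finest,7000000,nostril_left_velocity,0.742,
finest,7000000,nostril_left_pressure,101309,
finest,7000000,choana_velocity,0.276,
finest,7000000,choana_pressure,101299.992,
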