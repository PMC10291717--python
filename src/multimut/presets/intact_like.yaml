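# Community state with the keystone interaction in place: species-rich,
# strongly coupled layers.
name: intact
n_plants: 37
n_pollinators: 95
n_dispersers: 4
interlayer_fraction: 0.22
n_dispersal_only_plants: 2
activity_sigma: 1.0
events_pollination: 1200
events_dispersal: 400
seed: 0
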