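# Ungulate-invaded community state: fewer species, weaker layer coupling.
name: invaded
n_plants: 24
n_pollinators: 67
n_dispersers: 4
interlayer_fraction: 0.21
n_dispersal_only_plants: 2
activity_sigma: 1.0
events_pollination: 800
events_dispersal: 250
seed: 1
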