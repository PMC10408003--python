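# Default mass-extinction schedule: the Great Oxidation Event plus the
# Big Five macroorganismal extinctions.  Ages in Mya before present;
# the GOE is the only event striking free-living microbes directly.
p: 0.0
q: 1.0
t_origin: 4000
events:
  - {name: GOE,  age_mya: 2450, host_associated: false}
  - {name: O-S,  age_mya: 445,  host_associated: true}
  - {name: D,    age_mya: 375,  host_associated: true}
  - {name: P-Tr, age_mya: 252,  host_associated: true}
  - {name: Tr-J, age_mya: 201,  host_associated: true}
  - {name: K-T,  age_mya: 66,   host_associated: true}
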