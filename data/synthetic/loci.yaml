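loci:
- name: 199/200
  motif_length: 2
- name: 417/418
  motif_length: 2
- name: 464/465
  motif_length: 2
- name: EV1Pm
  motif_length: 2
- name: EV37Mn
  motif_length: 2
- name: EV94Mn
  motif_length: 2
- name: EV96Mn
  motif_length: 2
- name: GATA028
  motif_length: 4
- name: TAA031
  motif_length: 3
- name: GATA053
  motif_length: 4
- name: GATA417
  motif_length: 4
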