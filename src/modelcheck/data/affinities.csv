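ligand_id,kd_molar,temperature_K
QNB,74e-12,298.15
NMQNB,120e-12,298.15
NMS,260e-12,298.15
Atropine,490e-12,298.15
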