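type,epsilon_K,sigma_A,charge
CH4,158.5,3.72,0.0
CH3,108.0,3.76,0.0
CH2,56.0,3.96,0.0
CH,17.0,4.67,0.0
C,0.8,6.38,0.0
Si,22.0,2.30,0.0
O,53.0,3.30,0.0
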