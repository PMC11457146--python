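class,pattern,style,p1,p2,p3,p4
bond,*-*,HARMONIC_BOND,96500,1.54,,
bend,*-CH2-*,HARMONIC_BEND,62500,114.0,,
bend,*-CH-*,HARMONIC_BEND,62500,112.0,,
bend,*-C-*,HARMONIC_BEND,62500,109.47,,
torsion,*-CH2-CH2-*,TRAPPE_DIHEDRAL,0.0,355.03,-68.19,791.32
torsion,*-CH2-CH-*,TRAPPE_DIHEDRAL,-251.06,428.73,-111.85,441.27
torsion,*-CH2-C-*,TRAPPE_DIHEDRAL,0.0,0.0,0.0,461.29
torsion,*-CH-CH-*,TRAPPE_DIHEDRAL,-251.06,428.73,-111.85,441.27
torsion,*-CH-C-*,TRAPPE_DIHEDRAL,0.0,0.0,0.0,461.29
torsion,*-C-C-*,TRAPPE_DIHEDRAL,0.0,0.0,0.0,461.29
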