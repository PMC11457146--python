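# critical constants: Critical Temperature [T], Critical Pressure [Pa], and Acentric factor [-]
0.0
0.0
0.0
# Number Of Atoms
14
# Number Of Groups
1
# Alkane-group
flexible
# number of atoms
14
# atomic positions
0 CH3
1 CH2
2 CH2
3 CH2
4 CH2
5 CH2
6 CH2
7 CH2
8 CH2
9 CH2
10 CH2
11 CH2
12 CH2
13 CH3
# Chiral centers Bond  BondDipoles Bend  UrayBradley InvBend  Torsion Imp. Torsion Bond/Bond Stretch/Bend Bend/Bend Stretch/Torsion Bend/Torsion IntraVDW IntraCoulomb
0 13 0 12 0 0 11 0 0 0 0 0 0 55 0
# Bond stretch: atom n1-n2, type, parameters
0 1 HARMONIC_BOND 96500 1.54
1 2 HARMONIC_BOND 96500 1.54
2 3 HARMONIC_BOND 96500 1.54
3 4 HARMONIC_BOND 96500 1.54
4 5 HARMONIC_BOND 96500 1.54
5 6 HARMONIC_BOND 96500 1.54
6 7 HARMONIC_BOND 96500 1.54
7 8 HARMONIC_BOND 96500 1.54
8 9 HARMONIC_BOND 96500 1.54
9 10 HARMONIC_BOND 96500 1.54
10 11 HARMONIC_BOND 96500 1.54
11 12 HARMONIC_BOND 96500 1.54
12 13 HARMONIC_BOND 96500 1.54
# Bond bending: atom n1-n2-n3, type, parameters
0 1 2 HARMONIC_BEND 62500 114
1 2 3 HARMONIC_BEND 62500 114
2 3 4 HARMONIC_BEND 62500 114
3 4 5 HARMONIC_BEND 62500 114
4 5 6 HARMONIC_BEND 62500 114
5 6 7 HARMONIC_BEND 62500 114
6 7 8 HARMONIC_BEND 62500 114
7 8 9 HARMONIC_BEND 62500 114
8 9 10 HARMONIC_BEND 62500 114
9 10 11 HARMONIC_BEND 62500 114
10 11 12 HARMONIC_BEND 62500 114
11 12 13 HARMONIC_BEND 62500 114
# Torsion: atom n1-n2-n3-n4, type, parameters
0 1 2 3 TRAPPE_DIHEDRAL 0 355.03 -68.19 791.32
1 2 3 4 TRAPPE_DIHEDRAL 0 355.03 -68.19 791.32
2 3 4 5 TRAPPE_DIHEDRAL 0 355.03 -68.19 791.32
3 4 5 6 TRAPPE_DIHEDRAL 0 355.03 -68.19 791.32
4 5 6 7 TRAPPE_DIHEDRAL 0 355.03 -68.19 791.32
5 6 7 8 TRAPPE_DIHEDRAL 0 355.03 -68.19 791.32
6 7 8 9 TRAPPE_DIHEDRAL 0 355.03 -68.19 791.32
7 8 9 10 TRAPPE_DIHEDRAL 0 355.03 -68.19 791.32
8 9 10 11 TRAPPE_DIHEDRAL 0 355.03 -68.19 791.32
9 10 11 12 TRAPPE_DIHEDRAL 0 355.03 -68.19 791.32
10 11 12 13 TRAPPE_DIHEDRAL 0 355.03 -68.19 791.32
# Intra VDW: atom n1-n2
0 4
0 5
0 6
0 7
0 8
0 9
0 10
0 11
0 12
0 13
1 5
1 6
1 7
1 8
1 9
1 10
1 11
1 12
1 13
2 6
2 7
2 8
2 9
2 10
2 11
2 12
2 13
3 7
3 8
3 9
3 10
3 11
3 12
3 13
4 8
4 9
4 10
4 11
4 12
4 13
5 9
5 10
5 11
5 12
5 13
6 10
6 11
6 12
6 13
7 11
7 12
7 13
8 12
8 13
9 13
# Number of config moves
0
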